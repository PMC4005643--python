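# Nearest-neighbor free-energy parameters for intermolecular RNA duplexes
# at 37 C, kcal/mol.  Stack lines give the top-strand doublet read 5'->3'
# and the bottom-strand doublet read 3'->5' (first letters pair, second
# letters pair); the loader applies strand-exchange symmetry automatically.
# Watson-Crick stacks follow Xia et al. (Turner 2004 set); wobble stacks
# follow the published Turner-style G:U set (see docs/methods.md for the
# stated precision).  Loop initiations are tabulated; larger sizes are
# extrapolated logarithmically in code.
#
# Conventions (deliberate, see docs/methods.md): duplex_init and
# terminal_au are 0.0 so reported energies are hybridization energies on
# the RNAhybrid scale; set 4.09 / 0.45 to recover folding-style totals.
stack	AA	UU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	CU	GA	-2.08
stack	CA	GU	-2.11
stack	GU	CA	-2.24
stack	GA	CU	-2.35
stack	CG	GC	-2.36
stack	GG	CC	-3.26
stack	GC	CG	-3.42
stack	AG	UU	-0.55
stack	AU	UG	-1.36
stack	CG	GU	-1.41
stack	CU	GG	-2.11
stack	GA	UU	-1.27
stack	GG	CU	-1.53
stack	GU	CG	-2.51
stack	UG	AU	-1.00
stack	GG	UU	-0.50
stack	GU	UG	1.29
stack	UG	GU	0.30
loop	bulge	1	3.80
loop	bulge	2	2.80
loop	bulge	3	3.20
loop	bulge	4	3.60
loop	bulge	5	4.00
loop	bulge	6	4.40
loop	internal	2	1.50
loop	internal	3	2.00
loop	internal	4	1.10
loop	internal	5	2.00
loop	internal	6	2.00
loop	internal	7	2.10
loop	internal	8	2.30
loop	internal	9	2.40
loop	internal	10	2.50
param	asymmetry	0.60
param	asymmetry_max	3.00
param	terminal_au	0.00
param	duplex_init	0.00
param	max_bulge	15
param	max_internal	30
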