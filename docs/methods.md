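# Methods

## The thermodynamic model

Intermolecular duplexes are scored with a nearest-neighbor free-energy
model at a fixed 37 °C:

```
ΔG = duplex_init
   + Σ stacking terms over consecutive base pairs
   + Σ loop terms (bulge or internal-loop initiation + asymmetry)
   + terminal penalty per helix end closed by A:U or G:U
```

Legal pairs are the Watson–Crick pairs plus G:U wobbles. The dynamic
program (`bulgescan.duplex`, kernel in `bulgescan._dp`, numba-compiled)
considers every antiparallel pairing of the query with a window,
with bulges capped at 15 nt and internal loops at 30 nt total size;
intramolecular structure of either strand is not modelled, and there are
no dangling-end or terminal-mismatch bonuses. Alignments are trimmed to
begin and end on a base pair; a window whose best score is ≥ 0 returns
the "no duplex" sentinel (`None`) rather than raising, so transcriptome
scans never abort.

### Parameter provenance and conventions

* Watson–Crick stacks are the standard Turner-2004/Xia set (e.g.
  5′GC/3′CG = −3.42, 5′GG/3′CC = −3.26 kcal/mol). G:U wobble stacks
  follow the published Turner-style wobble set; because those values were
  transcribed without access to the original tables they should be
  treated as accurate to roughly ±0.3 kcal/mol. No packaged headline
  number depends on a wobble stack.
* Bulge initiations are tabulated for sizes 1–6 (2.8–4.4 kcal/mol;
  a 1-nt bulge retains the stack across it) and internal-loop
  initiations for sizes 2–10; larger loops grow logarithmically with the
  Jacobson–Stockmayer coefficient 1.75·RT. Generic internal-loop values
  for sizes 2 and 3 (1.5 / 2.0 kcal/mol) replace the special 1×1 / 1×2
  tables, whose terminal-mismatch contributions this model deliberately
  omits. Loop asymmetry costs 0.6 kcal/mol per unpaired-nucleotide
  difference, capped at 3.0.
* **Energy scale.** `duplex_init` and the terminal A:U/G:U penalty
  default to **0.0**, so reported energies are *hybridization* energies
  on the scale used by RNAhybrid-like tools: a perfect helix scores the
  bare stacking sum. This convention was chosen because the published
  anchor values this package is checked against were produced on that
  scale (a 21-nt miR398a perfect complement sums to −46.8 kcal/mol,
  matching the ≈ −47 implied by the published MFE and MFE-ratio pair);
  adding the folding-style +4.09 initiation and +0.45 terminal-A:U terms
  would shift every absolute MFE by ≈ +4.5 while leaving rankings nearly
  unchanged. Both scalars are ordinary keys of the parameter file, so a
  folding-style model is one config away (`tests/test_energy.py`
  exercises it).

### Determinism

Among equal-MFE alignments the aligner prefers more base pairs, then
fewer loops, then the 5′-most target start. All generators and the
empirical null take explicit seeds; identical inputs give byte-identical
outputs.

## Site scoring

The classic position-weighted score assigns +1.0 per mismatch, +0.5 per
G:U pair and +1.0 per indel *nucleotide*, doubling every penalty that
falls at miRNA positions 2–13. An n₁×n₂ internal loop is counted as
min(n₁,n₂) mismatches plus |n₁−n₂| indel nucleotides forming one indel
*event*; a bulge is one event of its full length; miRNA positions left
outside the trimmed helix count as mismatches at their own positions.
Target-side indel nucleotides (which have no miRNA position) take the
doubling weight of the base pair flanking the loop on the miRNA-5′
side. The screen thresholds are inclusive: score ≤ 3.5, G:U ≤ 6, indel
events ≤ 1, mismatches ≤ 5. The filter layer never re-aligns; it scores
the MFE-optimal alignment, which is this package's deliberate departure
from edit-distance aligners.

The thermodynamic (bulge) screen requires MFE ratio ≥ 0.8 and at least
one target-side bulge of ≥ 4 nt. Bulges are labelled by the miRNA
position of their 5′-flanking pair: 5prime (≤ 8), central (9–12), 3prime
(≥ 13); labels are descriptive, not filters.

The predicted slice coordinate is the transcript position paired to
miRNA position 10 — the 5′ end of the 3′ cleavage fragment, cleavage
falling between the partners of positions 10 and 11. If either guide
position is unpaired the site is slice-incompetent (`None`), mirroring
the experimental observation that two central mismatches abolish
cleavage.

## Degradome analysis

Reads are mapped by exact sense-strand 20-nt 5′-prefix match;
multi-mapping reads increment every matching locus (no fractional
weights), and `library_size` counts placements, so per-million
normalization sums to exactly 10⁶. Evidence categories follow the
standard degradome convention — with c the raw count at the slice
position, M the transcript maximum and med the median over nonzero
positions: c = 0 → no hit; c = 1 → category 4; c = M unique → 0,
shared → 1; med < c < M → 2; otherwise → 3. The single-read rule takes
precedence over the maximum rules.

The empirical p-value shuffles the miRNA (mononucleotide-preserving
permutation), rescans the same transcriptome and profiles, and applies
the add-one estimator to the count of shuffles achieving a hit at least
as good (category ≤ observed, MFE ratio ≥ observed); its floor is
1/(1+n). This null is a pragmatic stand-in for pipeline-specific p-value
models used by established degradome tools and is not numerically
equivalent to them.

## Synthetic data: what it does and does not establish

`make_site` builds the reverse complement of an miRNA, inserts a
target-side bulge of chosen size between chosen positions (inserted
nucleotides are resampled until they cannot pair with either flanking
miRNA base, preserving the intended architecture; a bulge at a terminal
pair is rejected as a dangling end) and mutates chosen partners to
non-pairing residues. `make_transcriptome` implants such sites into
i.i.d. random transcripts (default GC fraction 0.42, a typical plant
transcript composition; default length 1000 nt). `simulate_degradome`
places `signal_reads` 5′ ends exactly at the true slice position
(default 50) over uniform Poisson background (default 0.01 reads/nt,
read length 20), with no 5′→3′ decay gradient.

A green synthetic test therefore establishes that the aligner, filters,
mapper and categorizer are internally consistent and recover known
ground truth under realistic signal-to-noise; it does not establish
recovery of the exact published transcriptome-wide counts, which depend
on the full *Arabidopsis* transcriptome, miRBase catalogue, nine public
degradome libraries and the original engine's heuristics.

### The packaged BCBP-style site

The natural *BCBP* site's verbatim sequence is not bundled; the packaged
`BCBP_SITE_SYNTHETIC` reconstructs its published architecture (reverse
complement of miR398a, 6-nt bulge between the partners of miRNA
positions 6 and 7, pyrimidine bulge fill) and is named synthetic
everywhere it appears. The natural site additionally carries mismatches
in the miRNA 3′-pairing region that are not modelled because their
positions are not recoverable from the text alone. On this stand-in the
model yields MFE −40.02 kcal/mol and MFE ratio 85.6 %, against published
anchors of −39.5 kcal/mol and 84 % for the natural site — agreement at
the level expected across nearest-neighbor parameter sets, but a
consistency check rather than a sequence-exact reproduction.

## Numerical choices and edge cases

* Energies are float64; optimum selection uses a 10⁻⁹ tie tolerance.
* Scan windows are `query + max_bulge + margin` nt (margin defaults to
  `max_bulge`, so a maximal bulged site always fits) at stride 1
  (results are stride-invariant for implanted sites up to stride 5);
  overlapping window optima are merged greedily, best energy first.
* Degenerate inputs: a query whose perfect-complement MFE is ≥ 0 makes
  the MFE ratio undefined (raises); reads shorter than the mapping
  prefix are skipped and tallied; simulated reads truncated at
  transcript ends are logged.
* The brute-force enumeration oracle in `tests/helpers.py` shares only
  the public scalar accessors with the DP and is feasible to ~9-nt
  duplexes; DP/oracle agreement is exact on 200+ random cases.

## Known limitations

* No target-site accessibility / intramolecular structure, partition
  function, salt or temperature corrections.
* Wobble-stack precision as stated above; absolute MFEs of wobble-rich
  duplexes may deviate by ~1 kcal/mol from reference implementations.
* The classic score convention (indel = 1.0 per nucleotide, events
  counted for the ≤ 1-indel threshold) is the dominant community
  convention but not uniquely defined in the literature this package
  follows; alternative conventions would shift scores of gapped sites.
* The empirical p-value is seed-reproducible but null-model-specific.
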