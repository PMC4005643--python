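"""Packaged reference sequences for the miR398 / BCBP worked example.

miR398a is derived from the published probe sequence by reverse
complement; miR398b and miR398c share it except for a terminal U.  The
BCBP (At5G20230) target-site entry is a SYNTHETIC stand-in: the exact
5'-UTR site sequence is not bundled, so the site is reconstructed from
its published architecture -- the reverse complement of miR398a carrying
a six-nucleotide target-side bulge between the positions pairing miRNA
nucleotides 6 and 7, filled with pyrimidines that cannot pair with the
flanking miRNA bases.  The real site additionally carries mismatches in
the miRNA 3' region that are not modelled here.
"""

from .seqio import NucleotideSequence

#: mature miR398a (reverse complement of the probe CAGGGGTGACCTGAGAACACA)
MIR398A = NucleotideSequence(id="ath-miR398a", residues="UGUGUUCUCAGGUCACCCCUG")

#: mature miR398b/c (terminal U instead of G)
MIR398BC = NucleotideSequence(id="ath-miR398b", residues="UGUGUUCUCAGGUCACCCCUU")

#: synthetic stand-in for the BCBP (At5G20230) 5'-UTR miR398 site:
#: RC(miR398a) = CAGGGGUGACCUGAGAACACA with the hexamer UCUUCC inserted
#: between the nucleotides pairing miRNA positions 7 and 6
BCBP_SITE_SYNTHETIC = NucleotideSequence(
    id="BCBP_site_synthetic", residues="CAGGGGUGACCUGAGUCUUCCAACACA"
)
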