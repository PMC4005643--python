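>BCBP_site_synthetic synthetic stand-in for the At5G20230 5'-UTR miR398 complementary site (6-nt target-side bulge between miRNA positions 6 and 7)
CAGGGGUGACCUGAGUCUUCCAACACA
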