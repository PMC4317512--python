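locus_id	genotype
qGY-psr-2D.1	CC
qGY-psr-3A.2	CC
qGY-psr-3B.2	AA
qTGW-psr-5A.1	CC
qGRL-psr-5A.1	CC
qGRW-psr-5A.2	AA
qPH-psr-2A.1	AA
qPH-psr-3A	AA
qPH-psr-3B.1	CC
qPH-psr-4D	AA
qPH-psr-5A.1	AA
qEM-psr-1B.2	CC
qEM-psr-1D.1	AA
qEM-psr-5A	CC
qEM-psr-6A.1	AA
Vrn-A1b	AA
qTRSA-2A	CC
qSDW-5A	CC
qTRL-5B	CC
qTRL-6A	AA
Sbm1-5D	CC
Yr6	CC
Yr7	CC
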