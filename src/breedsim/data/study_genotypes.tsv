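locus_id	DH27	DH61	DH182	DH109	DH160	Avalon	Cadenza
qGY-psr-2D.1	CC	AA	CC	CC	AA	AA	CC
qGY-psr-3A.2	AA	CC	AA	CC	AA	AA	CC
qGY-psr-3B.2	CC	AA	AA	AA	AA	AA	CC
qTGW-psr-5A.1	CC	AA	CC	AA	CC	AA	CC
qGRL-psr-5A.1	CC	AA	CC	CC	CC	AA	CC
qGRW-psr-5A.2	AA	AA	AA	AA	CC	AA	CC
qPH-psr-2A.1	CC	AA	AA	CC	AA	AA	CC
qPH-psr-3A	AA	AA	CC	AA	AA	AA	CC
qPH-psr-3B.1	CC	CC	AA	CC	AA	AA	CC
qPH-psr-4D	AA	AA	AA	AA	AA	AA	CC
qPH-psr-5A.1	CC	AA	CC	AA	CC	AA	CC
qEM-psr-1B.2	CC	AA	CC	CC	CC	AA	CC
qEM-psr-1D.1	AA	AA	AA	AA	AA	AA	CC
qEM-psr-5A	AA	CC	AA	AA	CC	AA	CC
qEM-psr-6A.1	CC	AA	AA	CC	AA	AA	CC
Vrn-A1b	CC	AA	AA	CC	AA	AA	CC
qTRSA-2A	CC	AA	CC	AA	CC	AA	CC
qSDW-5A	CC	AA	CC	CC	CC	AA	CC
qTRL-5B	CC	CC	CC	CC	AA	AA	CC
qTRL-6A	CC	AA	AA	CC	AA	AA	CC
Sbm1-5D	CC	CC	CC	CC	AA	AA	CC
Yr6	CC	AA	CC	AA	CC	AA	CC
Yr7	CC	CC	AA	CC	AA	AA	CC
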