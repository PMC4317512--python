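locus_id	chromosome	pos_cM
qGY-psr-2D.1	2D	0
qGY-psr-3A.2	3A	0
qGY-psr-3B.2	3B	0
qTGW-psr-5A.1	5A	0
qGRL-psr-5A.1	5A	60
qGRW-psr-5A.2	5A	65
qPH-psr-2A.1	2A	0
qPH-psr-3A	3A	110
qPH-psr-3B.1	3B	60
qPH-psr-4D	4D	0
qPH-psr-5A.1	5A	130
qEM-psr-1B.2	1B	0
qEM-psr-1D.1	1D	0
qEM-psr-5A	5A	200
qEM-psr-6A.1	6A	0
Vrn-A1b	5A	370
qTRSA-2A	2A	110
qSDW-5A	5A	260
qTRL-5B	5B	0
qTRL-6A	6A	75
Sbm1-5D	5D	0
Yr6	7B	0
Yr7	2B	0
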