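locus_id	trait	environment	additive_effect	increasing_parent	provenance
qGY-psr-2D.1	GY	MET	0.37	C	paper
qGY-psr-2D.1	PH	MET	4.92	C	paper
qGY-psr-2D.1	GN	MET	856.47	C	paper
qGY-psr-3A.2	GY	MET	0.2	C	synthetic
qGY-psr-3B.2	GY	MET	0.15	A	synthetic
qTGW-psr-5A.1	TGW	MET	1.72	C	paper
qGRL-psr-5A.1	GRL	MET	0.15	C	paper
qGRW-psr-5A.2	GRW	MET	0.08	A	synthetic
qPH-psr-2A.1	PH	MET	2	A	synthetic
qPH-psr-2A.1	GY	MET	0.21	A	paper
qPH-psr-3A	PH	MET	4.42	C	paper
qPH-psr-3A	EM	MET	2	C	synthetic
qPH-psr-3B.1	PH	MET	2.4	A	paper
qPH-psr-3B.1	SS	MET	20.29	C	paper
qPH-psr-4D	PH	MET	4.67	C	synthetic
qPH-psr-4D	GN	MET	600	A	synthetic
qPH-psr-5A.1	PH	MET	2.5	C	synthetic
qEM-psr-1B.2	EM	MET	1.2	C	synthetic
qEM-psr-1D.1	EM	MET	3	A	synthetic
qEM-psr-5A	EM	MET	1.5	A	synthetic
qEM-psr-5A	GN	MET	500	C	synthetic
qEM-psr-6A.1	EM	MET	1	C	synthetic
qEM-psr-6A.1	TGW	MET	1	A	synthetic
qEM-psr-6A.1	GRW	MET	0.05	A	synthetic
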