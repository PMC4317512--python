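locus_id	trait	environment	additive_effect	increasing_parent	provenance
qGY-psr-2D.1	GY	MET	0.37	C	paper
qGY-psr-2D.1	GY	2005	0.444	C	synthetic
qGY-psr-2D.1	GY	2006	0.222	A	synthetic
qGY-psr-2D.1	GY	2007	0.407	C	synthetic
qGY-psr-2D.1	GY	2008	0.333	C	synthetic
qGY-psr-3A.2	GY	MET	0.2	C	synthetic
qGY-psr-3A.2	GY	2005	0.24	C	synthetic
qGY-psr-3A.2	GY	2006	0.12	A	synthetic
qGY-psr-3A.2	GY	2007	0.22	C	synthetic
qGY-psr-3A.2	GY	2008	0.18	C	synthetic
qGY-psr-3B.2	GY	MET	0.15	A	synthetic
qGY-psr-3B.2	GY	2005	0.18	A	synthetic
qGY-psr-3B.2	GY	2006	0.09	C	synthetic
qGY-psr-3B.2	GY	2007	0.165	A	synthetic
qGY-psr-3B.2	GY	2008	0.135	A	synthetic
qPH-psr-2A.1	PH	MET	2	A	synthetic
qPH-psr-2A.1	PH	2005	2.2	A	synthetic
qPH-psr-2A.1	PH	2006	1.7	A	synthetic
qPH-psr-2A.1	PH	2007	2.1	A	synthetic
qPH-psr-2A.1	PH	2008	1.9	A	synthetic
qPH-psr-2D	PH	MET	4.92	C	paper
qPH-psr-2D	PH	2005	5.412	C	synthetic
qPH-psr-2D	PH	2006	4.182	C	synthetic
qPH-psr-2D	PH	2007	5.166	C	synthetic
qPH-psr-2D	PH	2008	4.674	C	synthetic
qPH-psr-3A	PH	MET	4.42	C	paper
qPH-psr-3A	PH	2005	4.862	C	synthetic
qPH-psr-3A	PH	2006	3.757	C	synthetic
qPH-psr-3A	PH	2007	4.641	C	synthetic
qPH-psr-3A	PH	2008	4.199	C	synthetic
qPH-psr-3B.1	PH	MET	2.4	A	paper
qPH-psr-3B.1	PH	2005	2.64	A	synthetic
qPH-psr-3B.1	PH	2006	2.04	A	synthetic
qPH-psr-3B.1	PH	2007	2.52	A	synthetic
qPH-psr-3B.1	PH	2008	2.28	A	synthetic
qPH-psr-4D	PH	MET	4.67	C	synthetic
qPH-psr-4D	PH	2005	5.137	C	synthetic
qPH-psr-4D	PH	2006	3.9695	C	synthetic
qPH-psr-4D	PH	2007	4.9035	C	synthetic
qPH-psr-4D	PH	2008	4.4365	C	synthetic
qPH-psr-5A.1	PH	MET	2.5	C	synthetic
qPH-psr-5A.1	PH	2005	2.75	C	synthetic
qPH-psr-5A.1	PH	2006	2.125	C	synthetic
qPH-psr-5A.1	PH	2007	2.625	C	synthetic
qPH-psr-5A.1	PH	2008	2.375	C	synthetic
qEM-psr-1B.2	EM	MET	1.2	C	synthetic
qEM-psr-1B.2	EM	2005	1.38	C	synthetic
qEM-psr-1B.2	EM	2006	0.96	C	synthetic
qEM-psr-1B.2	EM	2007	1.32	C	synthetic
qEM-psr-1B.2	EM	2008	1.08	C	synthetic
qEM-psr-1D.1	EM	MET	3	A	synthetic
qEM-psr-1D.1	EM	2005	3.45	A	synthetic
qEM-psr-1D.1	EM	2006	2.4	A	synthetic
qEM-psr-1D.1	EM	2007	3.3	A	synthetic
qEM-psr-1D.1	EM	2008	2.7	A	synthetic
qEM-psr-3A	EM	MET	2	C	synthetic
qEM-psr-3A	EM	2005	2.3	C	synthetic
qEM-psr-3A	EM	2006	1.6	C	synthetic
qEM-psr-3A	EM	2007	2.2	C	synthetic
qEM-psr-3A	EM	2008	1.8	C	synthetic
qEM-psr-5A	EM	MET	1.5	A	synthetic
qEM-psr-5A	EM	2005	1.725	A	synthetic
qEM-psr-5A	EM	2006	1.2	A	synthetic
qEM-psr-5A	EM	2007	1.65	A	synthetic
qEM-psr-5A	EM	2008	1.35	A	synthetic
qEM-psr-6A.1	EM	MET	1	C	synthetic
qEM-psr-6A.1	EM	2005	1.15	C	synthetic
qEM-psr-6A.1	EM	2006	0.8	C	synthetic
qEM-psr-6A.1	EM	2007	1.1	C	synthetic
qEM-psr-6A.1	EM	2008	0.9	C	synthetic
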