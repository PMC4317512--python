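line	qGY-psr-2D.1	qGY-psr-3A.2	qGY-psr-3B.2	qPH-psr-2A.1	qPH-psr-2D	qPH-psr-3A	qPH-psr-3B.1	qPH-psr-4D	qPH-psr-5A.1	qEM-psr-1B.2	qEM-psr-1D.1	qEM-psr-3A	qEM-psr-5A	qEM-psr-6A.1
SDH1	C	C	A	A	C	A	A	A	A	A	A	A	A	A
SDH2	C	C	A	A	C	A	A	A	A	A	A	C	A	A
SDH3	C	C	A	A	C	C	A	A	A	A	A	C	A	A
SDH4	C	C	A	A	C	A	A	A	A	A	A	A	C	A
SDH5	C	C	A	A	C	C	A	A	A	A	A	A	A	A
SDH6	C	C	A	A	C	A	A	A	C	A	A	A	A	A
SDH7	C	C	A	A	C	A	A	A	A	A	A	A	A	C
SDH8	C	C	A	A	C	A	A	A	A	C	A	C	A	A
SDH9	C	C	A	A	C	A	A	A	A	A	C	A	A	A
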