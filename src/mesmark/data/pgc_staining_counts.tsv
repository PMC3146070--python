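genotype	assay	positive	total
N2	H5	4	54
N2	H3K4me2	0	37
mes-2(bn11)	H5	3	35
mes-2(bn11)	H3K4me2	1	40
mes-4(bn67)	H5	32	45
mes-4(bn67)	H3K4me2	15	21
mes-4(bn85)	H5	15	23
mes-4(bn85)	H3K4me2	29	37
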