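# RT-qPCR mRNA summaries (arbitrary units, mean and sd) for P. putida
# wild type (KT2442) and the cbrB deletion mutant (MPO401) grown to
# mid-exponential phase on oxaloacetate minimal medium; replicate count
# defaults to 9 (three biological replicates, each in triplicate).
gene_id	strain	condition	mean	sd
PP0952	KT2442	OAA	0.24	0.06
PP0952	MPO401	OAA	1.78	0.64
PP1206	KT2442	OAA	1.71	0.85
PP1206	MPO401	OAA	5.77	1.64
PP3009	KT2442	OAA	0.30	0.09
PP3009	MPO401	OAA	0.30	0.11
PP3074	KT2442	OAA	0.68	0.25
PP3074	MPO401	OAA	0.12	0.09
PP3420	KT2442	OAA	0.70	0.16
PP3420	MPO401	OAA	0.06	0.02
PP3656	KT2442	OAA	0.015	0.006
PP3656	MPO401	OAA	0.014	0.003
PP4050	KT2442	OAA	0.23	0.07
PP4050	MPO401	OAA	0.33	0.04
PP4391	KT2442	OAA	5.87	0.92
PP4391	MPO401	OAA	1.26	0.17
PP4486	KT2442	OAA	0.36	0.11
PP4486	MPO401	OAA	0.13	0.04
PP4643	KT2442	OAA	0.034	0.01
PP4643	MPO401	OAA	0.01	0.002
crcZ	KT2442	OAA	170.39	39.17
crcZ	MPO401	OAA	3.92	0.52
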