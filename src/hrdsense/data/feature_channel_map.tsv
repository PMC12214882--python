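# hrdsense channel-to-feature membership map, v1
feature	channel_class	channel
n_ct_g	sbs96	A[C>T]G
n_ct_g	sbs96	C[C>T]G
n_ct_g	sbs96	G[C>T]G
n_ct_g	sbs96	T[C>T]G
n_cg_t	sbs96	A[C>G]T
n_cg_t	sbs96	C[C>G]T
n_cg_t	sbs96	G[C>G]T
n_cg_t	sbs96	T[C>G]T
del5_mh	id83	5:Del:M:1
del5_mh	id83	5:Del:M:2
del5_mh	id83	5:Del:M:3
del5_mh	id83	5:Del:M:4
del5_mh	id83	5:Del:M:5
loh_1_40	cn48	1:LOH:1-10Mb
loh_1_40	cn48	1:LOH:10-40Mb
loh_1_40	cn48	2:LOH:1-10Mb
loh_1_40	cn48	2:LOH:10-40Mb
loh_1_40	cn48	3-4:LOH:1-10Mb
loh_1_40	cn48	3-4:LOH:10-40Mb
loh_1_40	cn48	5-8:LOH:1-10Mb
loh_1_40	cn48	5-8:LOH:10-40Mb
loh_1_40	cn48	9+:LOH:1-10Mb
loh_1_40	cn48	9+:LOH:10-40Mb
het3_9_10_40	cn48	3-4:HET:10-40Mb
het3_9_10_40	cn48	5-8:HET:10-40Mb
het3_9_10_40	cn48	9+:HET:10-40Mb
het2_4_gt40	cn48	2:HET:>40Mb
het2_4_gt40	cn48	3-4:HET:>40Mb
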