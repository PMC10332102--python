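gene_a	gene_b	ka	ks	ratio
TkERF2	AT1G78080.1	0.311575	1.659059	0.187802
TkERF3	AT1G78080.1	0.346134	1.462689	0.236643
TkERF10	AT1G78080.1	0.245749	2.276362	0.107957
TkERF19	AT4G17500.1	0.316265	1.637429	0.193148
TkERF25	AT5G51990.1	0.361576	1.537269	0.235207
TkERF48	AT4G17500.1	0.316265	1.737577	0.182015
TkERF49	AT3G23240.1	0.31717	1.471628	0.215523
TkERF53	AT1G64380.1	0.46312	2.064286	0.224349
TkERF60	AT1G78080.1	0.333777	1.461567	0.228369
TkERF63	AT1G78080.1	0.235316	2.695244	0.087308
TkERF84	AT3G23240.1	0.31717	1.471628	0.215523
TkAP2-2	AT4G37750.1	0.366574	2.421057	0.151411
TkAP2-6	AT2G41710.1	0.202289	1.874449	0.107919
TkAP2-17	AT5G57390.1	0.2386	2.381813	0.100176
TkAP2-27	AT4G37750.1	0.300933	1.888938	0.159313
TkRAV1	AT1G68840.1	0.307604	2.181663	0.140995
TkRAV1	AT1G25560.1	0.348257	2.389618	0.145738
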