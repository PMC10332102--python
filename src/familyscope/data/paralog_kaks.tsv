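gene_a	gene_b	ka	ks	ratio
TkERF1	TkERF6	0	0.011976	0
TkERF2	TkERF60	0.00653	0.040938	0.159517
TkERF4	TkERF27	0.006168	0.019941	0.309329
TkERF7	TkERF76	0.004885	0.023141	0.211076
TkERF8	TkERF45	0.087128	0.143827	0.605781
TkERF9	TkERF92	0.077307	0.073641	1.049774
TkERF12	TkERF75	0.005274	0.013053	0.404005
TkERF14	TkERF22	0.023889	0.019529	1.223224
TkERF15	TkERF78	0.202012	1.387938	0.145548
TkERF15	TkERF33	0.205087	1.299267	0.157848
TkERF16	TkERF89	0.047165	0.068679	0.686737
TkERF17	TkERF94	0.008825	0.034789	0.253681
TkERF17	TkERF28	0.008817	0.03489	0.252713
TkERF17	TkERF85	0.008811	0.04943	0.178247
TkERF18	TkERF39	0.005015	0.015095	0.332209
TkERF18	TkERF24	0.091125	0.124866	0.729785
TkERF19	TkERF28	0.001566	0.018266	0.085721
TkERF24	TkERF39	0.087706	0.125062	0.701307
TkERF28	TkERF85	0.004388	0.042314	0.10369
TkERF28	TkERF94	0.008816	0.056664	0.155575
TkERF30	TkERF82	0.394187	0.54574	0.722298
TkERF35	TkERF37	0.021245	0.038706	0.548875
TkERF41	TkERF43	0.182809	0.341772	0.534886
TkERF52	TkERF57	0.005816	0.014883	0.390797
TkERF62	TkERF93	0.323095	2.316687	0.139464
TkERF64	TkERF69	0	0.004739	0
TkERF67	TkERF88	0.003011	0.008584	0.350724
TkERF85	TkERF94	0.00699	0.045533	0.153514
TkAP2-7	TkAP2-36	0.044531	0.058211	0.765
TkAP2-8	TkAP2-32	0.00224	0.005147	0.435278
TkAP2-10	TkAP2-17	0.002468	0.011785	0.209416
TkAP2-25	TkAP2-32	0.014136	0.033965	0.41618
TkRAV3	TkRAV4	0.003766	0.004658	0.808367
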