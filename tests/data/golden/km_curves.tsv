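time	survival	group
0	1	P+G+
3.970038192	1	P+G+
6.227701705	0.9411764706	P+G+
6.766540611	0.8823529412	P+G+
7.041863901	0.8823529412	P+G+
7.684437929	0.8193277311	P+G+
13.97713954	0.756302521	P+G+
14.86243415	0.6932773109	P+G+
16.40535725	0.6932773109	P+G+
22.41053817	0.6239495798	P+G+
23.43423322	0.5546218487	P+G+
27.60512373	0.4852941176	P+G+
29.94959871	0.4159663866	P+G+
33.67914763	0.3466386555	P+G+
33.9965952	0.2773109244	P+G+
42.44665148	0.2079831933	P+G+
61.16469799	0.1386554622	P+G+
86.8839255	0.06932773109	P+G+
157.4954326	0	P+G+
0	1	P+G-
7.249768492	0.9166666667	P+G-
26.44692784	0.8333333333	P+G-
45.05992384	0.8333333333	P+G-
53.59428108	0.7407407407	P+G-
75.53013578	0.6481481481	P+G-
99.06169703	0.6481481481	P+G-
103.0198107	0.5401234568	P+G-
106.9400302	0.4320987654	P+G-
112.4237529	0.3240740741	P+G-
149.2219413	0.2160493827	P+G-
181.2813693	0.2160493827	P+G-
185.2092353	0	P+G-
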