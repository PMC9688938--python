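sample_id	76GS	KS	Epi	Mes	pEMT	NES:PDL1	NES:GLYCOLYSIS	NES:HIF1A_TARGETS	NES:OXPHOS	EXPR:CD274
D0_S0000	75.9411703	-0.56	0.2160654507	-0.0222828463	0.06138071744	0.5097260686	0.4361799153	0.3385999972	-0.2685179159	11.03488048
D0_S0001	-286.0397331	1	-0.430162895	0.5001005041	0.3147782721	0.1083542858	-0.4286045956	-0.03189273404	0.4609505568	9.213153972
D0_S0002	120.4071347	-0.76	0.4630017369	0.1057603516	0.2568399283	0.007127257228	0.09101654936	0.3751003125	0.1086487387	7.874500542
D0_S0003	-113.1226595	0.92	-0.222754868	0.4493660353	0.06457624309	0.02785321524	-0.275594342	-0.3782904211	0.2242969951	7.99807228
D0_S0004	-68.42089803	0.76	-0.06985025101	0.3743538244	0.1429732927	0.04503929299	0.07557683144	0.4573427875	0.02085320536	7.992256395
D0_S0005	-38.70070197	0.88	0.1939394039	0.4409983301	0.5881801208	0.553185335	-0.1603471719	0.1341541484	-0.2343011254	12.28650169
D0_S0006	56.55378281	-0.4	0.1469122823	-0.05640059236	0.3490573733	0.5593537892	0.4545036185	0.5069444507	-0.2924807727	14.51857746
D0_S0007	-54.6132867	0.88	-0.01628313854	0.4208593802	0.5873429281	0.4464505238	-0.2691538206	0.1143745476	0.1955624536	11.4133314
D0_S0008	-171.9176967	1	-0.4147764361	0.437368484	0.5566512019	0.4920487481	0.03755287395	0.4341461954	0.05772175795	10.63907445
D0_S0009	330.3840537	-1	0.5008450501	-0.4262296737	0.06994290356	-0.421563385	-0.3495567029	-0.3646481709	0.1410399201	5.077032617
D0_S0010	155.3024448	-0.84	0.4039772141	-0.1129323583	0.5372684996	0.06484467812	-0.1528794269	-0.4025024691	0.485779027	7.953712704
D0_S0011	-144.9166726	0.92	-0.3648456168	0.3659132155	-0.113395462	-0.223167381	0.132359445	-0.4220529496	0.3584840459	7.51328045
D0_S0012	-18.91341062	0.24	0.03395591892	0.09292467582	-0.2443599534	-0.2490288728	0.3058780369	0.2843660632	-0.4451458243	5.600451943
D0_S0013	237.8108862	-1	0.4732791392	-0.3257900482	0.1580339301	0.2508341339	-0.2450541578	0.03925881319	0.2662865694	10.10879913
D0_S0014	-232.8875189	1	-0.2906234665	0.5110454621	0.2704747955	0.3948951593	0.04692111035	0.01149245124	-0.1324564905	10.68640151
D0_S0015	-145.1114907	1	-0.2506348237	0.4612398901	0.1895470515	0.116789488	0.2129848202	0.1203437684	0.4810779851	8.177958283
D0_S0016	131.8631842	-0.68	0.4097718781	0.1114931016	0.5296559657	0.3463577247	0.3104890994	0.182301551	0.1177938034	10.76796817
D0_S0017	-189.2571198	1	-0.4666065684	0.3432126785	-0.2141096064	-0.138132561	0.09035648532	-0.007410854257	0.2248198843	7.520709498
D0_S0018	-45.35378071	0.64	-0.04988999026	0.3097162271	0.3004753205	-0.08832007917	0.2686615579	0.5362132579	0.2802508699	6.982982399
D0_S0019	-133.0999629	1	0.0009541076514	0.4679462586	0.5962440274	0.4999487972	-0.1364594289	-0.2999790246	-0.07054100798	13.39172401
D0_S0020	187.9917736	-1	0.4125550403	-0.3297202223	0.00472699761	-0.3690593105	-0.1837940828	-0.3723407497	0.4182057274	5.125248269
D0_S0021	89.12431039	-0.68	0.3457830361	-0.06737724574	0.1228948452	0.1162315834	0.1221565114	-0.1327118656	0.4165488004	7.701475157
D0_S0022	-389.961051	1	-0.4917172389	0.5048834952	0.1850678699	0.3490089286	-0.04581913803	-0.06615514609	0.277294328	8.688039779
D0_S0023	-72.46802127	0.72	0.04142659728	0.3768717785	-0.1290785122	-0.3143174263	-0.3569720746	-0.1967513062	0.07098102553	7.414133552
D0_S0024	-56.81530082	0.72	-0.164670867	0.2546212648	0.4150529943	0.4747224896	0.3286290301	0.06875957578	0.06546064618	10.51366153
D0_S0025	130.2876684	-0.84	0.406336411	-0.114991566	-0.2701316965	-0.2220801268	0.1049989181	-0.1601737675	0.5548541757	6.894131509
D0_S0026	95.16289126	-0.72	0.3519290117	-0.02059425849	0.1084908048	0.3352482158	0.1694653563	0.439962533	-0.2097744173	9.760490899
D0_S0027	-46.50015863	0.8	0.2037561291	0.4783943138	0.4041574644	0.5108729846	-0.1344009785	0.398854126	-0.3957448167	12.41687644
D0_S0028	-141.5337221	1	-0.1851012978	0.4441209224	-0.2921046066	-0.4406462108	-0.3584602902	-0.1051166465	0.2852761829	6.1808219
D0_S0029	-45.45198919	0.56	-0.1603209166	0.07880105576	0.2231819373	0.5243147111	0.2934091413	0.4906116867	-0.1668507595	9.498974951
D0_S0030	159.7289713	-0.96	0.2805376586	-0.4493475054	0.3454326277	0.07147291129	0.02761827692	0.3501223941	-0.1293640689	8.102493694
D0_S0031	-304.5918075	1	-0.4715415752	0.4848898734	-0.2735494684	0.1560814624	0.4392425891	-0.2065357181	-0.004113805798	9.585700255
D0_S0032	-187.0303291	1	-0.4477563617	0.4195418257	0.3354509046	-0.2548461669	-0.009805523188	-0.1437599509	0.3945612682	7.761617653
D0_S0033	-55.90978552	0.48	-0.1225843107	0.1311139815	0.2257464461	-0.4013787742	0.1342089648	-0.1734152325	0.5309511601	5.096550022
D0_S0034	81.29402001	-0.56	0.4116778375	0.2630345942	0.3952333955	0.3821786755	0.3540089419	0.1301029947	-0.1322633932	11.37496491
D0_S0035	-173.4985125	1	-0.4250482109	0.3733453996	-0.3086132442	0.09732932652	0.4341948045	-0.1959799735	0.1127431713	7.326412879
D0_S0036	-94.61300361	0.76	-0.06327190179	0.2991175976	-0.1186944005	0.07448010279	0.03818761358	-0.1397686936	0.195347895	7.784456449
D0_S0037	-160.4184342	1	-0.3753454389	0.4103755906	-0.05176131585	0.5132059076	0.1448817676	0.4096037948	0.3060034809	12.19589669
D0_S0038	410.2612755	-1	0.5082827611	-0.4515375134	0.3324121596	0.007345470704	-0.2827639162	0.2230288557	0.3858259187	8.976611796
D0_S0039	-62.13256519	0.8	0.03219777923	0.4381248981	0.2855863134	0.5009362679	0.08196101884	0.3544759601	0.06578215748	11.58990799
D0_S0040	-110.3093106	0.92	-0.3589104371	0.2586601461	-0.3887082178	-0.4216520626	0.01217362255	0.22339396	0.4139395648	7.885219051
D0_S0041	-176.6701058	1	-0.4285100997	0.4353434417	-0.2786070212	0.2104072492	0.4442791456	0.4204532762	0.1093984757	9.031964602
D0_S0042	75.14053039	-0.56	0.23610332	-0.166491062	-0.008605513499	0.3186205576	0.421740807	0.553420305	-0.4117566943	10.99701966
D0_S0043	137.3200928	-0.96	0.2930407746	-0.2705839718	0.1324506955	-0.02225764724	-0.5004133496	0.5779470504	0.282995964	7.981452556
D0_S0044	-37.04895895	0.72	0.132823876	0.4197288387	0.6112917822	0.4329064782	0.03445390236	0.176578259	0.1790988602	10.80997984
D0_S0045	214.2721418	-1	0.4755887063	-0.313097323	0.03837784417	0.07193218841	-0.1030720342	0.1738905613	0.4139095722	10.0490312
D0_S0046	118.1296807	-0.92	0.3987364217	-0.2276660302	0.3604276811	0.04458420572	0.2037883359	-0.03354216049	0.2155066242	9.230838351
D0_S0047	-73.2949562	0.84	-0.213977444	0.3219139779	0.1112444941	0.03339118849	-0.2745710981	0.4983344634	-0.03441907733	8.69703918
D0_S0048	-208.8971828	1	-0.4260740097	0.4253119929	-0.1353612212	0.4043894811	0.4733862004	0.3442167253	0.1182586553	10.78863314
D0_S0049	222.8449107	-1	0.4649696904	-0.4512965003	-0.213824952	0.3007065862	0.1851734423	0.5555777859	-0.1673238297	8.822858925
D0_S0050	198.14716	-0.96	0.451898147	-0.4245438021	0.5194276813	-0.1355213147	-0.04814856946	0.2259575504	0.3509802284	6.263124964
D0_S0051	326.6503423	-1	0.4922867653	-0.4889545379	0.3591020084	-0.03170439866	0.2522464082	0.02900224374	0.3856653861	7.640236977
D0_S0052	127.7928219	-0.88	0.3913967605	-0.1498502869	-0.2706503201	0.1400489325	0.3533331818	0.4182644468	0.05241729497	8.330663449
D0_S0053	21.6389735	0.16	0.1539736701	0.1580975423	0.3443120169	0.09911232165	0.4995866504	0.3053512298	0.01634046957	9.60142184
D0_S0054	1.965074186	0.2	0.06294164872	0.1280489416	0.3149496979	-0.3435697307	0.03132353153	0.4591326938	0.5204390383	8.4883358
D0_S0055	227.9528875	-1	0.4902522625	-0.2683976287	-0.1560515909	-0.03941628885	0.08313494714	0.3682104798	0.3117794644	9.695732998
D0_S0056	-121.9096313	0.96	0.02724002558	0.4820285366	0.485516144	0.357378763	-0.05506582807	-0.1188440213	0.1943640018	11.61437194
D0_S0057	-120.4650033	0.92	-0.02538532244	0.4742334559	0.5298627895	0.4646501481	0.1009023596	-0.1536536387	0.4170695499	11.86698592
D0_S0058	100.710515	-0.8	0.3433535731	-0.1937825772	0.45147889	-0.1629084492	0.05195132449	0.4071358894	-0.09059866511	7.032734364
D0_S0059	247.1960638	-1	0.4943830017	-0.2230458209	0.0428695342	-0.161104197	0.2492028389	0.2826768944	0.1498324225	7.785952746
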