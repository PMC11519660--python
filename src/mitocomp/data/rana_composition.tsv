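# Whole-mitogenome base composition of 22 Rana records (published values).
species	pct_T	pct_C	pct_A	pct_G	total_length	pct_AT	gc_skew	at_skew	accession
R.hanluica	29.37567	30.49626	24.47528	15.65279	17505	53.85094	-0.32164	-0.091	PP228844
R.jiemuxiensis	29.11775	30.73639	24.33298	15.81288	17506	53.45073	-0.3206	-0.08952	PP228843
R.dybowskii	30.53428	29.31434	24.57703	15.57435	18864	55.11131	-0.30609	-0.1081	KF898355
R.chensinensis	30.69457	29.10062	24.94212	15.26269	18808	55.63669	-0.31192	-0.10339	KF898356
R.draytonii	29.67805	30.06937	25.37353	14.87905	17805	55.05158	-0.33795	-0.07819	KP013110
R.huanrensis	30.76512	29.04605	25.06458	15.12425	19253	55.8297	-0.31518	-0.10211	KT588071
R.amurensis	30.9651	29.11325	25.5609	14.36075	18470	56.526	-0.33934	-0.09561	KU343216
R.chaochiaoensis	30.19221	29.76508	24.68411	15.3586	18591	54.87631	-0.31927	-0.10037	KU246048
R.kukunoris	30.70901	29.11663	25.06005	15.11431	18863	55.76906	-0.31657	-0.10129	KU246049
R.omeimontis	29.75714	30.03292	24.16155	16.04839	19934	53.91869	-0.30347	-0.10378	KU246050
R.temporaria	30.66239	29.20228	24.90207	15.23326	16061	55.56446	-0.31437	-0.10367	MH536744
R.uenoi	30.60552	29.439	24.87979	15.07569	17370	55.48531	-0.32266	-0.10319	MW009067
R.johnsi	29.40915	30.72611	25.2981	14.56665	17837	54.70724	-0.35678	-0.07515	MZ571365
R.dabieshanensis	29.61744	30.22242	24.1637	15.99644	18291	53.78114	-0.3078	-0.10141	MW526989
R.hanluica-2	29.37461	30.5133	24.4907	15.62139	19395	53.86531	-0.32279	-0.09067	MZ680529
R.zhenhaiensis	29.16111	30.59336	24.66862	15.57691	18806	53.82973	-0.32524	-0.08346	OL681880
R.wuyiensis	29.43584	30.66382	25.44937	14.45097	17779	54.88521	-0.35937	-0.07263	OL467321
R.catesbeiana	32.8264	26.68979	25.99609	14.48773	17212	58.82248	-0.29633	-0.11612	ON746668
R.arvalis	30.69122	29.13442	24.81986	15.35451	16143	55.51108	-0.30974	-0.10577	MT872666
R.coreana	29.22448	30.46958	24.7243	15.58164	22262	53.94877	-0.32329	-0.08342	ON920705
R.longicrus	31.33066	28.63373	25.73209	14.30352	17833	57.06275	-0.33375	-0.09811	MZ680528
R.kunyuensis	31.27726	28.63373	25.8834	14.20561	22255	57.16066	-0.3368	-0.09436	KF840516
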