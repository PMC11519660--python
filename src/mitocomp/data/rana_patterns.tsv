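# Gene-order pattern membership of the 22 Rana mitogenome records.
# pattern1 = ancestral vertebrate order; pattern2 = dominant Rana order
# (L1/T/P cluster relocated next to tRNA-Phe); pattern3 = pattern2 with
# ND5 transposed behind the control region.
species	accession	pattern
R.hanluica	PP228844	pattern2
R.jiemuxiensis	PP228843	pattern2
R.dybowskii	KF898355	pattern2
R.chensinensis	KF898356	pattern2
R.draytonii	KP013110	pattern1
R.huanrensis	KT588071	pattern2
R.amurensis	KU343216	pattern3
R.chaochiaoensis	KU246048	pattern2
R.kukunoris	KU246049	pattern2
R.omeimontis	KU246050	pattern2
R.temporaria	MH536744	pattern2
R.uenoi	MW009067	pattern2
R.johnsi	MZ571365	pattern2
R.dabieshanensis	MW526989	pattern2
R.hanluica-2	MZ680529	pattern2
R.zhenhaiensis	OL681880	pattern1
R.wuyiensis	OL467321	pattern2
R.catesbeiana	ON746668	pattern2
R.arvalis	MT872666	pattern2
R.coreana	ON920705	pattern3
R.longicrus	MZ680528	pattern2
R.kunyuensis	KF840516	pattern2
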