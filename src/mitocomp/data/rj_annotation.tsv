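# Annotation table of the Rana jiemuxiensis mitogenome (published record PP228843).
# Coordinates 1-based inclusive; strand H/L; '-' = not applicable.
# species: R.jiemuxiensis
# accession: PP228843
# genome_length: 17506
# circular: true
gene	category	start	end	strand	start_codon	stop_codon	anticodon
L1	tRNA	1	74	H	-	-	TAG
T	tRNA	75	144	H	-	-	TGT
P	tRNA	145	213	L	-	-	TGG
F	tRNA	215	286	H	-	-	GAA
12S	rRNA	287	1216	H	-	-	-
V	tRNA	1217	1285	H	-	-	TAC
16S	rRNA	1286	2860	H	-	-	-
L2	tRNA	2861	2934	H	-	-	TAA
ND1	PCG	2982	3935	H	ATT	AGG	-
I	tRNA	3895	3965	H	-	-	GAT
Q	tRNA	3967	4037	L	-	-	TAA
M	tRNA	4036	4106	H	-	-	CAT
ND2	PCG	4106	5140	H	ATG	TAG	-
W	tRNA	5139	5208	H	-	-	TCA
A	tRNA	5208	5278	L	-	-	TGC
N	tRNA	5279	5351	L	-	-	GTT
O	NCR	5354	5378	H	-	-	-
C	tRNA	5377	5442	L	-	-	GCA
Y	tRNA	5443	5509	L	-	-	GTA
COX1	PCG	5511	7064	H	GTG	AGG	-
S1	tRNA	7055	7126	L	-	-	TGA
D	tRNA	7128	7196	H	-	-	GTC
COX2	PCG	7332	7884	H	ATG	T(AA)	-
K	tRNA	7885	7953	H	-	-	TTT
ATP8	PCG	7955	8117	H	ATG	TAA	-
ATP6	PCG	8110	8823	H	ATG	AGT	-
COX3	PCG	8792	9576	H	ATG	TA(A)	-
G	tRNA	9575	9644	H	-	-	TCC
ND3	PCG	9599	9948	H	ATG	TA(A)	-
R	tRNA	9984	10053	H	-	-	TCG
ND4L	PCG	10054	10338	H	ATG	TAA	-
ND4	PCG	10332	11703	H	ATG	T(AA)	-
H	tRNA	11692	11759	H	-	-	GTG
S2	tRNA	11760	11826	H	-	-	GCT
ND5	PCG	11859	13646	H	ATG	AGG	-
ND6	PCG	14271	14765	L	ATG	AGA	-
E	tRNA	14766	14834	L	-	-	TTC
CYTB	PCG	14838	15980	H	ATG	TAA	-
CR	CR	15981	17505	H	-	-	-
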