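# Annotation table of the Rana hanluica mitogenome (published record PP228844).
# Coordinates 1-based inclusive; strand H/L; '-' = not applicable.
# species: R.hanluica
# accession: PP228844
# genome_length: 17505
# circular: true
gene	category	start	end	strand	start_codon	stop_codon	anticodon
L1	tRNA	1	74	H	-	-	TAG
T	tRNA	75	144	H	-	-	TGT
P	tRNA	145	213	L	-	-	TGG
F	tRNA	215	285	H	-	-	GAA
12S	rRNA	286	1215	H	-	-	-
V	tRNA	1216	1284	H	-	-	TAC
16S	rRNA	1285	2859	H	-	-	-
L2	tRNA	2860	2933	H	-	-	TAA
ND1	PCG	2981	3934	H	ATT	AGG	-
I	tRNA	3894	3964	H	-	-	GAT
Q	tRNA	3965	4035	L	-	-	TAA
M	tRNA	4034	4104	H	-	-	CAT
ND2	PCG	4104	5138	H	ATG	TAG	-
W	tRNA	5137	5206	H	-	-	TCA
A	tRNA	5206	5276	L	-	-	TGC
N	tRNA	5277	5349	L	-	-	GTT
O	NCR	5352	5377	H	-	-	-
C	tRNA	5376	5441	L	-	-	GCA
Y	tRNA	5442	5508	L	-	-	GTA
COX1	PCG	5510	7063	H	GTG	AGG	-
S1	tRNA	7054	7125	L	-	-	TGA
D	tRNA	7127	7195	H	-	-	GTC
COX2	PCG	7196	7883	H	ATG	T(AA)	-
K	tRNA	7884	7952	H	-	-	TTT
ATP8	PCG	7954	8115	H	ATG	TAA	-
ATP6	PCG	8109	8791	H	ATG	AGT	-
COX3	PCG	8791	9575	H	ATG	TA(A)	-
G	tRNA	9574	9643	H	-	-	TCC
ND3	PCG	9598	9947	H	ATG	TA(A)	-
R	tRNA	9983	10052	H	-	-	TCG
ND4L	PCG	10053	10337	H	ATG	TAA	-
ND4	PCG	10331	11702	H	ATG	T(AA)	-
H	tRNA	11691	11758	H	-	-	GTG
S2	tRNA	11759	11825	H	-	-	GCT
ND5	PCG	11857	13644	H	ATG	AGG	-
ND6	PCG	13950	14444	L	ATG	AGA	-
E	tRNA	14445	14513	L	-	-	TTC
CYTB	PCG	14517	15659	H	ATG	TAA	-
CR	CR	15660	17505	H	-	-	-
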