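name	ftype	strand	start	end	anticodon	start_codon	stop_codon
CR	CR	H	1	1071	.	.	.
tRNA-Phe	tRNA	H	1072	1141	GAA	.	.
12S rRNA	rRNA	H	1142	2124	.	.	.
tRNA-Val	tRNA	H	2125	2195	TAC	.	.
16S rRNA	rRNA	H	2196	3799	.	.	.
tRNA-Leu2	tRNA	H	3800	3873	TAA	.	.
ND1	PCG	H	3878	4855	.	ATG	AGG
tRNA-Ile	tRNA	H	4854	4925	GAT	.	.
tRNA-Gln	tRNA	L	4934	5004	TGG	.	.
tRNA-Met	tRNA	H	5004	5072	CAT	.	.
ND2	PCG	H	5073	6113	.	ATG	TAG
tRNA-Trp	tRNA	H	6112	6187	TCA	.	.
tRNA-Ala	tRNA	L	6191	6259	TGC	.	.
tRNA-Asn	tRNA	L	6262	6334	GTT	.	.
tRNA-Cys	tRNA	L	6335	6400	GCA	.	.
tRNA-Tyr	tRNA	L	6400	6470	GTA	.	.
COI	PCG	H	6472	8022	.	GTG	AGG
tRNA-Ser2	tRNA	L	8014	8086	TGA	.	.
tRNA-Asp	tRNA	H	8089	8157	GTC	.	.
COII	PCG	H	8159	8845	.	GTG	TAA
tRNA-Lys	tRNA	H	8847	8914	TTT	.	.
ATP8	PCG	H	8916	9083	.	ATG	TAA
ATP6	PCG	H	9074	9757	.	ATG	TAA
COIII	PCG	H	9757	10540	.	ATG	T-
tRNA-Gly	tRNA	H	10541	10609	TCC	.	.
ND3	PCG	H	10610	10961	.	ATG	TAA
tRNA-Arg	tRNA	H	10963	11033	TCG	.	.
ND4L	PCG	H	11034	11330	.	ATG	TAA
ND4	PCG	H	11324	12701	.	ATG	T-
tRNA-His	tRNA	H	12702	12770	GTG	.	.
tRNA-Ser1	tRNA	H	12771	12836	GCT	.	.
tRNA-Leu1	tRNA	H	12836	12906	TAG	.	.
ND5	PCG	H	12907	14730	.	GTG	TAA
Cytb	PCG	H	14730	15872	.	ATG	TAA
tRNA-Thr	tRNA	H	15875	15943	TGT	.	.
tRNA-Pro	tRNA	L	15954	16023	TGG	.	.
ND6	PCG	L	16034	16555	.	ATG	TAG
tRNA-Glu	tRNA	L	16556	16623	TTC	.	.
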