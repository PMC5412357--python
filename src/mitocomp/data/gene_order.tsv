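# Ancestral insect mitochondrial gene order (23 J-strand / 14 N-strand genes),
# rotation-normalized to start at tRNA-Ile, with the control region last
# (between srRNA and tRNA-Ile).  Extra columns are defaults for the synthetic
# genome generator: PCG length (nt, includes start and any stop residues),
# start codon, and stop ("TAA"/"TAG" complete, "T" incomplete).
# name	type	strand	length	start	stop
tRNA-Ile	tRNA	J	.	.	.
tRNA-Gln	tRNA	N	.	.	.
tRNA-Met	tRNA	J	.	.	.
ND2	PCG	J	1023	ATT	TAA
tRNA-Trp	tRNA	J	.	.	.
tRNA-Cys	tRNA	N	.	.	.
tRNA-Tyr	tRNA	N	.	.	.
CO1	PCG	J	1537	ATG	T
tRNA-Leu(UUR)	tRNA	J	.	.	.
CO2	PCG	J	688	ATG	T
tRNA-Lys	tRNA	J	.	.	.
tRNA-Asp	tRNA	J	.	.	.
ATP8	PCG	J	159	ATT	TAA
ATP6	PCG	J	675	ATG	TAA
CO3	PCG	J	786	ATG	TAA
tRNA-Gly	tRNA	J	.	.	.
ND3	PCG	J	354	ATT	TAG
tRNA-Ala	tRNA	J	.	.	.
tRNA-Arg	tRNA	J	.	.	.
tRNA-Asn	tRNA	J	.	.	.
tRNA-Ser(AGN)	tRNA	J	.	.	.
tRNA-Glu	tRNA	J	.	.	.
tRNA-Phe	tRNA	N	.	.	.
ND5	PCG	N	1720	ATT	T
tRNA-His	tRNA	N	.	.	.
ND4	PCG	N	1339	ATG	T
ND4L	PCG	N	291	ATG	TAA
tRNA-Thr	tRNA	J	.	.	.
tRNA-Pro	tRNA	N	.	.	.
ND6	PCG	J	525	ATT	TAA
CYTB	PCG	J	1137	ATG	TAG
tRNA-Ser(UCN)	tRNA	J	.	.	.
ND1	PCG	N	940	TTG	T
tRNA-Leu(CUN)	tRNA	N	.	.	.
lrRNA	rRNA	N	1325	.	.
tRNA-Val	tRNA	N	.	.	.
srRNA	rRNA	N	790	.	.
CR	control_region	J	.	.	.
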