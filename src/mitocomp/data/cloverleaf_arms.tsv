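# Arm boundary table for the packaged cloverleaf templates.
# Zero-based half-open coordinates; an empty stem/loop has start == end.
# name	arm	stem5_start	stem5_end	stem3_start	stem3_end	loop_start	loop_end
tRNA-Ile	acceptor	0	7	64	71	0	0
tRNA-Ile	DHU	9	13	21	25	13	21
tRNA-Ile	anticodon	26	31	38	43	31	38
tRNA-Ile	TPSIC	47	52	59	64	52	59
tRNA-Ile	extra	.	.	.	.	43	47
tRNA-Gln	acceptor	0	7	64	71	0	0
tRNA-Gln	DHU	9	13	21	25	13	21
tRNA-Gln	anticodon	26	31	38	43	31	38
tRNA-Gln	TPSIC	47	52	59	64	52	59
tRNA-Gln	extra	.	.	.	.	43	47
tRNA-Met	acceptor	0	7	64	71	0	0
tRNA-Met	DHU	9	13	21	25	13	21
tRNA-Met	anticodon	26	31	38	43	31	38
tRNA-Met	TPSIC	47	52	59	64	52	59
tRNA-Met	extra	.	.	.	.	43	47
tRNA-Trp	acceptor	0	7	64	71	0	0
tRNA-Trp	DHU	9	13	21	25	13	21
tRNA-Trp	anticodon	26	31	38	43	31	38
tRNA-Trp	TPSIC	47	52	59	64	52	59
tRNA-Trp	extra	.	.	.	.	43	47
tRNA-Cys	acceptor	0	7	64	71	0	0
tRNA-Cys	DHU	9	13	21	25	13	21
tRNA-Cys	anticodon	26	31	38	43	31	38
tRNA-Cys	TPSIC	47	52	59	64	52	59
tRNA-Cys	extra	.	.	.	.	43	47
tRNA-Tyr	acceptor	0	7	64	71	0	0
tRNA-Tyr	DHU	9	13	21	25	13	21
tRNA-Tyr	anticodon	26	31	38	43	31	38
tRNA-Tyr	TPSIC	47	52	59	64	52	59
tRNA-Tyr	extra	.	.	.	.	43	47
tRNA-Leu(UUR)	acceptor	0	7	64	71	0	0
tRNA-Leu(UUR)	DHU	9	13	21	25	13	21
tRNA-Leu(UUR)	anticodon	26	31	38	43	31	38
tRNA-Leu(UUR)	TPSIC	47	52	59	64	52	59
tRNA-Leu(UUR)	extra	.	.	.	.	43	47
tRNA-Lys	acceptor	0	7	64	71	0	0
tRNA-Lys	DHU	9	13	21	25	13	21
tRNA-Lys	anticodon	26	31	38	43	31	38
tRNA-Lys	TPSIC	47	52	59	64	52	59
tRNA-Lys	extra	.	.	.	.	43	47
tRNA-Asp	acceptor	0	7	64	71	0	0
tRNA-Asp	DHU	9	13	21	25	13	21
tRNA-Asp	anticodon	26	31	38	43	31	38
tRNA-Asp	TPSIC	47	52	59	64	52	59
tRNA-Asp	extra	.	.	.	.	43	47
tRNA-Gly	acceptor	0	7	64	71	0	0
tRNA-Gly	DHU	9	13	21	25	13	21
tRNA-Gly	anticodon	26	31	38	43	31	38
tRNA-Gly	TPSIC	47	52	59	64	52	59
tRNA-Gly	extra	.	.	.	.	43	47
tRNA-Ala	acceptor	0	7	64	71	0	0
tRNA-Ala	DHU	9	13	21	25	13	21
tRNA-Ala	anticodon	26	31	38	43	31	38
tRNA-Ala	TPSIC	47	52	59	64	52	59
tRNA-Ala	extra	.	.	.	.	43	47
tRNA-Arg	acceptor	0	7	64	71	0	0
tRNA-Arg	DHU	9	13	21	25	13	21
tRNA-Arg	anticodon	26	31	38	43	31	38
tRNA-Arg	TPSIC	47	52	59	64	52	59
tRNA-Arg	extra	.	.	.	.	43	47
tRNA-Asn	acceptor	0	7	64	71	0	0
tRNA-Asn	DHU	9	13	21	25	13	21
tRNA-Asn	anticodon	26	31	38	43	31	38
tRNA-Asn	TPSIC	47	52	59	64	52	59
tRNA-Asn	extra	.	.	.	.	43	47
tRNA-Ser(AGN)	acceptor	0	7	49	56	0	0
tRNA-Ser(AGN)	DHU	9	9	9	9	9	9
tRNA-Ser(AGN)	anticodon	11	16	23	28	16	23
tRNA-Ser(AGN)	TPSIC	32	37	44	49	37	44
tRNA-Ser(AGN)	extra	.	.	.	.	28	32
tRNA-Glu	acceptor	0	7	64	71	0	0
tRNA-Glu	DHU	9	13	21	25	13	21
tRNA-Glu	anticodon	26	31	38	43	31	38
tRNA-Glu	TPSIC	47	52	59	64	52	59
tRNA-Glu	extra	.	.	.	.	43	47
tRNA-Phe	acceptor	0	7	64	71	0	0
tRNA-Phe	DHU	9	13	21	25	13	21
tRNA-Phe	anticodon	26	31	38	43	31	38
tRNA-Phe	TPSIC	47	52	59	64	52	59
tRNA-Phe	extra	.	.	.	.	43	47
tRNA-His	acceptor	0	7	64	71	0	0
tRNA-His	DHU	9	13	21	25	13	21
tRNA-His	anticodon	26	31	38	43	31	38
tRNA-His	TPSIC	47	52	59	64	52	59
tRNA-His	extra	.	.	.	.	43	47
tRNA-Thr	acceptor	0	7	64	71	0	0
tRNA-Thr	DHU	9	13	21	25	13	21
tRNA-Thr	anticodon	26	31	38	43	31	38
tRNA-Thr	TPSIC	47	52	59	64	52	59
tRNA-Thr	extra	.	.	.	.	43	47
tRNA-Pro	acceptor	0	7	64	71	0	0
tRNA-Pro	DHU	9	13	21	25	13	21
tRNA-Pro	anticodon	26	31	38	43	31	38
tRNA-Pro	TPSIC	47	52	59	64	52	59
tRNA-Pro	extra	.	.	.	.	43	47
tRNA-Ser(UCN)	acceptor	0	7	64	71	0	0
tRNA-Ser(UCN)	DHU	9	13	21	25	13	21
tRNA-Ser(UCN)	anticodon	26	31	38	43	31	38
tRNA-Ser(UCN)	TPSIC	47	52	59	64	52	59
tRNA-Ser(UCN)	extra	.	.	.	.	43	47
tRNA-Leu(CUN)	acceptor	0	7	64	71	0	0
tRNA-Leu(CUN)	DHU	9	13	21	25	13	21
tRNA-Leu(CUN)	anticodon	26	31	38	43	31	38
tRNA-Leu(CUN)	TPSIC	47	52	59	64	52	59
tRNA-Leu(CUN)	extra	.	.	.	.	43	47
tRNA-Val	acceptor	0	7	64	71	0	0
tRNA-Val	DHU	9	13	21	25	13	21
tRNA-Val	anticodon	26	31	38	43	31	38
tRNA-Val	TPSIC	47	52	59	64	52	59
tRNA-Val	extra	.	.	.	.	43	47
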