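# Gene-name normalization table: synonym -> canonical symbol.
# Lookup is case-insensitive and ignores spaces, hyphens and underscores.
# synonym	canonical
co1	CO1
cox1	CO1
coi	CO1
coxi	CO1
cytochromecoxidasesubuniti	CO1
cytochromecoxidasesubunit1	CO1
co2	CO2
cox2	CO2
coii	CO2
coxii	CO2
cytochromecoxidasesubunitii	CO2
cytochromecoxidasesubunit2	CO2
co3	CO3
cox3	CO3
coiii	CO3
coxiii	CO3
cytochromecoxidasesubunitiii	CO3
cytochromecoxidasesubunit3	CO3
nd1	ND1
nad1	ND1
nadh1	ND1
nadhdehydrogenasesubunit1	ND1
nd2	ND2
nad2	ND2
nadh2	ND2
nadhdehydrogenasesubunit2	ND2
nd3	ND3
nad3	ND3
nadh3	ND3
nadhdehydrogenasesubunit3	ND3
nd4	ND4
nad4	ND4
nadh4	ND4
nadhdehydrogenasesubunit4	ND4
nd4l	ND4L
nad4l	ND4L
nadh4l	ND4L
nadhdehydrogenasesubunit4l	ND4L
nd5	ND5
nad5	ND5
nadh5	ND5
nadhdehydrogenasesubunit5	ND5
nd6	ND6
nad6	ND6
nadh6	ND6
nadhdehydrogenasesubunit6	ND6
atp6	ATP6
atpase6	ATP6
atpsynthasef0subunit6	ATP6
atp8	ATP8
atpase8	ATP8
atpsynthasef0subunit8	ATP8
cytb	CYTB
cob	CYTB
cytochromeb	CYTB
12s	srRNA
12srrna	srRNA
12sribosomalrna	srRNA
rrns	srRNA
srrna	srRNA
smallsubunitribosomalrna	srRNA
ssurrna	srRNA
16s	lrRNA
16srrna	lrRNA
16sribosomalrna	lrRNA
rrnl	lrRNA
lrrna	lrRNA
largesubunitribosomalrna	lrRNA
lsurrna	lrRNA
trni	tRNA-Ile
trnaile	tRNA-Ile
trnq	tRNA-Gln
trnagln	tRNA-Gln
trnm	tRNA-Met
trnamet	tRNA-Met
trnw	tRNA-Trp
trnatrp	tRNA-Trp
trnc	tRNA-Cys
trnacys	tRNA-Cys
trny	tRNA-Tyr
trnatyr	tRNA-Tyr
trnl2	tRNA-Leu(UUR)
trnaleu(uur)	tRNA-Leu(UUR)
trnaleuuur	tRNA-Leu(UUR)
trnl1	tRNA-Leu(CUN)
trnaleu(cun)	tRNA-Leu(CUN)
trnaleucun	tRNA-Leu(CUN)
trnk	tRNA-Lys
trnalys	tRNA-Lys
trnd	tRNA-Asp
trnaasp	tRNA-Asp
trng	tRNA-Gly
trnagly	tRNA-Gly
trna	tRNA-Ala
trnaala	tRNA-Ala
trnr	tRNA-Arg
trnaarg	tRNA-Arg
trnn	tRNA-Asn
trnaasn	tRNA-Asn
trns1	tRNA-Ser(AGN)
trnaser(agn)	tRNA-Ser(AGN)
trnaseragn	tRNA-Ser(AGN)
trns2	tRNA-Ser(UCN)
trnaser(ucn)	tRNA-Ser(UCN)
trnaserucn	tRNA-Ser(UCN)
trne	tRNA-Glu
trnaglu	tRNA-Glu
trnf	tRNA-Phe
trnaphe	tRNA-Phe
trnh	tRNA-His
trnahis	tRNA-His
trnt	tRNA-Thr
trnathr	tRNA-Thr
trnp	tRNA-Pro
trnapro	tRNA-Pro
trnv	tRNA-Val
trnaval	tRNA-Val
cr	CR
controlregion	CR
dloop	CR
atrichregion	CR
a+trichregion	CR
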