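# alias	canonical
# Aliases are matched case-insensitively after removing spaces, dashes,
# underscores and periods.  Edit or extend freely.
COX1	COX1
COI	COX1
CO1	COX1
COXI	COX1
MTCO1	COX1
CYTOCHROMECOXIDASESUBUNITI	COX1
CYTOCHROMECOXIDASESUBUNIT1	COX1
COX2	COX2
COII	COX2
CO2	COX2
COXII	COX2
MTCO2	COX2
CYTOCHROMECOXIDASESUBUNITII	COX2
CYTOCHROMECOXIDASESUBUNIT2	COX2
COX3	COX3
COIII	COX3
CO3	COX3
COXIII	COX3
MTCO3	COX3
CYTOCHROMECOXIDASESUBUNITIII	COX3
CYTOCHROMECOXIDASESUBUNIT3	COX3
CYTB	CYTB
COB	CYTB
CYB	CYTB
MTCYB	CYTB
CYTOCHROMEB	CYTB
ND1	ND1
NAD1	ND1
NADH1	ND1
MTND1	ND1
NADHDEHYDROGENASESUBUNIT1	ND1
ND2	ND2
NAD2	ND2
NADH2	ND2
MTND2	ND2
NADHDEHYDROGENASESUBUNIT2	ND2
ND3	ND3
NAD3	ND3
NADH3	ND3
MTND3	ND3
NADHDEHYDROGENASESUBUNIT3	ND3
ND4	ND4
NAD4	ND4
NADH4	ND4
MTND4	ND4
NADHDEHYDROGENASESUBUNIT4	ND4
ND4L	ND4L
NAD4L	ND4L
NADH4L	ND4L
MTND4L	ND4L
NADHDEHYDROGENASESUBUNIT4L	ND4L
ND5	ND5
NAD5	ND5
NADH5	ND5
MTND5	ND5
NADHDEHYDROGENASESUBUNIT5	ND5
ND6	ND6
NAD6	ND6
NADH6	ND6
MTND6	ND6
NADHDEHYDROGENASESUBUNIT6	ND6
ATP6	ATP6
ATPASE6	ATP6
ATPASESUBUNIT6	ATP6
ATPSYNTHASEF0SUBUNIT6	ATP6
MTATP6	ATP6
ATP8	ATP8
ATPASE8	ATP8
ATPASESUBUNIT8	ATP8
ATPSYNTHASEF0SUBUNIT8	ATP8
MTATP8	ATP8
RRNS	rrnS
12S	rrnS
12SRRNA	rrnS
12SRIBOSOMALRNA	rrnS
SRRNA	rrnS
SSURRNA	rrnS
SMALLSUBUNITRIBOSOMALRNA	rrnS
RRNL	rrnL
16S	rrnL
16SRRNA	rrnL
16SRIBOSOMALRNA	rrnL
LRRNA	rrnL
LSURRNA	rrnL
LARGESUBUNITRIBOSOMALRNA	rrnL
TRNF	tRNA-Phe
TRNAPHE	tRNA-Phe
TRNV	tRNA-Val
TRNAVAL	tRNA-Val
TRNL(UUR)	tRNA-Leu(UUR)
TRNL1	tRNA-Leu(UUR)
TRNALEU(UUR)	tRNA-Leu(UUR)
TRNL(CUN)	tRNA-Leu(CUN)
TRNL2	tRNA-Leu(CUN)
TRNALEU(CUN)	tRNA-Leu(CUN)
TRNI	tRNA-Ile
TRNAILE	tRNA-Ile
TRNQ	tRNA-Gln
TRNAGLN	tRNA-Gln
TRNM	tRNA-Met
TRNAMET	tRNA-Met
TRNW	tRNA-Trp
TRNATRP	tRNA-Trp
TRNA	tRNA-Ala
TRNAALA	tRNA-Ala
TRNN	tRNA-Asn
TRNAASN	tRNA-Asn
TRNC	tRNA-Cys
TRNACYS	tRNA-Cys
TRNY	tRNA-Tyr
TRNATYR	tRNA-Tyr
TRNS(UCN)	tRNA-Ser(UCN)
TRNS1	tRNA-Ser(UCN)
TRNASER(UCN)	tRNA-Ser(UCN)
TRNS(AGY)	tRNA-Ser(AGY)
TRNS2	tRNA-Ser(AGY)
TRNASER(AGY)	tRNA-Ser(AGY)
TRND	tRNA-Asp
TRNAASP	tRNA-Asp
TRNK	tRNA-Lys
TRNALYS	tRNA-Lys
TRNG	tRNA-Gly
TRNAGLY	tRNA-Gly
TRNR	tRNA-Arg
TRNAARG	tRNA-Arg
TRNH	tRNA-His
TRNAHIS	tRNA-His
TRNE	tRNA-Glu
TRNAGLU	tRNA-Glu
TRNT	tRNA-Thr
TRNATHR	tRNA-Thr
TRNP	tRNA-Pro
TRNAPRO	tRNA-Pro
DLOOP	D-loop
CONTROLREGION	D-loop
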