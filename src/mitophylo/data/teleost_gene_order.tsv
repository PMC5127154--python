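# Canonical teleost mitochondrial gene arrangement: 13 protein-coding genes,
# 22 tRNAs, 2 rRNAs and the control region, with ND6 and eight tRNAs encoded
# on the minus strand.
# name	kind	strand
tRNA-Phe	tRNA	+
rrnS	rRNA	+
tRNA-Val	tRNA	+
rrnL	rRNA	+
tRNA-Leu(UUR)	tRNA	+
ND1	CDS	+
tRNA-Ile	tRNA	+
tRNA-Gln	tRNA	-
tRNA-Met	tRNA	+
ND2	CDS	+
tRNA-Trp	tRNA	+
tRNA-Ala	tRNA	-
tRNA-Asn	tRNA	-
tRNA-Cys	tRNA	-
tRNA-Tyr	tRNA	-
COX1	CDS	+
tRNA-Ser(UCN)	tRNA	-
tRNA-Asp	tRNA	+
COX2	CDS	+
tRNA-Lys	tRNA	+
ATP8	CDS	+
ATP6	CDS	+
COX3	CDS	+
tRNA-Gly	tRNA	+
ND3	CDS	+
tRNA-Arg	tRNA	+
ND4L	CDS	+
ND4	CDS	+
tRNA-His	tRNA	+
tRNA-Ser(AGY)	tRNA	+
tRNA-Leu(CUN)	tRNA	+
ND5	CDS	+
ND6	CDS	-
tRNA-Glu	tRNA	-
CYTB	CDS	+
tRNA-Thr	tRNA	+
tRNA-Pro	tRNA	-
D-loop	D-loop	+
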