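# alias	canonical
# Gene-symbol normalization table, v1. Aliases are matched case-insensitively.
# tRNA anticodon punctuation variants not listed here are rewritten mechanically.
16s ribosomal rna	rrn16
16s rrna	rrn16
rrn16s	rrn16
rrn16	rrn16
23s ribosomal rna	rrn23
23s rrna	rrn23
rrn23s	rrn23
rrn23	rrn23
4.5s ribosomal rna	rrn4.5
4.5s rrna	rrn4.5
rrn4.5s	rrn4.5
rrn4.5	rrn4.5
5s ribosomal rna	rrn5
5s rrna	rrn5
rrn5s	rrn5
rrn5	rrn5
psba	psbA
psbb	psbB
psbc	psbC
psbd	psbD
psbe	psbE
psbf	psbF
psbh	psbH
psbi	psbI
psbj	psbJ
psbk	psbK
psbl	psbL
psbm	psbM
psbn	psbN
psbt	psbT
psbz	psbZ
psaa	psaA
psab	psaB
psac	psaC
psai	psaI
psaj	psaJ
psam	psaM
atpa	atpA
atpb	atpB
atpe	atpE
atpf	atpF
atph	atpH
atpi	atpI
peta	petA
petb	petB
petd	petD
petg	petG
petl	petL
petn	petN
rbcl	rbcL
ndha	ndhA
ndhb	ndhB
ndhc	ndhC
ndhd	ndhD
ndhe	ndhE
ndhf	ndhF
ndhg	ndhG
ndhh	ndhH
ndhi	ndhI
ndhj	ndhJ
ndhk	ndhK
rpoa	rpoA
rpob	rpoB
rpoc1	rpoC1
rpoc2	rpoC2
rps2	rps2
rps3	rps3
rps4	rps4
rps7	rps7
rps8	rps8
rps11	rps11
rps12	rps12
rps14	rps14
rps15	rps15
rps16	rps16
rps18	rps18
rps19	rps19
rpl2	rpl2
rpl14	rpl14
rpl16	rpl16
rpl20	rpl20
rpl21	rpl21
rpl22	rpl22
rpl23	rpl23
rpl32	rpl32
rpl33	rpl33
rpl36	rpl36
clpp	clpP
matk	matK
ccsa	ccsA
cema	cemA
infa	infA
accd	accD
chlb	chlB
chll	chlL
chln	chlN
ycf1	ycf1
ycf2	ycf2
ycf2n	ycf2n
ycf2c	ycf2c
ycf3	ycf3
ycf4	ycf4
ycf12	ycf12
ycf66	ycf66
ycf94	ycf94
trnt(ggu)	trnT-GGU
trnt-ggu	trnT-GGU
trnt(ugu)	trnT-UGU
trnt-ugu	trnT-UGU
trnd(guc)	trnD-GUC
trnd-guc	trnD-GUC
trnf(gaa)	trnF-GAA
trnf-gaa	trnF-GAA
trnq(uug)	trnQ-UUG
trnq-uug	trnQ-UUG
trnq	trnQ-UUG
trni(cau)	trnI-CAU
trni-cau	trnI-CAU
trni(gau)	trnI-GAU
trni-gau	trnI-GAU
trna(ugc)	trnA-UGC
trna-ugc	trnA-UGC
trnn(guu)	trnN-GUU
trnn-guu	trnN-GUU
trnr(acg)	trnR-ACG
trnr-acg	trnR-ACG
trnv(gac)	trnV-GAC
trnv-gac	trnV-GAC
trnl(caa)	trnL-CAA
trnl-caa	trnL-CAA
trnl(uaa)	trnL-UAA
trnl-uaa	trnL-UAA
trnl(uag)	trnL-UAG
trnl-uag	trnL-UAG
trnfm(cau)	trnfM-CAU
trnfm-cau	trnfM-CAU
trnm(cau)	trnM-CAU
trnm-cau	trnM-CAU
trng(gcc)	trnG-GCC
trng-gcc	trnG-GCC
trng(ucc)	trnG-UCC
trng-ucc	trnG-UCC
trne(uuc)	trnE-UUC
trne-uuc	trnE-UUC
trny(gua)	trnY-GUA
trny-gua	trnY-GUA
trnd(gac)	trnD-GUC
trnc(gca)	trnC-GCA
trnc-gca	trnC-GCA
trns(gcu)	trnS-GCU
trns-gcu	trnS-GCU
trns(uga)	trnS-UGA
trns-uga	trnS-UGA
trns(gga)	trnS-GGA
trns-gga	trnS-GGA
trnk(uuu)	trnK-UUU
trnk-uuu	trnK-UUU
trnh(gug)	trnH-GUG
trnh-gug	trnH-GUG
trnw(cca)	trnW-CCA
trnw-cca	trnW-CCA
trnp(ugg)	trnP-UGG
trnp-ugg	trnP-UGG
trnr(ucu)	trnR-UCU
trnr-ucu	trnR-UCU
trnv(uac)	trnV-UAC
trnv-uac	trnV-UAC
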