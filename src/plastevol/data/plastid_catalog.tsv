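# element	category	host
# Canonical land-plant plastome element catalog, v1.
# categories: protein (87, incl. ycf94), rRNA (4), tRNA (32), intron (22).
atpA	protein
atpB	protein
atpE	protein
atpF	protein
atpH	protein
atpI	protein
ndhA	protein
ndhB	protein
ndhC	protein
ndhD	protein
ndhE	protein
ndhF	protein
ndhG	protein
ndhH	protein
ndhI	protein
ndhJ	protein
ndhK	protein
petA	protein
petB	protein
petD	protein
petG	protein
petL	protein
petN	protein
psaA	protein
psaB	protein
psaC	protein
psaI	protein
psaJ	protein
psaM	protein
psbA	protein
psbB	protein
psbC	protein
psbD	protein
psbE	protein
psbF	protein
psbH	protein
psbI	protein
psbJ	protein
psbK	protein
psbL	protein
psbM	protein
psbN	protein
psbT	protein
psbZ	protein
rpl2	protein
rpl14	protein
rpl16	protein
rpl20	protein
rpl21	protein
rpl22	protein
rpl23	protein
rpl32	protein
rpl33	protein
rpl36	protein
rpoA	protein
rpoB	protein
rpoC1	protein
rpoC2	protein
rps2	protein
rps3	protein
rps4	protein
rps7	protein
rps8	protein
rps11	protein
rps12	protein
rps14	protein
rps15	protein
rps16	protein
rps18	protein
rps19	protein
rbcL	protein
matK	protein
ccsA	protein
cemA	protein
clpP	protein
infA	protein
accD	protein
chlB	protein
chlL	protein
chlN	protein
ycf1	protein
ycf2	protein
ycf3	protein
ycf4	protein
ycf12	protein
ycf66	protein
ycf94	protein
rrn16	rRNA
rrn23	rRNA
rrn4.5	rRNA
rrn5	rRNA
trnA-UGC	tRNA
trnC-GCA	tRNA
trnD-GUC	tRNA
trnE-UUC	tRNA
trnF-GAA	tRNA
trnfM-CAU	tRNA
trnG-GCC	tRNA
trnG-UCC	tRNA
trnH-GUG	tRNA
trnI-CAU	tRNA
trnI-GAU	tRNA
trnK-UUU	tRNA
trnL-CAA	tRNA
trnL-UAA	tRNA
trnL-UAG	tRNA
trnM-CAU	tRNA
trnN-GUU	tRNA
trnP-GGG	tRNA
trnP-UGG	tRNA
trnQ-UUG	tRNA
trnR-ACG	tRNA
trnR-CCG	tRNA
trnR-UCU	tRNA
trnS-GCU	tRNA
trnS-GGA	tRNA
trnS-UGA	tRNA
trnT-GGU	tRNA
trnT-UGU	tRNA
trnV-GAC	tRNA
trnV-UAC	tRNA
trnW-CCA	tRNA
trnY-GUA	tRNA
atpF-intron1	intron	atpF
clpP-intron1	intron	clpP
clpP-intron2	intron	clpP
ndhA-intron1	intron	ndhA
ndhB-intron1	intron	ndhB
petB-intron1	intron	petB
petD-intron1	intron	petD
rpl2-intron1	intron	rpl2
rpl16-intron1	intron	rpl16
rpoC1-intron1	intron	rpoC1
rps12-intron1	intron	rps12
rps12-intron2	intron	rps12
rps16-intron1	intron	rps16
trnA-UGC-intron1	intron	trnA-UGC
trnG-UCC-intron1	intron	trnG-UCC
trnI-GAU-intron1	intron	trnI-GAU
trnK-UUU-intron1	intron	trnK-UUU
trnL-UAA-intron1	intron	trnL-UAA
trnV-UAC-intron1	intron	trnV-UAC
ycf3-intron1	intron	ycf3
ycf3-intron2	intron	ycf3
ycf66-intron1	intron	ycf66
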