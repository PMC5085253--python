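# rCRS gene annotation, 1-based inclusive coordinates (MITOMAP convention).
# The D-loop wraps across the origin (16024..576). Light-strand genes are
# read from the reverse complement. Several protein genes end in incomplete
# stop codons completed by polyadenylation.
name	start	end	strand	kind
D-loop	16024	576	heavy	dloop
TRNF	577	647	heavy	trna
RNR1	648	1601	heavy	rrna
TRNV	1602	1670	heavy	trna
RNR2	1671	3229	heavy	rrna
TRNL1	3230	3304	heavy	trna
ND1	3307	4262	heavy	protein
TRNI	4263	4331	heavy	trna
TRNQ	4329	4400	light	trna
TRNM	4402	4469	heavy	trna
ND2	4470	5511	heavy	protein
TRNW	5512	5579	heavy	trna
TRNA	5587	5655	light	trna
TRNN	5657	5729	light	trna
TRNC	5761	5826	light	trna
TRNY	5826	5891	light	trna
CO1	5904	7445	heavy	protein
TRNS1	7446	7514	light	trna
TRND	7518	7585	heavy	trna
CO2	7586	8269	heavy	protein
TRNK	8295	8364	heavy	trna
ATP8	8366	8572	heavy	protein
ATP6	8527	9207	heavy	protein
CO3	9207	9990	heavy	protein
TRNG	9991	10058	heavy	trna
ND3	10059	10404	heavy	protein
TRNR	10405	10469	heavy	trna
ND4L	10470	10766	heavy	protein
ND4	10760	12137	heavy	protein
TRNH	12138	12206	heavy	trna
TRNS2	12207	12265	heavy	trna
TRNL2	12266	12336	heavy	trna
ND5	12337	14148	heavy	protein
ND6	14149	14673	light	protein
TRNE	14674	14742	light	trna
CYB	14747	15887	heavy	protein
TRNT	15888	15953	heavy	trna
TRNP	15956	16023	light	trna
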