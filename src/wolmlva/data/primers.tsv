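locus	forward	reverse
VNTR-141	ggagtattattgatatgcg	gactaaaggttagttgcat
VNTR-105	gcaattgaaaatgtggtgcc	atgacaccttacttaaccgtc
WD0550	ggccaccatgggatcagaatttgaag	gatgacttatacgcagccccatag
WD0766	gaccaccatgaaatatgacaaattt	tcaagtaagtgctttttctgtc
wsp	tggtccaataagtgatgaagaaac	aaaaattaaacgctactcca
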