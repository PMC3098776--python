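symbol	locus
B	rpoB
C	trnC-GCA
N	petN
M	psbM
D	trnD-GUC
Y	trnY-GUA
E	trnE-UUC
G	trnG-GCC
Z	psbZ
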