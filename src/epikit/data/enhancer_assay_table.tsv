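element	dar_pos	dar_neg	egfp
bmp2a+43k	Yes	Yes	-
chst3b+5k	Yes	Yes	+
cygb1-13k	Yes	Yes	+
dnajc17-138k	Yes	Yes	+
lef1-2k	Yes	Yes	-
pdgfab-8k	Yes	Yes	+
prdm1c+6k	Yes	Yes	+
runx1-102k	Yes	Yes	-
cdc42ep3+2k	Yes	No	+
col11a1a-6k	Yes	No	+
col11a2-7k	Yes	No	+
fam102aa+11k	Yes	No	+
fbln1+17k	Yes	No	+
mef2aa+2k	Yes	No	+
mitd1-6k	Yes	No	-
prdm5+120k	Yes	No	+
rmb7-120k	Yes	No	-
swap70b+3k	Yes	No	+
fhod3b+138k	No	Yes	+
frmd4a+87k	No	Yes	+
grip2a-23k	No	Yes	+
igflr1-2k	No	Yes	-
mtnr1aa+31k	No	Yes	+
ptk2aa+9k	No	Yes	+
rasl11a-13k	No	Yes	-
atp5g3a-14k	No	No	-
lmbr1+11k(ZRS)	No	No	-
lnpa+56k	No	No	-
six3b-102k	No	No	-
six3b-104k	No	No	-
six3b-36k	No	No	-
six3b-39k	No	No	-
wnt3-11k	No	No	-
zgc:173726-2kb	No	No	-
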