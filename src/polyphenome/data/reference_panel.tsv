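# Curated classification reference panel: named compounds with expected
# labels under the shipped 43-pattern library. Multi-label entries reflect
# documented core redundancy (a flavonol embeds the flavone core; the
# flavanone core is shared with the 3-hydroxy dihydroflavonols).
compound_id	smiles	expected_subclasses	expected_classes	expected_excluded	expected_reason
quercetin	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	flavones;flavonols	flavonoids	False	none
luteolin	O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	flavones	flavonoids	False	none
(+)-catechin	O[C@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1ccc(O)c(O)c1	flavanols	flavonoids	False	none
naringenin	O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21	dihydroflavonols;flavanones	flavonoids	False	none
taxifolin	O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)C1O	dihydroflavonols	flavonoids	False	none
genistein	O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12	isoflavonoids	flavonoids	False	none
daidzein	O=c1c(-c2ccc(O)cc2)coc2ccc(O)cc12	isoflavonoids	flavonoids	False	none
coumestrol	Oc1ccc2c(c1)oc1c2c(=O)oc2ccc(O)cc12	isoflavonoids	flavonoids	False	none
equol	Oc1ccc(C2COc3cc(O)ccc3C2)cc1	isoflavonoids	flavonoids	False	none
cyanidin	Oc1cc(O)c2cc(O)c(-c3ccc(O)c(O)c3)[o+]c2c1	anthocyanins	flavonoids	False	none
phloretin	O=C(CCc1ccc(O)cc1)c1c(O)cc(O)cc1O	dihydrochalcones	flavonoids	False	none
butein	O=C(/C=C/c1ccc(O)c(O)c1)c1ccc(O)cc1O	chalcones	flavonoids	False	none
gallic acid	O=C(O)c1cc(O)c(O)c(O)c1	hydroxybenzoic acids	phenolic acids	False	none
caffeic acid	O=C(O)/C=C/c1ccc(O)c(O)c1	hydroxycinnamic acids	phenolic acids	False	none
ferulic acid	COc1cc(/C=C/C(=O)O)ccc1O	hydroxycinnamic acids	phenolic acids	False	none
4-hydroxyphenylacetic acid	O=C(O)Cc1ccc(O)cc1	hydroxyphenylacetic acids	phenolic acids	False	none
phloretic acid	O=C(O)CCc1ccc(O)cc1	hydroxyphenylpropanoic acids	phenolic acids	False	none
trans-resveratrol	Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	stilbenes	stilbenes	False	none
secoisolariciresinol	COc1cc(CC(CO)C(CO)Cc2ccc(O)c(OC)c2)ccc1O	lignans	lignans	False	none
pinoresinol	COc1cc(C2OCC3C2COC3c2ccc(O)c(OC)c2)ccc1O	lignans	lignans	False	none
tyrosol	OCCc1ccc(O)cc1	tyrosols	other polyphenols	False	none
curcumin	COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O	curcuminoids	other polyphenols	False	none
psoralen	O=c1ccc2cc3ccoc3cc2o1	furanocoumarins	other polyphenols	False	none
umbelliferone	O=c1ccc2ccc(O)cc2o1	hydroxycoumarins	other polyphenols	False	none
vanillin	COc1cc(C=O)ccc1O	hydroxybenzaldehydes	other polyphenols	False	none
coniferaldehyde	COc1cc(/C=C/C=O)ccc1O	hydroxycinnamaldehydes	other polyphenols	False	none
acetovanillone	CC(=O)c1ccc(O)c(OC)c1	hydroxybenzoketones	other polyphenols	False	none
eugenol	C=CCc1ccc(O)c(OC)c1	hydroxyphenylpropenes	other polyphenols	False	none
5-pentadecylresorcinol	CCCCCCCCCCCCCCCc1cc(O)cc(O)c1	alkylphenols	other polyphenols	False	none
4-methylguaiacol	Cc1ccc(O)c(OC)c1	alkylmethoxyphenols	other polyphenols	False	none
guaiacol	COc1ccccc1O	methoxyphenols	other polyphenols	False	none
thymol	Cc1ccc(C(C)C)c(O)c1	phenolic terpenes	other polyphenols	False	none
carvacrol	Cc1ccc(C(C)C)cc1O	phenolic terpenes	other polyphenols	False	none
juglone	O=C1C=CC(=O)c2cccc(O)c21	naphthoquinones	other polyphenols	False	none
emodin	Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O	anthraquinones	other polyphenols	False	none
phloroglucinol	Oc1cc(O)cc(O)c1	other polyphenols	other polyphenols	False	none
caffeine	Cn1c(=O)c2c(ncn2C)n(C)c1=O			True	contains_nitrogen
nicotine	CN1CCC[C@H]1c1cccnc1			True	contains_nitrogen
cholesterol	CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C			True	steroid
estradiol	CC12CCC3c4ccc(O)cc4CCC3C1CCC2O			True	steroid
nonacontane	CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC			True	mass_gt_1200
hexane	CCCCCC			False	none
limonene	CC(=C)C1CCC(C)=CC1			False	none
benzoic acid	O=C(O)c1ccccc1			False	none
toluene	Cc1ccccc1			False	none
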