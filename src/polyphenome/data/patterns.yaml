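# Polyphenol substructure library: 43 SMARTS cores covering 31 subclasses in
# 5 queryable classes. Patterns are written against aromatized, standardized
# structures (see polyphenome.standardize) and are deliberately permissive
# cores: ring positions not constrained by the SMARTS are open to
# substitution (hydroxylation, methoxylation, glycosylation).
# A pattern may map to more than one subclass (redundancy): e.g. the
# flavanone core is shared by flavanones and their 3-hydroxy derivatives.
patterns:
  - pattern_id: anthocyanidin
    smarts: "c1cc2ccccc2[o+]c1-c1ccccc1"
    subclasses: [anthocyanins]
    class: flavonoids
  - pattern_id: anthraquinone
    smarts: "O=C1c2ccccc2C(=O)c2ccccc21"
    subclasses: [anthraquinones]
    class: other polyphenols
  - pattern_id: alkylmethoxyphenol
    smarts: "[$([CH3]),$([CH2][CH3]),$([CH]=[CH2])]c1ccc([OX2H])c([OX2][CH3])c1"
    subclasses: [alkylmethoxyphenols]
    class: other polyphenols
  - pattern_id: alkylresorcinol
    smarts: "[CX4;!$(C[#8])]c1cc([OX2H])cc([OX2H])c1"
    subclasses: [alkylphenols]
    class: other polyphenols
  - pattern_id: chalcone
    smarts: "O=C(C=Cc1ccccc1)c1ccccc1"
    subclasses: [chalcones]
    class: flavonoids
  - pattern_id: coumestan
    smarts: "O=c1oc2ccccc2c2oc3ccccc3c12"
    subclasses: [isoflavonoids]
    class: flavonoids
  - pattern_id: curcuminoid
    smarts: "O=C(C=Cc1ccccc1)CC(=O)C=Cc1ccccc1"
    subclasses: [curcuminoids]
    class: other polyphenols
  - pattern_id: dibenzylbutane
    smarts: "c1ccc(C[CH]([#6])[CH]([#6])Cc2ccccc2)cc1"
    subclasses: [lignans]
    class: lignans
  - pattern_id: dihydrochalcone
    smarts: "O=C([CH2][CH2]c1ccccc1)c1ccccc1"
    subclasses: [dihydrochalcones]
    class: flavonoids
  - pattern_id: dihydroflavonol
    smarts: "O=C1[CH](c2ccccc2)Oc2ccccc2[CH]1[OX2]"
    subclasses: [dihydroflavonols]
    class: flavonoids
  - pattern_id: flavan-3-ol
    smarts: "[OX2][CH]1[CH2]c2ccccc2O[CH]1c1ccccc1"
    subclasses: [flavanols]
    class: flavonoids
  - pattern_id: flavanone
    smarts: "O=C1C[CH](c2ccccc2)Oc2ccccc21"
    subclasses: [flavanones, dihydroflavonols]
    class: flavonoids
  - pattern_id: flavone
    smarts: "O=c1cc(-c2ccccc2)oc2ccccc12"
    subclasses: [flavones]
    class: flavonoids
  - pattern_id: flavonol
    smarts: "O=c1c([OX2])c(-c2ccccc2)oc2ccccc12"
    subclasses: [flavonols]
    class: flavonoids
  - pattern_id: furanocoumarin
    smarts: "O=c1ccc2cc3ccoc3cc2o1"
    subclasses: [furanocoumarins]
    class: other polyphenols
  - pattern_id: furofuran-lignan
    smarts: "c1ccc([CH]2OC[CH]3[CH]2CO[CH]3c2ccccc2)cc1"
    subclasses: [lignans]
    class: lignans
  - pattern_id: hydroxybenzaldehyde
    smarts: "O=[CH]c1ccc([OX2])cc1"
    subclasses: [hydroxybenzaldehydes]
    class: other polyphenols
  - pattern_id: hydroxybenzoic-acid-meta
    smarts: "[#8]C(=O)c1cccc([OX2])c1"
    subclasses: [hydroxybenzoic acids]
    class: phenolic acids
  - pattern_id: hydroxybenzoic-acid-ortho
    smarts: "[#8]C(=O)c1ccccc1[OX2]"
    subclasses: [hydroxybenzoic acids]
    class: phenolic acids
  - pattern_id: hydroxybenzoic-acid-para
    smarts: "[#8]C(=O)c1ccc([OX2])cc1"
    subclasses: [hydroxybenzoic acids]
    class: phenolic acids
  - pattern_id: hydroxybenzoketone
    smarts: "[CX4;$([CH3]),$([CH2][OX2]),$([CH]([OX2]))][CX3;!R](=O)c1ccc([OX2])cc1"
    subclasses: [hydroxybenzoketones]
    class: other polyphenols
  - pattern_id: hydroxycinnamaldehyde
    smarts: "O=[CH]C=Cc1ccc([OX2])cc1"
    subclasses: [hydroxycinnamaldehydes]
    class: other polyphenols
  - pattern_id: hydroxycinnamic-acid-meta
    smarts: "[#8]C(=O)C=Cc1cccc([OX2])c1"
    subclasses: [hydroxycinnamic acids]
    class: phenolic acids
  - pattern_id: hydroxycinnamic-acid-ortho
    smarts: "[#8]C(=O)C=Cc1ccccc1[OX2]"
    subclasses: [hydroxycinnamic acids]
    class: phenolic acids
  - pattern_id: hydroxycinnamic-acid-para
    smarts: "[#8]C(=O)C=Cc1ccc([OX2])cc1"
    subclasses: [hydroxycinnamic acids]
    class: phenolic acids
  - pattern_id: hydroxycoumarin
    smarts: "O=c1ccc2ccc([OX2])cc2o1"
    subclasses: [hydroxycoumarins]
    class: other polyphenols
  - pattern_id: hydroxyphenylacetic-acid-meta
    smarts: "[#8]C(=O)[CH2]c1cccc([OX2])c1"
    subclasses: [hydroxyphenylacetic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylacetic-acid-ortho
    smarts: "[#8]C(=O)[CH2]c1ccccc1[OX2]"
    subclasses: [hydroxyphenylacetic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylacetic-acid-para
    smarts: "[#8]C(=O)[CH2]c1ccc([OX2])cc1"
    subclasses: [hydroxyphenylacetic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylpentanoic-acid
    smarts: "[#8]C(=O)[CH2][CH2][CH2][CH2]c1ccc([OX2])cc1"
    subclasses: [hydroxyphenylpentanoic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylpropanoic-acid-meta
    smarts: "[#8]C(=O)[CH2][CH2]c1cccc([OX2])c1"
    subclasses: [hydroxyphenylpropanoic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylpropanoic-acid-ortho
    smarts: "[#8]C(=O)[CH2][CH2]c1ccccc1[OX2]"
    subclasses: [hydroxyphenylpropanoic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylpropanoic-acid-para
    smarts: "[#8]C(=O)[CH2][CH2]c1ccc([OX2])cc1"
    subclasses: [hydroxyphenylpropanoic acids]
    class: phenolic acids
  - pattern_id: hydroxyphenylpropene
    smarts: "C=C[CX4]c1ccc([OX2])cc1"
    subclasses: [hydroxyphenylpropenes]
    class: other polyphenols
  - pattern_id: isoflavan
    smarts: "[CH2]1Oc2ccccc2[CH2][CH]1-c1ccccc1"
    subclasses: [isoflavonoids]
    class: flavonoids
  - pattern_id: isoflavone
    smarts: "O=c1c(-c2ccccc2)coc2ccccc12"
    subclasses: [isoflavonoids]
    class: flavonoids
  - pattern_id: methoxyphenol
    smarts: "[OX2H]c1[cH][cH][cH][cH]c1[OX2][CH3]"
    subclasses: [methoxyphenols]
    class: other polyphenols
  - pattern_id: naphthoquinone
    smarts: "O=C1C=CC(=O)c2ccccc21"
    subclasses: [naphthoquinones]
    class: other polyphenols
  - pattern_id: phenolic-terpene-carvacrol
    smarts: "[CH3][CH]([CH3])c1ccc([CH3])c([OX2H])c1"
    subclasses: [phenolic terpenes]
    class: other polyphenols
  - pattern_id: phenolic-terpene-thymol
    smarts: "[CH3][CH]([CH3])c1ccccc1[OX2H]"
    subclasses: [phenolic terpenes]
    class: other polyphenols
  - pattern_id: phloroglucinol
    smarts: "[OX2H]c1[cH]c([OX2H])[cH]c([OX2H])[cH]1"
    subclasses: [other polyphenols]
    class: other polyphenols
  - pattern_id: stilbene
    smarts: "c1ccc(C=Cc2ccccc2)cc1"
    subclasses: [stilbenes]
    class: stilbenes
  - pattern_id: tyrosol
    smarts: "[OX2][CH2][CH2]c1ccc([OX2])cc1"
    subclasses: [tyrosols]
    class: other polyphenols
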