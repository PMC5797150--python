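"""Standardize and classify a handful of named food bioactives.

Each compound is normalized (fragment removal, neutralization, canonical
tautomer, aromatization) and then matched against the 43-pattern polyphenol
substructure library. The printed labels are multi-label: a molecule may
carry several subclasses, and decoys are either excluded (nitrogen, steroid,
>1200 Da) or kept with no class at all.
"""

from polyphenome import classify, load_pattern_library, standardize

COMPOUNDS = [
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),
    ("genistein", "O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12"),
    ("trans-resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1"),
    ("caffeic acid", "O=C(O)/C=C/c1ccc(O)c(O)c1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("cholesterol", "CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C"),
]

library = load_pattern_library()
print(f"{'compound':20s} {'status':18s} subclasses")
for name, smiles in COMPOUNDS:
    c = classify(standardize(smiles, name), library)
    status = f"excluded ({c.exclusion_reason.value})" if c.excluded else "classified"
    print(f"{name:20s} {status:18s} {', '.join(sorted(c.subclasses)) or '-'}")
# A flavonol reports both the flavone and flavonol subclasses because the
# 3-hydroxyflavone core embeds the flavone core; caffeine and cholesterol
# never reach pattern matching - the exclusion filters remove them first.
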