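"""Strict-stereochemistry list matching on canonical keys.

Two lists are matched by canonical SMILES equality. Under strict stereo the
(+)- and (-)-catechin enantiomers get different keys and do not match; with
stereo relaxed they collapse to the same key.
"""

from polyphenome import match_lists, standardize_many

list_a = standardize_many([
    ("(+)-catechin", "O[C@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1ccc(O)c(O)c1"),
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),
])
list_b = standardize_many([
    ("(-)-catechin", "O[C@@H]1Cc2c(O)cc(O)cc2O[C@H]1c1ccc(O)c(O)c1"),
    ("quercetin-scrambled", "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O"),
])

for strict in (True, False):
    result = match_lists(list_a, list_b, strict_stereo=strict)
    print(f"strict_stereo={strict}: {len(result.pairs)} pair(s): {list(result.pairs)}")
# Quercetin matches regardless of the SMILES atom order it was written with;
# the catechin pair only matches once stereo descriptors are stripped.
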