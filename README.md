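# polyphenome

From polyphenol structures to the pathways their protein targets cover.

Dietary polyphenols — flavonoids, phenolic acids, stilbenes, lignans, and a
long tail of "other" phenolics — interact with hundreds of human proteins
(detoxification enzymes, transporters, nuclear receptors, kinases), and the
systems-level question is which biological pathways those targets cover.
`polyphenome` is a library (plus a thin CLI) for researchers in food
bioactives and polypharmacology who want to run that analysis end to end:

1. **Standardize** structures deterministically — keep the largest organic
   fragment, neutralize, suppress explicit hydrogens, pick a canonical
   tautomer, aromatize — and match compound lists by canonical SMILES keys
   with strict stereochemistry.
2. **Classify** polyphenols by substructure: a shipped library of 43 SMARTS
   cores covering 31 subclasses in 5 queryable classes (flavonoids, lignans,
   phenolic acids, stilbenes, other polyphenols; a sixth declared class,
   non-phenolic metabolites, has no fixed structural feature). Exclusion
   filters first remove molecules with average mass > 1200 Da, any nitrogen
   atom, or a steroid (gonane) scaffold.
3. **Assemble an interactome** from three interaction-table dialects
   (STITCH-like TSV with evidence channels, Pathway-Commons-like SIF,
   BindingDB-like TSV), excluding records supported solely by text mining or
   with combined confidence < 0.9, and merging into a deduplicated bipartite
   compound–protein network with per-edge source provenance.
4. **Enrich**: for a query set of n proteins from a universe of N, a pathway
   with K members and k hits gets the exact upper-tail hypergeometric
   p-value P[X ≥ k], X ~ Hypergeom(N, K, n); p-values are Benjamini–Hochberg
   adjusted per query family, and a pathway is significant when
   p_BH < 0.1 **and** coverage k/K > 0.1, with KEGG-style category roll-ups
   including the cardiometabolic (CMD) super-category.
5. **Food case studies**: binary composition sets, per-food sub-interactomes,
   and per-compound enrichment networks at the stricter coverage > 0.2.

Seeded synthetic-data generators emit every input dialect together with a
ground-truth ledger (planted subclasses, decoys, cross-source overlaps,
planted enrichments, food overlaps), so each stage is testable without any
external database.

## Worked example

```bash
python examples/classify_compounds.py
```

```
compound             status             subclasses
quercetin            classified         flavones, flavonols
genistein            classified         isoflavonoids
trans-resveratrol    classified         stilbenes
caffeic acid         classified         hydroxycinnamic acids
caffeine             excluded (contains_nitrogen) -
cholesterol          excluded (steroid) -
```

Quercetin carries both the flavone and flavonol labels because the
3-hydroxyflavone core embeds the flavone core (the library is deliberately
multi-label); caffeine and cholesterol never reach pattern matching — the
exclusion filters remove nitrogen-containing compounds and steroids first.

```bash
python examples/pathway_enrichment.py
```

```
pathway    k/K      p_raw       p_bh  coverage  significant
PW0    10/12    8.75e-10   2.63e-09      0.83  True
PW1     0/28           1          1      0.00  False
PW2     0/20           1          1      0.00  False
```

Ten of the twelve members of PW0 appear among the ten query proteins, so its
coverage is 0.83 and its adjusted p-value is far below 0.1: significant on
both criteria.

Other examples: `build_interactome.py` (dialect parsing, evidence filter,
source overlap, degree histograms), `match_compound_lists.py` (strict-stereo
matching), `citrus_case_study.py` (six-food comparison and per-compound food
network), `simulate_and_run_pipeline.py` (full run with manifest). The same
functionality is exposed as a CLI:

```bash
polyphenome simulate --seed 42 --out sim/
polyphenome run --config config.yaml --out results/
```

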