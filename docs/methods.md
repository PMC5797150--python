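# Methods

## Scope and model

`polyphenome` operationalizes "polyphenol" not by nomenclature but by
substructure membership in a two-level taxonomy: 43 SMARTS cores map to 31
subclasses organized in 5 queryable classes (flavonoids, lignans, phenolic
acids, stilbenes, other polyphenols). A sixth declared class, non-phenolic
metabolites, has no fixed structural feature and is deliberately not
queryable. Downstream, compounds are linked to proteins through evidence-
filtered interaction records, and the protein sets are interpreted through
hypergeometric pathway over-representation.

## Structure standardization

Standardization applies, in order: (i) largest-organic-fragment selection
(ties broken by RDKit's deterministic chooser), (ii) charge neutralization,
(iii) explicit-hydrogen suppression, (iv) canonical-tautomer selection
(bounded enumeration, max 500 transforms/tautomers, so the choice is
deterministic and fast), and (v) aromatization, followed by canonical SMILES
generation. The canonical SMILES is a fixed point of the pipeline
(idempotence is asserted on every synthetic library).

Stereochemistry: tetrahedral stereocenters survive standardization, so
strict-key matching distinguishes enantiomers such as (+)- and
(−)-catechin, and an entry with unspecified stereocenters never matches a
stereo-annotated one under strict mode. Double-bond stereo on
tautomer-mobile bonds (e.g. the stilbene C=C conjugated to phenols) is
dropped by the canonical-tautomer step: the chosen tautomer is a
deterministic representative of the interconvertible set, and keeping an
E/Z label on a bond the tautomer graph can formally invert would make equal
molecules hash to different keys. This is the documented contract where the
underlying toolkit behavior was genuinely open.

## The substructure library

The 43 cores are authored from the subclass definitions (flavone =
2-phenylchromen-4-one; stilbene = 1,2-diphenylethene; hydroxycinnamic acid
= hydroxyphenyl-propenoic acid with ortho/meta/para variants; and so on)
and shipped as an editable YAML file. Design choices:

* **Permissive cores.** Ring positions not constrained by a SMARTS are open
  to substitution, so hydroxylated, methoxylated, and glycosylated
  derivatives match their parent core. Ring oxygen substituents are written
  as `[OX2]` (hydroxy or ether/glycoside) except where a free phenol is the
  defining feature (`[OX2H]`, e.g. alkylresorcinols).
* **Deliberate multi-labeling.** Some cores embed others (3-hydroxyflavone
  embeds flavone), and the flavanone core is shared with dihydroflavonols
  (3-hydroxyflavanones); one pattern may therefore map to more than one
  subclass, and one compound to several labels.
* **Patterns are written against standardized structures.** The
  dihydroflavonol core, in particular, is expressed against the canonical
  tautomer the standardizer actually produces (3-keto-4-ol), not the
  textbook 4-keto-3-ol depiction.
* **Exclusion filters precede matching**, in fixed order: average molecular
  mass > 1200 Da, any nitrogen atom, steroid scaffold (gonane
  cyclopenta[a]phenanthrene tetracycle with any bond orders, so estrane-type
  aromatized steroids also match). First hit wins; excluded compounds carry
  no labels. The order is a reproducibility convention — the three rules
  are near-disjoint in practice.

A curated 45-compound reference panel (named compounds spanning all 31
subclasses plus nine decoys) ships with the package; the classifier must
agree with it exactly.

## Interactome assembly

Three dialects are parsed into a common record type. Only the STITCH-like
dialect carries evidence channels (experimental, database, prediction,
textmining) and a combined confidence score; raw scores are integers 0–999
normalized by /1000, so the published 0.9 threshold equals raw 900.
Filtering removes a record when (a) its only positive channel is text
mining — a high combined score does not rescue such a record — or,
independently, (b) its combined score is strictly below the threshold (0.9
default; 0.7 is the relaxed micronutrient-style setting). Non-scored
dialects (SIF, BindingDB-like) pass the score test vacuously: direct-binding
evidence is not confidence-scored, and no affinity cutoff is applied by
default (an optional ceiling flag exists). Protein identifiers are
normalized to uppercase gene symbols, optionally through a user-supplied
two-column mapping.

Merging deduplicates (compound, protein) pairs across dialects; each edge
remembers its supporting sources, and both the raw input-record count and
the deduplicated edge count are reported. Degree histograms use the
per-side bin schemes with half-open [lo, hi) intervals, so a boundary
degree (a protein with exactly 50 partners) falls in the higher bin
("50–70"); the lowest compound bin is labeled "<=10".

## Enrichment

The test is the exact one-sided upper-tail hypergeometric probability
P[X ≥ k] (scipy's survival function; no normal approximation), verified in
the test suite against full draw-by-draw enumeration for every feasible
(k, K, n, N) with N ≤ 12. Benjamini–Hochberg adjustment (statsmodels) is
verified against a literal implementation of the step-up definition.
Conventions:

* **Universe** defaults to the union of all gene-set members; query
  proteins outside it are dropped with a logged count.
* **Family** = all pathways tested for one query (one polyphenol class, or
  one compound in the food analysis); families are never pooled across
  queries, because results are reported per class.
* **Significance** requires both p_BH < alpha (0.1) and coverage k/K >
  min_coverage (0.1 at class level, 0.2 for the per-compound food
  analysis); both inequalities are strict. A `raw_p` escape hatch calls
  significance on the unadjusted p-value instead, reproducing the looser
  reading some summary figures use.
* **No minimum pathway size**: the coverage criterion already suppresses
  tiny-overlap artifacts.
* Category roll-ups report, per category, the percentage of its tested
  pathways called significant; the CMD (cardiometabolic) super-category is
  the union of the "Cardiovascular Diseases" and "Endocrine and Metabolic
  Diseases" subcategories.

## Food-level analysis

A food is a binary compound set — presence irrespective of concentration;
concentration weighting and bioavailability are out of scope by design.
The food interactome is the sub-network induced by the food's compounds.
The food enrichment network is built per compound (not pooled): each
compound's own interactor set is tested against the shared universe, and an
edge compound→pathway exists only for significant calls at the stricter
coverage > 0.2. Compound names in composition files resolve by exact id
first, then by canonical-key match; unresolved names are reported, never
silently dropped.

## Synthetic data and what it does (not) show

The generators emulate the shapes of the real inputs, not their content: a
natural-product library where true polyphenols (scaffold decorations with
hydroxy/methoxy/glycosyl substituents over all 31 subclasses) sit among
nitrogen heterocycles, steroid cores, >1200 Da constructs, and unremarkable
kept-but-unclassified organics; interaction tables whose channel scores
span [0.15, 0.999] with a configurable text-mining-only fraction, planted
cross-source overlaps, and a planted top-degree hub; a category-organized
pathway collection (default 100 pathways of 10–60 members) with optional
planted enrichments at a chosen odds ratio; and a block-design food table
whose pairwise Jaccard overlaps are realized exactly.

Every generator is deterministic under a fixed seed: one integer seed
drives a labeled sub-stream per generator (CRC-hashed label), so outputs
are byte-identical and adding a generator does not shift the others.
Default scales (500 compounds, 2,000 proteins, 100 pathways) keep the full
suite at minutes on one CPU.

Passing on synthetic data shows the machinery is correct (planted truths
are recovered; filters, counts, and statistics behave as specified). It
does not show that the SMARTS cores delimit the real polyphenol chemical
space as a curated database would, nor that real interaction databases have
the generator's independence structure — real channel scores are
correlated, real degree distributions are heavier-tailed, and real pathway
collections overlap heavily.

## Enrichment calibration benchmark

`polyphenome.calibration` measures power and false-positive behavior under
known truth, at the operating point: query 50 proteins, universe 1,000,
families of 50 pathways, alpha 0.1, coverage > 0.1.

* **Power**: one pathway per family has its members sampled with weight 5
  (odds ratio 5) for query proteins. Benchmark pathways have 80–120
  members — at this universe scale the large-pathway regime, chosen because
  an odds-ratio-5 plant must produce a detectable *absolute* effect: with
  ~50 query proteins, the same odds ratio in a 10–20-member pathway shifts
  the expected hit count by only 2–4 proteins and is intrinsically hard to
  detect at any error control. Measured recovery is ≈ 0.95 over 100 seeded
  runs.
* **Null**: with nothing planted, the fraction of families showing any
  significant pathway is ≈ 0.05 over 200 runs, consistent with BH control
  plus the coverage criterion.

## Numerical and degenerate-input conventions

* Hypergeometric edge cases: k ≤ 0 returns exactly 1; K = 0 (pathway
  disjoint from the universe) is reported with p = 1 and coverage 0.
* Duplicate canonical keys within one list log a warning and keep the first
  occurrence; duplicate compound ids are a hard error.
* All outputs (tables, JSON, GraphML) are emitted in sorted order with no
  timestamps, so identical runs are byte-identical.
* Average atomic masses are used for the 1200 Da cut (strictly greater
  than).

## Known limitations

* The substructure cores trade precision for recall at the margins: the
  open-position convention can attach a sibling subclass to heavily
  decorated molecules. The library is a data file precisely so such cores
  can be refined.
* Tautomer canonicalization is bounded; for very large tautomer graphs the
  canonical form depends on the enumeration cap (fixed, hence still
  deterministic).
* Anthocyanidins are retained as flavylium cations: their positive charge
  is not neutralizable by deprotonation-style rules, so the net-zero-charge
  invariant applies only where neutralization is chemically possible.
* The SIF and BindingDB-like dialects carry no evidence scores, so the
  confidence filter cannot apply to them; a user wanting an affinity cutoff
  must opt in.
* Real-food analyses require user-supplied composition tables; the shipped
  six-fruit table is synthetic.
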