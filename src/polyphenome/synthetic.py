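"""Seeded generators for every input the pipeline consumes.

Each generator emits both the artifact (SMILES library, interaction tables
in three dialects, GMT pathway collection, food composition table) and a
ledger of the ground truth it planted (intended subclass per compound,
intended exclusion reason per decoy, cross-source node overlaps, planted
pathway enrichments, pairwise food overlaps). The ledger is what downstream
stages are checked against, so every stage has an oracle without any
external download.

Determinism: one integer seed drives a labeled sub-stream per generator
(derived by hashing the generator's label), so outputs are byte-identical
under a fixed seed and adding a generator does not shift the others.

The emulated conditions mirror the data sources the pipeline targets: a
natural-product library in which true polyphenols sit among nitrogen
decoys, steroids, and very large molecules; interaction records with
evidence channels and confidence scores spanning the 0.15-0.9(+) range, a
fraction supported by text mining alone; and a category-organized pathway
collection at the few-hundred-pathway scale, scaled down to run in seconds.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

from .errors import ParameterError

__all__ = [
    "substream",
    "gen_compound_library",
    "gen_interaction_db",
    "gen_pathway_collection",
    "gen_food_table",
    "simulate_all",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Labeled child stream of one integer seed (stable across generators)."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


# --- compound library -------------------------------------------------------

#: Oxygen substituents used to decorate scaffold slots: hydroxy, methoxy,
#: and O-glycosyl, the decorations polyphenols actually carry.
_O_SUBS = ("O", "OC", "OC9OC(CO)C(O)C(O)C9O")

#: Templates per intended subclass. ``{a}``/``{b}`` slots take O-substituents.
_POLYPHENOL_TEMPLATES: dict[str, tuple[str, ...]] = {
    "flavones": ("O=c1cc(-c2ccc({a})cc2)oc2cc({b})ccc12",),
    "flavonols": ("O=c1c(O)c(-c2ccc({a})cc2)oc2cc({b})ccc12",),
    "flavanones": ("O=C1CC(c2ccc({a})cc2)Oc2cc({b})ccc21",),
    "dihydroflavonols": ("O=C1C(O)C(c2ccc({a})cc2)Oc2cc({b})ccc21",),
    "flavanols": ("OC1Cc2cc({b})ccc2OC1c1ccc({a})cc1",),
    "anthocyanins": ("Oc1cc(O)c2cc({b})c(-c3ccc({a})cc3)[o+]c2c1",),
    "isoflavonoids": ("O=c1c(-c2ccc({a})cc2)coc2cc({b})ccc12",),
    "chalcones": ("O=C(C=Cc1ccc({a})cc1)c1ccc({b})cc1",),
    "dihydrochalcones": ("O=C(CCc1ccc({a})cc1)c1ccc({b})cc1",),
    "hydroxybenzoic acids": ("O=C(O)c1ccc({a})cc1", "O=C(O)c1cccc({a})c1"),
    "hydroxycinnamic acids": ("O=C(O)C=Cc1ccc({a})cc1", "O=C(O)C=Cc1cccc({a})c1"),
    "hydroxyphenylacetic acids": ("O=C(O)Cc1ccc({a})cc1",),
    "hydroxyphenylpropanoic acids": ("O=C(O)CCc1ccc({a})cc1",),
    "hydroxyphenylpentanoic acids": ("O=C(O)CCCCc1ccc({a})cc1",),
    "stilbenes": ("Oc1ccc(C=Cc2cc({a})cc({b})c2)cc1",),
    "lignans": ("OCC(Cc1ccc(O)c({a})c1)C(CO)Cc1ccc(O)c({b})c1",),
    "tyrosols": ("OCCc1ccc({a})cc1",),
    "curcuminoids": ("O=C(C=Cc1ccc(O)c({a})c1)CC(=O)C=Cc1ccc(O)c({b})c1",),
    "hydroxybenzaldehydes": ("O=Cc1ccc({a})cc1",),
    "hydroxycinnamaldehydes": ("O=CC=Cc1ccc({a})cc1",),
    "hydroxybenzoketones": ("CC(=O)c1ccc(O)c({b})c1",),
    "hydroxyphenylpropenes": ("C=CCc1ccc({a})cc1",),
}

#: Subclasses whose cores tolerate no decoration: fixed literal structures.
_POLYPHENOL_LITERALS: dict[str, tuple[str, ...]] = {
    "furanocoumarins": ("O=c1ccc2cc3ccoc3cc2o1",),
    "hydroxycoumarins": ("O=c1ccc2ccc(O)cc2o1", "O=c1ccc2cc(O)c(O)cc2o1", "COc1cc2ccc(=O)oc2cc1O"),
    "alkylphenols": ("CCCCCc1cc(O)cc(O)c1", "CCCCCCCCCCCCCCCc1cc(O)cc(O)c1", "CCc1cc(O)cc(O)c1"),
    "alkylmethoxyphenols": ("Cc1ccc(O)c(OC)c1", "CCc1ccc(O)c(OC)c1", "C=Cc1ccc(O)c(OC)c1"),
    "methoxyphenols": ("COc1ccccc1O",),
    "phenolic terpenes": ("CC(C)c1ccccc1O", "Cc1ccc(C(C)C)cc1O", "CC(C)c1ccc(C)c(O)c1"),
    "naphthoquinones": ("O=C1C=CC(=O)c2cccc(O)c21", "CC1=CC(=O)c2cccc(O)c2C1=O"),
    "anthraquinones": ("Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O", "Oc1ccc2c(c1)C(=O)c1ccccc1C2=O"),
    "other polyphenols": ("Oc1cc(O)cc(O)c1",),
}

_NITROGEN_DECOYS = (
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",          # xanthine alkaloid
    "CN1CCCC1c1cccnc1",                    # pyridine alkaloid
    "c1ccc2[nH]ccc2c1",                    # indole
    "O=C(O)C(N)Cc1ccc(O)cc1",              # aromatic amino acid
    "CCN(CC)C(=O)c1ccccc1",                # benzamide
)
_STEROID_DECOYS = (
    "CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C",   # cholestane 3-ol
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",                  # estrane diol
    "CC12CCC3C(CCC4=CC(=O)CCC43C)C1CCC2O",             # androstene ketone
)
_NEUTRAL_DECOYS = (
    "CCCCCC",                  # alkane
    "CC(=O)OCC",               # ester
    "OC1CCCCC1",               # alicyclic alcohol
    "CC(=C)C1CCC(C)=CC1",      # monoterpene
    "Cc1ccccc1",               # plain arene
    "O=C(O)c1ccccc1",          # benzoic acid, no ring hydroxyl
)

_DECOY_REASONS = ("contains_nitrogen", "steroid", "mass_gt_1200", "none")


def _polyphenol_smiles(subclass: str, rng: np.random.Generator) -> str:
    if subclass in _POLYPHENOL_TEMPLATES:
        template = _POLYPHENOL_TEMPLATES[subclass][rng.integers(len(_POLYPHENOL_TEMPLATES[subclass]))]
        a = _O_SUBS[rng.integers(len(_O_SUBS))]
        b = _O_SUBS[rng.integers(len(_O_SUBS))]
        return template.format(a=a, b=b)
    literals = _POLYPHENOL_LITERALS[subclass]
    return literals[rng.integers(len(literals))]


def _decoy_smiles(reason: str, rng: np.random.Generator) -> str:
    if reason == "contains_nitrogen":
        return _NITROGEN_DECOYS[rng.integers(len(_NITROGEN_DECOYS))]
    if reason == "steroid":
        return _STEROID_DECOYS[rng.integers(len(_STEROID_DECOYS))]
    if reason == "mass_gt_1200":
        return "C" * int(rng.integers(90, 121))
    return _NEUTRAL_DECOYS[rng.integers(len(_NEUTRAL_DECOYS))]


def gen_compound_library(
    n: int = 500,
    polyphenol_fraction: float = 0.7,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Generate a natural-product-style SMILES library with planted truth.

    Returns ``(records, ledger)`` where records are ``(compound_id, smiles)``
    pairs. Polyphenols are scaffold decorations over all 31 subclasses;
    decoys cover nitrogen heterocycles, steroid cores, >1200 Da constructs,
    and unremarkable kept-but-unclassified organics.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not 0.0 <= polyphenol_fraction <= 1.0:
        raise ParameterError(f"polyphenol_fraction must be in [0, 1], got {polyphenol_fraction}")
    rng = substream(seed, "compound_library")
    n_poly = round(n * polyphenol_fraction)
    subclass_names = sorted([*_POLYPHENOL_TEMPLATES, *_POLYPHENOL_LITERALS])
    records: list[tuple[str, str]] = []
    planted: dict[str, str] = {}
    decoys: dict[str, str] = {}
    for i in range(n):
        cid = f"CPD{i:05d}"
        if i < n_poly:
            subclass = subclass_names[int(rng.integers(len(subclass_names)))]
            smiles = _polyphenol_smiles(subclass, rng)
            planted[cid] = subclass
        else:
            reason = _DECOY_REASONS[int(rng.integers(len(_DECOY_REASONS)))]
            smiles = _decoy_smiles(reason, rng)
            decoys[cid] = reason
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - templates are pre-validated
            raise RuntimeError(f"generator emitted unparseable SMILES: {smiles!r}")
        records.append((cid, smiles))
    ledger = {
        "seed": int(seed),
        "n": n,
        "polyphenol_fraction": polyphenol_fraction,
        "planted_polyphenols": planted,
        "decoys": decoys,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "compounds.smi", "w") as fh:
            for cid, smiles in records:
                fh.write(f"{smiles}\t{cid}\n")
        _write_json(ledger, out_dir / "compound_ledger.json")
    return records, ledger


# --- interaction tables -----------------------------------------------------

def gen_interaction_db(
    compounds: Sequence[str],
    n_proteins: int = 2000,
    seed: int = 0,
    score_range: tuple[float, float] = (0.15, 0.999),
    textmining_only_rate: float = 0.1,
    cross_source_overlap: int = 10,
    mean_degree: float = 8.0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], dict]:
    """Generate the three interaction-table dialects plus a ledger.

    Every compound is assigned a source combination (``cross_source_overlap``
    of them occur in all three sources) and each of its edges is emitted in
    each assigned dialect, so the merged network's source-overlap cells
    equal the ledger exactly. One compound is planted as the top-degree hub.
    Returns ``(tables, ledger)`` with tables mapping dialect name to file
    content.
    """
    if not compounds:
        raise ParameterError("compounds must be non-empty")
    if cross_source_overlap > len(compounds):
        raise ParameterError("cross_source_overlap exceeds the compound count")
    if not 0.0 <= textmining_only_rate <= 1.0:
        raise ParameterError(f"textmining_only_rate must be in [0, 1], got {textmining_only_rate}")
    lo, hi = score_range
    if not 0.0 <= lo < hi <= 1.0:
        raise ParameterError(f"score_range must satisfy 0 <= lo < hi <= 1, got {score_range}")
    rng = substream(seed, "interaction_db")
    proteins = [f"G{i:04d}" for i in range(n_proteins)]
    sources = ("stitch_like", "pathway_commons_like", "bindingdb_like")

    order = list(rng.permutation(len(compounds)))
    all_three = [compounds[i] for i in order[:cross_source_overlap]]
    assignment: dict[str, tuple[str, ...]] = {c: sources for c in all_three}
    for i in order[cross_source_overlap:]:
        c = compounds[i]
        n_src = 1 if rng.random() < 0.6 else 2
        picked = rng.choice(len(sources), size=n_src, replace=False)
        assignment[c] = tuple(sources[j] for j in sorted(picked))

    hub = all_three[0] if all_three else compounds[order[0]]
    edges: list[tuple[str, str]] = []
    for c in compounds:
        deg = int(max(50, 5 * mean_degree)) if c == hub else int(rng.poisson(mean_degree)) + 1
        deg = min(deg, n_proteins)
        partners = rng.choice(n_proteins, size=deg, replace=False)
        edges.extend((c, proteins[j]) for j in sorted(partners))

    stitch_rows = ["compound_id\tprotein_id\texperimental\tdatabase\tprediction\ttextmining\tcombined_score"]
    sif_rows: list[str] = []
    bdb_rows = ["compound_id\tprotein_id\taffinity_nM"]
    n_textmining_only = 0
    for c, p in edges:
        srcs = assignment[c]
        if "stitch_like" in srcs:
            raw = {ch: 0 for ch in ("experimental", "database", "prediction", "textmining")}
            if rng.random() < textmining_only_rate:
                raw["textmining"] = int(round(rng.uniform(lo, hi) * 1000))
                combined = raw["textmining"]
                n_textmining_only += 1
            else:
                active = [ch for ch in ("experimental", "database", "prediction") if rng.random() < 0.6]
                if not active:
                    active = ["experimental"]
                if rng.random() < 0.3:
                    active.append("textmining")
                for ch in active:
                    raw[ch] = int(round(rng.uniform(lo, hi) * 1000))
                combined = min(999, int(round(1000 * (1.0 - np.prod([1.0 - raw[ch] / 1000.0 for ch in active])))))
            stitch_rows.append(
                f"{c}\t{p}\t{raw['experimental']}\t{raw['database']}\t{raw['prediction']}\t{raw['textmining']}\t{combined}"
            )
        if "pathway_commons_like" in srcs:
            sif_rows.append(f"{c}\tinteracts-with\t{p}")
        if "bindingdb_like" in srcs:
            bdb_rows.append(f"{c}\t{p}\t{10 ** rng.uniform(0, 4):.1f}")

    combo_counts: dict[str, int] = {}
    for c in compounds:
        key = "+".join(sorted(assignment[c]))
        combo_counts[key] = combo_counts.get(key, 0) + 1
    protein_sources: dict[str, set[str]] = {}
    for c, p in edges:
        protein_sources.setdefault(p, set()).update(assignment[c])
    protein_combos: dict[str, int] = {}
    for srcs in protein_sources.values():
        key = "+".join(sorted(srcs))
        protein_combos[key] = protein_combos.get(key, 0) + 1

    tables = {
        "stitch_like": "\n".join(stitch_rows) + "\n",
        "pathway_commons_like": "\n".join(sif_rows) + ("\n" if sif_rows else ""),
        "bindingdb_like": "\n".join(bdb_rows) + "\n",
    }
    ledger = {
        "seed": int(seed),
        "n_proteins": n_proteins,
        "textmining_only_rate": textmining_only_rate,
        "textmining_only_emitted": n_textmining_only,
        "n_stitch_records": len(stitch_rows) - 1,
        "n_edges_emitted": len(edges),
        "hub_compound": hub,
        "planted_overlaps": {
            "compounds": dict(sorted(combo_counts.items())),
            "proteins": dict(sorted(protein_combos.items())),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "stitch_like.tsv").write_text(tables["stitch_like"])
        (out_dir / "pathway_commons_like.sif").write_text(tables["pathway_commons_like"])
        (out_dir / "bindingdb_like.tsv").write_text(tables["bindingdb_like"])
        _write_json(ledger, out_dir / "interaction_ledger.json")
    return tables, ledger


# --- pathway collection -----------------------------------------------------

_CATEGORY_POOL = (
    ("Metabolism", ("Carbohydrate Metabolism", "Lipid Metabolism")),
    ("Human Diseases", ("Cardiovascular Diseases", "Endocrine and Metabolic Diseases")),
    ("Genetic Information Processing", ("Transcription", "Translation")),
    ("Cellular Processes", ("Cell Growth", "Transport and Catabolism")),
    ("Environmental Information Processing", ("Signal Transduction", "Membrane Transport")),
    ("Organismal Systems", ("Immune System", "Digestive System")),
)


def gen_pathway_collection(
    universe: Sequence[str],
    n_pathways: int = 100,
    size_range: tuple[int, int] = (10, 60),
    n_categories: int = 3,
    planted: Sequence[tuple[str, str, float]] = (),
    query_sets: Mapping[str, Iterable[str]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list, dict]:
    """Generate a KEGG-style pathway collection with optional planted effects.

    ``planted`` holds ``(query_label, pathway_id, odds_ratio)`` triples: that
    pathway's members are sampled with weight ``odds_ratio`` for proteins in
    the labeled query set, so the query is over-represented in it. Category
    and subcategory labels are assigned round-robin from a fixed ontology
    pool (including the cardiovascular and endocrine/metabolic disease
    subcategories needed for the cardiometabolic roll-up).
    """
    from .enrichment import PathwayGeneSet, write_gmt, write_ontology

    if size_range[1] > len(universe):
        raise ParameterError(f"max pathway size {size_range[1]} exceeds universe size {len(universe)}")
    if not 1 <= n_categories <= len(_CATEGORY_POOL):
        raise ParameterError(f"n_categories must be in 1..{len(_CATEGORY_POOL)}")
    ids = [f"PW{i:04d}" for i in range(n_pathways)]
    planted_by_id = {pid: (label, float(odds)) for label, pid, odds in planted}
    unknown = sorted(set(planted_by_id) - set(ids))
    if unknown:
        raise ParameterError(f"planted pathway id(s) not in collection: {', '.join(unknown)}")
    if planted_by_id and query_sets is None:
        raise ParameterError("query_sets required when planting enrichments")
    for label, pid, odds in planted:
        if label not in (query_sets or {}):
            raise ParameterError(f"planted query label {label!r} missing from query_sets")
        if odds < 1:
            raise ParameterError(f"odds_ratio must be >= 1, got {odds}")

    rng = substream(seed, "pathway_collection")
    universe = list(universe)
    gene_sets = []
    for i, pid in enumerate(ids):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if pid in planted_by_id:
            label, odds = planted_by_id[pid]
            query = set(query_sets[label])
            weights = np.array([odds if p in query else 1.0 for p in universe])
            weights /= weights.sum()
            members = rng.choice(len(universe), size=size, replace=False, p=weights)
        else:
            members = rng.choice(len(universe), size=size, replace=False)
        category, subcats = _CATEGORY_POOL[i % n_categories]
        gene_sets.append(PathwayGeneSet(
            pathway_id=pid,
            name=f"synthetic pathway {i}",
            members=frozenset(universe[j] for j in members),
            category=category,
            subcategory=subcats[(i // n_categories) % len(subcats)],
        ))
    ledger = {
        "seed": int(seed),
        "n_pathways": n_pathways,
        "planted_enrichments": [[label, pid, odds] for label, pid, odds in planted],
        "sizes": {gs.pathway_id: len(gs.members) for gs in gene_sets},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gmt(gene_sets, out_dir / "pathways.gmt")
        write_ontology(gene_sets, out_dir / "pathway_ontology.tsv")
        _write_json(ledger, out_dir / "pathway_ledger.json")
    return gene_sets, ledger


# --- food composition -------------------------------------------------------

def gen_food_table(
    foods: Sequence[str],
    compounds: Sequence[str],
    overlap_spec: Mapping[tuple[str, ...], int],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, frozenset[str]], dict]:
    """Generate a food -> compound composition table from a block design.

    ``overlap_spec`` maps a tuple of food names to the number of compounds
    shared by exactly those foods; disjoint blocks make any requested
    overlap structure exactly realizable, and the ledger records the implied
    pairwise Jaccard matrix.
    """
    foods = list(foods)
    total = sum(overlap_spec.values())
    if total > len(compounds):
        raise ParameterError(f"overlap_spec requests {total} compounds, only {len(compounds)} available")
    for block, count in overlap_spec.items():
        if count < 0:
            raise ParameterError("block counts must be non-negative")
        unknown = sorted(set(block) - set(foods))
        if unknown:
            raise ParameterError(f"unknown food(s) in overlap_spec: {', '.join(unknown)}")
    rng = substream(seed, "food_table")
    pool = [compounds[i] for i in rng.permutation(len(compounds))]
    composition: dict[str, set[str]] = {f: set() for f in foods}
    cursor = 0
    for block in sorted(overlap_spec, key=lambda b: tuple(sorted(b))):
        count = overlap_spec[block]
        chunk = pool[cursor:cursor + count]
        cursor += count
        for food in block:
            composition[food].update(chunk)
    jaccard_matrix = {}
    for a in foods:
        row = {}
        for b in foods:
            union = composition[a] | composition[b]
            row[b] = len(composition[a] & composition[b]) / len(union) if union else 1.0
        jaccard_matrix[a] = row
    ledger = {
        "seed": int(seed),
        "blocks": {"+".join(sorted(b)): c for b, c in sorted(overlap_spec.items(), key=lambda kv: tuple(sorted(kv[0])))},
        "food_overlaps": jaccard_matrix,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "food_composition.tsv", "w") as fh:
            fh.write("food\tcompound_id\n")
            for food in sorted(composition):
                for cid in sorted(composition[food]):
                    fh.write(f"{food}\t{cid}\n")
        _write_json(ledger, out_dir / "food_ledger.json")
    return {f: frozenset(c) for f, c in composition.items()}, ledger


# --- end-to-end -------------------------------------------------------------

def simulate_all(
    seed: int,
    out_dir: str | Path,
    n_compounds: int = 500,
    polyphenol_fraction: float = 0.7,
    n_proteins: int = 2000,
    n_pathways: int = 100,
) -> dict:
    """Emit every input dialect the pipeline consumes, plus ``ledger.json``.

    Plants one enriched pathway for the flavonoid class (odds ratio 5) and a
    six-food composition table with one near-universal food pair.
    """
    from .interactome import filter_interactions, merge, parse_bindingdb_like, parse_sif_like, parse_stitch_like
    from .standardize import standardize_many
    from .taxonomy import classify_batch, load_pattern_library

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, compound_ledger = gen_compound_library(
        n=n_compounds, polyphenol_fraction=polyphenol_fraction, seed=seed, out_dir=out_dir)
    compound_ids = [cid for cid, _ in records]
    tables, interaction_ledger = gen_interaction_db(
        compound_ids, n_proteins=n_proteins, seed=seed, out_dir=out_dir)

    # classify to obtain the flavonoid query set for the planted enrichment
    structures = standardize_many(records)
    classifications = classify_batch(structures, load_pattern_library())
    flavonoid_ids = {c.compound_id for c in classifications if "flavonoids" in c.classes}
    stitch = filter_interactions(parse_stitch_like(out_dir / "stitch_like.tsv"))
    net = merge(stitch, parse_sif_like(out_dir / "pathway_commons_like.sif"),
                parse_bindingdb_like(out_dir / "bindingdb_like.tsv"))
    flavonoid_query = set()
    for cid in flavonoid_ids:
        flavonoid_query |= net.neighbors(cid)

    planted = [("flavonoids", "PW0000", 5.0)] if flavonoid_query else []
    _, pathway_ledger = gen_pathway_collection(
        universe=sorted(net.proteins) or [f"G{i:04d}" for i in range(n_proteins)],
        n_pathways=n_pathways, planted=planted,
        query_sets={"flavonoids": flavonoid_query}, seed=seed, out_dir=out_dir)

    foods = ["grapefruit", "lemon", "lime", "orange", "tangerine", "pomelo"]
    poly_ids = sorted(compound_ledger["planted_polyphenols"])
    spec = {
        ("lemon", "lime"): min(40, len(poly_ids) // 4),
        ("grapefruit",): min(10, len(poly_ids) // 8),
        ("lemon", "lime", "orange", "tangerine", "pomelo"): min(20, len(poly_ids) // 8),
        ("grapefruit", "pomelo"): min(5, len(poly_ids) // 10),
        ("orange", "tangerine"): min(8, len(poly_ids) // 10),
    }
    _, food_ledger = gen_food_table(foods, poly_ids, spec, seed=seed, out_dir=out_dir)

    ledger = {
        "seed": int(seed),
        "compound_library": compound_ledger,
        "interactions": interaction_ledger,
        "pathways": pathway_ledger,
        "foods": food_ledger,
    }
    _write_json(ledger, out_dir / "ledger.json")
    return ledger


def _write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
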