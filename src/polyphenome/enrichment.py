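"""Hypergeometric over-representation analysis with BH adjustment and coverage.

For a query set of n proteins drawn from a universe of N, a pathway with K
members, and k hits (query proteins that are pathway members), the raw
p-value is the exact upper tail P[X >= k] of Hypergeometric(N, K, n).
P-values are Benjamini-Hochberg adjusted within the family of pathways
tested for one query; a pathway is called significant when the adjusted
p-value is strictly below alpha (default 0.1) AND coverage k/K is strictly
above the minimum (default 10%; the per-compound food analysis uses 20%).

The universe defaults to the union of all gene-set members; query proteins
outside the universe are dropped (with a logged count) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGeneSet",
    "EnrichmentResult",
    "hypergeometric_p",
    "bh_adjust",
    "enrich",
    "enrich_by_class",
    "category_summary",
    "read_gmt",
    "read_ontology",
    "write_gmt",
    "write_ontology",
    "results_table",
    "CMD_SUBCATEGORIES",
]

#: Cardiometabolic diseases: the union of these two subcategories.
CMD_SUBCATEGORIES = ("Cardiovascular Diseases", "Endocrine and Metabolic Diseases")


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str
    name: str
    members: frozenset[str]
    category: str = ""
    subcategory: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    query_label: str
    pathway_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_bh: float
    coverage: float
    significant: bool
    hits: frozenset[str]


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P[X >= k], X ~ Hypergeometric(N, K, n)."""
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ParameterError(f"infeasible universe: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ParameterError(f"infeasible hit count k={k} for K={K}, n={n}, N={N}")
    if k <= 0:
        return 1.0
    # sf(k-1) = P[X >= k]; exact evaluation, no normal approximation
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_proteins: Iterable[str],
    gene_sets: Sequence[PathwayGeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.1,
    min_coverage: float = 0.1,
    query_label: str = "query",
    raw_p: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of a query protein set against every gene set.

    ``raw_p`` switches the significance call to the unadjusted p-value
    (looser reading used for some figure captions); the default applies the
    BH-adjusted criterion together with the coverage criterion.
    """
    if universe is None:
        universe = set().union(*(gs.members for gs in gene_sets)) if gene_sets else set()
    universe = set(universe)
    if not universe:
        raise ParameterError("universe is empty")
    query = set(query_proteins)
    dropped = query - universe
    if dropped:
        logger.info("%s: %d query protein(s) outside the universe dropped", query_label, len(dropped))
    query &= universe
    n, N = len(query), len(universe)
    ordered = sorted(gene_sets, key=lambda gs: gs.pathway_id)
    stats_rows = []
    for gs in ordered:
        members = gs.members & universe
        hits = query & members
        k, K = len(hits), len(members)
        p = hypergeometric_p(k, K, n, N) if K > 0 else 1.0
        stats_rows.append((gs, k, K, hits, p))
    adjusted = bh_adjust([row[4] for row in stats_rows])
    results = []
    for (gs, k, K, hits, p), p_bh in zip(stats_rows, adjusted):
        coverage = k / K if K else 0.0
        p_for_call = p if raw_p else float(p_bh)
        results.append(EnrichmentResult(
            query_label=query_label,
            pathway_id=gs.pathway_id,
            k=k, K=K, n=n, N=N,
            p_raw=p,
            p_bh=float(p_bh),
            coverage=coverage,
            significant=(p_for_call < alpha) and (coverage > min_coverage),
            hits=frozenset(hits),
        ))
    return results


def enrich_by_class(
    interactome,
    classifications,
    gene_sets: Sequence[PathwayGeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.1,
    min_coverage: float = 0.1,
    classes: Sequence[str] | None = None,
    raw_p: bool = False,
) -> dict[str, list[EnrichmentResult]]:
    """Run one enrichment family per polyphenol class.

    A class's query set is the union of proteins interacting with any
    compound carrying that class label. BH adjustment is applied within each
    class's family, not pooled across classes. Classes with no interacting
    proteins yield an empty result list (logged).
    """
    class_members: dict[str, set[str]] = {}
    for c in classifications:
        for cls in c.classes:
            class_members.setdefault(cls, set()).add(c.compound_id)
    if classes is not None:
        unknown = [cls for cls in classes if cls not in class_members]
        if unknown:
            raise ValidationError(f"class(es) absent from classifications: {', '.join(sorted(unknown))}")
    else:
        classes = sorted(class_members)
    out: dict[str, list[EnrichmentResult]] = {}
    for cls in classes:
        query = set()
        for compound in class_members[cls]:
            query |= interactome.neighbors(compound)
        if not query:
            logger.info("class %r has no interacting proteins; skipping enrichment", cls)
            out[cls] = []
            continue
        out[cls] = enrich(query, gene_sets, universe=universe, alpha=alpha,
                          min_coverage=min_coverage, query_label=cls, raw_p=raw_p)
    return out


def category_summary(
    results: Sequence[EnrichmentResult],
    gene_sets: Sequence[PathwayGeneSet],
    include_cmd: bool = True,
) -> dict[str, dict[str, float]]:
    """Roll significant pathways up to their categories.

    Returns, per category, the percentage of that category's pathways called
    significant, plus the 'CMD' super-category covering the cardiovascular
    and endocrine/metabolic disease subcategories.
    """
    by_id = {gs.pathway_id: gs for gs in gene_sets}
    missing = sorted({r.pathway_id for r in results if r.pathway_id not in by_id})
    if missing:
        raise ValidationError(f"pathway id(s) without category mapping: {', '.join(missing)}")
    categories = sorted({gs.category for gs in gene_sets})
    out: dict[str, dict[str, float]] = {}
    tested = {r.pathway_id for r in results}
    significant = {r.pathway_id for r in results if r.significant}
    for cat in categories:
        ids = {gs.pathway_id for gs in gene_sets if gs.category == cat} & tested
        n_sig = len(ids & significant)
        out[cat] = {
            "n_pathways": len(ids),
            "n_significant": n_sig,
            "percent_enriched": 100.0 * n_sig / len(ids) if ids else 0.0,
        }
    if include_cmd:
        ids = {gs.pathway_id for gs in gene_sets if gs.subcategory in CMD_SUBCATEGORIES} & tested
        n_sig = len(ids & significant)
        out["CMD"] = {
            "n_pathways": len(ids),
            "n_significant": n_sig,
            "percent_enriched": 100.0 * n_sig / len(ids) if ids else 0.0,
        }
    return out


def coverage_matrix(
    results_by_query: Mapping[str, Sequence[EnrichmentResult]],
    gene_sets: Sequence[PathwayGeneSet],
    subcategory: str | None = None,
) -> pd.DataFrame:
    """Pathway x query coverage values for significant calls (0 elsewhere)."""
    by_id = {gs.pathway_id: gs for gs in gene_sets}
    ids = sorted(
        pid for pid in by_id
        if subcategory is None or by_id[pid].subcategory == subcategory
    )
    data = {}
    for label, results in sorted(results_by_query.items()):
        col = {r.pathway_id: (r.coverage if r.significant else 0.0) for r in results}
        data[label] = [col.get(pid, 0.0) for pid in ids]
    return pd.DataFrame(data, index=ids)


def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read gene sets from GMT: pathway_id, description, members...."""
    gene_sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT lines need id, description, and >=1 member")
        gene_sets.append(PathwayGeneSet(
            pathway_id=fields[0], name=fields[1],
            members=frozenset(f.strip().upper() for f in fields[2:] if f.strip()),
        ))
    return gene_sets


def read_ontology(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read pathway_id -> (category, subcategory) from a 3-column TSV."""
    mapping = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty ontology file")
    start = 1 if lines[0].startswith("pathway_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        mapping[fields[0]] = (fields[1], fields[2])
    return mapping


def apply_ontology(gene_sets: Sequence[PathwayGeneSet], ontology: Mapping[str, tuple[str, str]]) -> list[PathwayGeneSet]:
    """Attach category/subcategory labels; unmapped pathways raise."""
    missing = sorted(gs.pathway_id for gs in gene_sets if gs.pathway_id not in ontology)
    if missing:
        raise ValidationError(f"pathway id(s) missing from ontology: {', '.join(missing)}")
    return [
        PathwayGeneSet(gs.pathway_id, gs.name, gs.members, *ontology[gs.pathway_id])
        for gs in gene_sets
    ]


def write_gmt(gene_sets: Sequence[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.pathway_id, gs.name, *sorted(gs.members)]) + "\n")


def write_ontology(gene_sets: Sequence[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tcategory\tsubcategory\n")
        for gs in gene_sets:
            fh.write(f"{gs.pathway_id}\t{gs.category}\t{gs.subcategory}\n")


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "query_label": r.query_label, "pathway_id": r.pathway_id,
            "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p_raw": r.p_raw, "p_bh": r.p_bh, "coverage": r.coverage,
            "significant": r.significant, "hits": ";".join(sorted(r.hits)),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "query_label", "pathway_id", "k", "K", "n", "N",
        "p_raw", "p_bh", "coverage", "significant", "hits",
    ])
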