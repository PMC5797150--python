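"""Food-level analysis: composition sets, sub-interactomes, and per-compound
enrichment networks (the citrus / grapefruit style case study).

A food is a binary set of compounds (presence irrespective of
concentration). Its interactome is the sub-network induced by those
compounds; its enrichment network connects each compound to the pathways
significantly enriched among that compound's own interacting proteins,
under the stricter food-level coverage threshold (>0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentResult, PathwayGeneSet, enrich
from .errors import FormatError, ValidationError
from .interactome import Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "FoodComposition",
    "FoodNetwork",
    "read_composition",
    "food_interactome",
    "food_enrichment_network",
    "compare_foods",
    "jaccard",
]


@dataclass(frozen=True)
class FoodComposition:
    food_name: str
    compounds: frozenset[str]


@dataclass(frozen=True)
class FoodNetwork:
    """Tripartite compound / pathway / protein view of one food's enrichment."""

    food_name: str
    #: (compound_id, pathway_id) edges, each backed by a significant result.
    edges: tuple[tuple[str, str], ...]
    results: Mapping[str, tuple[EnrichmentResult, ...]]
    pathway_categories: Mapping[str, str]
    #: proteins attached per pathway category (hit proteins of significant pathways)
    proteins_by_category: Mapping[str, frozenset[str]]
    compounds: frozenset[str]

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for c in sorted(self.compounds):
            g.add_node(c, kind="compound")
        for _, pid in self.edges:
            g.add_node(pid, kind="pathway", category=self.pathway_categories.get(pid, ""))
        for c, pid in sorted(self.edges):
            g.add_edge(c, pid)
        nx.write_graphml(g, str(path))


def read_composition(path: str | Path) -> list[FoodComposition]:
    """Read a food composition TSV with columns food, compound_id."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty composition file")
    start = 1 if lines[0].startswith("food") else 0
    table: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        table.setdefault(fields[0], set()).add(fields[1])
    return [FoodComposition(name, frozenset(cpds)) for name, cpds in sorted(table.items())]


def food_interactome(food: FoodComposition, interactome: Interactome) -> tuple[frozenset[str], Interactome]:
    """Proteins reached by the food's compounds, plus the induced sub-network."""
    sub = interactome.subnetwork(food.compounds)
    if not sub.edges:
        logger.info("food %r: none of its %d compound(s) occur in the interactome",
                    food.food_name, len(food.compounds))
    return sub.proteins, sub


def food_enrichment_network(
    food: FoodComposition,
    interactome: Interactome,
    gene_sets: Sequence[PathwayGeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.1,
    min_coverage: float = 0.2,
) -> FoodNetwork:
    """Per-compound enrichment (not pooled) against a shared universe.

    Edges connect a compound to each pathway significant for that compound's
    own interacting proteins under BH < alpha and coverage > min_coverage.
    """
    if universe is None:
        universe = set().union(*(gs.members for gs in gene_sets)) if gene_sets else set()
    pathway_categories = {gs.pathway_id: gs.category for gs in gene_sets}
    edges: list[tuple[str, str]] = []
    results: dict[str, tuple[EnrichmentResult, ...]] = {}
    proteins_by_category: dict[str, set[str]] = {}
    for compound in sorted(food.compounds):
        partners = interactome.neighbors(compound)
        if not partners:
            results[compound] = ()
            continue
        res = enrich(partners, gene_sets, universe=universe, alpha=alpha,
                     min_coverage=min_coverage, query_label=compound)
        results[compound] = tuple(res)
        for r in res:
            if r.significant:
                edges.append((compound, r.pathway_id))
                cat = pathway_categories.get(r.pathway_id, "")
                proteins_by_category.setdefault(cat, set()).update(r.hits)
    return FoodNetwork(
        food_name=food.food_name,
        edges=tuple(sorted(edges)),
        results=results,
        pathway_categories=pathway_categories,
        proteins_by_category={c: frozenset(p) for c, p in sorted(proteins_by_category.items())},
        compounds=food.compounds,
    )


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_foods(
    foods: Sequence[FoodComposition],
    networks: Mapping[str, FoodNetwork] | None = None,
) -> dict:
    """Pairwise Jaccard overlap of compound sets, plus per-food significant pathways."""
    if len(foods) < 2:
        raise ValidationError("compare_foods needs at least two foods")
    names = [f.food_name for f in foods]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate food names")
    by_name = {f.food_name: f.compounds for f in foods}
    overlap = {
        a: {b: jaccard(by_name[a], by_name[b]) for b in sorted(by_name)}
        for a in sorted(by_name)
    }
    pathways = {}
    if networks is not None:
        unknown = sorted(set(networks) - set(by_name))
        if unknown:
            raise ValidationError(f"unknown food name(s): {', '.join(unknown)}")
        pathways = {
            name: sorted({pid for _, pid in net.edges})
            for name, net in sorted(networks.items())
        }
    return {"jaccard": overlap, "significant_pathways": pathways}
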