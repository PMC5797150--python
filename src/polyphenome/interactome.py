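"""Compound-protein interaction parsing, evidence filtering, and network assembly.

Three table dialects are supported:

* ``stitch_like`` - TSV with per-channel evidence scores (experimental,
  database, prediction, textmining) and a combined confidence score, all as
  raw integers 0-999 that are normalized to [0, 1];
* ``pathway_commons_like`` - SIF triples ``compound  relation  protein``;
* ``bindingdb_like`` - TSV with an affinity column (records are kept
  regardless of affinity; only the stitch-like dialect carries confidence).

Filtering removes stitch-like records supported solely by text mining and
records whose combined confidence falls below a threshold (0.9 by default;
0.7 is the relaxed setting used for micronutrient-style queries). Merging
deduplicates (compound, protein) pairs across dialects into a bipartite
network that remembers which sources support each edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import FormatError, ParameterError

__all__ = [
    "CHANNELS",
    "SOURCE_DBS",
    "COMPOUND_DEGREE_BINS",
    "PROTEIN_DEGREE_BINS",
    "InteractionRecord",
    "Interactome",
    "parse_stitch_like",
    "parse_sif_like",
    "parse_bindingdb_like",
    "filter_interactions",
    "merge",
    "source_overlap",
    "degree_histogram",
    "to_graphml",
    "write_edge_list",
    "summary",
]

CHANNELS = ("experimental", "database", "prediction", "textmining")
SOURCE_DBS = ("stitch_like", "pathway_commons_like", "bindingdb_like")

#: Fig.-style degree bins, as (label, lower bound) with half-open
#: [lo, hi) intervals: a boundary degree falls in the higher bin.
COMPOUND_DEGREE_BINS = (
    ("<=10", 1), ("10-20", 10), ("20-50", 20), ("50-100", 50),
    ("100-500", 100), ("500-1000", 500), ("1000-2000", 1000), (">2000", 2000),
)
PROTEIN_DEGREE_BINS = (
    ("1", 1), ("2-5", 2), ("5-10", 5), ("10-25", 10),
    ("25-50", 25), ("50-70", 50), (">70", 70),
)


@dataclass(frozen=True)
class InteractionRecord:
    """One compound-protein edge as read from a source table."""

    compound_id: str
    protein_id: str
    source_db: str
    channels: Mapping[str, float] = field(default_factory=dict)
    combined_score: float | None = None

    def textmining_only(self) -> bool:
        """True for stitch-like records whose only evidence channel is text mining."""
        if self.source_db != "stitch_like":
            return False
        tm = self.channels.get("textmining", 0.0)
        others = [self.channels.get(c, 0.0) for c in CHANNELS if c != "textmining"]
        return tm > 0.0 and all(v == 0.0 for v in others)


@dataclass(frozen=True)
class Interactome:
    """Bipartite compound-protein network with per-edge source provenance."""

    edges: Mapping[tuple[str, str], frozenset[str]]
    n_input_records: int
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.edges)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for _, p in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, compound_id: str) -> frozenset[str]:
        return frozenset(p for c, p in self.edges if c == compound_id)

    def subnetwork(self, compound_ids: Iterable[str]) -> "Interactome":
        keep = set(compound_ids)
        sub = {e: s for e, s in self.edges.items() if e[0] in keep}
        return Interactome(edges=sub, n_input_records=len(sub), provenance=dict(self.provenance))


def _norm_protein(protein_id: str, id_map: Mapping[str, str] | None) -> str:
    pid = protein_id.strip()
    if id_map is not None and pid in id_map:
        pid = id_map[pid]
    return pid.upper()


def parse_stitch_like(path: str | Path, id_map: Mapping[str, str] | None = None) -> list[InteractionRecord]:
    """Parse a STITCH-style TSV with raw channel scores as integers 0-999."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header line")
    header = lines[0].rstrip("\n").split("\t")
    required = ["compound_id", "protein_id", *CHANNELS, "combined_score"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in required}
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}")
        try:
            raw = {c: int(fields[idx[c]]) for c in (*CHANNELS, "combined_score")}
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer score ({exc})") from None
        for name, value in raw.items():
            if not 0 <= value <= 999:
                raise FormatError(f"{path}:{lineno}: {name} score {value} outside 0-999")
        records.append(InteractionRecord(
            compound_id=fields[idx["compound_id"]].strip(),
            protein_id=_norm_protein(fields[idx["protein_id"]], id_map),
            source_db="stitch_like",
            channels={c: raw[c] / 1000.0 for c in CHANNELS},
            combined_score=raw["combined_score"] / 1000.0,
        ))
    return records


def parse_sif_like(path: str | Path, id_map: Mapping[str, str] | None = None) -> list[InteractionRecord]:
    """Parse Pathway-Commons-style SIF triples: compound, relation, protein."""
    path = Path(path)
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 whitespace-separated fields, found {len(parts)}")
        compound, _relation, protein = parts
        records.append(InteractionRecord(
            compound_id=compound,
            protein_id=_norm_protein(protein, id_map),
            source_db="pathway_commons_like",
        ))
    return records


def parse_bindingdb_like(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
    max_affinity_nm: float | None = None,
) -> list[InteractionRecord]:
    """Parse a BindingDB-style TSV (compound_id, protein_id, affinity_nM).

    All records are kept regardless of affinity (direct-binding evidence is
    not confidence-scored); ``max_affinity_nm`` optionally applies a ceiling.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header line")
    header = lines[0].split("\t")
    required = ["compound_id", "protein_id", "affinity_nM"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in required}
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}")
        try:
            affinity = float(fields[idx["affinity_nM"]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric affinity_nM") from None
        if max_affinity_nm is not None and affinity > max_affinity_nm:
            continue
        records.append(InteractionRecord(
            compound_id=fields[idx["compound_id"]].strip(),
            protein_id=_norm_protein(fields[idx["protein_id"]], id_map),
            source_db="bindingdb_like",
        ))
    return records


def filter_interactions(
    records: Sequence[InteractionRecord],
    min_score: float = 0.9,
    exclude_textmining_only: bool = True,
) -> list[InteractionRecord]:
    """Apply the evidence filters, preserving record order.

    A stitch-like record is removed if its only evidence channel is text
    mining, or (independently) if its combined confidence is strictly below
    ``min_score``. Non-scored dialects pass the score test vacuously.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ParameterError(f"min_score must be in [0, 1], got {min_score}")
    kept = []
    for rec in records:
        if exclude_textmining_only and rec.textmining_only():
            continue
        if rec.combined_score is not None and rec.combined_score < min_score:
            continue
        kept.append(rec)
    return kept


def merge(*record_lists: Sequence[InteractionRecord], provenance: Mapping[str, object] | None = None) -> Interactome:
    """Merge filtered record lists into a deduplicated bipartite network."""
    edges: dict[tuple[str, str], set[str]] = {}
    n_input = 0
    for records in record_lists:
        for rec in records:
            n_input += 1
            edges.setdefault((rec.compound_id, rec.protein_id), set()).add(rec.source_db)
    return Interactome(
        edges={e: frozenset(s) for e, s in sorted(edges.items())},
        n_input_records=n_input,
        provenance=dict(provenance or {}),
    )


def source_overlap(interactome: Interactome) -> dict[str, dict[str, int]]:
    """Partition compounds and proteins by the combination of sources they occur in.

    Cell keys are '+'-joined sorted source names; cells partition each node
    set, so cell totals sum to the node counts.
    """
    def cells(side: int) -> dict[str, int]:
        node_sources: dict[str, set[str]] = {}
        for edge, sources in interactome.edges.items():
            node_sources.setdefault(edge[side], set()).update(sources)
        out: dict[str, int] = {}
        for srcs in node_sources.values():
            key = "+".join(sorted(srcs))
            out[key] = out.get(key, 0) + 1
        return dict(sorted(out.items()))

    return {"compounds": cells(0), "proteins": cells(1)}


def degree_histogram(
    interactome: Interactome,
    side: str,
    bins: Sequence[tuple[str, int]] | None = None,
) -> dict[str, int]:
    """Bin node degrees using the per-side default bin schemes.

    Bins are half-open ``[lo, hi)`` intervals defined by their lower bounds,
    so a boundary degree (e.g. a protein with exactly 50 partners) falls in
    the higher bin ("50-70").
    """
    if side not in ("compound", "protein"):
        raise ParameterError(f"side must be 'compound' or 'protein', got {side!r}")
    if bins is None:
        bins = COMPOUND_DEGREE_BINS if side == "compound" else PROTEIN_DEGREE_BINS
    lows = [lo for _, lo in bins]
    if any(b <= a for a, b in zip(lows, lows[1:])):
        raise ParameterError("bin lower bounds must be strictly increasing")
    pos = 0 if side == "compound" else 1
    degrees: dict[str, int] = {}
    for edge in interactome.edges:
        degrees[edge[pos]] = degrees.get(edge[pos], 0) + 1
    hist = {label: 0 for label, _ in bins}
    for d in degrees.values():
        chosen = bins[0][0]
        for label, lo in bins:
            if d >= lo:
                chosen = label
        hist[chosen] += 1
    return hist


def to_graphml(interactome: Interactome, path: str | Path) -> None:
    """Write the bipartite network as GraphML (node attribute ``kind``)."""
    g = nx.Graph()
    for c in sorted(interactome.compounds):
        g.add_node(c, kind="compound")
    for p in sorted(interactome.proteins):
        g.add_node(p, kind="protein")
    for (c, p), sources in sorted(interactome.edges.items()):
        g.add_edge(c, p, sources="+".join(sorted(sources)))
    nx.write_graphml(g, str(path))


def write_edge_list(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tprotein_id\tsources\n")
        for (c, p), sources in sorted(interactome.edges.items()):
            fh.write(f"{c}\t{p}\t{'+'.join(sorted(sources))}\n")


def summary(interactome: Interactome) -> dict:
    """JSON-serializable summary: counts, source overlap, degree histograms."""
    return {
        "n_compounds": len(interactome.compounds),
        "n_proteins": len(interactome.proteins),
        "n_edges": interactome.n_edges,
        "n_input_records": interactome.n_input_records,
        "source_overlap": source_overlap(interactome),
        "degree_histogram": {
            "compound": degree_histogram(interactome, "compound"),
            "protein": degree_histogram(interactome, "protein"),
        },
        "provenance": dict(interactome.provenance),
    }
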