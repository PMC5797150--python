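"""End-to-end orchestration: standardize -> classify -> interactome ->
enrichment -> food, driven by one configuration and emitting a run manifest.

Every stage writes its outputs under a stage-named subdirectory; the
manifest echoes the fully resolved configuration (the thresholds default to
the published operating point: confidence >= 0.9, BH alpha 0.1, class-level
coverage > 0.1, food-level coverage > 0.2, strict stereochemistry). Runs
are deterministic: re-running with identical config and inputs reproduces
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import enrichment as enr
from . import food as food_mod
from . import interactome as inter
from .errors import ConfigError, PolyphenomeError
from .standardize import read_sdf, read_smiles_file, standardize_many
from .taxonomy import classification_table, classify_batch, load_pattern_library, summary_counts

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved inputs and thresholds for one pipeline run."""

    compounds: str
    stitch: str | None = None
    sif: str | None = None
    bindingdb: str | None = None
    gmt: str | None = None
    ontology: str | None = None
    composition: str | None = None
    patterns: str | None = None
    id_map: str | None = None
    min_score: float = 0.9
    alpha: float = 0.1
    min_coverage_class: float = 0.1
    min_coverage_food: float = 0.2
    strict_stereo: bool = True
    raw_p: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        if "compounds" not in doc:
            raise ConfigError("config must set 'compounds'")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name in ("min_score", "alpha", "min_coverage_class", "min_coverage_food"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        required = [("compounds", self.compounds)]
        optional = [("stitch", self.stitch), ("sif", self.sif), ("bindingdb", self.bindingdb),
                    ("gmt", self.gmt), ("ontology", self.ontology),
                    ("composition", self.composition), ("patterns", self.patterns),
                    ("id_map", self.id_map)]
        for name, path in required + [(n, p) for n, p in optional if p is not None]:
            if path is None or not Path(path).exists():
                raise ConfigError(f"input '{name}' missing or not found: {path}")
        if not any(p is not None for p in (self.stitch, self.sif, self.bindingdb)):
            raise ConfigError("at least one interaction table (stitch/sif/bindingdb) is required")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PolyphenomeError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise PolyphenomeError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _slug(label: str) -> str:
    return label.replace(" ", "_").replace("/", "_")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every configured stage; returns the output directory."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []

    # --- standardize
    stage_dir = out_dir / "standardize"
    stage_dir.mkdir(exist_ok=True)
    reader = read_sdf if str(config.compounds).endswith(".sdf") else read_smiles_file
    structures = _stage("standardize")(standardize_many)(reader(config.compounds))
    with open(stage_dir / "standardized.tsv", "w") as fh:
        fh.write("compound_id\tcanonical_smiles\tformula\tavg_mass\thas_stereo\n")
        for s in structures:
            fh.write(f"{s.compound_id}\t{s.canonical_smiles}\t{s.formula}\t{s.avg_mass:.3f}\t{s.has_stereo}\n")
    stages_run.append("standardize")

    # --- classify
    stage_dir = out_dir / "classify"
    stage_dir.mkdir(exist_ok=True)
    library = load_pattern_library(config.patterns)
    classifications = _stage("classify")(classify_batch)(structures, library)
    classification_table(classifications).to_csv(stage_dir / "classification.tsv", sep="\t", index=False)
    _write_json(summary_counts(classifications), stage_dir / "summary.json")
    stages_run.append("classify")

    # --- interactome
    id_map = None
    if config.id_map:
        id_map = dict(
            line.split("\t")[:2]
            for line in Path(config.id_map).read_text().splitlines()[1:] if line.strip()
        )
    record_lists = []
    if config.stitch:
        records = inter.parse_stitch_like(config.stitch, id_map=id_map)
        record_lists.append(inter.filter_interactions(records, min_score=config.min_score))
    if config.sif:
        record_lists.append(inter.parse_sif_like(config.sif, id_map=id_map))
    if config.bindingdb:
        record_lists.append(inter.parse_bindingdb_like(config.bindingdb, id_map=id_map))
    network = _stage("interactome")(inter.merge)(
        *record_lists,
        provenance={"min_score": config.min_score, "exclude_textmining_only": True},
    )
    stage_dir = out_dir / "interactome"
    stage_dir.mkdir(exist_ok=True)
    inter.write_edge_list(network, stage_dir / "edges.tsv")
    inter.to_graphml(network, stage_dir / "network.graphml")
    _write_json(inter.summary(network), stage_dir / "summary.json")
    stages_run.append("interactome")

    # --- enrichment (per polyphenol class)
    gene_sets = None
    if config.gmt:
        gene_sets = enr.read_gmt(config.gmt)
        if config.ontology:
            gene_sets = enr.apply_ontology(gene_sets, enr.read_ontology(config.ontology))
        results = _stage("enrich")(enr.enrich_by_class)(
            network, classifications, gene_sets,
            alpha=config.alpha, min_coverage=config.min_coverage_class, raw_p=config.raw_p)
        stage_dir = out_dir / "enrich"
        stage_dir.mkdir(exist_ok=True)
        summaries = {}
        for cls, res in sorted(results.items()):
            enr.results_table(res).to_csv(stage_dir / f"{_slug(cls)}.tsv", sep="\t", index=False)
            if res:
                summaries[cls] = enr.category_summary(res, gene_sets)
        _write_json(summaries, stage_dir / "category_summary.json")
        stages_run.append("enrich")

    # --- food case study
    if config.composition and gene_sets is not None:
        foods = food_mod.read_composition(config.composition)
        stage_dir = out_dir / "food"
        stage_dir.mkdir(exist_ok=True)
        networks = {}
        for food in foods:
            fnet = _stage("food")(food_mod.food_enrichment_network)(
                food, network, gene_sets,
                alpha=config.alpha, min_coverage=config.min_coverage_food)
            networks[food.food_name] = fnet
            with open(stage_dir / f"{_slug(food.food_name)}_edges.tsv", "w") as fh:
                fh.write("compound_id\tpathway_id\tcategory\n")
                for c, pid in fnet.edges:
                    fh.write(f"{c}\t{pid}\t{fnet.pathway_categories.get(pid, '')}\n")
            fnet.to_graphml(stage_dir / f"{_slug(food.food_name)}.graphml")
        if len(foods) >= 2:
            _write_json(food_mod.compare_foods(foods, networks), stage_dir / "comparison.json")
        stages_run.append("food")

    manifest = {"config": config.to_dict(), "stages": stages_run}
    _write_json(manifest, out_dir / "manifest.json")
    return out_dir
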