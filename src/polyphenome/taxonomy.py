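"""The polyphenol chemical taxonomy and substructure classifier.

The shipped library encodes 43 substructure cores as SMARTS, mapped to 31
subclasses organized in 5 queryable classes (flavonoids, lignans, phenolic
acids, stilbenes, other polyphenols). A sixth declared class, non-phenolic
metabolites, has no fixed structural feature and is therefore not queryable.

Before matching, exclusion filters remove molecules that the taxonomy is not
meant to cover: average molecular mass above 1200 Da, any nitrogen atom
(alkaloids and peptides), and steroids (gonane tetracycle). Filters are
checked in that fixed order; the first hit wins, and excluded compounds
never carry class labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem

from .errors import ValidationError
from .standardize import StandardStructure

__all__ = [
    "QUERYABLE_CLASSES",
    "DECLARED_CLASSES",
    "EXPECTED_PATTERN_COUNT",
    "EXPECTED_SUBCLASS_COUNT",
    "ExclusionReason",
    "SubstructurePattern",
    "Classification",
    "load_pattern_library",
    "apply_exclusion_filters",
    "classify",
    "classify_batch",
    "classification_table",
    "summary_counts",
]

QUERYABLE_CLASSES: tuple[str, ...] = (
    "flavonoids",
    "lignans",
    "other polyphenols",
    "phenolic acids",
    "stilbenes",
)
#: The declared taxonomy: the 5 queryable classes plus non-phenolic
#: metabolites, which have no fixed structural feature to query.
DECLARED_CLASSES: tuple[str, ...] = QUERYABLE_CLASSES + ("non-phenolic metabolites",)

EXPECTED_PATTERN_COUNT = 43
EXPECTED_SUBCLASS_COUNT = 31

#: Gonane (cyclopenta[a]phenanthrene) tetracycle with any bond orders, so
#: both saturated (cholestane) and aromatized-A-ring (estrane) steroids match.
STEROID_SMARTS = (
    "[#6]1~[#6]~[#6]~[#6]2~[#6](~[#6]1)~[#6]~[#6]~[#6]1~[#6]2~[#6]~[#6]~"
    "[#6]2~[#6]~[#6]~[#6]~[#6]12"
)
_STEROID_QUERY = Chem.MolFromSmarts(STEROID_SMARTS)

MASS_LIMIT = 1200.0


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    MASS = "mass_gt_1200"
    NITROGEN = "contains_nitrogen"
    STEROID = "steroid"


@dataclass(frozen=True)
class SubstructurePattern:
    """One substructure core: a SMARTS expression mapped to subclass(es) and a class."""

    pattern_id: str
    expression: str
    subclasses: tuple[str, ...]
    class_name: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.expression)
        if q is None:
            raise ValidationError(f"pattern {self.pattern_id!r}: unparseable SMARTS {self.expression!r}")
        return q


@dataclass(frozen=True)
class Classification:
    """Multi-label classification of one standardized compound."""

    compound_id: str
    matched_pattern_ids: frozenset[str]
    subclasses: frozenset[str]
    classes: frozenset[str]
    excluded: bool
    exclusion_reason: ExclusionReason


def load_reference_panel() -> pd.DataFrame:
    """The curated classification panel shipped with the package.

    Named compounds (true polyphenols across all 31 subclasses plus decoys)
    with hand-curated expected subclass/class labels and exclusion calls.
    """
    raw = resources.files("polyphenome.data").joinpath("reference_panel.tsv").read_text()
    lines = [l for l in raw.splitlines() if not l.startswith("#")]
    from io import StringIO

    return pd.read_csv(StringIO("\n".join(lines)), sep="\t", keep_default_na=False)


def load_pattern_library(path: str | Path | None = None) -> list[SubstructurePattern]:
    """Load the substructure library (the shipped one when ``path`` is None).

    Returns the 43 patterns in deterministic ``pattern_id`` order. A
    user-supplied library must satisfy the same cardinality contract
    (43 patterns / 31 subclasses / 5 classes) and every expression must
    parse as a substructure query.
    """
    if path is None:
        raw = resources.files("polyphenome.data").joinpath("patterns.yaml").read_text()
    else:
        raw = Path(path).read_text()
    doc = yaml.safe_load(raw)
    if not isinstance(doc, dict) or "patterns" not in doc:
        raise ValidationError("pattern library must be a mapping with a 'patterns' list")
    patterns = []
    for entry in doc["patterns"]:
        pat = SubstructurePattern(
            pattern_id=str(entry["pattern_id"]),
            expression=str(entry["smarts"]),
            subclasses=tuple(entry["subclasses"]),
            class_name=str(entry["class"]),
        )
        if Chem.MolFromSmarts(pat.expression) is None:
            raise ValidationError(
                f"pattern {pat.pattern_id!r}: expression does not parse as SMARTS: {pat.expression!r}"
            )
        patterns.append(pat)
    patterns.sort(key=lambda p: p.pattern_id)
    ids = [p.pattern_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate pattern_id in library")
    if len(patterns) != EXPECTED_PATTERN_COUNT:
        raise ValidationError(f"library must contain exactly {EXPECTED_PATTERN_COUNT} patterns, found {len(patterns)}")
    subclasses = {s for p in patterns for s in p.subclasses}
    if len(subclasses) != EXPECTED_SUBCLASS_COUNT:
        raise ValidationError(f"library must span exactly {EXPECTED_SUBCLASS_COUNT} subclasses, found {len(subclasses)}")
    classes = {p.class_name for p in patterns}
    if classes != set(QUERYABLE_CLASSES):
        raise ValidationError(f"library classes must be {set(QUERYABLE_CLASSES)}, found {classes}")
    return patterns


def apply_exclusion_filters(structure: StandardStructure) -> tuple[bool, ExclusionReason]:
    """Decide whether a standardized structure enters classification.

    Checks, in order: average molecular mass > 1200 Da, presence of any
    nitrogen atom, steroid scaffold. Returns ``(kept, reason)``.
    """
    mol = structure.to_mol()
    if structure.avg_mass > MASS_LIMIT:
        return False, ExclusionReason.MASS
    if any(atom.GetAtomicNum() == 7 for atom in mol.GetAtoms()):
        return False, ExclusionReason.NITROGEN
    if mol.HasSubstructMatch(_STEROID_QUERY):
        return False, ExclusionReason.STEROID
    return True, ExclusionReason.NONE


def classify(structure: StandardStructure, library: Sequence[SubstructurePattern]) -> Classification:
    """Classify one standardized structure against the pattern library."""
    kept, reason = apply_exclusion_filters(structure)
    if not kept:
        return Classification(
            compound_id=structure.compound_id,
            matched_pattern_ids=frozenset(),
            subclasses=frozenset(),
            classes=frozenset(),
            excluded=True,
            exclusion_reason=reason,
        )
    mol = structure.to_mol()
    matched = [p for p in library if mol.HasSubstructMatch(p.query())]
    return Classification(
        compound_id=structure.compound_id,
        matched_pattern_ids=frozenset(p.pattern_id for p in matched),
        subclasses=frozenset(s for p in matched for s in p.subclasses),
        classes=frozenset(p.class_name for p in matched),
        excluded=False,
        exclusion_reason=ExclusionReason.NONE,
    )


def classify_batch(
    structures: Sequence[StandardStructure],
    library: Sequence[SubstructurePattern],
) -> list[Classification]:
    """Classify a batch of standardized structures (ids must be unique)."""
    ids = [s.compound_id for s in structures]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate compound_id(s): {', '.join(dupes)}")
    return [classify(s, library) for s in structures]


def classification_table(classifications: Iterable[Classification]) -> pd.DataFrame:
    """One row per compound, sets serialized as sorted ';'-joined strings."""
    rows = [
        {
            "compound_id": c.compound_id,
            "excluded": c.excluded,
            "exclusion_reason": c.exclusion_reason.value,
            "matched_patterns": ";".join(sorted(c.matched_pattern_ids)),
            "subclasses": ";".join(sorted(c.subclasses)),
            "classes": ";".join(sorted(c.classes)),
        }
        for c in classifications
    ]
    return pd.DataFrame(rows, columns=[
        "compound_id", "excluded", "exclusion_reason", "matched_patterns", "subclasses", "classes",
    ])


def summary_counts(classifications: Iterable[Classification]) -> dict[str, dict[str, int]]:
    """Tally compounds per class and per subclass (multi-label: a compound may count in several)."""
    by_class: dict[str, int] = {}
    by_subclass: dict[str, int] = {}
    n_excluded = 0
    for c in classifications:
        if c.excluded:
            n_excluded += 1
            continue
        for cls in c.classes:
            by_class[cls] = by_class.get(cls, 0) + 1
        for sub in c.subclasses:
            by_subclass[sub] = by_subclass.get(sub, 0) + 1
    return {
        "classes": dict(sorted(by_class.items())),
        "subclasses": dict(sorted(by_subclass.items())),
        "excluded": {"count": n_excluded},
    }
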