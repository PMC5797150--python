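"""Structure standardization, canonical keys, and strict-stereo list matching.

Standardization applies, in order: (i) fragment removal (keep the largest
organic fragment), (ii) charge neutralization, (iii) explicit-hydrogen
suppression, (iv) canonical tautomer selection, and (v) aromatization, then
emits a unique canonical SMILES. Equal molecules yield equal keys, which is
what list matching relies on.

Tetrahedral stereocenters survive standardization; double-bond stereo on
tautomer-mobile bonds is dropped by the canonical-tautomer step (the chosen
tautomer is a deterministic representative of the interconvertible set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import StructureError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardStructure",
    "MatchResult",
    "standardize",
    "standardize_many",
    "canonical_key",
    "match_lists",
    "read_smiles_file",
    "read_sdf",
    "write_smiles_file",
]


@dataclass(frozen=True)
class StandardStructure:
    """A standardized molecule: single fragment, neutralized, canonical tautomer."""

    compound_id: str
    canonical_smiles: str
    formula: str
    avg_mass: float
    has_stereo: bool

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise StructureError(f"stored canonical SMILES failed to parse: {self.canonical_smiles!r}")
        return mol


@dataclass(frozen=True)
class MatchResult:
    """Outcome of canonical-key matching between two compound lists."""

    pairs: tuple[tuple[str, str], ...]
    unmatched_a: frozenset[str]
    unmatched_b: frozenset[str]


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    params = rdMolStandardize.CleanupParameters()
    # bounded enumeration keeps the canonical choice deterministic and fast
    params.maxTransforms = 500
    params.maxTautomers = 500
    return rdMolStandardize.TautomerEnumerator(params)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = _tautomer_enumerator()


def _has_stereo(mol: Chem.Mol) -> bool:
    if Chem.FindMolChiralCenters(mol, includeUnassigned=False, useLegacyImplementation=False):
        return True
    return any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds())


def standardize(raw_smiles: str, compound_id: str = "") -> StandardStructure:
    """Standardize one SMILES string.

    Raises
    ------
    StructureError
        If ``raw_smiles`` does not parse.
    """
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES for {compound_id or '<anonymous>'}: {raw_smiles!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)          # (i) remove fragments
    mol = _UNCHARGER.uncharge(mol)               # (ii) neutralize
    mol = Chem.RemoveHs(mol)                     # (iii) suppress explicit H
    mol = _TAUTOMERIZER.Canonicalize(mol)        # (iv) tautomerize
    Chem.SanitizeMol(mol)                        # (v) aromatize
    smiles = Chem.MolToSmiles(mol)
    return StandardStructure(
        compound_id=compound_id,
        canonical_smiles=smiles,
        formula=rdMolDescriptors.CalcMolFormula(mol),
        avg_mass=Descriptors.MolWt(mol),
        has_stereo=_has_stereo(mol),
    )


def standardize_many(records: Iterable[tuple[str, str]]) -> list[StandardStructure]:
    """Standardize ``(compound_id, smiles)`` pairs, preserving input order."""
    return [standardize(smiles, compound_id) for compound_id, smiles in records]


def canonical_key(structure: StandardStructure | str, strict_stereo: bool = True) -> str:
    """Matching key for a standardized structure.

    With ``strict_stereo`` the key keeps stereo descriptors, so enantiomers
    get distinct keys and an entry without stereo annotation never matches a
    stereo-annotated one. Without it, stereo is stripped before
    canonicalization.
    """
    smiles = structure.canonical_smiles if isinstance(structure, StandardStructure) else structure
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol, isomericSmiles=strict_stereo)


def _key_index(structures: Sequence[StandardStructure], strict_stereo: bool, side: str) -> dict[str, str]:
    index: dict[str, str] = {}
    for s in structures:
        key = canonical_key(s, strict_stereo=strict_stereo)
        if key in index:
            logger.warning(
                "duplicate canonical key in list %s: %s duplicates %s; first occurrence kept",
                side, s.compound_id, index[key],
            )
            continue
        index[key] = s.compound_id
    return index


def match_lists(
    list_a: Sequence[StandardStructure],
    list_b: Sequence[StandardStructure],
    strict_stereo: bool = True,
) -> MatchResult:
    """Match two standardized lists by canonical-key equality."""
    index_a = _key_index(list_a, strict_stereo, "A")
    index_b = _key_index(list_b, strict_stereo, "B")
    pairs = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for key in sorted(set(index_a) & set(index_b)):
        pairs.append((index_a[key], index_b[key]))
        matched_a.add(index_a[key])
        matched_b.add(index_b[key])
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        unmatched_a=frozenset(s.compound_id for s in list_a) - matched_a,
        unmatched_b=frozenset(s.compound_id for s in list_b) - matched_b,
    )


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, ``SMILES<ws>id``.

    Lines without an id get a positional one (``line<n>``).
    """
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        cid = parts[1].strip() if len(parts) == 2 else f"line{i}"
        out.append((cid, parts[0]))
    return out


def read_sdf(path: str | Path) -> list[tuple[str, str]]:
    """Read an SDF file into ``(compound_id, smiles)`` pairs (id = molecule title)."""
    out = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            raise StructureError(f"unparseable SDF record {i} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        out.append((name, Chem.MolToSmiles(mol)))
    return out


def write_smiles_file(structures: Iterable[StandardStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.canonical_smiles}\t{s.compound_id}\n")
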