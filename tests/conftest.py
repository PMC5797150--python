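import pytest

from polyphenome import load_pattern_library, standardize
from polyphenome.taxonomy import load_reference_panel


@pytest.fixture(scope="session")
def library():
    return load_pattern_library()


@pytest.fixture(scope="session")
def panel():
    """Curated reference panel rows as dicts with parsed label sets."""
    df = load_reference_panel()
    rows = []
    for row in df.itertuples():
        rows.append({
            "compound_id": row.compound_id,
            "smiles": row.smiles,
            "subclasses": frozenset(str(row.expected_subclasses).split(";")) - {""},
            "classes": frozenset(str(row.expected_classes).split(";")) - {""},
            "excluded": row.expected_excluded,
            "reason": row.expected_reason,
        })
    return rows


@pytest.fixture(scope="session")
def panel_structures(panel):
    return {r["compound_id"]: standardize(r["smiles"], r["compound_id"]) for r in panel}
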