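import pandas as pd
import pytest

from pairprot import Dataset, load_worked_example

#: per-subject coded values of the bundled three-peptide demonstration:
#: a float is a case:control ratio, "+" case-only, "-" control-only, None absent
WORKED_CODES = {
    "LVNEVTEFAK": [None, "+", None, None, None, 0.19, 0.86, 1.37, 1.63, None],
    "YLYEIAR": [0.68, 1.15, 0.30, 0.23, "+", "-", 0.18, 0.10, 0.57, 0.42],
    "AEFAEVSK": [None, 3.64, "+", 1.06, "+", None, "+", None, 8.31, None],
}


def make_dataset(rows: list[dict]) -> Dataset:
    """Build a Dataset from sparse row dicts, filling sensible defaults."""
    defaults = {
        "peptide": "PEPTIDEK",
        "proteins": ("P1",),
        "subject": "S1",
        "condition": "case",
        "run": None,
        "xic_area": 1.0,
        "charge": 2,
        "n_points": 10,
    }
    full = []
    for row in rows:
        r = {**defaults, **row}
        if r["run"] is None:
            r["run"] = f"{r['subject']}_{r['condition']}"
        full.append(r)
    if not full:
        return Dataset(pd.DataFrame(columns=list(defaults)))
    return Dataset(pd.DataFrame(full))


@pytest.fixture(scope="session")
def worked_example() -> Dataset:
    return load_worked_example()


def make_srm_records(rows: list[dict]) -> pd.DataFrame:
    """Build an SRM transition frame from sparse row dicts."""
    defaults = {
        "peptide": "PEPTIDEK",
        "protein": "P1",
        "transition": "T1",
        "subject": "S1",
        "condition": "case",
        "replicate": 1,
        "area": 1.0,
        "is_global_standard": False,
    }
    if not rows:
        return pd.DataFrame(columns=list(defaults))
    return pd.DataFrame([{**defaults, **row} for row in rows])
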