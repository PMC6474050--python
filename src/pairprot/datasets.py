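"""Bundled demonstration data.

The worked example is a small synthetic quant table of three peptides across
ten paired subjects whose coded values exercise all four paired states; raw
areas are constructed so that every run has the same total ion current, so
the case:control ratios survive TIC normalization unchanged.  A shared
(non-proteotypic) anchor peptide tops every run up to the common total and
is removed by the proteotypic filter before statistics.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_quant_table
from .model import Dataset

#: expected per-peptide summaries of the worked example after the pipeline:
#: (successes x, trials n, exact binomial p, average log2 fold)
WORKED_EXAMPLE_EXPECTED = {
    "LVNEVTEFAK": {"x": 3, "n": 5, "p_value": 0.5},
    "YLYEIAR": {"x": 2, "n": 10, "p_value": 0.9892578125},
    "AEFAEVSK": {"x": 6, "n": 6, "p_value": 0.015625},
}


def worked_example_path() -> Path:
    return Path(resources.files("pairprot") / "data" / "worked_example_quant.tsv")


def load_worked_example() -> Dataset:
    """Load the three-peptide paired demonstration dataset."""
    return read_quant_table(worked_example_path())
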