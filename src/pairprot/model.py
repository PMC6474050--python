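"""Core domain types for paired label-free quantitation.

The central object is a :class:`Dataset`, a thin wrapper around a long-format
:class:`pandas.DataFrame` of per-run peptide XIC areas.  Per-subject paired
observations are summarised as :class:`PairedCode` values (a case:control
ratio, case-only ``+``, control-only ``-``, or absent ``0``), which feed the
exact binomial peptide statistic and the Stouffer protein roll-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

#: canonical frame columns of a quantitation dataset, in order
QUANT_COLUMNS = [
    "peptide",
    "proteins",
    "subject",
    "condition",
    "run",
    "xic_area",
    "charge",
    "n_points",
]

REQUIRED_QUANT_COLUMNS = ["peptide", "proteins", "subject", "condition", "run", "xic_area"]

#: columns identifying one quantitation record
QUANT_KEY = ["peptide", "subject", "condition", "run", "charge"]


class Condition(str, Enum):
    """Side of the pair: diseased (case) or contralateral control breast."""

    CASE = "case"
    CONTROL = "control"


class Direction(str, Enum):
    """Protein-level significance call from the symmetric p-value thresholds."""

    CASE_UP = "case_up"
    CONTROL_UP = "control_up"
    NOT_SIGNIFICANT = "not_significant"


class CodeTag(str, Enum):
    RATIO = "ratio"
    ABSENT = "absent"
    CASE_ONLY = "case_only"
    CONTROL_ONLY = "control_only"


@dataclass(frozen=True, slots=True)
class PairedCode:
    """Per-subject coded observation of one peptide.

    Exactly one of four states: ``Ratio(r)`` when the peptide was quantified
    in both breasts (r = case:control after TIC normalization), ``CaseOnly``
    (``+``) / ``ControlOnly`` (``-``) when quantified in a single breast, and
    ``Absent`` (``0``) when not observed at all.
    """

    tag: CodeTag
    value: float | None = None

    def __post_init__(self) -> None:
        if self.tag is CodeTag.RATIO:
            if self.value is None or not (self.value > 0):
                raise ValueError(f"Ratio code requires a positive value, got {self.value!r}")
        elif self.value is not None:
            raise ValueError(f"{self.tag.value} code carries no value")

    @classmethod
    def ratio(cls, value: float) -> "PairedCode":
        return cls(CodeTag.RATIO, float(value))

    @classmethod
    def absent(cls) -> "PairedCode":
        return cls(CodeTag.ABSENT)

    @classmethod
    def case_only(cls) -> "PairedCode":
        return cls(CodeTag.CASE_ONLY)

    @classmethod
    def control_only(cls) -> "PairedCode":
        return cls(CodeTag.CONTROL_ONLY)

    @property
    def is_trial(self) -> bool:
        """True when the subject contributes a binomial trial (non-absent)."""
        return self.tag is not CodeTag.ABSENT

    @property
    def is_success(self) -> bool:
        """Success = more abundant in the case breast: '+' or ratio > 1.

        A ratio of exactly 1 counts as a failure (success requires a ratio
        strictly greater than 1).
        """
        if self.tag is CodeTag.CASE_ONLY:
            return True
        return self.tag is CodeTag.RATIO and self.value > 1.0

    def __str__(self) -> str:
        if self.tag is CodeTag.RATIO:
            return format(self.value, "g")
        return {CodeTag.ABSENT: "0", CodeTag.CASE_ONLY: "+", CodeTag.CONTROL_ONLY: "-"}[self.tag]


@dataclass
class PeptideStat:
    """Binomial sign-test summary for one peptide across subjects.

    ``n`` counts non-absent subjects (trials), ``x`` the successes, and
    ``p_value`` the inclusive upper tail P(X >= x) under Bin(n, 1/2).
    ``avg_log2_fold`` averages log2 of the ratio codes only and is NaN when
    no ratio code exists.
    """

    peptide: str
    x: int
    n: int
    p_value: float
    avg_log2_fold: float = math.nan
    codes: dict[str, PairedCode] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")


@dataclass
class ProteinStat:
    """Weighted Stouffer combination of a protein's peptide p-values."""

    accession: str
    peptide_stats: list[PeptideStat]
    weights: list[float]
    z_scores: list[float]
    z: float
    p_value: float
    direction: Direction

    @property
    def k(self) -> int:
        return len(self.peptide_stats)


class Dataset:
    """Long-format collection of peptide quantitation records.

    Wraps a DataFrame with columns ``peptide, proteins, subject, condition,
    run, xic_area, charge, n_points`` where ``proteins`` holds a tuple of
    accessions (more than one marks the peptide non-proteotypic).
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy()
        for col in ("charge", "n_points"):
            if col not in frame.columns:
                frame[col] = pd.NA
        missing = [c for c in REQUIRED_QUANT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns: {missing}")
        self.frame = frame[QUANT_COLUMNS].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        f = self.frame
        if len(f) and (f["xic_area"] < 0).any():
            bad = f.loc[f["xic_area"] < 0].index[0]
            raise ValueError(f"negative xic_area at row {bad}")
        if len(f) and f["proteins"].map(len).eq(0).any():
            raise ValueError("record with empty protein accession list")
        dup = f.duplicated(subset=QUANT_KEY)
        if dup.any():
            keys = f.loc[dup, QUANT_KEY].to_dict("records")
            raise ValueError(f"duplicate quantitation records for keys: {keys[:5]}")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, check_like=True)
        except AssertionError:
            return False
        return True

    @property
    def subjects(self) -> list[str]:
        """Subject ids in order of first appearance."""
        return list(dict.fromkeys(self.frame["subject"]))

    @property
    def run_totals(self) -> pd.Series:
        """Total ion current per run: sum of xic_area grouped by run id."""
        return self.frame.groupby("run", sort=False)["xic_area"].sum()

    def replace_frame(self, frame: pd.DataFrame) -> "Dataset":
        return Dataset(frame, validate=False)
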