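"""Normalization and quality filters applied before the paired statistics.

Order of application in the standard pipeline: TIC normalization first (it
uses every record of a run, including those later filtered out), then the
record-level filters, which are mutually order-independent.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

from .model import CodeTag, Dataset, PairedCode

logger = logging.getLogger("pairprot")


def normalize_tic(dataset: Dataset) -> Dataset:
    """Divide each XIC area by its run's total ion current.

    After normalization each run's areas sum to 1, correcting for loading and
    instrument response differences between runs.  Idempotent up to floating
    tolerance: a second application divides by totals of 1.
    """
    if len(dataset) == 0:
        return dataset
    totals = dataset.run_totals
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"run(s) with non-positive total ion current: {bad}")
    frame = dataset.frame.copy()
    frame["xic_area"] = frame["xic_area"] / frame["run"].map(totals)
    return dataset.replace_frame(frame)


def filter_sequential_points(dataset: Dataset, min_points: int = 6) -> Dataset:
    """Drop records whose XIC has fewer than *min_points* sequential MS1 measurements.

    Guards against quantifying spurious one-scan signals.  The default of 6
    requires a minimally sampled chromatographic peak; the bound is inclusive
    (exactly 6 points is retained).  When the column is absent the filter is a
    pass-through with a warning.
    """
    frame = dataset.frame
    if frame["n_points"].isna().all():
        if len(frame):
            logger.warning("n_points unavailable; sequential-point filter skipped")
        return dataset
    keep = frame["n_points"].isna() | (frame["n_points"] >= min_points)
    removed = int((~keep).sum())
    if removed:
        logger.info("sequential-point filter removed %d record(s) (< %d points)", removed, min_points)
    return dataset.replace_frame(frame[keep])


def filter_proteotypic(dataset: Dataset) -> Dataset:
    """Keep only proteotypic peptides (mapping to exactly one accession).

    Shared peptides cannot be attributed to a single protein and would leak
    evidence between roll-ups.
    """
    frame = dataset.frame
    keep = frame["proteins"].map(len) == 1
    removed = int((~keep).sum())
    if removed:
        logger.info("proteotypic filter removed %d record(s) of shared peptides", removed)
    return dataset.replace_frame(frame[keep])


def filter_charges(dataset: Dataset, allowed_charges: Iterable[int] = (2, 3)) -> Dataset:
    """Keep records whose precursor charge is in *allowed_charges*.

    Records without a charge annotation pass through unchanged.
    """
    frame = dataset.frame
    if frame["charge"].isna().all():
        if len(frame):
            logger.warning("charge unavailable; charge filter skipped")
        return dataset
    allowed = set(int(c) for c in allowed_charges)
    keep = frame["charge"].isna() | frame["charge"].isin(allowed)
    removed = int((~keep).sum())
    if removed:
        logger.info("charge filter removed %d record(s) outside %s", removed, sorted(allowed))
    return dataset.replace_frame(frame[keep])


def apply_fold_change_gate(
    codes: Mapping[str, PairedCode],
    min_fold: float = 1.5,
    mode: str = "off",
) -> dict[str, PairedCode]:
    """Optionally neutralize ratio codes with sub-threshold fold changes.

    In ``neutralize`` mode a ratio strictly inside (1/min_fold, min_fold) is
    re-coded Absent, removing the subject from the binomial trials; one-sided
    (+/-) codes are never gated.  ``off`` (the default) is the identity: the
    worked-example coding counts ratios such as 1.06 and 1.15 as successes,
    so the statistic itself applies no fold threshold.
    """
    if mode not in ("off", "neutralize"):
        raise ValueError(f"unknown fold-gate mode {mode!r}")
    if min_fold < 1:
        raise ValueError(f"min_fold must be >= 1, got {min_fold}")
    if mode == "off":
        return dict(codes)
    out: dict[str, PairedCode] = {}
    for subject, code in codes.items():
        if code.tag is CodeTag.RATIO and 1.0 / min_fold < code.value < min_fold:
            out[subject] = PairedCode.absent()
        else:
            out[subject] = code
    return out
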