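"""Statistics for the targeted (SRM) verification experiment.

Transition areas exported from a targeted run are normalized to spiked
global standards, filtered by replicate coefficient of variation, averaged
over replicates, and then pushed through the same paired coding / binomial /
Stouffer machinery with transitions playing the role of peptides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import Dataset
from .paired import PairedResult, analyze_dataset

logger = logging.getLogger("pairprot")

#: one SRM "run" = one injection of one sample
RUN_KEY = ["subject", "condition", "replicate"]


def normalize_to_global_standards(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each transition area by the summed global-standard area of its run.

    Corrects injection-to-injection response drift.  Runs without any
    global-standard transition cannot be normalized and are dropped with a
    warning.  Standard rows themselves are retained (normalized like the
    rest) so downstream steps may still inspect them.
    """
    totals = (
        records[records["is_global_standard"]]
        .groupby(RUN_KEY, sort=False)["area"]
        .sum()
    )
    totals = totals[totals > 0]
    keyed = records.set_index(RUN_KEY)
    have = keyed.index.isin(totals.index)
    if (~have).any():
        dropped = sorted(set(map(tuple, records.loc[~have, RUN_KEY].itertuples(index=False))))
        logger.warning("dropping %d run(s) without global standards: %s", len(dropped), dropped[:5])
    out = keyed[have].copy()
    out["area"] = out["area"] / totals.reindex(out.index).to_numpy()
    return out.reset_index()


def cv_filter(
    records: pd.DataFrame,
    max_cv: float = 0.15,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep transitions reproducibly measured across technical replicates.

    CV = sd/mean (sample sd, n-1 denominator) of normalized areas across
    replicates, per transition per sample (subject x condition).  A
    transition is retained iff its CV is strictly below *max_cv* in every
    sample where it was measured with >= 2 replicates; with ``pooled=True``
    the CV is instead computed once on all replicate measurements pooled
    across samples.  Samples with an all-zero mean have undefined CV and
    drop the transition.

    Returns ``(retained_records, summary)`` where summary has one row per
    transition with its worst (or pooled) CV and the retention flag.
    """
    std = records[records["is_global_standard"]]
    work = records[~records["is_global_standard"]]
    group = ["transition"] if pooled else ["transition", "subject", "condition"]
    stats = work.groupby(group, sort=False)["area"].agg(["mean", "std", "size"])
    stats = stats[stats["size"] >= 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        stats["cv"] = stats["std"] / stats["mean"]
    worst = stats.groupby("transition", sort=False)["cv"].max()
    retained_ids = worst[(worst < max_cv) & worst.notna()].index
    summary = pd.DataFrame(
        {"transition": worst.index, "worst_cv": worst.to_numpy(), "retained": worst.index.isin(retained_ids)}
    ).reset_index(drop=True)
    dropped = summary.loc[~summary["retained"], "transition"].tolist()
    if dropped:
        logger.info("CV filter dropped %d transition(s): %s", len(dropped), dropped[:10])
    kept = work[work["transition"].isin(retained_ids)]
    return pd.concat([kept, std], ignore_index=True), summary


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean area per (transition, subject, condition) across replicates."""
    return (
        records.groupby(
            ["peptide", "protein", "transition", "subject", "condition", "is_global_standard"],
            sort=False,
        )["area"]
        .mean()
        .reset_index()
    )


def srm_paired_analysis(
    records: pd.DataFrame,
    *,
    alpha_low: float = 0.025,
    alpha_high: float = 0.975,
) -> PairedResult:
    """Paired binomial/Stouffer analysis of SRM transition areas.

    Expects standard-normalized, CV-filtered records; replicates are
    averaged per transition per sample and each transition then acts as a
    "peptide" of its protein in the paired statistic.  Global-standard rows
    are excluded from the comparison.
    """
    work = records[~records["is_global_standard"]]
    if len(work) == 0:
        return analyze_dataset(Dataset(pd.DataFrame(columns=["peptide", "proteins", "subject", "condition", "run", "xic_area"])))
    means = average_replicates(work)
    frame = pd.DataFrame(
        {
            "peptide": means["transition"],
            "proteins": means["protein"].map(lambda a: (a,)),
            "subject": means["subject"],
            "condition": means["condition"],
            "run": means["subject"].astype(str) + "_" + means["condition"].astype(str),
            "xic_area": means["area"],
        }
    )
    return analyze_dataset(Dataset(frame), alpha_low=alpha_low, alpha_high=alpha_high)
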