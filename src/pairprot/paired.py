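"""Paired peptide-centric differential-abundance statistics.

The model: for each peptide and each subject, the pair of TIC-normalized XIC
areas (diseased breast vs contralateral control) is reduced to a
:class:`~pairprot.model.PairedCode`.  Every subject with the peptide observed
in at least one breast is a Bernoulli trial; "success" means higher abundance
on the case side (ratio > 1 or case-only '+').  Under the null of no
disease association each trial succeeds with probability 1/2, so the
peptide's evidence is the exact binomial upper tail

    p = P(X >= x) = sum_{j=x}^{n} C(n, j) / 2^n .

Low p links the peptide to the case condition; high p (close to 1) to the
control condition.  Peptide p-values of one protein are combined with a
weighted Stouffer Z, with weights sqrt(n_i), and mapped back to a one-sided
protein p-value p = 1 - Phi(Z).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .model import CodeTag, Dataset, Direction, PairedCode, PeptideStat, ProteinStat

logger = logging.getLogger("pairprot")

#: clamp for peptide p-values before the normal quantile, guarding
#: Phi^-1 overflow at p = 0 or 1 without affecting ranking
P_CLAMP_EPS = 1e-15


# ---------------------------------------------------------------------------
# per-subject coding


def code_subject(case_area: float | None, control_area: float | None) -> PairedCode:
    """Code one subject's paired observation of a peptide.

    An area of ``None`` or 0 counts as "no XIC obtained" on that side (zero
    is the missing symbol in the four-state coding).  Areas are assumed
    TIC-normalized so the ratio is comparable across subjects.
    """
    case_present = case_area is not None and case_area > 0
    control_present = control_area is not None and control_area > 0
    if case_present and control_present:
        return PairedCode.ratio(case_area / control_area)
    if case_present:
        return PairedCode.case_only()
    if control_present:
        return PairedCode.control_only()
    return PairedCode.absent()


# ---------------------------------------------------------------------------
# exact binomial peptide statistic


@lru_cache(maxsize=None)
def binom_tail_p(x: int, n: int) -> float:
    """Inclusive upper tail P(X >= x) for X ~ Binomial(n, 1/2), exactly.

    Computed as an integer combinatorial sum divided by 2^n; no normal
    approximation.  ``binom_tail_p(0, n) == 1`` for every n.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 trial, got n={n}")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    return sum(math.comb(n, j) for j in range(x, n + 1)) / 2**n


def peptide_pvalue(codes: Mapping[str, PairedCode], peptide: str = "") -> PeptideStat:
    """Binomial sign-test summary of one peptide's per-subject codes.

    Trials n are the non-absent subjects; successes x are '+' codes and
    ratios strictly greater than 1 (a ratio of exactly 1 is a failure).
    Raises ``ValueError`` when every code is absent (no trial).
    """
    n = sum(1 for c in codes.values() if c.is_trial)
    if n == 0:
        raise ValueError(f"peptide {peptide!r} has no non-absent subject (n=0)")
    x = sum(1 for c in codes.values() if c.is_success)
    return PeptideStat(
        peptide=peptide,
        x=x,
        n=n,
        p_value=binom_tail_p(x, n),
        avg_log2_fold=avg_log2_fold(codes),
        codes=dict(codes),
    )


def avg_log2_fold(codes: Mapping[str, PairedCode]) -> float:
    """Mean log2 of the ratio codes; NaN when the peptide has no ratio code.

    One-sided ('+'/'-') and absent codes carry no fold information and are
    excluded, so the average reflects only subjects quantified in both
    breasts.
    """
    logs = [math.log2(c.value) for c in codes.values() if c.tag is CodeTag.RATIO]
    if not logs:
        return math.nan
    return float(np.mean(logs))


# ---------------------------------------------------------------------------
# Stouffer protein roll-up


def _z_from_p(p: np.ndarray | float) -> np.ndarray | float:
    return ndtri(1.0 - np.clip(p, P_CLAMP_EPS, 1.0 - P_CLAMP_EPS))


def stouffer_combine(z_scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted Stouffer combination Z = sum(w_i Z_i) / sqrt(sum(w_i^2)).

    Invariant under rescaling all weights by a common positive constant.
    """
    z = np.asarray(z_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.shape != w.shape or z.size == 0:
        raise ValueError("z_scores and weights must be equal-length and non-empty")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float((w * z).sum() / math.sqrt((w * w).sum()))


def classify(p: float, alpha_low: float = 0.025, alpha_high: float = 0.975) -> Direction:
    """Call direction from a one-sided p-value with symmetric thresholds.

    p < alpha_low links the protein (or peptide) to the case condition,
    p > alpha_high to the control condition.
    """
    if not 0 < alpha_low < alpha_high < 1:
        raise ValueError(f"need 0 < alpha_low < alpha_high < 1, got {alpha_low}, {alpha_high}")
    if p < alpha_low:
        return Direction.CASE_UP
    if p > alpha_high:
        return Direction.CONTROL_UP
    return Direction.NOT_SIGNIFICANT


def stouffer_protein(
    peptide_stats: Sequence[PeptideStat],
    accession: str = "",
    alpha_low: float = 0.025,
    alpha_high: float = 0.975,
) -> ProteinStat:
    """Combine a protein's peptide p-values into one protein-level call.

    Z_i = Phi^-1(1 - p_i) and w_i = sqrt(n_i), the square root of the number
    of subjects in which peptide i was observed; the protein p-value is the
    one-sided 1 - Phi(Z), so small p means case-abundant and large p
    control-abundant.
    """
    if len(peptide_stats) == 0:
        raise ValueError(f"protein {accession!r} has no peptide statistic (k=0)")
    z_scores = [float(_z_from_p(ps.p_value)) for ps in peptide_stats]
    weights = [math.sqrt(ps.n) for ps in peptide_stats]
    z = stouffer_combine(z_scores, weights)
    p = float(ndtr(-z))
    return ProteinStat(
        accession=accession,
        peptide_stats=list(peptide_stats),
        weights=weights,
        z_scores=z_scores,
        z=z,
        p_value=p,
        direction=classify(p, alpha_low, alpha_high),
    )


# ---------------------------------------------------------------------------
# vectorized whole-dataset analysis


@dataclass
class PairedResult:
    """Peptide- and protein-level report frames from one paired analysis."""

    proteins: pd.DataFrame
    peptides: pd.DataFrame


def code_peptides(dataset: Dataset, charge_merge: str = "sum") -> pd.DataFrame:
    """Per-(peptide, subject) paired coding of a (normalized) dataset.

    Charge states and repeat runs of the same subject/condition are merged
    into a single XIC value per breast, either by summing areas (default) or
    by keeping the most intense charge state (``charge_merge="best"``).

    Returns a frame with one row per non-absent subject:
    ``peptide, accession, subject, case_area, control_area, code, ratio,
    success`` where ``code`` is one of ``ratio|case_only|control_only``.
    """
    if charge_merge not in ("sum", "best"):
        raise ValueError(f"unknown charge_merge {charge_merge!r}")
    frame = dataset.frame
    if len(frame) == 0:
        return pd.DataFrame(
            columns=["peptide", "accession", "subject", "case_area", "control_area", "code", "ratio", "success"]
        )
    df = frame.copy()
    df["accession"] = df["proteins"].map(";".join)
    agg = "sum" if charge_merge == "sum" else "max"
    merged = (
        df.groupby(["peptide", "accession", "subject", "condition"], sort=False)["xic_area"]
        .agg(agg)
        .unstack("condition", fill_value=0.0)
    )
    for col in ("case", "control"):
        if col not in merged.columns:
            merged[col] = 0.0
    merged = merged.rename(columns={"case": "case_area", "control": "control_area"}).reset_index()
    merged = merged[(merged["case_area"] > 0) | (merged["control_area"] > 0)]

    both = (merged["case_area"] > 0) & (merged["control_area"] > 0)
    merged["code"] = np.where(
        both, CodeTag.RATIO.value, np.where(merged["case_area"] > 0, CodeTag.CASE_ONLY.value, CodeTag.CONTROL_ONLY.value)
    )
    merged["ratio"] = np.where(both, merged["case_area"] / merged["control_area"].replace(0, np.nan), np.nan)
    merged["success"] = (merged["code"] == CodeTag.CASE_ONLY.value) | (merged["ratio"] > 1.0)
    return merged.reset_index(drop=True)


def _code_symbol(row) -> str:
    if row["code"] == CodeTag.RATIO.value:
        return format(row["ratio"], "g")
    return "+" if row["code"] == CodeTag.CASE_ONLY.value else "-"


def analyze_dataset(
    dataset: Dataset,
    *,
    alpha_low: float = 0.025,
    alpha_high: float = 0.975,
    fold_gate_mode: str = "off",
    min_fold: float = 1.5,
    charge_merge: str = "sum",
) -> PairedResult:
    """Full paired analysis of a TIC-normalized, filtered dataset.

    Codes every peptide per subject, computes exact binomial peptide
    p-values and average log2 folds, rolls peptides up per protein with the
    weighted Stouffer Z, and classifies each protein at the symmetric
    thresholds.  A Benjamini-Hochberg column (``bh_q``) is emitted for
    information only; the classification itself uses the raw one-sided
    p-values.
    """
    codes = code_peptides(dataset, charge_merge=charge_merge)
    if fold_gate_mode == "neutralize":
        inside = (
            (codes["code"] == CodeTag.RATIO.value)
            & (codes["ratio"] > 1.0 / min_fold)
            & (codes["ratio"] < min_fold)
        )
        if inside.any():
            logger.info("fold-change gate neutralized %d coded value(s)", int(inside.sum()))
        codes = codes[~inside]
    elif fold_gate_mode != "off":
        raise ValueError(f"unknown fold_gate_mode {fold_gate_mode!r}")

    if len(codes) == 0:
        empty_prot = pd.DataFrame(columns=["accession", "p_value", "z", "k", "direction", "avg_log2_fold", "bh_q"])
        empty_pep = pd.DataFrame(columns=["peptide", "accession", "x", "n", "p_value", "avg_log2_fold", "codes"])
        return PairedResult(proteins=empty_prot, peptides=empty_pep)

    codes = codes.copy()
    codes["log2_ratio"] = np.log2(codes["ratio"])
    codes["symbol"] = codes["subject"].astype(str) + "=" + codes.apply(_code_symbol, axis=1)

    peptides = (
        codes.groupby(["peptide", "accession"], sort=False)
        .agg(
            x=("success", "sum"),
            n=("success", "size"),
            avg_log2_fold=("log2_ratio", "mean"),
            codes=("symbol", ",".join),
        )
        .reset_index()
    )
    peptides["p_value"] = [binom_tail_p(int(x), int(n)) for x, n in zip(peptides["x"], peptides["n"])]
    peptides = peptides[["peptide", "accession", "x", "n", "p_value", "avg_log2_fold", "codes"]]

    pz = _z_from_p(peptides["p_value"].to_numpy())
    pw = np.sqrt(peptides["n"].to_numpy(dtype=float))
    per_protein = pd.DataFrame(
        {"accession": peptides["accession"], "wz": pw * pz, "w2": pw * pw, "fold": peptides["avg_log2_fold"]}
    )
    grouped = per_protein.groupby("accession", sort=False)
    proteins = grouped.agg(wz=("wz", "sum"), w2=("w2", "sum"), k=("wz", "size"), avg_log2_fold=("fold", "mean")).reset_index()
    proteins["z"] = proteins["wz"] / np.sqrt(proteins["w2"])
    proteins["p_value"] = ndtr(-proteins["z"].to_numpy())
    proteins["direction"] = [classify(p, alpha_low, alpha_high).value for p in proteins["p_value"]]
    proteins["bh_q"] = multipletests(proteins["p_value"], method="fdr_bh")[1]
    proteins = proteins[["accession", "p_value", "z", "k", "direction", "avg_log2_fold", "bh_q"]]
    proteins = proteins.sort_values(["p_value", "accession"], kind="mergesort").reset_index(drop=True)
    return PairedResult(proteins=proteins, peptides=peptides.reset_index(drop=True))


# ---------------------------------------------------------------------------
# control-cohort exclusion


def cross_cohort_exclude(
    case_results: pd.DataFrame,
    control_cohort_results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove case-significant proteins that are also significant control-vs-control.

    Proteins flagged in a comparison between two *healthy* samples of the
    same subjects can only be false positives of the platform, so any
    protein significant in both comparisons is excluded from the case
    results.  Returns ``(filtered, removed)`` frames; removals are logged
    with both p-values.
    """
    if len(control_cohort_results) == 0 or len(case_results) == 0:
        return case_results.copy(), case_results.iloc[0:0].copy()
    sig_control = control_cohort_results.loc[
        control_cohort_results["direction"] != Direction.NOT_SIGNIFICANT.value
    ]
    control_p = sig_control.set_index("accession")["p_value"]
    drop = case_results["accession"].isin(control_p.index) & (
        case_results["direction"] != Direction.NOT_SIGNIFICANT.value
    )
    removed = case_results[drop].copy()
    for _, row in removed.iterrows():
        logger.info(
            "excluded %s: case p=%.4g, control-cohort p=%.4g",
            row["accession"],
            row["p_value"],
            control_p[row["accession"]],
        )
    return case_results[~drop].reset_index(drop=True), removed.reset_index(drop=True)


# ---------------------------------------------------------------------------
# NIAF abundance ranking


def niaf(dataset: Dataset, condition: str = "case") -> pd.DataFrame:
    """Normalized intensity abundance factor per protein, averaged over subjects.

    Within each sample of the chosen condition, a protein's NIAF is the sum
    of its peptides' TIC-normalized XIC areas divided by the summed areas of
    all proteins, so NIAFs in one sample add to 1.  The reported value is the
    mean over subjects (proteins missing from a sample contribute 0).  The
    output also carries the abundance rank (1 = most abundant) and the
    display transform ``-1e7 * log10(mean NIAF)`` used for rank plots.
    """
    frame = dataset.frame
    sel = frame[frame["condition"] == condition].copy()
    if len(sel) == 0:
        return pd.DataFrame(columns=["accession", "mean_niaf", "rank", "neg_log_score"])
    sel["accession"] = sel["proteins"].map(";".join)
    table = sel.pivot_table(index="accession", columns="subject", values="xic_area", aggfunc="sum", fill_value=0.0)
    shares = table / table.sum(axis=0)
    mean_niaf = shares.mean(axis=1)
    out = mean_niaf.rename("mean_niaf").reset_index()
    out = out.sort_values("mean_niaf", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    with np.errstate(divide="ignore"):
        out["neg_log_score"] = -1e7 * np.log10(out["mean_niaf"])
    return out


# ---------------------------------------------------------------------------
# unpaired group-mean baseline


def baseline_unpaired(
    dataset: Dataset,
    fold_cutoff: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Conventional unpaired comparison of group means, as a contrast method.

    Per protein: sample abundances are the summed normalized peptide areas
    per subject and condition, log2-transformed; case vs control compared
    with Welch's t-test; Benjamini-Hochberg adjustment across proteins; a
    protein is flagged when q < *alpha* and the absolute mean log2 fold is at
    least log2(*fold_cutoff*).  Proteins with fewer than two samples per
    group are marked untestable.  This ignores the pairing, which is exactly
    why it loses power on heterogeneous paired cohorts.
    """
    frame = dataset.frame.copy()
    frame["accession"] = frame["proteins"].map(";".join)
    ab = (
        frame.groupby(["accession", "subject", "condition"], sort=False)["xic_area"]
        .sum()
        .reset_index()
    )
    ab = ab[ab["xic_area"] > 0]
    ab["log2_abundance"] = np.log2(ab["xic_area"])

    rows = []
    for accession, sub in ab.groupby("accession", sort=False):
        case = sub.loc[sub["condition"] == "case", "log2_abundance"].to_numpy()
        control = sub.loc[sub["condition"] == "control", "log2_abundance"].to_numpy()
        testable = len(case) >= 2 and len(control) >= 2
        if testable:
            fold = float(case.mean() - control.mean())
            if case.std() == 0.0 and control.std() == 0.0:
                # degenerate zero-variance groups: identical means carry no
                # evidence, distinct means are a deterministic difference
                p = 1.0 if fold == 0.0 else 0.0
            else:
                p = float(ttest_ind(case, control, equal_var=False).pvalue)
        else:
            p, fold = np.nan, np.nan
        rows.append(
            {"accession": accession, "mean_log2_fold": fold, "t_p": p, "testable": testable}
        )
    out = pd.DataFrame(rows)
    out["bh_q"] = np.nan
    mask = out["testable"] & out["t_p"].notna()
    if mask.any():
        out.loc[mask, "bh_q"] = multipletests(out.loc[mask, "t_p"], method="fdr_bh")[1]
    out["flagged"] = (
        mask
        & (out["bh_q"] < alpha)
        & (out["mean_log2_fold"].abs() >= math.log2(fold_cutoff))
    )
    return out.reset_index(drop=True)
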