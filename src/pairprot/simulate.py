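"""Synthetic paired-secretome generator.

Emulates the statistical structure of a paired biofluid cohort: strong
between-patient protein-level heterogeneity shared by both samples of a
subject, a multiplicative disease effect confined to the case sample of
affected proteins, peptide-specific response, measurement noise,
run-to-run total-ion-current variation, and left-censored missingness at a
detection limit (which is what produces the one-sided '+'/'-' codes
mechanistically rather than at random).

The log2-intensity model for peptide j of protein p in subject i, condition c:

    log2 A = b_p + e_j + s_ip + d_p * 1[c = case] + noise

with b_p the protein base abundance, e_j a peptide (ionization) offset,
s_ip ~ N(0, subject_scale_sd) the subject-protein heterogeneity shared by
both breasts, d_p the disease effect (effect_log2fold for affected
proteins, 0 otherwise), and noise ~ N(0, peptide_noise_sd) independent per
measurement.  Raw areas are 2**log2A, perturbed per run by a lognormal TIC
factor, and censored below detection_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import Dataset


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-secretome generator.

    Defaults describe a cohort of 10 patients with paired samples, 100
    proteins of 3-8 peptides, a disease effect of 1.5 log2 units (2.8-fold)
    on 10% of proteins, moderate biological heterogeneity and measurement
    noise, and a detection limit censoring roughly the bottom 5% of
    measurements.
    """

    n_subjects: int = 10
    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (3, 8)
    frac_case_up: float = 0.1
    effect_log2fold: float = 1.5
    subject_scale_sd: float = 1.0
    peptide_noise_sd: float = 0.5
    detection_threshold: float = 65536.0  # 2**16 against a 2**20 base
    tic_variation_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_proteins < 1:
            raise ValueError("need at least one subject and one protein")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid peptides_per_protein range {self.peptides_per_protein}")
        for name in ("subject_scale_sd", "peptide_noise_sd", "tic_variation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_case_up <= 1.0:
            raise ValueError("frac_case_up must be in [0, 1]")


#: protein base log2 abundance ~ N(BASE_LOG2_MEAN, BASE_LOG2_SD)
BASE_LOG2_MEAN = 20.0
BASE_LOG2_SD = 2.0
#: peptide ionization offset SD (log2)
PEPTIDE_OFFSET_SD = 1.0

_PRESETS = {
    # typical cohort: modest heterogeneity, paired and unpaired both workable
    "homogeneous": {"subject_scale_sd": 0.3},
    # patient heterogeneity exceeding the disease effect: unpaired group
    # means overlap, only the within-pair contrast survives
    "heterogeneous": {"subject_scale_sd": 3.0},
    # no disease effect anywhere: type-I error testbed
    "null": {"frac_case_up": 0.0, "effect_log2fold": 0.0},
}


def preset(name: str, **overrides) -> SimConfig:
    """Named reproducible configuration: homogeneous | heterogeneous | null."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(SimConfig(**_PRESETS[name]), **overrides)


def simulate(config: SimConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a paired quantitation dataset and its ground truth.

    Returns ``(dataset, truth)`` where truth has one row per protein with
    columns ``accession, affected, effect_log2`` (signed disease effect).
    Identical configs produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.peptides_per_protein

    n_pep = rng.integers(lo, hi + 1, size=config.n_proteins)
    accessions = np.array([f"SIM{p:05d}" for p in range(config.n_proteins)])
    n_affected = int(round(config.frac_case_up * config.n_proteins))
    affected_idx = rng.choice(config.n_proteins, size=n_affected, replace=False)
    effect = np.zeros(config.n_proteins)
    effect[affected_idx] = config.effect_log2fold

    base = rng.normal(BASE_LOG2_MEAN, BASE_LOG2_SD, size=config.n_proteins)
    total_pep = int(n_pep.sum())
    pep_protein = np.repeat(np.arange(config.n_proteins), n_pep)
    pep_offset = rng.normal(0.0, PEPTIDE_OFFSET_SD, size=total_pep)
    pep_names = np.array(
        [f"PEP{p:05d}_{j:02d}" for p, j in zip(pep_protein, _within_counts(n_pep))]
    )
    pep_charge = rng.choice([2, 3], size=total_pep)

    # subject-protein heterogeneity shared by both samples of a subject
    subj_scale = rng.normal(0.0, config.subject_scale_sd, size=(config.n_subjects, config.n_proteins))

    subjects = np.array([f"S{i + 1:03d}" for i in range(config.n_subjects)])
    conditions = np.array(["case", "control"])
    tic_factor = 2.0 ** rng.normal(0.0, config.tic_variation_sd, size=(config.n_subjects, 2))

    rows = []
    for i in range(config.n_subjects):
        for ci, cond in enumerate(conditions):
            log2a = (
                base[pep_protein]
                + pep_offset
                + subj_scale[i, pep_protein]
                + (effect[pep_protein] if cond == "case" else 0.0)
                + rng.normal(0.0, config.peptide_noise_sd, size=total_pep)
            )
            area = 2.0**log2a * tic_factor[i, ci]
            n_points = rng.integers(4, 40, size=total_pep)
            detected = area >= config.detection_threshold
            rows.append(
                pd.DataFrame(
                    {
                        "peptide": pep_names[detected],
                        "proteins": [(a,) for a in accessions[pep_protein[detected]]],
                        "subject": subjects[i],
                        "condition": cond,
                        "run": f"{subjects[i]}_{cond}",
                        "xic_area": area[detected],
                        "charge": pep_charge[detected],
                        "n_points": n_points[detected],
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    frame["charge"] = frame["charge"].astype("Int64")
    frame["n_points"] = frame["n_points"].astype("Int64")
    truth = pd.DataFrame(
        {"accession": accessions, "affected": effect != 0.0, "effect_log2": effect}
    )
    return Dataset(frame, validate=False), truth


def _within_counts(n_pep: np.ndarray) -> np.ndarray:
    """Per-protein running peptide index: [2,3] -> [0,1,0,1,2]."""
    return np.concatenate([np.arange(k) for k in n_pep]) if len(n_pep) else np.array([], dtype=int)
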