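"""End-to-end wiring: normalize -> filter -> paired stats -> exclusion -> reports.

These functions are the programmatic equivalent of a batch tool: they take a
table (path or :class:`Dataset`), run every stage in the canonical order,
return the results, and optionally write deterministic TSV reports plus a
run log recording all parameter values and per-filter removal counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .io import read_quant_table, write_results
from .model import Dataset
from .paired import PairedResult, analyze_dataset, cross_cohort_exclude, niaf
from .preprocess import filter_charges, filter_proteotypic, filter_sequential_points, normalize_tic

logger = logging.getLogger("pairprot")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the standard paired analysis."""

    min_points: int = 6
    allowed_charges: tuple[int, ...] | None = None  # None = no charge filter
    fold_gate_mode: str = "off"
    min_fold: float = 1.5
    charge_merge: str = "sum"
    alpha_low: float = 0.025
    alpha_high: float = 0.975


@dataclass
class PipelineResult:
    result: PairedResult
    removed: pd.DataFrame | None
    log: dict = field(default_factory=dict)


def run_pipeline(
    data: Dataset | str | Path,
    config: AnalysisConfig | None = None,
    *,
    exclude_from: PairedResult | pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full paired differential-abundance workflow.

    Stages, in order: read (if *data* is a path), TIC normalization,
    sequential-point / charge / proteotypic filters, per-subject coding with
    exact binomial peptide p-values, Stouffer protein roll-up and
    classification, and optionally the control-cohort exclusion against
    *exclude_from* (the protein report of a control-vs-control run).  When
    *out_dir* is given, protein/peptide TSV reports and a JSON run log are
    written there; identical inputs produce byte-identical reports.
    """
    config = config or AnalysisConfig()
    dataset = data if isinstance(data, Dataset) else read_quant_table(data)
    log: dict = {"parameters": asdict(config), "n_records_input": len(dataset)}

    dataset = normalize_tic(dataset)
    n = len(dataset)
    dataset = filter_sequential_points(dataset, config.min_points)
    log["removed_sequential_points"] = n - len(dataset)
    n = len(dataset)
    if config.allowed_charges is not None:
        dataset = filter_charges(dataset, config.allowed_charges)
    log["removed_charge"] = n - len(dataset)
    n = len(dataset)
    dataset = filter_proteotypic(dataset)
    log["removed_non_proteotypic"] = n - len(dataset)
    log["n_records_analyzed"] = len(dataset)

    result = analyze_dataset(
        dataset,
        alpha_low=config.alpha_low,
        alpha_high=config.alpha_high,
        fold_gate_mode=config.fold_gate_mode,
        min_fold=config.min_fold,
        charge_merge=config.charge_merge,
    )
    log["n_peptides"] = len(result.peptides)
    log["n_proteins"] = len(result.proteins)

    removed = None
    if exclude_from is not None:
        control = exclude_from.proteins if isinstance(exclude_from, PairedResult) else exclude_from
        filtered, removed = cross_cohort_exclude(result.proteins, control)
        result = PairedResult(proteins=filtered, peptides=result.peptides)
        log["excluded_from_control_cohort"] = removed["accession"].tolist()

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_results(result.proteins, result.peptides, out_dir)
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        logger.info("reports written to %s", out_dir)
    return PipelineResult(result=result, removed=removed, log=log)


def niaf_ranking(data: Dataset | str | Path, out_path: str | Path | None = None) -> pd.DataFrame:
    """TIC-normalize a dataset and export the protein NIAF abundance ranking."""
    dataset = data if isinstance(data, Dataset) else read_quant_table(data)
    ranking = niaf(normalize_tic(dataset))
    if out_path is not None:
        ranking.to_csv(out_path, sep="\t", index=False)
    return ranking
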