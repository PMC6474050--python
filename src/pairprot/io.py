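"""Readers and writers for quantitation tables, SRM transition tables and reports.

All interchange is plain UTF-8 TSV with a ``.`` decimal separator.  The quant
table is long-format: one row per (peptide, subject, condition, run, charge)
XIC area.  Vendor binary formats are deliberately not parsed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    QUANT_COLUMNS,
    QUANT_KEY,
    REQUIRED_QUANT_COLUMNS,
    Dataset,
    PeptideStat,
    ProteinStat,
)

logger = logging.getLogger("pairprot")


class SchemaError(ValueError):
    """Input table does not match the documented TSV schema."""


class DuplicateRecordError(ValueError):
    """Two rows share the (peptide, subject, condition, run, charge) key."""


_CONDITION_ALIASES = {
    "case": "case",
    "cancer": "case",
    "disease": "case",
    "control": "control",
    "healthy": "control",
}

SRM_COLUMNS = [
    "peptide",
    "protein",
    "transition",
    "subject",
    "condition",
    "replicate",
    "area",
    "is_global_standard",
]


def _normalize_condition(series: pd.Series) -> pd.Series:
    cond = series.astype(str).str.strip().str.lower().map(_CONDITION_ALIASES)
    if cond.isna().any():
        bad = sorted(set(series[cond.isna()].astype(str)))
        raise SchemaError(f"unrecognized condition labels: {bad}; expected case|control")
    return cond


def _numeric_area(series: pd.Series, column: str) -> pd.Series:
    area = pd.to_numeric(series, errors="coerce")
    if area.isna().any():
        bad = series[area.isna()].iloc[0]
        raise SchemaError(f"non-numeric {column} value {bad!r}")
    if (area < 0).any():
        bad = area[area < 0].iloc[0]
        raise SchemaError(f"negative {column} value {bad}")
    return area.astype(float)


def read_quant_table(path: str | Path, *, accession_delimiter: str = ";") -> Dataset:
    """Read a long-format peptide quantitation TSV into a :class:`Dataset`.

    Required columns: ``peptide, proteins, subject, condition, run, xic_area``;
    optional: ``charge, n_points``.  ``proteins`` may list several accessions
    separated by *accession_delimiter*; such peptides are non-proteotypic and
    are excluded later by :func:`pairprot.preprocess.filter_proteotypic`.

    Raises :class:`SchemaError` for missing columns, non-numeric or negative
    areas, and :class:`DuplicateRecordError` for repeated record keys.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    out = pd.DataFrame(
        {
            "peptide": df["peptide"].astype(str),
            "proteins": df["proteins"]
            .astype(str)
            .map(lambda s: tuple(a.strip() for a in s.split(accession_delimiter) if a.strip())),
            "subject": df["subject"].astype(str),
            "condition": _normalize_condition(df["condition"]),
            "run": df["run"].astype(str),
            "xic_area": _numeric_area(df["xic_area"], "xic_area"),
        }
    )
    if out["proteins"].map(len).eq(0).any():
        raise SchemaError("row with empty protein accession list")

    for col, kind in (("charge", "Int64"), ("n_points", "Int64")):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce").astype(kind)
        else:
            out[col] = pd.array([pd.NA] * len(df), dtype=kind)
            logger.warning("column %r absent from %s; dependent filters disabled", col, path.name)

    dup = out.duplicated(subset=QUANT_KEY)
    if dup.any():
        keys = out.loc[dup, QUANT_KEY].to_dict("records")
        raise DuplicateRecordError(f"duplicate record key(s): {keys[:5]}")
    return Dataset(out)


def write_quant_table(dataset: Dataset, path: str | Path, *, accession_delimiter: str = ";") -> None:
    """Write a :class:`Dataset` back to the long-format quant TSV."""
    df = dataset.frame.copy()
    df["proteins"] = df["proteins"].map(accession_delimiter.join)
    df.to_csv(path, sep="\t", index=False)


def read_srm_table(path: str | Path) -> pd.DataFrame:
    """Read a Skyline-style long TSV of SRM transition areas.

    Columns: ``peptide, protein, transition, subject, condition, replicate,
    area, is_global_standard`` (0|1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SRM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    out = df[SRM_COLUMNS[:5]].astype(str).copy()
    out["condition"] = _normalize_condition(df["condition"])
    out["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    out["area"] = _numeric_area(df["area"], "area")
    out["is_global_standard"] = (
        pd.to_numeric(df["is_global_standard"], errors="raise").astype(int).astype(bool)
    )
    dup = out.duplicated(subset=["transition", "subject", "condition", "replicate"])
    if dup.any():
        keys = out.loc[dup, ["transition", "subject", "condition", "replicate"]].to_dict("records")
        raise DuplicateRecordError(f"duplicate transition record(s): {keys[:5]}")
    return out


PROTEIN_REPORT_COLUMNS = [
    "accession",
    "p_value",
    "z",
    "k",
    "direction",
    "avg_log2_fold",
    "bh_q",
]

PEPTIDE_REPORT_COLUMNS = [
    "peptide",
    "accession",
    "x",
    "n",
    "p_value",
    "avg_log2_fold",
    "codes",
]


def _protein_frame(protein_stats) -> pd.DataFrame:
    if isinstance(protein_stats, pd.DataFrame):
        return protein_stats
    rows = []
    for ps in protein_stats:
        folds = [p.avg_log2_fold for p in ps.peptide_stats if np.isfinite(p.avg_log2_fold)]
        rows.append(
            {
                "accession": ps.accession,
                "p_value": ps.p_value,
                "z": ps.z,
                "k": ps.k,
                "direction": ps.direction.value,
                "avg_log2_fold": float(np.mean(folds)) if folds else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=[c for c in PROTEIN_REPORT_COLUMNS if c != "bh_q"])


def _peptide_frame(peptide_stats, accessions: dict[str, str] | None = None) -> pd.DataFrame:
    if isinstance(peptide_stats, pd.DataFrame):
        return peptide_stats
    rows = []
    for ps in peptide_stats:
        codes = ""
        if ps.codes is not None:
            codes = ",".join(f"{s}={c}" for s, c in ps.codes.items())
        rows.append(
            {
                "peptide": ps.peptide,
                "accession": (accessions or {}).get(ps.peptide, ""),
                "x": ps.x,
                "n": ps.n,
                "p_value": ps.p_value,
                "avg_log2_fold": ps.avg_log2_fold,
                "codes": codes,
            }
        )
    return pd.DataFrame(rows, columns=PEPTIDE_REPORT_COLUMNS)


def write_results(protein_stats, peptide_stats, out_dir: str | Path) -> tuple[Path, Path]:
    """Write protein- and peptide-level TSV reports into *out_dir*.

    Accepts either report DataFrames or lists of :class:`ProteinStat` /
    :class:`PeptideStat`.  Protein rows are sorted ascending by p-value so the
    strongest case-associated proteins lead the report; column order is fixed.
    Returns the two paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins = _protein_frame(protein_stats)
    peptides = _peptide_frame(peptide_stats)
    proteins = proteins.sort_values(["p_value", "accession"], kind="mergesort").reset_index(drop=True)
    prot_cols = [c for c in PROTEIN_REPORT_COLUMNS if c in proteins.columns]
    pep_cols = [c for c in PEPTIDE_REPORT_COLUMNS if c in peptides.columns]
    protein_path = out_dir / "proteins.tsv"
    peptide_path = out_dir / "peptides.tsv"
    proteins[prot_cols].to_csv(protein_path, sep="\t", index=False)
    peptides[pep_cols].to_csv(peptide_path, sep="\t", index=False)
    return protein_path, peptide_path
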