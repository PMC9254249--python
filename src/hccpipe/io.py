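"""Readers and writers for the pipeline's tab-separated file dialects.

MAF-like mutation tables, SEG copy-number segments, expression matrices,
clinical tables and per-sample purity profiles.  All coordinates are
1-based inclusive; all files are plain TSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MAF_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "t_depth", "t_alt_count", "context96", "coding",
]
SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "integer_cn"]
CLINICAL_COLUMNS = [
    "sample_id", "cohort", "age", "sex", "viral_status", "stage", "grade",
    "os_time", "os_event",
]
PURITY_COLUMNS = ["sample_id", "purity", "ploidy", "sex"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_columns(df, MAF_COLUMNS, "MAF table")
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    _check_columns(df, MAF_COLUMNS, "MAF table")
    df.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_columns(df, SEG_COLUMNS, "SEG table")
    return df


def write_seg(df: pd.DataFrame, path) -> None:
    _check_columns(df, SEG_COLUMNS, "SEG table")
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV; header row holds sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, CLINICAL_COLUMNS, "clinical table")
    return df


def read_purity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, PURITY_COLUMNS, "purity table")
    return df


def seg_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive SEG intervals to 0-based half-open BED."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def bed_to_seg(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
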