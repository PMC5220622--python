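"""TSV reading/writing conventions shared by all pipeline stages.

Tables are tab-delimited UTF-8 with a header row, '.' decimal separator and
the empty string for missing values.  Intensity matrices are wide: one row
per sample (first column = sample id), one column per feature.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_table",
    "write_table",
]

SAMPLE_COLUMNS = ["subject_id", "time_point", "ft4", "tsh", "age", "bmi", "batch", "run_day"]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"batch": str, "run_day": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"{path}: sample table lacks column(s) {', '.join(missing)}")
    return samples


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
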