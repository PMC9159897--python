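"""CSV input/output for series, covariates, counts and results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tables import ContingencyTable

__all__ = [
    "read_series_csv",
    "read_covariates_csv",
    "read_counts_csv",
    "write_outcomes_csv",
    "write_cohort_csvs",
]

SERIES_COLUMNS = ("patient_id", "session", "score")


def read_series_csv(path) -> pd.DataFrame:
    """Long-format measurement series: patient_id, session, score."""
    path = Path(path)
    frame = pd.read_csv(path, encoding="utf-8")
    missing = set(SERIES_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = frame.index[pd.to_numeric(frame["score"], errors="coerce").isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-numeric score on line {int(bad[0]) + 2}")
    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["session"] = frame["session"].astype(int)
    frame["score"] = frame["score"].astype(float)
    return frame


def read_covariates_csv(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, encoding="utf-8")
    if "patient_id" not in frame.columns:
        raise ValueError(f"{path}: missing patient_id column")
    frame["patient_id"] = frame["patient_id"].astype(str)
    return frame


def read_counts_csv(path) -> ContingencyTable:
    """A bare counts table: first column row labels, header column labels."""
    path = Path(path)
    frame = pd.read_csv(path, encoding="utf-8", index_col=0)
    counts = frame.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cell in counts table")
    return ContingencyTable(
        counts,
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
        name=path.stem,
    )


def write_outcomes_csv(outcomes: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(path, index=False)
    return path


def write_cohort_csvs(cohort, out_dir) -> dict[str, Path]:
    """Write a simulated cohort: series.csv, covariates.csv, config.yaml."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_path = out_dir / "series.csv"
    cov_path = out_dir / "covariates.csv"
    cfg_path = out_dir / "config.yaml"
    cohort.series_frame().to_csv(series_path, index=False)
    cohort.covariates.to_csv(cov_path, index=False)
    cfg_path.write_text(yaml.safe_dump(cohort.config.to_dict(), sort_keys=True))
    return {"series": series_path, "covariates": cov_path, "config": cfg_path}
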