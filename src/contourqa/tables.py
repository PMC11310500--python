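"""Cohort metric table: the long-form record of every computed metric.

One row per (patient, organ, method, metric).  The 13 metric names are the
six overlap scores plus the seven surface-distance statistics; NaN is the
universal "undefined" sentinel and serializes as an empty CSV cell.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OVERLAP_METRIC_NAMES",
    "DISTANCE_METRIC_NAMES",
    "METRIC_NAMES",
    "IntegrityError",
    "CohortMetricTable",
    "write_metric_table",
    "read_metric_table",
]

OVERLAP_METRIC_NAMES: tuple[str, ...] = ("DSC", "JAC", "TPR", "TNR", "RI", "PPV")
DISTANCE_METRIC_NAMES: tuple[str, ...] = (
    "HD_std",
    "HD_min",
    "HD_median",
    "HD_mean",
    "MDA",
    "HD_95",
    "HD_max",
)
METRIC_NAMES: tuple[str, ...] = OVERLAP_METRIC_NAMES + DISTANCE_METRIC_NAMES

_COLUMNS = ["patient_id", "organ", "method", "metric", "value"]
_KEY = ["patient_id", "organ", "method", "metric"]


class IntegrityError(ValueError):
    """Duplicate (patient, organ, method, metric) keys or bad metric names."""


class CohortMetricTable:
    """Thin validating wrapper around a long-form pandas DataFrame."""

    def __init__(self, records: pd.DataFrame | list[tuple] | None = None):
        if records is None:
            df = pd.DataFrame(columns=_COLUMNS)
        elif isinstance(records, pd.DataFrame):
            df = records.loc[:, _COLUMNS].copy()
        else:
            df = pd.DataFrame(records, columns=_COLUMNS)
        df["value"] = df["value"].astype(float)
        for c in _KEY:
            df[c] = df[c].astype(str)
        bad = set(df["metric"]) - set(METRIC_NAMES)
        if bad:
            raise IntegrityError(f"unknown metric names: {sorted(bad)}")
        if df.duplicated(subset=_KEY).any():
            dups = df[df.duplicated(subset=_KEY, keep=False)][_KEY]
            raise IntegrityError(f"duplicate metric records:\n{dups}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMetricTable):
            return NotImplemented
        a = self.df.sort_values(_KEY).reset_index(drop=True)
        b = other.df.sort_values(_KEY).reset_index(drop=True)
        if len(a) != len(b):
            return False
        same_keys = (a[_KEY] == b[_KEY]).all().all()
        va, vb = a["value"].to_numpy(), b["value"].to_numpy()
        same_vals = np.all((va == vb) | (np.isnan(va) & np.isnan(vb)))
        return bool(same_keys and same_vals)

    def add(self, patient_id: str, organ: str, method: str, metric: str, value: float):
        """Append one record, enforcing key uniqueness."""
        row = pd.DataFrame(
            [[str(patient_id), str(organ), str(method), str(metric), float(value)]],
            columns=_COLUMNS,
        )
        new = CohortMetricTable(pd.concat([self.df, row], ignore_index=True))
        self.df = new.df
        return self


def write_metric_table(table: CohortMetricTable, path: str | Path) -> None:
    """Write the table as CSV; NaN values become empty cells."""
    table.df.to_csv(path, index=False, na_rep="")


def read_metric_table(path: str | Path) -> CohortMetricTable:
    """Read a metric CSV back; empty value cells become NaN."""
    df = pd.read_csv(
        path, dtype={c: str for c in _KEY}, keep_default_na=True
    )
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise IntegrityError(f"metric CSV missing columns: {sorted(missing)}")
    return CohortMetricTable(df)
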