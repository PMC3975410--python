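"""Tidy time-course datasets: the exchange format for measurements.

All measurement and trajectory exchange uses long-format CSV with columns
``time_h, variable, value, sd`` (``sd`` optional on read; a ``censored``
column marks below-detection records that carry the detection threshold
as their value).
"""

from __future__ import annotations

import io
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time_h", "variable", "value")

#: measured observables of the default model (culture panel, nucleotides,
#: NSDs)
KNOWN_VARIABLES = (
    "Glc_ext", "Gln_ext", "Xv", "Xd", "mAb",
    "ADP", "AMP", "ATP", "CTP", "GTP", "UTP",
    "CMP-Neu5Ac", "GDP-Fuc", "GDP-Man", "UDP-GalNAc",
    "UDP-Gal", "UDP-Glc", "UDP-GlcNAc",
)


@dataclass
class TimeSeriesDataset:
    """Measurement records driving calibration.

    ``data`` columns: time_h, variable, value, sd, censored.  Missing sd
    defaults to 10% of the value (never below a small positive floor).
    """

    data: pd.DataFrame
    default_cv: float = 0.10

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"dataset lacks column {col!r}")
        if "sd" not in df.columns:
            df["sd"] = np.nan
        if "censored" not in df.columns:
            df["censored"] = False
        fill = df["sd"].isna()
        df.loc[fill, "sd"] = np.maximum(
            self.default_cv * df.loc[fill, "value"].abs(), 1e-12
        )
        bad = df.index[df["sd"] <= 0]
        if len(bad):
            raise ValueError(f"non-positive sd in rows {list(bad[:5])}")
        self.data = df.reset_index(drop=True)

    @property
    def variables(self) -> List[str]:
        return sorted(self.data["variable"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_h"].unique())

    def subset(self, variables: Sequence[str]) -> "TimeSeriesDataset":
        df = self.data[self.data["variable"].isin(variables)]
        return TimeSeriesDataset(df.reset_index(drop=True), self.default_cv)

    def __len__(self) -> int:
        return len(self.data)


def read_timeseries(
    path,
    known_variables: Optional[Iterable[str]] = KNOWN_VARIABLES,
) -> TimeSeriesDataset:
    """Read a tidy CSV; reject malformed rows and unknown variable ids."""
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in ("time_h", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()][:5]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            lines = [int(i) + 2 for i in bad]
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = vals
    if "sd" in df.columns:
        df["sd"] = pd.to_numeric(df["sd"], errors="coerce")
        bad = df.index[df["sd"].notna() & (df["sd"] <= 0)][:5]
        if len(bad):
            lines = [int(i) + 2 for i in bad]
            raise ValueError(f"{path}: non-positive sd at line(s) {lines}")
    if known_variables is not None:
        known = set(known_variables)
        unknown = sorted(set(df["variable"]) - known)
        if unknown:
            raise ValueError(
                f"{path}: unknown variable id(s) {unknown}; known ids: "
                f"{sorted(known)}"
            )
    return TimeSeriesDataset(df)


def write_timeseries(ds: TimeSeriesDataset | pd.DataFrame, path) -> None:
    """Write a dataset as RFC-4180 CSV with 12 significant digits."""
    df = ds.data if isinstance(ds, TimeSeriesDataset) else ds
    pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
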