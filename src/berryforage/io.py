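"""Readers and writers for the pipeline's plain-text formats.

Telemetry CSV dialect: header ``bear_id,timestamp,x,y,valid`` with ISO-8601
UTC timestamps, planar metre coordinates, and valid in {0, 1}; failed fixes
keep their row with empty x/y and valid=0.  Raster layers use ESRI ASCII
grids (see :mod:`berryforage.grid`).  Run configuration is YAML.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory import GpsFix, Track

__all__ = ["read_telemetry", "write_telemetry", "read_plots", "RunConfig"]


def write_telemetry(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for f in tr.fixes:
            rows.append(
                {
                    "bear_id": tr.bear_id,
                    "timestamp": f.t.isoformat(),
                    "x": f"{f.x:.3f}" if f.valid else "",
                    "y": f"{f.y:.3f}" if f.valid else "",
                    "valid": int(f.valid),
                }
            )
    pd.DataFrame(rows, columns=["bear_id", "timestamp", "x", "y", "valid"]).to_csv(
        path, index=False
    )


def read_telemetry(path) -> list[Track]:
    """Parse a telemetry CSV into per-bear time-sorted tracks.

    Invalid rows are preserved as invalid fixes.  Out-of-order rows are
    sorted with a warning; malformed timestamps or coordinates raise with
    the offending line number.
    """
    df = pd.read_csv(path, dtype={"bear_id": str})
    if df.empty:
        raise ValueError(f"{path}: no telemetry rows")
    required = {"bear_id", "timestamp", "x", "y", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    except (ValueError, TypeError) as err:
        for i, v in enumerate(pd.read_csv(path)["timestamp"]):
            try:
                pd.to_datetime(v)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: malformed timestamp on data line {i + 1}: {v!r}") from err
        raise
    tracks = []
    for bear, sub in df.groupby("bear_id", sort=True):
        if not sub["timestamp"].is_monotonic_increasing:
            warnings.warn(f"{path}: rows for bear {bear} out of order; sorting", stacklevel=2)
            sub = sub.sort_values("timestamp")
        fixes = []
        for _, row in sub.iterrows():
            valid = bool(int(row["valid"]))
            x = float(row["x"]) if valid else float("nan")
            y = float(row["y"]) if valid else float("nan")
            fixes.append(GpsFix(t=row["timestamp"], x=x, y=y, valid=valid))
        tracks.append(Track(bear_id=str(bear), fixes=fixes))
    return tracks


def read_plots(path) -> pd.DataFrame:
    """Read a plot table CSV written by the sampler / scenario generator."""
    df = pd.read_csv(path, dtype={"bear_id": str, "plot_id": str})
    if df.empty:
        raise ValueError(f"{path}: no plot rows")
    return df


@dataclass
class RunConfig:
    """Analysis settings: classifier thresholds, inference knobs, seeds."""

    d_min: float = 25.0
    d_max: float = 300.0
    min_fixes: int = 3
    long_run: int = 7
    buffer_radius: float = 200.0
    alpha: float = 0.05
    quadrature_nodes: int = 10
    selection_nodes: int = 5  # cheaper quadrature during model-selection scans
    mc_draws: int = 100_000
    seed: int = 0
    vif_cutoff: float = 3.0
    seasonal_family: str = "negbin"  # "truncnegbin" available via config

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.d_min <= 0 or self.d_max <= self.d_min:
            raise ValueError("need 0 < d_min < d_max")
        if self.min_fixes < 2 or self.long_run < self.min_fixes:
            raise ValueError("need min_fixes >= 2 and long_run >= min_fixes")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
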