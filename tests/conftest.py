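"""Shared fixtures: small tracks, grids and data frames built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from berryforage.grid import LandscapeGrid
from berryforage.trajectory import GpsFix, Track


def build_track(
    positions: list[tuple[float, float] | None],
    bear_id: str = "B01",
    start: str = "2014-08-07T00:00:00",
) -> Track:
    """Track from a list of (x, y) tuples; ``None`` marks a failed fix."""
    t0 = pd.Timestamp(start)
    fixes = []
    for i, p in enumerate(positions):
        t = t0 + pd.Timedelta(minutes=30 * i)
        if p is None:
            fixes.append(GpsFix(t=t, x=float("nan"), y=float("nan"), valid=False))
        else:
            fixes.append(GpsFix(t=t, x=float(p[0]), y=float(p[1]), valid=True))
    return Track(bear_id=bear_id, fixes=fixes)


def track_from_steps(steps: list[float], **kw) -> Track:
    """Straight-line eastward track with the given step distances."""
    xs = np.concatenate([[0.0], np.cumsum(steps)])
    return build_track([(x, 0.0) for x in xs], **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """4x5 grid, 10 m cells, all five layers present."""
    rs = np.random.default_rng(7)
    nr, nc = 4, 5
    return LandscapeGrid(
        x0=1000.0,
        y0=2000.0,
        cell_size=10.0,
        layers={
            "habitat": rs.integers(0, 4, (nr, nc)),
            "elevation": rs.uniform(200, 600, (nr, nc)),
            "ndvi": rs.uniform(0.0, 0.86, (nr, nc)),
            "slope": rs.uniform(0, 40, (nr, nc)),
            "aspect": rs.integers(0, 4, (nr, nc)),
        },
    )


@pytest.fixture
def used_available_frame(rng):
    """Small assembled-style analysis table with hurdle counts."""
    n = 400
    df = pd.DataFrame(
        {
            "plottype": rng.integers(0, 2, n),
            "habitat": rng.choice(
                ["bog", "clearcut", "mature_forest", "young_forest"], n
            ),
            "elevation": rng.uniform(200, 600, n),
            "ndvi": rng.uniform(0.1, 0.8, n),
            "slope": rng.uniform(0, 40, n),
            "aspect": rng.choice(["N", "E", "S", "W"], n),
            "ordinal_day": rng.integers(219, 248, n),
            "bear_id": rng.choice([f"B{i:02d}" for i in range(7)], n),
        }
    )
    eta = -0.5 + 0.9 * df["plottype"] + 0.5 * (df["habitat"] == "mature_forest")
    occ = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
    mu = np.exp(1.8 + 0.5 * df["plottype"])
    theta = 1.2
    p = theta / (theta + mu)
    from scipy import stats

    draws = stats.nbinom.ppf(rng.uniform(p**theta, 1.0, n), theta, p).astype(int)
    df["count_bilberry"] = np.where(occ, draws, 0)
    df["plot_type"] = np.where(df["plottype"] == 1, "foraging", "random")
    return df
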