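"""The berry-plot protocol: plot placement, covariate annotation, assembly.

Field crews locate a 1-m2 sample quadrat near each GPS-derived foraging
position by a deterministic pseudo-random offset: walk 0-9 m (the last digit
of the position's integer Y coordinate) in one of the four cardinal directions
(picked by the last digit of the integer X coordinate).  If the chosen quadrat
shows obvious signs of foraging (stripped twigs, fallen berries) it is
relocated to the mirror position on the opposite side of the GPS location, so
counts are not biased downward by the bear's own consumption.

Availability is characterised by quadrats at uniformly random locations in the
study area.  Random plots are randomly assigned a bear id so that both plot
types enter the same mixed model.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import ASPECT_CLASSES, HABITAT_CLASSES, LandscapeGrid

__all__ = [
    "CARDINAL_DIRECTIONS",
    "offset_plot_location",
    "relocate_if_signs",
    "draw_random_plots",
    "annotate_plot",
    "assemble_dataset",
    "MODEL_COVARIATES",
]

#: unit vectors (dx, dy) for the digit -> direction map, in N, E, S, W order.
CARDINAL_DIRECTIONS = {
    "N": (0.0, 1.0),
    "E": (1.0, 0.0),
    "S": (0.0, -1.0),
    "W": (-1.0, 0.0),
}

#: covariates every analysed plot row must carry (besides counts / TSS).
MODEL_COVARIATES = [
    "plot_type",
    "bear_id",
    "habitat",
    "elevation",
    "ndvi",
    "slope",
    "aspect",
    "ordinal_day",
]


def offset_plot_location(
    x: float,
    y: float,
    direction_order: Sequence[str] = ("N", "E", "S", "W"),
) -> tuple[float, float]:
    """Quadrat centre from a GPS position by the digit-offset rule.

    Offset distance (m) is the last digit of the integer part of Y; the
    direction is the last digit of the integer part of X, mapped mod 4 onto
    ``direction_order``.  The exact digit->direction bijection is a protocol
    convention (any fixed bijection is statistically equivalent), hence
    configurable.
    """
    dist = int(math.floor(y)) % 10
    digit_x = int(math.floor(x)) % 10
    dx, dy = CARDINAL_DIRECTIONS[direction_order[digit_x % 4]]
    return (x + dist * dx, y + dist * dy)


def relocate_if_signs(
    center: tuple[float, float], origin: tuple[float, float], signs: bool
) -> tuple[float, float]:
    """Mirror the quadrat through the GPS position when foraging signs found.

    Same distance, opposite direction; a no-op when ``signs`` is false or the
    offset was zero.
    """
    if not signs:
        return center
    return (2 * origin[0] - center[0], 2 * origin[1] - center[1])


def draw_random_plots(n: int, grid: LandscapeGrid, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniform random quadrat locations within the grid extent, (n, 2)."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    xmin, ymin, xmax, ymax = grid.extent
    xs = rng.uniform(xmin, xmax, size=n)
    ys = rng.uniform(ymin, ymax, size=n)
    return np.column_stack([xs, ys])


def annotate_plot(
    xy: tuple[float, float],
    grid: LandscapeGrid,
    plot_type: str,
    ordinal_day: int,
) -> dict:
    """Landscape covariates for one quadrat by nearest-cell lookup.

    Categorical layers use the same nearest-cell convention as the continuous
    ones; there is no interpolation.  Raises for points outside the extent.
    """
    row, col = grid.cell_index(*xy)
    rec = {
        "plot_type": plot_type,
        "x": xy[0],
        "y": xy[1],
        "ordinal_day": int(ordinal_day),
        "habitat": HABITAT_CLASSES[int(grid.layers["habitat"][row, col])],
        "elevation": float(grid.layers["elevation"][row, col]),
        "ndvi": float(grid.layers["ndvi"][row, col]),
    }
    if "slope" in grid.layers:
        rec["slope"] = float(grid.layers["slope"][row, col])
    if "aspect" in grid.layers:
        rec["aspect"] = ASPECT_CLASSES[int(grid.layers["aspect"][row, col])]
    return rec


def assemble_dataset(
    foraging: pd.DataFrame,
    random: pd.DataFrame,
    rng: np.random.Generator,
    bear_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Single used-available analysis table with the standard exclusions.

    Drops rows in habitat class ``other`` and rows with any missing model
    covariate; assigns each random plot a bear id uniformly at random (random
    plots carry no bear of their own but the mixed models need the grouping),
    and adds the 0/1 ``plottype`` indicator (random = 0, bear foraging = 1).
    """
    if len(foraging) == 0 or len(random) == 0:
        raise ValueError("both foraging and random plot tables must be non-empty")
    foraging = foraging.copy()
    random = random.copy()
    foraging["plot_type"] = "foraging"
    random["plot_type"] = "random"
    if bear_ids is None:
        bear_ids = sorted(foraging["bear_id"].dropna().unique())
    if len(bear_ids) == 0:
        raise ValueError("no bear ids available for random-plot assignment")
    if "bear_id" not in random.columns:
        random["bear_id"] = None
    missing = random["bear_id"].isna()
    if missing.any():
        random.loc[missing, "bear_id"] = rng.choice(
            np.asarray(bear_ids, dtype=object), size=int(missing.sum())
        )
    out = pd.concat([foraging, random], ignore_index=True)
    out = out[out["habitat"] != "other"]
    covars = [c for c in MODEL_COVARIATES if c in out.columns]
    out = out.dropna(subset=covars)
    out = out.reset_index(drop=True)
    out["plottype"] = (out["plot_type"] == "foraging").astype(int)
    return out
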