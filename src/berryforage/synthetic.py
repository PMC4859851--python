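"""Synthetic landscapes, berry fields, and bear movement with known truth.

No field data ship with this package, so every pipeline stage is exercised on
simulated inputs whose generating parameters are recorded and returned.  The
generator emulates the study conditions: a boreal production-forest landscape
(clearcut / bog / young / mature mosaic, elevation 200-600 m, NDVI up to
0.86), three berry species with hurdle-structured counts (bilberry declining
and lingonberry increasing over the ~32-day late-summer season, crowberry rare
and never modelled), sugar content with a plot-type effect for lingonberry
only, and seven GPS-collared bears moving on a 30-min fix schedule with ~92 %
fix success whose foraging steps are attracted to berry-rich cells.

Two generation routes exist:

* :func:`make_scenario` - the full end-to-end route: landscape, movement,
  trajectory classification, the plot protocol, counts and sugar.  Selection
  for berries *emerges* from the movement attraction; there is no explicit
  plot-type coefficient in the truth.
* :func:`sample_used_available` - the direct route for parameter-recovery
  experiments: covariates drawn independently, counts drawn from an explicit
  hurdle linear predictor that includes a plot-type coefficient.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from . import plots as plots_mod
from . import trajectory as traj
from .grid import ASPECT_CLASSES, HABITAT_CLASSES, LandscapeGrid, write_landscape
from .trajectory import GpsFix, Track

__all__ = [
    "LandscapeConfig",
    "BerryFieldParams",
    "SugarParams",
    "MovementParams",
    "ScenarioConfig",
    "Scenario",
    "gen_landscape",
    "sample_plot_counts",
    "rtruncnb",
    "gen_sugar",
    "simulate_bear",
    "berry_expectation_surface",
    "make_scenario",
    "write_scenario",
    "sample_used_available",
    "DEFAULT_BERRY_PARAMS",
    "DEFAULT_SUGAR_PARAMS",
]

# covariate centring used by every synthetic linear predictor, so that
# intercepts are interpretable as mid-season values at mid elevation
ELEV_CENTER = 400.0
NDVI_CENTER = 0.45
DAY_CENTER = 233  # ~Aug 21, middle of the Aug 7 - Sep 4 window


# --------------------------------------------------------------------------
# landscape
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Grid geometry and habitat composition of the synthetic study area."""

    n_rows: int = 160
    n_cols: int = 160
    cell_size: float = 25.0
    x0: float = 500_000.0
    y0: float = 6_800_000.0
    # approximate areal shares; production-forest mosaic with ~8 % recent
    # clearcuts and a large share of young stands
    habitat_shares: dict = field(
        default_factory=lambda: {
            "clearcut": 0.08,
            "bog": 0.10,
            "young_forest": 0.42,
            "mature_forest": 0.40,
        }
    )
    n_patches: int = 60
    elevation_range: tuple[float, float] = (200.0, 600.0)
    ndvi_max: float = 0.86


def _grow_habitat(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Patchy habitat mosaic by quota-limited multi-source region growth."""
    shares = cfg.habitat_shares
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError(f"habitat shares must sum to 1, got {sum(shares.values())}")
    nr, nc = cfg.n_rows, cfg.n_cols
    total = nr * nc
    classes = list(shares)
    codes = {c: HABITAT_CLASSES.index(c) for c in classes}
    quota = {c: int(round(shares[c] * total)) for c in classes}
    quota[classes[-1]] += total - sum(quota.values())  # rounding slack

    out = np.full((nr, nc), -1, dtype=int)
    heap: list[tuple[float, int, int, str]] = []
    for c in classes:
        n_seed = max(1, int(round(cfg.n_patches * shares[c])))
        for _ in range(n_seed):
            r, col = rng.integers(nr), rng.integers(nc)
            heapq.heappush(heap, (rng.exponential(), int(r), int(col), c))
    assigned = 0
    while heap and assigned < total:
        prio, r, col, c = heapq.heappop(heap)
        if out[r, col] != -1 or quota[c] <= 0:
            continue
        out[r, col] = codes[c]
        quota[c] -= 1
        assigned += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, col + dc
            if 0 <= rr < nr and 0 <= cc < nc and out[rr, cc] == -1:
                heapq.heappush(heap, (prio + rng.exponential(), rr, cc, c))
    if assigned < total:  # stranded cells: hand to classes with quota left
        open_classes = [c for c in classes if quota[c] > 0]
        for r, col in zip(*np.where(out == -1)):
            c = open_classes[rng.integers(len(open_classes))]
            out[r, col] = codes[c]
    return out


def gen_landscape(cfg: LandscapeConfig | None = None, rng: np.random.Generator | None = None) -> LandscapeGrid:
    """Generate all co-registered layers of a synthetic landscape.

    Habitat is a patchy categorical mosaic with approximate target shares;
    elevation is a smooth field spanning the configured range; slope and
    aspect derive from the elevation surface; NDVI is positively associated
    with the local density of young forest (dense regrowth) plus noise,
    clipped to [-1, ndvi_max].
    """
    cfg = cfg or LandscapeConfig()
    rng = rng or np.random.default_rng()
    habitat = _grow_habitat(cfg, rng)

    noise = rng.normal(size=(cfg.n_rows, cfg.n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=max(cfg.n_rows, cfg.n_cols) / 12)
    lo, hi = cfg.elevation_range
    rngspan = smooth.max() - smooth.min()
    elevation = lo + (smooth - smooth.min()) / rngspan * (hi - lo)

    dzdr, dzdc = np.gradient(elevation, cfg.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdr, dzdc)))
    # aspect: compass direction of steepest descent, quantised to N/E/S/W.
    # row axis points south, so descent vector is (east, north) = (-dzdc, +dzdr)
    angle = np.degrees(np.arctan2(-dzdc, dzdr))  # 0 = N, 90 = E
    aspect = np.round(((angle % 360.0) / 90.0)).astype(int) % 4

    young = (habitat == HABITAT_CLASSES.index("young_forest")).astype(float)
    young_density = ndimage.uniform_filter(young, size=9)
    ndvi = 0.35 + 0.45 * young_density + 0.05 * rng.normal(size=habitat.shape)
    ndvi = np.clip(ndvi, -1.0, cfg.ndvi_max)

    return LandscapeGrid(
        x0=cfg.x0,
        y0=cfg.y0,
        cell_size=cfg.cell_size,
        layers={
            "habitat": habitat,
            "elevation": elevation,
            "ndvi": ndvi,
            "slope": slope,
            "aspect": aspect,
        },
    )


# --------------------------------------------------------------------------
# berry field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BerryFieldParams:
    """Hurdle-model truth for one berry species.

    Linear predictors use centred covariates: elevation - 400 m,
    ndvi - 0.45, ordinal day - 233.  ``habitat_occ`` / ``habitat_abn`` are
    log-odds / log-mean offsets relative to bog.  ``plottype_occ/abn`` only
    act in the direct used-available generator; in the movement scenario
    selection emerges from berry attraction instead.
    """

    name: str
    intercept_occ: float
    habitat_occ: dict
    elevation_occ: float
    ndvi_occ: float
    day_occ: float
    intercept_abn: float
    habitat_abn: dict
    elevation_abn: float
    ndvi_abn: float
    day_abn: float
    theta: float
    plottype_occ: float = 0.0
    plottype_abn: float = 0.0
    re_sd_occ: float = math.sqrt(0.2)
    re_sd_abn: float = math.sqrt(0.2)
    # latent spatial patchiness: berry variation real bears can sense but the
    # model covariates do not capture; selection on it is what produces a
    # plot-type effect in the used-available fits
    patch_sd_occ: float = 0.0
    patch_sd_abn: float = 0.0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def eta_occ(self, habitat, elevation, ndvi, day, plottype=0.0):
        hab = np.vectorize(lambda h: self.habitat_occ.get(h, 0.0))(np.asarray(habitat, dtype=object))
        return (
            self.intercept_occ
            + hab.astype(float)
            + self.elevation_occ * (np.asarray(elevation) - ELEV_CENTER)
            + self.ndvi_occ * (np.asarray(ndvi) - NDVI_CENTER)
            + self.day_occ * (np.asarray(day) - DAY_CENTER)
            + self.plottype_occ * np.asarray(plottype)
        )

    def eta_abn(self, habitat, elevation, ndvi, day, plottype=0.0):
        hab = np.vectorize(lambda h: self.habitat_abn.get(h, 0.0))(np.asarray(habitat, dtype=object))
        return (
            self.intercept_abn
            + hab.astype(float)
            + self.elevation_abn * (np.asarray(elevation) - ELEV_CENTER)
            + self.ndvi_abn * (np.asarray(ndvi) - NDVI_CENTER)
            + self.day_abn * (np.asarray(day) - DAY_CENTER)
            + self.plottype_abn * np.asarray(plottype)
        )


# Defaults echo the magnitudes and, importantly, the sign structure of the
# field estimates: bilberry occurrence/abundance decline with ordinal day,
# lingonberry rises; mature forest is the best bilberry habitat, clearcuts
# the best lingonberry habitat; NDVI suppresses lingonberries; crowberry is
# rare, patchy and strongly overdispersed.
DEFAULT_BERRY_PARAMS: dict[str, BerryFieldParams] = {
    "bilberry": BerryFieldParams(
        name="bilberry",
        intercept_occ=-1.3,
        habitat_occ={"clearcut": 1.5, "mature_forest": 2.6, "young_forest": 1.3},
        elevation_occ=0.003,
        ndvi_occ=0.0,
        day_occ=-0.022,
        intercept_abn=2.3,
        habitat_abn={"clearcut": 0.64, "mature_forest": 0.57, "young_forest": 0.57},
        elevation_abn=0.004,
        ndvi_abn=0.0,
        day_abn=-0.012,
        theta=1.5,
        patch_sd_occ=1.1,
        patch_sd_abn=0.8,
    ),
    "lingonberry": BerryFieldParams(
        name="lingonberry",
        intercept_occ=-1.6,
        habitat_occ={"clearcut": 2.7, "mature_forest": 1.47, "young_forest": 1.64},
        elevation_occ=0.0,
        ndvi_occ=0.0,
        day_occ=0.07,
        intercept_abn=2.4,
        habitat_abn={"clearcut": 0.99, "mature_forest": 0.25, "young_forest": 0.64},
        elevation_abn=0.0,
        ndvi_abn=-2.3,
        day_abn=0.028,
        theta=0.8,
        patch_sd_occ=1.1,
        patch_sd_abn=0.8,
    ),
    "crowberry": BerryFieldParams(
        name="crowberry",
        intercept_occ=-2.2,
        habitat_occ={"clearcut": 0.3, "mature_forest": 0.0, "young_forest": -0.3},
        elevation_occ=0.0,
        ndvi_occ=0.0,
        day_occ=0.0,
        intercept_abn=1.8,
        habitat_abn={},
        elevation_abn=0.0,
        ndvi_abn=0.0,
        day_abn=0.0,
        theta=0.3,
        patch_sd_occ=1.5,
        patch_sd_abn=1.0,
    ),
}


def rtruncnb(mu, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated NB2 draws by inverse-cdf (conditioning on k >= 1)."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    p0 = p**theta
    u = rng.uniform(p0, 1.0, size=mu.shape)
    return stats.nbinom.ppf(u, theta, p).astype(int)


def sample_plot_counts(
    covariates: pd.DataFrame,
    params: BerryFieldParams,
    rng: np.random.Generator,
    bear_u_occ: pd.Series | None = None,
    bear_u_abn: pd.Series | None = None,
    patch: np.ndarray | None = None,
) -> np.ndarray:
    """Hurdle draw of per-plot counts for one species.

    Occurrence is Bernoulli on the inverse-logit of the occurrence predictor;
    conditional on occurrence the count is zero-truncated NB2.  Species are
    drawn independently of each other (cross-species counts were essentially
    uncorrelated in the field).  Optional per-bear random intercepts are
    added to either predictor via ``bear_u_*`` (indexed by bear id, looked up
    through covariates['bear_id']; missing ids get 0).
    """
    c = covariates
    plottype = c["plottype"].to_numpy() if "plottype" in c else 0.0
    eo = params.eta_occ(c["habitat"], c["elevation"], c["ndvi"], c["ordinal_day"], plottype)
    ea = params.eta_abn(c["habitat"], c["elevation"], c["ndvi"], c["ordinal_day"], plottype)
    if bear_u_occ is not None:
        eo = eo + c["bear_id"].map(bear_u_occ).fillna(0.0).to_numpy()
    if bear_u_abn is not None:
        ea = ea + c["bear_id"].map(bear_u_abn).fillna(0.0).to_numpy()
    if patch is not None:
        eo = eo + params.patch_sd_occ * patch
        ea = ea + params.patch_sd_abn * patch
    occ = rng.uniform(size=len(c)) < special.expit(eo)
    counts = np.zeros(len(c), dtype=int)
    if occ.any():
        counts[occ] = rtruncnb(np.exp(np.clip(ea[occ], None, 8.0)), params.theta, rng)
    return counts


# --------------------------------------------------------------------------
# sugar
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SugarParams:
    """Gaussian TSS (%Brix) model for one species, centred covariates."""

    intercept: float
    plottype: float
    ndvi: float
    day: float
    resid_sd: float
    re_sd: float = 0.2


DEFAULT_SUGAR_PARAMS: dict[str, SugarParams] = {
    # intercepts offset by half the plot-type effect so the overall species
    # means sit at the observed 8.48 / 12.04 %Brix for an even used/available mix
    "bilberry": SugarParams(intercept=8.48, plottype=0.0, ndvi=-2.0, day=-0.049, resid_sd=1.30),
    "lingonberry": SugarParams(intercept=12.04 - 0.5 * 0.579, plottype=0.579, ndvi=-2.0, day=0.028, resid_sd=1.30),
    "crowberry": SugarParams(intercept=5.57, plottype=0.0, ndvi=0.0, day=0.0, resid_sd=0.9),
}


def gen_sugar(
    covariates: pd.DataFrame,
    params: SugarParams,
    rng: np.random.Generator,
    bear_u: pd.Series | None = None,
) -> np.ndarray:
    """Gaussian TSS draws around the linear predictor, %Brix."""
    c = covariates
    plottype = c["plottype"].to_numpy() if "plottype" in c else 0.0
    eta = (
        params.intercept
        + params.plottype * np.asarray(plottype, dtype=float)
        + params.ndvi * (c["ndvi"].to_numpy() - NDVI_CENTER)
        + params.day * (c["ordinal_day"].to_numpy() - DAY_CENTER)
    )
    if bear_u is not None:
        eta = eta + c["bear_id"].map(bear_u).fillna(0.0).to_numpy()
    return eta + params.resid_sd * rng.normal(size=len(c))


# --------------------------------------------------------------------------
# movement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementParams:
    """3-state (rest / forage / travel) switching walk on the 30-min lattice.

    Step-length regimes bracket the classifier band: resting steps are below
    25 m, foraging steps inside 25-300 m, travelling steps above 300 m.
    ``attraction`` (w >= 0) steers foraging steps toward cells of high
    expected bilberry count; w = 0 is unselective movement.
    """

    transition: tuple = (
        (0.88, 0.08, 0.04),  # from rest
        (0.14, 0.78, 0.08),  # from forage
        (0.25, 0.08, 0.67),  # from travel
    )
    rest_step: tuple[float, float] = (0.0, 18.0)
    forage_step: tuple[float, float] = (30.0, 260.0)
    travel_step: tuple[float, float] = (320.0, 900.0)
    attraction: float = 2.0
    fix_fail_prob: float = 0.08
    n_candidate_bearings: int = 12
    # range residency: bears drift back once they stray beyond home_range_radius
    # of their individual range centre, keeping the seven bears in distinct
    # (possibly overlapping) neighbourhoods as collared bears are
    home_range_radius: float = 900.0
    homing_strength: float = 3.0

    def __post_init__(self):
        for row in self.transition:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("transition matrix rows must sum to 1")


def gen_patch_field(
    grid: LandscapeGrid, rng: np.random.Generator, sigma_cells: float = 0.8
) -> np.ndarray:
    """Standardized latent patchiness field (mean 0, SD 1).

    Berry micro-patches are metre-scale, below the raster cell, so the
    default grain is sub-cell: distinct cells carry essentially independent
    patch values while a bear still perceives cell-level variation.
    """
    f = ndimage.gaussian_filter(rng.normal(size=(grid.n_rows, grid.n_cols)), sigma_cells)
    return (f - f.mean()) / max(f.std(), 1e-12)


def berry_expectation_surface(
    grid: LandscapeGrid,
    params: BerryFieldParams,
    day: int = DAY_CENTER,
    patch: np.ndarray | None = None,
) -> np.ndarray:
    """Expected berry count per cell: P(occ) * E[count | occ], at day ``day``."""
    hab = np.asarray(HABITAT_CLASSES, dtype=object)[grid.layers["habitat"]]
    eo = params.eta_occ(hab, grid.layers["elevation"], grid.layers["ndvi"], day)
    ea = params.eta_abn(hab, grid.layers["elevation"], grid.layers["ndvi"], day)
    if patch is not None:
        eo = eo + params.patch_sd_occ * patch
        ea = ea + params.patch_sd_abn * patch
    mu = np.exp(np.clip(ea, None, 8.0))
    p0 = (params.theta / (params.theta + mu)) ** params.theta
    return special.expit(eo) * mu / (1.0 - p0)


def simulate_bear(
    grid: LandscapeGrid,
    berry_surface: np.ndarray,
    params: MovementParams,
    bear_id: str,
    start_time: pd.Timestamp,
    n_days: int,
    rng: np.random.Generator,
    center: tuple[float, float] | None = None,
) -> Track:
    """One bear's 30-min fix stream over ``n_days`` (48 fixes/day).

    States follow the Markov chain; foraging step directions are chosen among
    candidate bearings with probability proportional to exp(w * standardized
    expected bilberry count at the landing cell).  Fix failures are applied
    i.i.d. afterward, so the underlying walk is unaffected by collar
    performance.  ``center`` anchors the bear's home range: beyond
    ``home_range_radius`` non-foraging steps head back toward it and foraging
    candidates are penalised for straying further.
    """
    n = n_days * 48
    T = np.asarray(params.transition)
    score = (berry_surface - berry_surface.mean()) / max(berry_surface.std(), 1e-9)
    xmin, ymin, xmax, ymax = grid.extent
    margin = grid.cell_size
    # states for the whole sequence
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(3)
    for t in range(1, n):
        states[t] = rng.choice(3, p=T[states[t - 1]])
    lows = np.array([params.rest_step[0], params.forage_step[0], params.travel_step[0]])
    highs = np.array([params.rest_step[1], params.forage_step[1], params.travel_step[1]])
    lengths = rng.uniform(lows[states], highs[states])

    if center is None:
        center = (rng.uniform(xmin + margin, xmax - margin),
                  rng.uniform(ymin + margin, ymax - margin))
    cx0, cy0 = center
    R = params.home_range_radius
    x = float(np.clip(cx0 + rng.normal(0, R / 3), xmin + margin, xmax - margin))
    y = float(np.clip(cy0 + rng.normal(0, R / 3), ymin + margin, ymax - margin))
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = x, y
    nb = params.n_candidate_bearings
    w = params.attraction
    for t in range(1, n):
        L = lengths[t]
        if states[t] == 1 and w > 0:
            bearings = rng.uniform(0.0, 2.0 * np.pi, nb)
            cx = np.clip(x + L * np.cos(bearings), xmin + margin, xmax - margin)
            cy = np.clip(y + L * np.sin(bearings), ymin + margin, ymax - margin)
            cols = np.ceil((cx - grid.x0) / grid.cell_size).astype(int) - 1
            rows = np.ceil((grid.y0 + grid.n_rows * grid.cell_size - cy) / grid.cell_size).astype(int) - 1
            s = score[np.clip(rows, 0, grid.n_rows - 1), np.clip(cols, 0, grid.n_cols - 1)]
            overshoot = np.maximum(np.hypot(cx - cx0, cy - cy0) - R, 0.0) / R
            logit = w * s - params.homing_strength * overshoot
            pr = np.exp(logit - logit.max())
            k = rng.choice(nb, p=pr / pr.sum())
            x, y = float(cx[k]), float(cy[k])
        else:
            d_home = np.hypot(x - cx0, y - cy0)
            if d_home > R:
                b = np.arctan2(cy0 - y, cx0 - x) + rng.normal(0.0, 0.8)
            else:
                b = rng.uniform(0.0, 2.0 * np.pi)
            x = float(np.clip(x + L * np.cos(b), xmin + margin, xmax - margin))
            y = float(np.clip(y + L * np.sin(b), ymin + margin, ymax - margin))
        xs[t], ys[t] = x, y

    valid = rng.uniform(size=n) >= params.fix_fail_prob
    times = start_time + pd.to_timedelta(np.arange(n) * 30, unit="m")
    fixes = [
        GpsFix(t=times[i], x=xs[i] if valid[i] else float("nan"),
               y=ys[i] if valid[i] else float("nan"), valid=bool(valid[i]))
        for i in range(n)
    ]
    return Track(bear_id=bear_id, fixes=fixes)


# --------------------------------------------------------------------------
# the scenario bundle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to regenerate one synthetic study, minus the seed."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    berry: dict = field(default_factory=lambda: dict(DEFAULT_BERRY_PARAMS))
    sugar: dict = field(default_factory=lambda: dict(DEFAULT_SUGAR_PARAMS))
    movement: MovementParams = field(default_factory=MovementParams)
    n_bears: int = 7  # 4 males, 3 females
    start_date: str = "2014-08-07"
    n_days: int = 28
    n_random_plots: int = 375
    n_exclusion_sites: int = 2
    sign_prob: float = 0.7  # chance a used quadrat shows foraging signs
    d_min: float = 25.0
    d_max: float = 300.0
    min_fixes: int = 3
    buffer_radius: float = 200.0


@dataclass
class Scenario:
    """A generated study: inputs plus the ground truth that made them."""

    config: ScenarioConfig
    seed: int
    grid: LandscapeGrid
    tracks: list[Track]
    exclusion_sites: np.ndarray
    foraging_plots: pd.DataFrame
    random_plots: pd.DataFrame
    patch_fields: dict
    ground_truth: dict


def _bear_ids(n: int) -> list[str]:
    # four males, three females by default, then alternating
    sexes = ["M", "M", "M", "M", "F", "F", "F"]
    return [f"{'MF'[i % 2] if i >= len(sexes) else sexes[i]}{i + 1:02d}" for i in range(n)]


def _sample_bear_effects(cfg: ScenarioConfig, ids, rng) -> dict:
    out = {}
    for sp, par in cfg.berry.items():
        out[sp] = {
            "occ": pd.Series(rng.normal(0.0, par.re_sd_occ, len(ids)), index=ids),
            "abn": pd.Series(rng.normal(0.0, par.re_sd_abn, len(ids)), index=ids),
        }
    out["sugar"] = {
        sp: pd.Series(rng.normal(0.0, p.re_sd, len(ids)), index=ids)
        for sp, p in cfg.sugar.items()
    }
    return out


def _fill_plot_measurements(
    df: pd.DataFrame, cfg: ScenarioConfig, effects, rng, grid, patches
) -> pd.DataFrame:
    """Draw counts and sugar for annotated plot rows (returns a copy)."""
    df = df.copy()
    cells = [grid.cell_index(x, y) for x, y in zip(df["x"], df["y"])]
    rows = np.array([r for r, _ in cells], dtype=int)
    cols = np.array([c for _, c in cells], dtype=int)
    for sp, par in cfg.berry.items():
        u_occ = effects[sp]["occ"] if "bear_id" in df else None
        u_abn = effects[sp]["abn"] if "bear_id" in df else None
        patch = patches[sp][rows, cols]
        df[f"count_{sp}"] = sample_plot_counts(df, par, rng, u_occ, u_abn, patch)
    for sp in ("bilberry", "lingonberry"):
        tss = gen_sugar(df, cfg.sugar[sp], rng, effects["sugar"][sp] if "bear_id" in df else None)
        df[f"tss_{sp}"] = np.where(df[f"count_{sp}"] >= 1, tss, np.nan)
    return df


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Generate a full synthetic study, reproducible from (config, seed).

    The pipeline inputs produced are exactly those the analyses consume:
    per-bear GPS tracks, landscape layers, a used (foraging) plot table built
    by classifying the simulated trajectories and applying the plot protocol,
    an available (random) plot table, and a ground-truth record of every
    generating coefficient.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    grid = gen_landscape(cfg.landscape, rng)
    patches = {sp: gen_patch_field(grid, rng) for sp in cfg.berry}
    surface = berry_expectation_surface(
        grid, cfg.berry["bilberry"], patch=patches["bilberry"]
    )

    ids = _bear_ids(cfg.n_bears)
    effects = _sample_bear_effects(cfg, ids, rng)
    start = pd.Timestamp(cfg.start_date)
    xmin, ymin, xmax, ymax = grid.extent
    margin = 0.12 * (xmax - xmin)
    centers = np.column_stack([
        rng.uniform(xmin + margin, xmax - margin, len(ids)),
        rng.uniform(ymin + margin, ymax - margin, len(ids)),
    ])
    tracks = [
        simulate_bear(grid, surface, cfg.movement, b, start, cfg.n_days, rng,
                      center=tuple(centers[i]))
        for i, b in enumerate(ids)
    ]
    sites = np.column_stack(
        [rng.uniform(xmin, xmax, cfg.n_exclusion_sites),
         rng.uniform(ymin, ymax, cfg.n_exclusion_sites)]
    ) if cfg.n_exclusion_sites else np.empty((0, 2))

    forage_rows = []
    for track in tracks:
        segments = traj.find_foraging_segments(track, cfg.d_min, cfg.d_max, cfg.min_fixes)
        segments = traj.exclude_near_sites(segments, track, sites, cfg.buffer_radius)
        for seg in segments:
            for pos in traj.choose_sample_positions(seg, track):
                center = plots_mod.offset_plot_location(pos.x, pos.y)
                signs = bool(rng.uniform() < cfg.sign_prob)
                center = plots_mod.relocate_if_signs(center, (pos.x, pos.y), signs)
                cx = min(max(center[0], xmin), xmax)
                cy = min(max(center[1], ymin), ymax)
                rec = plots_mod.annotate_plot((cx, cy), grid, "foraging", pos.ordinal_day)
                rec["bear_id"] = pos.bear_id
                rec["foraging_signs"] = signs
                rec["slot"] = pos.slot
                forage_rows.append(rec)
    foraging = pd.DataFrame(forage_rows)
    foraging.insert(0, "plot_id", [f"F{i:04d}" for i in range(len(foraging))])
    foraging["plottype"] = 1

    xy = plots_mod.draw_random_plots(cfg.n_random_plots, grid, rng)
    days = rng.integers(
        start.dayofyear, start.dayofyear + cfg.n_days, size=cfg.n_random_plots
    )
    random_plots = pd.DataFrame(
        [plots_mod.annotate_plot(tuple(p), grid, "random", d) for p, d in zip(xy, days)]
    )
    random_plots.insert(0, "plot_id", [f"R{i:04d}" for i in range(len(random_plots))])
    random_plots["foraging_signs"] = False
    random_plots["plottype"] = 0
    # random plots are assigned a bear up front so their measurements carry
    # that bear's intercept too: the grouping structure the mixed models
    # assume holds for every row, not only the used plots
    random_plots["bear_id"] = rng.choice(np.asarray(ids, dtype=object), size=len(random_plots))

    foraging = _fill_plot_measurements(foraging, cfg, effects, rng, grid, patches)
    random_plots = _fill_plot_measurements(random_plots, cfg, effects, rng, grid, patches)

    truth = {
        "seed": seed,
        "berry": {sp: asdict(p) for sp, p in cfg.berry.items()},
        "sugar": {sp: asdict(p) for sp, p in cfg.sugar.items()},
        "movement": asdict(cfg.movement),
        "bear_effects": {
            sp: {part: dict(series.round(6)) for part, series in eff.items()}
            for sp, eff in effects.items()
            if sp != "sugar"
        },
        "centering": {"elevation": ELEV_CENTER, "ndvi": NDVI_CENTER, "ordinal_day": DAY_CENTER},
    }
    return Scenario(
        config=cfg,
        seed=seed,
        grid=grid,
        tracks=tracks,
        exclusion_sites=sites,
        foraging_plots=foraging,
        random_plots=random_plots,
        patch_fields=patches,
        ground_truth=truth,
    )


def write_scenario(scn: Scenario, outdir: str | Path) -> None:
    """Write a scenario as pipeline input files (CSV / ASCII grids / JSON)."""
    from .io import write_telemetry

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_telemetry(scn.tracks, outdir / "telemetry.csv")
    write_landscape(scn.grid, outdir / "grid")
    scn.foraging_plots.to_csv(outdir / "foraging_plots.csv", index=False)
    scn.random_plots.to_csv(outdir / "random_plots.csv", index=False)
    pd.DataFrame(scn.exclusion_sites, columns=["x", "y"]).to_csv(
        outdir / "exclusion_sites.csv", index=False
    )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(scn.ground_truth, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# direct used-available generator (for parameter-recovery experiments)
# --------------------------------------------------------------------------

def sample_used_available(
    params: BerryFieldParams,
    n_foraging: int = 350,
    n_random: int = 375,
    n_bears: int = 7,
    rng: np.random.Generator | None = None,
    season: tuple[int, int] = (219, 247),
) -> pd.DataFrame:
    """Used-available plot table drawn directly from known hurdle coefficients.

    Covariates are drawn independently (habitat from the landscape shares,
    elevation uniform on 200-600 m, NDVI normal around 0.45, ordinal day
    uniform over the season); counts come from the hurdle predictor of
    ``params`` including its explicit plot-type coefficients and per-bear
    random intercepts.  Centred covariate columns (``elevation_c`` etc.) are
    included so fits recover the generating coefficients directly.
    """
    rng = rng or np.random.default_rng()
    n = n_foraging + n_random
    ids = _bear_ids(n_bears)
    habs = ["bog", "clearcut", "mature_forest", "young_forest"]
    df = pd.DataFrame(
        {
            "plottype": np.r_[np.ones(n_foraging, dtype=int), np.zeros(n_random, dtype=int)],
            "habitat": rng.choice(habs, n, p=[0.10, 0.08, 0.40, 0.42]),
            "elevation": rng.uniform(200.0, 600.0, n),
            "ndvi": np.clip(rng.normal(0.45, 0.12, n), -1.0, 0.86),
            "ordinal_day": rng.integers(season[0], season[1] + 1, n),
            "bear_id": rng.choice(ids, n),
        }
    )
    df["plot_type"] = np.where(df["plottype"] == 1, "foraging", "random")
    u_occ = pd.Series(rng.normal(0.0, params.re_sd_occ, n_bears), index=ids)
    u_abn = pd.Series(rng.normal(0.0, params.re_sd_abn, n_bears), index=ids)
    df[f"count_{params.name}"] = sample_plot_counts(df, params, rng, u_occ, u_abn)
    df["elevation_c"] = df["elevation"] - ELEV_CENTER
    df["ndvi_c"] = df["ndvi"] - NDVI_CENTER
    df["day_c"] = df["ordinal_day"] - DAY_CENTER
    return df
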