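"""Classification of berry-foraging behavior from 30-min GPS fix streams.

Brown bears foraging on berries move slowly but continuously, so a run of
consecutive half-hour GPS fixes whose successive displacements all fall in a
moderate band (25-300 m by default) is taken as a berry-foraging bout.  Failed
fixes poison the step before and after them: those distances are undefined and
any candidate run is broken there rather than bridged.

The module turns raw fix streams (:class:`Track`) into maximal
:class:`ForagingSegment` runs, picks the field-sampling positions within each
segment, and applies the exclusion buffer around attractant sites such as
slaughter dumps and oat fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GpsFix",
    "Track",
    "ForagingSegment",
    "SamplePosition",
    "compute_steps",
    "find_foraging_segments",
    "choose_sample_positions",
    "exclude_near_sites",
    "fix_success_rate",
]

SCHEDULE_MINUTES = 30


@dataclass(frozen=True)
class GpsFix:
    """One attempted GPS position.

    ``valid=False`` marks a scheduled fix the collar failed to acquire; its
    coordinates are meaningless (conventionally NaN).
    """

    t: pd.Timestamp
    x: float
    y: float
    valid: bool = True


@dataclass
class Track:
    """Time-ordered 30-min fix series for one bear.

    Gaps in the schedule must be represented as invalid fixes; timestamps are
    strictly increasing on the half-hour lattice.
    """

    bear_id: str
    fixes: list[GpsFix]
    schedule_minutes: int = SCHEDULE_MINUTES

    def __post_init__(self) -> None:
        times = [f.t for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.bear_id}: timestamps must be strictly increasing")
        for f in self.fixes:
            if f.valid and not (np.isfinite(f.x) and np.isfinite(f.y)):
                raise ValueError(f"track {self.bear_id}: valid fix with non-finite coordinates at {f.t}")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array, NaN for invalid fixes."""
        out = np.full((len(self.fixes), 2), np.nan)
        for i, f in enumerate(self.fixes):
            if f.valid:
                out[i] = (f.x, f.y)
        return out

    @property
    def valid(self) -> np.ndarray:
        return np.array([f.valid for f in self.fixes], dtype=bool)


@dataclass(frozen=True)
class ForagingSegment:
    """Maximal run of fixes classified as berry foraging (inclusive indices)."""

    bear_id: str
    start_index: int
    end_index: int

    @property
    def n_fixes(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class SamplePosition:
    """Field-sampling position chosen within a foraging segment."""

    bear_id: str
    x: float
    y: float
    ordinal_day: int
    segment: ForagingSegment
    slot: Literal["second", "second_to_last"]


def compute_steps(track: Track) -> np.ndarray:
    """Per-interval Euclidean step distances; NaN where an endpoint fix failed.

    Returns an array of length ``len(track) - 1`` (empty for tracks with fewer
    than two fixes).  A failed fix makes both the preceding and the following
    interval distance undefined.
    """
    n = len(track)
    if n < 2:
        return np.empty(0)
    xy = track.xy
    d = np.hypot(*(xy[1:] - xy[:-1]).T)
    valid = track.valid
    d[~(valid[:-1] & valid[1:])] = np.nan
    return d


def _window_ok(
    steps: np.ndarray, i: int, j: int, d_min: float, d_max: float, rule: str
) -> bool:
    w = steps[i:j]
    if np.isnan(w).any():
        return False
    if rule == "per_step":
        return bool(((w >= d_min) & (w <= d_max)).all())
    if rule == "path":
        s = float(w.sum())
        return d_min <= s <= d_max
    raise ValueError(f"unknown rule {rule!r}")


def find_foraging_segments(
    track: Track,
    d_min: float = 25.0,
    d_max: float = 300.0,
    min_fixes: int = 3,
    rule: Literal["per_step", "path"] = "per_step",
) -> list[ForagingSegment]:
    """All maximal runs of >= ``min_fixes`` consecutive fixes moving in-band.

    Under the default ``per_step`` rule every 30-min step in the run must lie
    in ``[d_min, d_max]`` metres; a missing step (failed fix on either side)
    terminates the run.  The alternative ``path`` rule instead constrains the
    summed path length of the window, in which case maximality means "not
    contained in a longer qualifying window" and windows may overlap.
    """
    if min_fixes < 2:
        raise ValueError("min_fixes must be >= 2")
    steps = compute_steps(track)
    m = steps.size  # number of intervals
    if m < min_fixes - 1:
        return []

    if rule == "per_step":
        ok = np.isfinite(steps) & (steps >= d_min) & (steps <= d_max)
        segments = []
        i = 0
        while i < m:
            if ok[i]:
                j = i
                while j + 1 < m and ok[j + 1]:
                    j += 1
                if j - i + 2 >= min_fixes:  # fixes spanned = steps + 1
                    segments.append(ForagingSegment(track.bear_id, i, j + 1))
                i = j + 1
            else:
                i += 1
        return segments

    # path rule: brute enumeration of qualifying windows, keep the maximal ones
    qualifying = [
        (i, j)
        for i in range(m)
        for j in range(i + min_fixes - 1, m + 1)
        if _window_ok(steps, i, j, d_min, d_max, rule)
    ]
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in qualifying)
    ]
    return [ForagingSegment(track.bear_id, i, j) for i, j in sorted(maximal)]


def choose_sample_positions(segment: ForagingSegment, track: Track) -> list[SamplePosition]:
    """Berry-plot sampling positions for one segment.

    Always the second fix of the run; for long runs (>= 7 fixes, i.e. more
    than 3.5 h of consistently slow movement) additionally the second-to-last
    fix, spatial autocorrelation between the two being considered low by then.
    """
    chosen: list[tuple[int, str]] = [(segment.start_index + 1, "second")]
    if segment.n_fixes >= 7:
        chosen.append((segment.end_index - 1, "second_to_last"))
    out = []
    for idx, slot in chosen:
        f = track.fixes[idx]
        out.append(
            SamplePosition(
                bear_id=track.bear_id,
                x=f.x,
                y=f.y,
                ordinal_day=int(f.t.dayofyear),
                segment=segment,
                slot=slot,
            )
        )
    return out


def exclude_near_sites(
    segments: Sequence[ForagingSegment],
    track: Track,
    sites: Iterable[tuple[float, float]],
    radius: float = 200.0,
) -> list[ForagingSegment]:
    """Drop whole segments with any fix within ``radius`` m of any site.

    Used to remove trajectories near known attractants (slaughter dump sites,
    agricultural fields) that would otherwise masquerade as berry foraging.
    The boundary is inclusive: distance exactly equal to ``radius`` removes.
    """
    site_arr = np.asarray(list(sites), dtype=float).reshape(-1, 2)
    if site_arr.size == 0:
        return list(segments)
    xy = track.xy
    kept = []
    for seg in segments:
        pts = xy[seg.start_index : seg.end_index + 1]
        d = np.hypot(
            pts[:, None, 0] - site_arr[None, :, 0],
            pts[:, None, 1] - site_arr[None, :, 1],
        )
        if not np.any(d <= radius):
            kept.append(seg)
    return kept


def fix_success_rate(track: Track) -> float:
    """Fraction of scheduled fixes successfully acquired."""
    if len(track) == 0:
        raise ValueError("empty track has no scheduled fixes")
    return float(track.valid.mean())
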