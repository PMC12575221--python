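"""Three-way classification of a marathon from its segment pace profile.

A race is labelled from the pace profile alone:

* the **base pace** is the distance-weighted mean pace over 5-20 km
  (the opening 5 km are excluded because early pacing is erratic);
* the **relative pace** of every segment starting at or beyond 25 km is its
  pace divided by the base pace;
* the race is **HTW** ("hit the wall") if relative pace stays above 1.25 over
  a continuous run of at least 5 km, otherwise **NHTW** if relative pace
  stays below 1.10 over a continuous run of at least 10 km, otherwise
  **EXCLUDED**.

Run lengths are sums of segment lengths within a maximal qualifying run;
"more than 5 km / 10 km" is implemented inclusively (>= threshold) because
segment quantisation makes a strict comparison fragile.  HTW is checked
first: a >25% slowdown sustained for 5 km is the defining event even if a
disjoint stretch of the same race is well paced.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class PaceLabel(str, enum.Enum):
    HTW = "HTW"
    NHTW = "NHTW"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class LabelRule:
    """Thresholds of the pace-label rule (distances in km, ratios unitless)."""

    base_window_km: tuple[float, float] = (5.0, 20.0)
    eval_start_km: float = 25.0
    htw_ratio: float = 1.25
    htw_run_km: float = 5.0
    nhtw_ratio: float = 1.10
    nhtw_run_km: float = 10.0
    min_coverage_km: float = 30.0

    def __post_init__(self) -> None:
        if not self.htw_ratio > self.nhtw_ratio > 1.0:
            raise ValueError(
                f"need htw_ratio > nhtw_ratio > 1, got {self.htw_ratio}, {self.nhtw_ratio}"
            )
        if self.htw_run_km <= 0 or self.nhtw_run_km <= 0:
            raise ValueError("run lengths must be positive")


@dataclass(frozen=True)
class PaceProfile:
    """Contiguous segment pace profile of one race.

    ``start_m``, ``length_m`` and ``pace_s_per_km`` are parallel arrays; the
    segments must be contiguous, non-overlapping and start at 0.
    """

    start_m: np.ndarray
    length_m: np.ndarray
    pace_s_per_km: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_m, dtype=float)
        length = np.asarray(self.length_m, dtype=float)
        pace = np.asarray(self.pace_s_per_km, dtype=float)
        if not (len(start) == len(length) == len(pace)):
            raise ValueError("start_m, length_m, pace_s_per_km must have equal length")
        if len(start) == 0:
            raise ValueError("empty pace profile")
        if np.any(length <= 0):
            raise ValueError("segment lengths must be positive")
        if np.any(pace <= 0):
            raise ValueError("pace values must be strictly positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("segments must be ordered by start")
        if not np.allclose(start[1:], start[:-1] + length[:-1], atol=1e-6):
            raise ValueError("segments must be contiguous and non-overlapping")
        object.__setattr__(self, "start_m", start)
        object.__setattr__(self, "length_m", length)
        object.__setattr__(self, "pace_s_per_km", pace)

    @property
    def end_m(self) -> np.ndarray:
        return self.start_m + self.length_m

    @property
    def total_distance_m(self) -> float:
        return float(self.end_m[-1])


def compute_base_pace(profile: PaceProfile, rule: LabelRule = LabelRule()) -> float:
    """Distance-weighted mean pace over the base window (default 5-20 km).

    Segments are weighted by their overlap with the window, so mixed
    250/500/1000 m profiles and segments straddling the window edges are
    handled exactly.
    """
    lo, hi = (1000.0 * k for k in rule.base_window_km)
    if profile.start_m[0] > lo + 1e-9 or profile.total_distance_m < hi - 1e-9:
        raise ValueError(
            f"profile does not cover the base-pace window "
            f"[{rule.base_window_km[0]}, {rule.base_window_km[1]}] km: covered span "
            f"[{profile.start_m[0] / 1000}, {profile.total_distance_m / 1000}] km"
        )
    overlap = np.clip(np.minimum(profile.end_m, hi) - np.maximum(profile.start_m, lo), 0.0, None)
    return float(np.sum(profile.pace_s_per_km * overlap) / np.sum(overlap))


def relative_pace_profile(
    profile: PaceProfile, base: float, rule: LabelRule = LabelRule()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative pace (segment pace / base) for segments starting >= 25 km.

    Returns ``(start_m, length_m, ratio)`` arrays in race order.
    """
    if base <= 0:
        raise ValueError("base pace must be positive")
    mask = profile.start_m >= rule.eval_start_km * 1000.0 - 1e-9
    if not mask.any():
        raise ValueError(f"no segments at or beyond {rule.eval_start_km} km")
    return (
        profile.start_m[mask],
        profile.length_m[mask],
        profile.pace_s_per_km[mask] / base,
    )


def _longest_run_km(length_m: np.ndarray, qualifies: np.ndarray) -> float:
    """Length (km) of the longest run of consecutive qualifying segments."""
    best = current = 0.0
    for length, ok in zip(length_m, qualifies):
        current = current + length if ok else 0.0
        best = max(best, current)
    return best / 1000.0


def classify_race(profile: PaceProfile, rule: LabelRule = LabelRule()) -> PaceLabel:
    """Apply the three-way pace-label rule to one race.

    Races that do not cover ``min_coverage_km`` (default 30 km) cannot be
    evaluated against either run-length criterion and are EXCLUDED.
    """
    if profile.total_distance_m < rule.min_coverage_km * 1000.0 - 1e-9:
        return PaceLabel.EXCLUDED
    base = compute_base_pace(profile, rule)
    _, length_m, ratio = relative_pace_profile(profile, base, rule)
    if _longest_run_km(length_m, ratio > rule.htw_ratio) >= rule.htw_run_km:
        return PaceLabel.HTW
    if _longest_run_km(length_m, ratio < rule.nhtw_ratio) >= rule.nhtw_run_km:
        return PaceLabel.NHTW
    return PaceLabel.EXCLUDED
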