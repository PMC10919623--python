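"""Criterion measure: resting VO2, steady-state bout VO2, METs, intensity.

The study's ground truth is metabolic: each activity bout's steady-state
oxygen consumption is divided by the participant's resting oxygen
consumption (the minutes-6-to-9 average of a 10-minute seated rest) to give
METs, and METs map to four intensity classes with the cut-offs
sedentary < 1.5, light < 3.0, moderate < 6.0, vigorous >= 6.0 (boundaries
belong to the upper class).  Bouts with no steady segment are excluded.

Steady state is detected quantitatively here: the longest suffix of the
bout, at least ``steady_min_duration`` long, whose least-squares VO2 slope
magnitude is at most ``trend_slope_tol`` (the study applied a visual
"no clear trend" criterion; the slope threshold is this package's
operationalization and is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthdata import CalorimetrySeries, Session

SEDENTARY = "sedentary"
LIGHT = "light"
MODERATE = "moderate"
VIGOROUS = "vigorous"
INTENSITIES = (SEDENTARY, LIGHT, MODERATE, VIGOROUS)


@dataclass(frozen=True)
class GroundTruthConfig:
    rest_window: tuple[float, float] = (6.0, 9.0)  # minutes into the rest period
    steady_min_duration: float = 180.0             # s
    # ~3x the sampling SD of the least-squares slope over a 3-min window at
    # typical steady-state calorimetry noise: accepts flat-but-noisy
    # segments, rejects true metabolic drift with little plateau bias
    trend_slope_tol: float = 0.3                   # (ml/kg/min) per minute
    met_cutoffs: tuple[float, float, float] = (1.5, 3.0, 6.0)

    def __post_init__(self) -> None:
        s, l, m = self.met_cutoffs
        if not (0.0 < s < l < m):
            raise ValueError("met_cutoffs must be increasing and positive")


@dataclass(frozen=True)
class BoutResult:
    bout_index: int
    steady_vo2: float | None       # ml/kg/min, None when excluded
    mets: float | None
    intensity: str | None
    exclusion_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.steady_vo2 is None


def resting_vo2(series: CalorimetrySeries,
                config: GroundTruthConfig = GroundTruthConfig()) -> float:
    """Mean VO2 between the configured minutes of the rest period."""
    lo = series.rest_start + config.rest_window[0] * 60.0
    hi = series.rest_start + config.rest_window[1] * 60.0
    mask = (series.t >= lo) & (series.t < hi)
    if not mask.any():
        raise ValueError(
            f"no calorimetry samples in the rest window [{lo}, {hi}) s")
    return float(series.vo2[mask].mean())


def steady_state_vo2(series: CalorimetrySeries, start_s: float, end_s: float,
                     config: GroundTruthConfig = GroundTruthConfig()
                     ) -> tuple[float | None, str | None]:
    """Steady-state mean VO2 of a bout, or (None, reason) when excluded.

    Scans suffix windows [t0, end) from longest to shortest; the bout is
    steady when some suffix at least ``steady_min_duration`` long has a
    least-squares slope magnitude within tolerance.  The returned value is
    the mean over the final ``steady_min_duration`` seconds of that window:
    the longest admissible suffix may still contain a sliver of on-transient
    whose inclusion the slope tolerance cannot detect, and averaging the
    final fully settled stretch removes that bias.
    """
    mask = (series.t >= start_s) & (series.t < end_s)
    t = series.t[mask]
    v = series.vo2[mask]
    if t.size < 2 or (end_s - start_s) < config.steady_min_duration:
        return None, "bout shorter than minimum steady-state duration"
    tol_per_s = config.trend_slope_tol / 60.0
    for i0 in range(t.size - 1):
        if (end_s - t[i0]) < config.steady_min_duration:
            break
        tt = t[i0:]
        vv = v[i0:]
        tc = tt - tt.mean()
        denom = float(np.dot(tc, tc))
        if denom == 0:
            continue
        slope = float(np.dot(tc, vv - vv.mean())) / denom
        if abs(slope) <= tol_per_s:
            tail = vv[tt >= end_s - config.steady_min_duration]
            return float(tail.mean()), None
    return None, "no steady-state window found"


def compute_mets(bout_vo2: float, resting: float) -> float:
    """METs: bout oxygen consumption divided by the resting value."""
    if resting <= 0:
        raise ValueError("resting VO2 must be > 0")
    return bout_vo2 / resting


def classify_intensity(mets: float,
                       config: GroundTruthConfig = GroundTruthConfig()) -> str:
    """Half-open MET lookup; each boundary belongs to the upper class."""
    if not math.isfinite(mets) or mets < 0:
        raise ValueError(f"mets must be finite and non-negative, got {mets}")
    sed, light, mod = config.met_cutoffs
    if mets < sed:
        return SEDENTARY
    if mets < light:
        return LIGHT
    if mets < mod:
        return MODERATE
    return VIGOROUS


def bout_result(series: CalorimetrySeries, bout_index: int, start_s: float,
                end_s: float, resting: float,
                config: GroundTruthConfig = GroundTruthConfig()) -> BoutResult:
    vo2, reason = steady_state_vo2(series, start_s, end_s, config)
    if vo2 is None:
        return BoutResult(bout_index=bout_index, steady_vo2=None, mets=None,
                          intensity=None, exclusion_reason=reason)
    mets = compute_mets(vo2, resting)
    return BoutResult(bout_index=bout_index, steady_vo2=vo2, mets=mets,
                      intensity=classify_intensity(mets, config))


def rest_bout_result(series: CalorimetrySeries,
                     config: GroundTruthConfig = GroundTruthConfig()
                     ) -> BoutResult:
    """The rest period scored as a bout.

    Resting oxygen consumption is *defined* as the minutes-6-to-9 average,
    so the rest period's MET value is that average divided by itself:
    exactly 1.0 (the published demographics table prints 1.0 +/- 0.0 METs
    for rest for the same reason).
    """
    rest = resting_vo2(series, config)
    mets = compute_mets(rest, rest)
    return BoutResult(bout_index=-1, steady_vo2=rest, mets=mets,
                      intensity=classify_intensity(mets, config))


def session_ground_truth(session: Session,
                         config: GroundTruthConfig = GroundTruthConfig()
                         ) -> tuple[float, list[BoutResult]]:
    """Run the full criterion pipeline on one simulated session."""
    rest = resting_vo2(session.calorimetry, config)
    results = [bout_result(session.calorimetry, lat.bout_index, lat.start_s,
                           lat.end_s, rest, config)
               for lat in session.latents]
    return rest, results
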