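"""Per-dive vertical metrics from 11-point time-depth profiles.

A tag stores each dive as 11 inflection points equally spaced in time plus
the recorded maximum depth.  This module applies the quality-control rules
(compressed multi-dive records from missed surfacings; sub-threshold
shallow dives) and computes the vertical foraging indices:

* bottom phase and bottom time BT — time spent in the lower 15 % of the
  dive's maximum depth, with threshold crossings found by linear
  interpolation between profile points;
* standardized bottom time stBT = BT / maxBT, where
  maxBT = duration − minimum travel time and the minimum travel time is
  the time needed to reach the bottom phase (85 % of maximum depth) from
  the surface and back at the animal's maximum vertical speed;
* leg (descent/ascent) speeds, dive skewness SK = ascent/descent speed
  (elevated for drifting resting dives), and a time-at-depth style index
  TAD used only as a correlation check.

All thresholds are parameters with the canonical defaults: upper 25 % /
50 % duration for compressed records, 5.6 m for shallow dives, lower 15 %
for the bottom phase, 0.95 quantile for the maximum vertical speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiveThresholds",
    "PROFILE_COLUMNS",
    "flag_shallow",
    "flag_compressed",
    "apply_qc",
    "bottom_phase",
    "leg_speeds",
    "dive_skewness",
    "standardized_bottom_time",
    "time_at_depth_index",
    "max_vertical_speed",
    "compute_dive_metrics",
]

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [f"d{k}" for k in range(11)]


@dataclass(frozen=True)
class DiveThresholds:
    """QC and index thresholds with their standard defaults."""

    shallow_max_depth: float = 5.6  # m, inclusive
    upper_fraction: float = 0.25  # "upper 25 %" compressed-record rule
    upper_time_fraction: float = 0.50  # ... "for more than 50 % of duration"
    bottom_fraction: float = 0.15  # bottom phase = lower 15 % of max depth
    vmax_quantile: float = 0.95
    min_dives_for_vmax: int = 50


def _profile(row):
    """(times, depths) of the 11-point profile of one dive row."""
    depths = np.asarray([row[c] for c in PROFILE_COLUMNS], dtype=float)
    if depths.size != 11 or np.any(~np.isfinite(depths)):
        raise ValueError("malformed dive record: need 11 finite profile depths")
    times = np.linspace(0.0, float(row["duration_s"]), 11)
    return times, depths


def _time_above(times, depths, z):
    """Total time with depth < z (shallower), linear interpolation."""
    total = 0.0
    for i in range(len(times) - 1):
        d0, d1 = depths[i], depths[i + 1]
        dt = times[i + 1] - times[i]
        if d0 < z and d1 < z:
            total += dt
        elif d0 < z or d1 < z:
            # one crossing inside the interval
            frac = (z - d0) / (d1 - d0)
            total += dt * (frac if d0 < z else 1.0 - frac)
    return total


def _time_below(times, depths, z):
    """Total time with depth >= z (deeper), linear interpolation."""
    return float(times[-1] - times[0]) - _time_above(times, depths, z)


def flag_shallow(max_depth: float, thresholds: DiveThresholds = DiveThresholds()) -> bool:
    """True if the dive is at or below the shallow cutoff (inclusive)."""
    return max_depth <= thresholds.shallow_max_depth


def flag_compressed(row, thresholds: DiveThresholds = DiveThresholds()) -> bool:
    """Detect probable multi-dive records from missed surfacings.

    A record is compressed if, excluding the first descending and last
    ascending phases, any reading lies in the upper 25 % of the dive's
    maximum depth, or if the dive spends more than 50 % of its duration in
    that upper layer (time fractions by linear interpolation).
    """
    times, depths = _profile(row)
    max_depth = float(row["max_depth_m"])
    z = thresholds.upper_fraction * max_depth
    # first descending phase: monotone non-decreasing depth prefix
    i0 = 0
    while i0 + 1 < len(depths) and depths[i0 + 1] >= depths[i0]:
        i0 += 1
    # last ascending phase: monotone non-increasing depth suffix
    i1 = len(depths) - 1
    while i1 - 1 >= 0 and depths[i1 - 1] >= depths[i1]:
        i1 -= 1
    interior = depths[i0 + 1:i1]
    if interior.size and np.any(interior < z):
        return True
    frac = _time_above(times, depths, z) / max(float(row["duration_s"]), 1e-12)
    return frac > thresholds.upper_time_fraction


def apply_qc(dives: pd.DataFrame, thresholds: DiveThresholds = DiveThresholds()) -> pd.DataFrame:
    """Add a ``qc`` column: 'ok', 'compressed', or 'shallow'.

    Shallow takes precedence: a sub-threshold record is unusable either way
    and the shallow rule mirrors how those records were screened.
    """
    qc = []
    for _, row in dives.iterrows():
        if flag_shallow(float(row["max_depth_m"]), thresholds):
            qc.append("shallow")
        elif flag_compressed(row, thresholds):
            qc.append("compressed")
        else:
            qc.append("ok")
    out = dives.copy()
    out["qc"] = qc
    counts = out["qc"].value_counts().to_dict()
    logger.info("dive QC: %s", counts)
    return out


def bottom_phase(row, thresholds: DiveThresholds = DiveThresholds()):
    """(entry time, exit time, BT) of the bottom phase.

    The bottom phase is depth >= (1 - bottom_fraction) * max depth; multiple
    excursions below the threshold are summed into BT, and entry/exit are
    the first and last threshold crossings.
    """
    times, depths = _profile(row)
    max_depth = float(row["max_depth_m"])
    z = (1.0 - thresholds.bottom_fraction) * max_depth
    bt = _time_below(times, depths, z)
    # entry: first crossing into depth >= z; exit: last crossing out
    entry = exit_ = None
    for i in range(len(times) - 1):
        d0, d1 = depths[i], depths[i + 1]
        if entry is None:
            if d0 >= z:
                entry = times[i]
            elif d1 >= z:
                entry = times[i] + (times[i + 1] - times[i]) * (z - d0) / (d1 - d0)
        if d1 >= z:
            exit_ = times[i + 1]
        elif d0 >= z:
            exit_ = times[i] + (times[i + 1] - times[i]) * (z - d0) / (d1 - d0)
    if entry is None:
        # profile quantization can hide the recorded maximum; treat the
        # deepest sample as a point visit
        k = int(np.argmax(depths))
        entry = exit_ = times[k]
        bt = 0.0
    return float(entry), float(exit_), float(bt)


def leg_speeds(row, thresholds: DiveThresholds = DiveThresholds()):
    """(descent speed, ascent speed) in m/s.

    Descent speed is the bottom-phase depth (85 % of max depth) divided by
    the time from dive start to first bottom-phase entry; ascent is the
    mirror image.  This matches the travel geometry used by maxBT.
    """
    entry, exit_, _ = bottom_phase(row, thresholds)
    max_depth = float(row["max_depth_m"])
    duration = float(row["duration_s"])
    z = (1.0 - thresholds.bottom_fraction) * max_depth
    down = z / entry if entry > 0 else np.nan
    up = z / (duration - exit_) if duration - exit_ > 0 else np.nan
    return down, up


def dive_skewness(descent_speed: float, ascent_speed: float) -> float:
    """SK = ascent / descent speed; NaN if either leg speed is invalid."""
    if not (descent_speed and ascent_speed) or descent_speed <= 0 or ascent_speed <= 0:
        return np.nan
    return ascent_speed / descent_speed


def standardized_bottom_time(duration: float, max_depth: float, bt: float,
                             v_max: float,
                             thresholds: DiveThresholds = DiveThresholds()):
    """(stBT, maxBT); stBT clipped to [0, 1], NaN when maxBT <= 0.

    maxBT = duration − 2 * (1 − bottom_fraction) * max_depth / v_max.
    """
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    min_travel = 2.0 * (1.0 - thresholds.bottom_fraction) * max_depth / v_max
    max_bt = duration - min_travel
    if max_bt <= 0:
        logger.warning("dive with non-positive maxBT (duration %.1f s)", duration)
        return np.nan, max_bt
    return float(np.clip(bt / max_bt, 0.0, 1.0)), max_bt


def time_at_depth_index(duration: float, max_depth: float,
                        descent_speed: float, ascent_speed: float,
                        v_max: float) -> float:
    """Time-at-depth style index: non-travel time over the maximum
    possible non-travel time given depth, duration and v_max.

    TAD = (duration - d/vd - d/va) / (duration - 2 d / v_max), a stand-in
    with the canonical limiting behaviour — exactly 1 for a square dive
    travelling at v_max, 0 for a v-shaped dive — used only for sign-level
    correlation checks, not in the model table.
    """
    if not (descent_speed > 0 and ascent_speed > 0):
        return np.nan
    denom = duration - 2.0 * max_depth / v_max
    if denom <= 0:
        return np.nan
    t_at_depth = duration - max_depth / descent_speed - max_depth / ascent_speed
    return float(np.clip(max(t_at_depth, 0.0) / denom, 0.0, 1.0))


def max_vertical_speed(metrics: pd.DataFrame,
                       thresholds: DiveThresholds = DiveThresholds()) -> pd.Series:
    """Per-animal maximum vertical speed: the 0.95 quantile of pooled
    descent and ascent speeds (linear-interpolation quantile).

    Animals with fewer than ``min_dives_for_vmax`` valid dives fall back to
    the population quantile (logged).
    """
    q = thresholds.vmax_quantile
    pooled = np.concatenate([
        metrics["descent_speed"].dropna().to_numpy(),
        metrics["ascent_speed"].dropna().to_numpy(),
    ])
    if pooled.size == 0:
        raise ValueError("no valid leg speeds to estimate v_max from")
    pop_vmax = float(np.quantile(pooled, q))
    out = {}
    for aid, grp in metrics.groupby("animal_id"):
        speeds = np.concatenate([
            grp["descent_speed"].dropna().to_numpy(),
            grp["ascent_speed"].dropna().to_numpy(),
        ])
        if len(grp) < thresholds.min_dives_for_vmax:
            logger.info("animal %s: %d dives < floor, using population v_max",
                        aid, len(grp))
            out[aid] = pop_vmax
        else:
            out[aid] = float(np.quantile(speeds, q))
    return pd.Series(out, name="v_max")


def compute_dive_metrics(dives: pd.DataFrame,
                         thresholds: DiveThresholds = DiveThresholds(),
                         v_max=None) -> pd.DataFrame:
    """Full per-dive metric table for QC-passing dives.

    Runs QC (unless a ``qc`` column is already present), computes BT and leg
    speeds per dive, estimates per-animal v_max from the data unless
    ``v_max`` (scalar or per-animal Series) is given, then stBT, TAD, SK.

    Returns one row per input dive; metric columns are NaN for dives that
    fail QC.
    """
    dives = dives if "qc" in dives.columns else apply_qc(dives, thresholds)
    n = len(dives)
    bt = np.full(n, np.nan)
    down = np.full(n, np.nan)
    up = np.full(n, np.nan)
    ok = (dives["qc"] == "ok").to_numpy()
    for k, (_, row) in enumerate(dives.iterrows()):
        if not ok[k]:
            continue
        _, _, bt[k] = bottom_phase(row, thresholds)
        down[k], up[k] = leg_speeds(row, thresholds)
    out = dives.copy()
    out["BT"] = bt
    out["descent_speed"] = down
    out["ascent_speed"] = up
    if v_max is None:
        vmax_per = max_vertical_speed(out[ok], thresholds)
        out["v_max"] = out["animal_id"].map(vmax_per)
    elif np.isscalar(v_max):
        out["v_max"] = float(v_max)
    else:
        out["v_max"] = out["animal_id"].map(v_max)

    stbt = np.full(n, np.nan)
    maxbt = np.full(n, np.nan)
    tad = np.full(n, np.nan)
    sk = np.full(n, np.nan)
    for k in range(n):
        if not ok[k]:
            continue
        dur = float(out["duration_s"].iloc[k])
        md = float(out["max_depth_m"].iloc[k])
        vm = float(out["v_max"].iloc[k])
        stbt[k], maxbt[k] = standardized_bottom_time(dur, md, bt[k], vm, thresholds)
        tad[k] = time_at_depth_index(dur, md, down[k], up[k], vm)
        sk[k] = dive_skewness(down[k], up[k])
    out["maxBT"] = maxbt
    out["stBT"] = stbt
    out["TAD"] = tad
    out["SK"] = sk
    out["log_SK"] = np.log(out["SK"])
    return out
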