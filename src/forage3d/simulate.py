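"""Synthetic biologging data with known ground truth.

Generates everything a tag deployment on a diving central-place forager
produces — an irregular GPS track, haul-out events from a wet/dry sensor,
dives summarised as 11-point time-depth profiles, and a bathymetry grid —
together with the behavioural truth behind it (two-state horizontal
movement, benthic/pelagic/resting dive classes, and the segment-level
linear model that generated standardized bottom time).

The generator reproduces the *statistical* structure the downstream
analysis assumes, not seal physiology: a two-state correlated random walk
in a flat planar world, alternating haul-out / at-sea renewal cycles at a
small fixed set of haul-out sites, dives as a dive-plus-surface-interval
renewal process, and tag artefacts (GPS dropout and delay, position
error, missed-surfacing record compression, sub-threshold shallow dives).

Standardized bottom time is generated *top-down*: a segment-level linear
model with configurable coefficients produces a target stBT per 20-min
trajectory segment, and each dive's bottom time is solved from that target
given its depth and leg speeds — so the mixed-model stage has an exactly
recoverable truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bathymetry import BathymetryGrid

__all__ = [
    "EffectSizes",
    "SimConfig",
    "SimData",
    "simulate_bathymetry",
    "simulate_track",
    "simulate_dives",
    "simulate_dataset",
    "simulate_model_table",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class EffectSizes:
    """Ground-truth coefficients of the segment-level stBT model.

    Defaults are realistic values for a benthic/pelagic diving pinniped:
    resting while diving strongly depresses stBT, a benthic tactic raises
    it, depth has a small positive effect, and the horizontal index (-HS)
    interacts with tactic (a positive vertical-horizontal coupling for
    benthic diving only).  Units: stBT is dimensionless, Depth in m,
    hFI = -HS in m/s.
    """

    intercept: float = 0.480
    resting: float = -0.278
    ptactic: float = 0.138
    depth: float = 0.002
    hfi: float = 0.001
    hfi_ptactic: float = 0.063
    residual_sd: float = 0.156  # sqrt(0.0243)
    # among-individual sds (random intercept / random hFI slope)
    intercept_sd: float = 0.02  # sqrt(4e-4)
    slope_sd: float = 0.0245  # sqrt(6e-4)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic deployment.

    Temporal resolution and tag behaviour copy a GPS phone tag: positions
    targeted every 20 min with occasional delay and dropout, dives stored
    as 11 inflection points equally spaced in time, haul-out events from a
    wet/dry sensor.
    """

    n_animals: int = 14
    days: float = 186.0  # ~6.2 months deployment
    # --- GPS sampling ---
    gps_interval: float = 1200.0  # s
    gps_dropout_prob: float = 0.10
    gps_delay_prob: float = 0.30
    gps_max_delay: float = 500.0  # s
    gps_error_sd: float = 15.0  # m, per-axis jitter
    gps_error_scale: float = 18.0  # m, mean of reported-error distribution
    # --- two-state horizontal movement (extensive=0, intensive=1) ---
    state_transition: tuple = ((0.85, 0.15), (0.05, 0.95))
    speed_mean: tuple = (1.0, 0.15)  # m/s per state
    speed_sd: tuple = (0.25, 0.08)
    turn_kappa: tuple = (4.0, 0.5)  # von Mises concentration per state
    # --- haul-out cycle ---
    haulout_mean_h: float = 6.0
    at_sea_mean_h: float = 18.0
    n_haulout_sites: int = 2
    world_size: float = 20000.0  # m
    # --- dives ---
    dive_rate: float = 60.0  # ceiling on dive initiations per hour at sea
    dive_duty_frac: float = 0.70  # fraction of at-sea time spent in dives
    min_surface_s: float = 20.0  # shortest surface interval between dives
    max_vertical_speed: float = 2.0  # m/s; true physiological ceiling
    active_speed_frac: tuple = (0.35, 1.0)  # leg speed as fraction of ceiling
    benthic_offset_sd: float = 2.0  # m, scatter of benthic max depth vs bottom
    pelagic_depth_frac: tuple = (0.15, 0.60)  # max depth as fraction of bottom
    min_dive_depth: float = 7.0  # m, active dives
    tactic_bout_mean_h: float = 6.0
    benthic_tactic_frac: float = 0.5
    benthic_prob_in_bout: float = 0.9
    # --- resting while diving ---
    resting_rate_per_day: float = 2.0  # bout starts per day at sea
    resting_bout_mean_h: float = 1.5
    resting_pelagic_frac: float = 2.0 / 3.0
    resting_descent_speed: tuple = (0.15, 0.35)  # m/s, drifting descent
    resting_ascent_speed: tuple = (1.0, 1.6)  # m/s
    # --- tag artefacts ---
    missed_surfacing_prob: float = 0.02  # per dive: merge with the next dive
    shallow_dive_prob: float = 0.05  # extra sub-threshold dives
    # --- bathymetry generator ---
    bathy_cell_size: float = 100.0
    bathy_base_depth: float = 60.0
    bathy_amplitude: float = 35.0
    bathy_length_scale: float = 6000.0
    bathy_min_depth: float = 10.0
    # --- stBT generation ---
    effects: EffectSizes = field(default_factory=EffectSizes)
    # floor 0.17: a dive with straight constant-speed legs cannot go below
    # stBT ~0.15 (the 15 % leg contribution to BT), ceiling avoids maxBT
    # degeneracy
    stbt_clip: tuple = (0.17, 0.95)

    def validate(self):
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (2, 2) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("state_transition must be 2x2 row-stochastic")
        if np.any(P < 0):
            raise ValueError("state_transition entries must be >= 0")
        if max(self.speed_mean) <= 0:
            raise ValueError("at least one state must have positive speed")
        for name in ("gps_interval", "dive_rate", "max_vertical_speed",
                     "haulout_mean_h", "at_sea_mean_h", "days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gps_error_sd < 0:
            raise ValueError("gps_error_sd must be >= 0")
        return self


@dataclass
class SimData:
    """One synthetic deployment: tag outputs plus ground truth."""

    tracks: pd.DataFrame  # irregular GPS fixes
    haulouts: pd.DataFrame  # wet/dry haul-out events
    dives: pd.DataFrame  # 11-point dive records (wide, d0..d10)
    bathymetry: BathymetryGrid
    haulout_sites: pd.DataFrame
    truth_states: pd.DataFrame  # per regular node: state, hauled
    truth_dives: pd.DataFrame  # per dive: class + generative parameters
    truth_segments: pd.DataFrame  # per segment: covariates behind stBT
    config: SimConfig


# ---------------------------------------------------------------------------
# bathymetry

def simulate_bathymetry(config: SimConfig, rng: np.random.Generator) -> BathymetryGrid:
    """Smooth synthetic bottom-depth field over the simulation world."""
    n = int(np.ceil(config.world_size / config.bathy_cell_size))
    xs = (np.arange(n) + 0.5) * config.bathy_cell_size
    X, Y = np.meshgrid(xs, xs)
    k = 2 * np.pi / config.bathy_length_scale
    ph = rng.uniform(0, 2 * np.pi, size=4)
    depths = (
        config.bathy_base_depth
        + config.bathy_amplitude * 0.6 * np.sin(k * X + ph[0]) * np.cos(k * Y + ph[1])
        + config.bathy_amplitude * 0.4 * np.sin(0.5 * k * (X + Y) + ph[2])
        + config.bathy_amplitude * 0.15 * np.cos(1.7 * k * (X - Y) + ph[3])
    )
    depths = np.clip(depths, config.bathy_min_depth, None)
    return BathymetryGrid(depths, origin=(0.0, 0.0), cell_size=config.bathy_cell_size)


# ---------------------------------------------------------------------------
# haul-out schedule and two-state movement

def _haulout_schedule(config: SimConfig, total_s: float, rng) -> np.ndarray:
    """Alternating at-sea / hauled-out renewal process.

    Returns an array of (start, end) haul-out intervals in seconds.
    Exponential durations; the deployment starts at sea.
    """
    events = []
    t = rng.exponential(config.at_sea_mean_h * 3600.0)
    while t < total_s:
        dur = rng.exponential(config.haulout_mean_h * 3600.0)
        events.append((t, min(t + dur, total_s)))
        t += dur + rng.exponential(config.at_sea_mean_h * 3600.0)
    return np.array(events).reshape(-1, 2)


def _simulate_one_track(config: SimConfig, sites: np.ndarray, rng):
    """True positions on the regular (gps_interval) grid plus states.

    Returns (times, x, y, state, hauled, haulout_events, site_index_per_event).
    """
    dt = config.gps_interval
    n = int(config.days * SECONDS_PER_DAY / dt) + 1
    times = np.arange(n) * dt
    total_s = times[-1]
    events = _haulout_schedule(config, total_s, rng)
    ev_sites = rng.integers(0, len(sites), size=len(events))

    P = np.asarray(config.state_transition)
    x = np.empty(n)
    y = np.empty(n)
    state = np.empty(n, dtype=int)
    hauled = np.zeros(n, dtype=bool)
    for s0, e0 in events:
        hauled |= (times >= s0) & (times < e0)

    # per-step target site: the site of the *next* haul-out event
    next_ev = np.searchsorted(events[:, 0], times, side="right") if len(events) else None

    start_site = sites[ev_sites[0]] if len(events) else sites[0]
    x[0], y[0] = start_site + rng.normal(0, 200, size=2)
    state[0] = int(rng.random() < 0.5)
    heading = rng.uniform(0, 2 * np.pi)
    v_home = max(config.speed_mean)

    for i in range(1, n):
        state[i] = int(rng.random() < P[state[i - 1], 1])
        if hauled[i - 1]:
            # sit at the haul-out site
            k = np.searchsorted(events[:, 1], times[i - 1], side="right")
            k = min(k, len(events) - 1)
            x[i], y[i] = sites[ev_sites[k]]
            heading = rng.uniform(0, 2 * np.pi)
            continue
        # homing: head for the next haul-out site when time is short
        steer = False
        if len(events):
            k = next_ev[i - 1]
            if k < len(events):
                t_left = events[k, 0] - times[i - 1]
                tgt = sites[ev_sites[k]]
                d = np.hypot(tgt[0] - x[i - 1], tgt[1] - y[i - 1])
                if d > 0.7 * v_home * max(t_left, 1.0):
                    steer = True
                    heading = np.arctan2(tgt[1] - y[i - 1], tgt[0] - x[i - 1])
                    spd = max(v_home * 0.9, 0.01)
        if not steer:
            s = state[i - 1]
            heading = heading + rng.vonmises(0.0, config.turn_kappa[s])
            spd = max(rng.normal(config.speed_mean[s], config.speed_sd[s]), 0.0)
        x[i] = x[i - 1] + spd * dt * np.cos(heading)
        y[i] = y[i - 1] + spd * dt * np.sin(heading)
        # keep inside the world with a margin
        lim = config.world_size
        if not (200 < x[i] < lim - 200 and 200 < y[i] < lim - 200):
            x[i] = np.clip(x[i], 300, lim - 300)
            y[i] = np.clip(y[i], 300, lim - 300)
            heading = heading + np.pi
    return times, x, y, state, hauled, events, ev_sites


def _observe_gps(times, x, y, config: SimConfig, rng):
    """Apply tag artefacts to the true track: dropout, delay, position error."""
    n = len(times)
    keep = rng.random(n) >= config.gps_dropout_prob
    keep[0] = True
    delay = np.where(
        rng.random(n) < config.gps_delay_prob,
        rng.uniform(0, config.gps_max_delay, size=n),
        0.0,
    )
    t_obs = times + delay
    # delayed fix positions: the animal kept moving; interpolate the truth
    x_obs = np.interp(t_obs, times, x)
    y_obs = np.interp(t_obs, times, y)
    err = rng.exponential(config.gps_error_scale, size=n)
    x_obs = x_obs + rng.normal(0, config.gps_error_sd, size=n)
    y_obs = y_obs + rng.normal(0, config.gps_error_sd, size=n)
    df = pd.DataFrame(
        {"time_s": t_obs[keep], "x": x_obs[keep], "y": y_obs[keep], "error_m": err[keep]}
    )
    return df.sort_values("time_s", ignore_index=True)


def simulate_track(config: SimConfig, seed=None, rng=None, sites=None, animal_id="a00"):
    """Simulate one animal's GPS track and haul-out events.

    Returns ``(fixes, haulouts, truth)`` where ``fixes`` is the irregular,
    error-jittered GPS table, ``haulouts`` the wet/dry events, and
    ``truth`` the regular-grid truth (time, x, y, state, hauled).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    if sites is None:
        sites = _default_sites(config)
    times, x, y, state, hauled, events, ev_sites = _simulate_one_track(config, sites, rng)
    fixes = _observe_gps(times, x, y, config, rng)
    fixes.insert(0, "animal_id", animal_id)
    haulouts = pd.DataFrame(
        {
            "animal_id": animal_id,
            "start_s": events[:, 0] if len(events) else [],
            "end_s": events[:, 1] if len(events) else [],
            "site_id": ev_sites if len(events) else [],
        }
    )
    truth = pd.DataFrame(
        {
            "animal_id": animal_id,
            "time_s": times,
            "x": x,
            "y": y,
            "state": state,
            "hauled": hauled,
        }
    )
    return fixes, haulouts, truth


def _default_sites(config: SimConfig) -> np.ndarray:
    w = config.world_size
    k = config.n_haulout_sites
    ang = np.linspace(0, 2 * np.pi, k, endpoint=False) + np.pi / 4
    return np.column_stack(
        [w / 2 + 0.3 * w * np.cos(ang), w / 2 + 0.3 * w * np.sin(ang)]
    )


# ---------------------------------------------------------------------------
# dives

def _merge_intervals(intervals):
    """Merge overlapping (start, end) intervals; assumes sorted starts."""
    if len(intervals) == 0:
        return intervals
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _interval_membership(t, intervals):
    """Boolean: does each time fall inside any (start, end) interval.

    Intervals must be sorted by start and non-overlapping.
    """
    if len(intervals) == 0:
        return np.zeros(len(t), dtype=bool)
    starts = intervals[:, 0]
    ends = intervals[:, 1]
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(t), dtype=bool)
    out[ok] = t[ok] < ends[idx[ok]]
    return out


def _profile_11pt(duration, max_depth, t_desc, bt, t_asc):
    """Sample the trapezoidal truth profile at 11 equally spaced times."""
    tt = np.linspace(0.0, duration, 11)
    knots_t = [0.0, t_desc, t_desc + bt, duration]
    knots_d = [0.0, max_depth, max_depth, 0.0]
    return np.interp(tt, knots_t, knots_d)


def _solve_dive_geometry(stbt, depth, vd, va, v_max, max_duration=1400.0):
    """Leg speeds and flat-bottom time realizing a target stBT.

    The measured bottom time of a trapezoidal dive is the flat time at
    maximum depth *plus* the leg time spent below 85 % of maximum depth:
    BT = bt + 0.15 d (1/vd + 1/va), while
    maxBT = d/vd + d/va + bt - 1.7 d / v_max.  Solving stBT = BT/maxBT for
    bt can go negative when the target is low and the legs fast — a dive
    with near-maximal legs cannot have a low stBT.  In that case both leg
    speeds are scaled down (preserving their ratio, hence dive skewness)
    to the v-shaped dive that meets the target exactly, subject to a cap
    on total duration.

    Returns ``(vd, va, bt)`` arrays.
    """
    stbt = np.asarray(stbt, dtype=float)
    vd = np.asarray(vd, dtype=float).copy()
    va = np.asarray(va, dtype=float).copy()
    m_tt = 2 * 0.85 * depth / v_max

    def _bt(vd_, va_):
        travel = depth / vd_ + depth / va_
        leg_bt = 0.15 * depth * (1 / vd_ + 1 / va_)
        return (stbt * (travel - m_tt) - leg_bt) / (1.0 - stbt)

    bt = _bt(vd, va)
    low = bt < 0
    if np.any(low):
        t0 = depth / vd + depth / va
        l0 = 0.15 * t0  # leg bottom time is always 15 % of travel time
        f = (stbt * t0 - l0) / (stbt * m_tt)
        f = np.clip(f, t0 / max_duration, 1.0)  # duration cap
        vd = np.where(low, f * vd, vd)
        va = np.where(low, f * va, va)
        bt = np.maximum(_bt(vd, va), 0.0)
    # cap very long flat bottoms (tags cannot register endless dives)
    travel = depth / vd + depth / va
    bt = np.minimum(bt, np.maximum(max_duration - travel, 0.0))
    return vd, va, bt


def simulate_dives(track_truth, haulouts, bathymetry, config: SimConfig,
                   seed=None, rng=None, animal_effects=(0.0, 0.0)):
    """Simulate dive records for one animal over its true track.

    Parameters
    ----------
    track_truth : DataFrame from :func:`simulate_track` (regular-grid truth).
    haulouts : DataFrame of haul-out events.
    bathymetry : BathymetryGrid.
    config : SimConfig.
    animal_effects : (random intercept, random hFI slope) for this animal.

    Returns ``(dives, truth_dives, truth_segments)``.  ``dives`` is the tag
    output (wide 11-point profiles); the truth tables carry the dive class
    and the segment covariates that generated stBT.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    eff = config.effects
    animal_id = track_truth["animal_id"].iloc[0]
    t_nodes = track_truth["time_s"].to_numpy()
    xs = track_truth["x"].to_numpy()
    ys = track_truth["y"].to_numpy()
    hauled = track_truth["hauled"].to_numpy()
    dt = config.gps_interval

    ev = haulouts[["start_s", "end_s"]].to_numpy(dtype=float).reshape(-1, 2)
    total_s = t_nodes[-1]

    # at-sea intervals between haul-out events
    sea_iv = []
    prev = 0.0
    for s0, e0 in ev:
        if s0 > prev:
            sea_iv.append((prev, s0))
        prev = e0
    if total_s > prev:
        sea_iv.append((prev, total_s))

    # resting bouts (at sea); dives inside a bout are resting dives
    at_sea_frac = 1.0 - hauled.mean()
    n_bouts = rng.poisson(config.resting_rate_per_day * config.days * at_sea_frac)
    bout_start = np.sort(rng.uniform(0, total_s, size=n_bouts))
    bout_dur = rng.exponential(config.resting_bout_mean_h * 3600.0, size=n_bouts)
    rest_iv = (
        _merge_intervals(np.column_stack([bout_start, bout_start + bout_dur]))
        if n_bouts else np.empty((0, 2))
    )

    # predatory-tactic bouts: alternating benthic / pelagic periods
    tac_edges = [0.0]
    while tac_edges[-1] < total_s:
        tac_edges.append(tac_edges[-1] + rng.exponential(config.tactic_bout_mean_h * 3600.0))
    tac_edges = np.asarray(tac_edges)
    first_benthic = rng.random() < config.benthic_tactic_frac

    hs_true = np.hypot(np.diff(xs), np.diff(ys)) / dt
    u0, u1 = animal_effects
    n_seg = len(t_nodes) - 1

    seg_cache = {}

    def _segment_base(j):
        """Non-depth part of the stBT linear predictor for segment j,
        including the segment's residual draw (cached so every dive in
        the segment shares it)."""
        if j in seg_cache:
            return seg_cache[j]
        tmid = t_nodes[j] + dt / 2
        resting = bool(_interval_membership(np.array([tmid]), rest_iv)[0])
        k = int(np.searchsorted(tac_edges, tmid, side="right")) - 1
        ptac = int((k % 2 == 0) == first_benthic)
        neg_hs = -hs_true[min(j, n_seg - 1)]
        base = (
            eff.intercept + u0
            + eff.resting * resting
            + eff.ptactic * ptac
            + (eff.hfi + u1) * neg_hs
            + eff.hfi_ptactic * neg_hs * ptac
            + rng.normal(0, eff.residual_sd)
        )
        seg_cache[j] = (base, resting, ptac, neg_hs)
        return seg_cache[j]

    # --- sequential dive generation: dive + surface interval renewal ---
    gap_target = 3600.0 / config.dive_rate
    rows = {k: [] for k in ("t", "cls", "depth", "vd", "va", "bt",
                            "duration", "seg", "stbt", "bottom")}
    for s0, e0 in sea_iv:
        t = s0 + rng.exponential(30.0)
        while t < e0 - 60.0:
            j = min(int(t // dt), n_seg - 1)
            base, seg_resting, seg_ptac, _ = _segment_base(j)
            is_resting = bool(_interval_membership(np.array([t]), rest_iv)[0])
            if is_resting:
                benthic_pos = rng.random() >= config.resting_pelagic_frac
                cls_i = "resting"
            else:
                k = int(np.searchsorted(tac_edges, t, side="right")) - 1
                bout_benthic = (k % 2 == 0) == first_benthic
                p_b = (config.benthic_prob_in_bout if bout_benthic
                       else 1 - config.benthic_prob_in_bout)
                benthic_pos = rng.random() < p_b
                cls_i = "benthic" if benthic_pos else "pelagic"
            x_i = np.interp(t, t_nodes, xs)
            y_i = np.interp(t, t_nodes, ys)
            bottom_i = float(bathymetry.depth_at(x_i, y_i))
            if not np.isfinite(bottom_i):
                raise ValueError("dive location falls outside the bathymetry grid")
            if benthic_pos:
                depth_i = max(bottom_i + rng.normal(0, config.benthic_offset_sd), 6.0)
            else:
                depth_i = max(bottom_i * rng.uniform(*config.pelagic_depth_frac),
                              config.min_dive_depth)
                depth_i = max(min(depth_i, bottom_i - 2.0), 6.0)
            stbt_i = float(np.clip(base + eff.depth * depth_i, *config.stbt_clip))
            if is_resting:
                vd_i = rng.uniform(*config.resting_descent_speed)
                va_i = rng.uniform(*config.resting_ascent_speed)
            else:
                vd_i = config.max_vertical_speed * rng.uniform(*config.active_speed_frac)
                va_i = config.max_vertical_speed * rng.uniform(*config.active_speed_frac)
            vd_i, va_i, bt_i = (float(v) for v in _solve_dive_geometry(
                stbt_i, depth_i, vd_i, va_i, config.max_vertical_speed))
            dur_i = depth_i / vd_i + bt_i + depth_i / va_i
            if t + dur_i > e0:
                break
            for key, val in zip(
                    ("t", "cls", "depth", "vd", "va", "bt", "duration",
                     "seg", "stbt", "bottom"),
                    (t, cls_i, depth_i, vd_i, va_i, bt_i, dur_i, j, stbt_i,
                     bottom_i)):
                rows[key].append(val)
            # surface interval: duty-cycle target with the rate as ceiling
            phi = config.dive_duty_frac
            gap_mean = max(dur_i * (1 - phi) / phi,
                           gap_target - dur_i - config.min_surface_s, 5.0)
            t += dur_i + config.min_surface_s + rng.exponential(gap_mean)

    t_dive = np.asarray(rows["t"])
    cls = np.asarray(rows["cls"], dtype=object)
    max_depth = np.asarray(rows["depth"])
    vd = np.asarray(rows["vd"])
    va = np.asarray(rows["va"])
    bt = np.asarray(rows["bt"])
    duration = np.asarray(rows["duration"])
    seg = np.asarray(rows["seg"], dtype=int)
    stbt_target = np.asarray(rows["stbt"])
    bottom = np.asarray(rows["bottom"])
    n_d = len(t_dive)
    t_desc = max_depth / vd
    t_asc = max_depth / va

    records = []
    truth_rows = []
    i = 0
    while i < n_d:
        merge = (
            config.missed_surfacing_prob > 0
            and i + 1 < n_d
            and rng.random() < config.missed_surfacing_prob
            and (t_dive[i + 1] - t_dive[i]) < 1500.0
        )
        if merge:
            # missed surfacing: two dives compressed into one record
            gap = float(np.clip(t_dive[i + 1] - (t_dive[i] + duration[i]), 90.0, 240.0))
            d_tot = duration[i] + gap + duration[i + 1]
            md = max(max_depth[i], max_depth[i + 1])
            tt = np.linspace(0, d_tot, 11)
            knots_t = np.array([
                0.0, t_desc[i], t_desc[i] + bt[i], duration[i],
                duration[i] + gap,
                duration[i] + gap + t_desc[i + 1],
                duration[i] + gap + t_desc[i + 1] + bt[i + 1],
                d_tot,
            ])
            knots_d = np.array([
                0.0, max_depth[i], max_depth[i], 0.5, 0.5,
                max_depth[i + 1], max_depth[i + 1], 0.0,
            ])
            prof = np.interp(tt, knots_t, knots_d)
            records.append((animal_id, t_dive[i], d_tot, md, *prof))
            for j in (i, i + 1):
                truth_rows.append(
                    (animal_id, t_dive[j], "artefact_merged", cls[j], seg[j],
                     stbt_target[j], vd[j], va[j], max_depth[j],
                     float(bottom[j] - max_depth[j]))
                )
            i += 2
            continue
        prof = _profile_11pt(duration[i], max_depth[i], t_desc[i], bt[i], t_asc[i])
        records.append((animal_id, t_dive[i], duration[i], max_depth[i], *prof))
        truth_rows.append(
            (animal_id, t_dive[i], cls[i], cls[i], seg[i], stbt_target[i],
             vd[i], va[i], max_depth[i], float(bottom[i] - max_depth[i]))
        )
        i += 1

    # extra sub-threshold shallow dives (sensor-missed surfacings nearby)
    n_sh = rng.poisson(config.shallow_dive_prob * n_d)
    for ts in rng.uniform(0, total_s - 600, size=n_sh):
        if _interval_membership(np.array([ts]), ev)[0]:
            continue
        md = rng.uniform(1.0, 5.5)
        dur = rng.uniform(30.0, 90.0)
        prof = _profile_11pt(dur, md, dur * 0.4, dur * 0.2, dur * 0.4)
        records.append((animal_id, ts, dur, md, *prof))
        truth_rows.append((animal_id, ts, "artefact_shallow", "shallow", -1,
                           np.nan, np.nan, np.nan, md, np.nan))

    cols = ["animal_id", "start_s", "duration_s", "max_depth_m"] + [f"d{k}" for k in range(11)]
    dives = pd.DataFrame(records, columns=cols).sort_values("start_s", ignore_index=True)
    truth_dives = pd.DataFrame(
        truth_rows,
        columns=["animal_id", "start_s", "record_class", "dive_class", "segment",
                 "stbt_target", "descent_speed", "ascent_speed", "max_depth_m",
                 "bottom_distance_m"],
    ).sort_values("start_s", ignore_index=True)
    seg_rows = []
    for j in sorted(seg_cache):
        base, resting_j, ptac_j, neg_hs_j = seg_cache[j]
        mask = seg == j
        depth_mean = float(max_depth[mask].mean()) if mask.any() else np.nan
        seg_rows.append({
            "animal_id": animal_id, "time_s": t_nodes[j],
            "neg_hs_true": neg_hs_j, "resting": int(resting_j),
            "ptactic": ptac_j, "depth_mean": depth_mean,
            "stbt_true": float(np.clip(base + eff.depth * depth_mean,
                                       *config.stbt_clip))
            if np.isfinite(depth_mean) else np.nan,
        })
    truth_segments = pd.DataFrame(seg_rows)
    return dives, truth_dives, truth_segments


# ---------------------------------------------------------------------------
# full deployment

def simulate_dataset(config: SimConfig = None, seed: int = 0) -> SimData:
    """Simulate a full multi-animal deployment with ground truth."""
    config = (config or SimConfig()).validate()
    rng = np.random.default_rng(seed)
    bathy = simulate_bathymetry(config, rng)
    sites = _default_sites(config)
    eff = config.effects
    tracks, haulouts, dives = [], [], []
    t_states, t_dives, t_segs = [], [], []
    for a in range(config.n_animals):
        aid = f"a{a:02d}"
        u0 = rng.normal(0, eff.intercept_sd)
        u1 = rng.normal(0, eff.slope_sd)
        fixes, ho, truth = simulate_track(config, rng=rng, sites=sites, animal_id=aid)
        dv, td, ts = simulate_dives(truth, ho, bathy, config, rng=rng,
                                    animal_effects=(u0, u1))
        tracks.append(fixes)
        haulouts.append(ho)
        dives.append(dv)
        t_states.append(truth)
        t_dives.append(td)
        t_segs.append(ts)
    site_df = pd.DataFrame({"site_id": np.arange(len(sites)),
                            "x": sites[:, 0], "y": sites[:, 1]})
    return SimData(
        tracks=pd.concat(tracks, ignore_index=True),
        haulouts=pd.concat(haulouts, ignore_index=True),
        dives=pd.concat(dives, ignore_index=True),
        bathymetry=bathy,
        haulout_sites=site_df,
        truth_states=pd.concat(t_states, ignore_index=True),
        truth_dives=pd.concat(t_dives, ignore_index=True),
        truth_segments=pd.concat(t_segs, ignore_index=True),
        config=config,
    )


# ---------------------------------------------------------------------------
# direct model-table simulation (for the mixed-model stage)

def simulate_model_table(
    n_animals: int = 14,
    n_segments: int = 5000,
    effects: EffectSizes = None,
    direction_effects=(0.013, 0.006),  # inward, other (vs outward)
    hfi_depth: float = 0.001,
    resting_confounding: float = 1.0,
    seed: int = 0,
    clip: bool = False,
    standardize_effects: bool = False,
) -> pd.DataFrame:
    """Segment table drawn directly from the generative linear mixed model.

    Bypasses track and dive simulation: covariates are drawn from realistic
    marginal distributions (HS gamma with mean 0.37 m/s, depth gamma with
    mean 40 m) and stBT from the linear predictor with per-animal random
    intercept and hFI slope.  ``resting_confounding`` couples resting to the
    horizontal index (resting is more likely when the animal is slow), the
    mechanism that makes RestingD a confounder of the hFI slope.
    """
    eff = effects or EffectSizes()
    rng = np.random.default_rng(seed)
    u0s = rng.normal(0, eff.intercept_sd, size=n_animals)
    u1s = rng.normal(0, eff.slope_sd, size=n_animals)
    if standardize_effects and n_animals > 1:
        # rescale so the *realized* among-animal sds equal the nominal ones
        # (with few animals the sample variance of the draws is very noisy;
        # calibration tests target the stated variance, not sampling luck)
        for u, sd in ((u0s, eff.intercept_sd), (u1s, eff.slope_sd)):
            u -= u.mean()
            s = u.std(ddof=0)
            if s > 0:
                u *= sd / s
    rows = []
    for a in range(n_animals):
        u0 = u0s[a]
        u1 = u1s[a]
        hs = rng.gamma(1.6, 0.23, size=n_segments)
        neg_hs = -hs
        z = (neg_hs - neg_hs.mean()) / max(neg_hs.std(), 1e-9)
        p_rest = 1.0 / (1.0 + np.exp(-(-1.4 + resting_confounding * z)))
        resting = (rng.random(n_segments) < p_rest).astype(int)
        ptactic = (rng.random(n_segments) < 0.5).astype(int)
        depth = rng.gamma(4.0, 10.0, size=n_segments)
        direction = rng.choice(["outward", "inward", "other"], size=n_segments,
                               p=[0.4, 0.3, 0.3])
        d_in = (direction == "inward").astype(int)
        d_ot = (direction == "other").astype(int)
        stbt = (
            eff.intercept + u0
            + eff.resting * resting
            + eff.ptactic * ptactic
            + eff.depth * depth
            + (eff.hfi + u1) * neg_hs
            + eff.hfi_ptactic * neg_hs * ptactic
            + hfi_depth * neg_hs * depth
            + direction_effects[0] * d_in
            + direction_effects[1] * d_ot
            + rng.normal(0, eff.residual_sd, size=n_segments)
        )
        if clip:
            stbt = np.clip(stbt, 0.0, 1.0)
        mt = (hs < 0.4).astype(int)
        rt_h = np.clip(2.2 * 0.4 / np.maximum(hs, 0.02), 0.05, 24.0)
        rows.append(pd.DataFrame({
            "animal_id": f"a{a:02d}",
            "stBT": stbt,
            "neg_HS": neg_hs,
            "MT": mt,
            "invRT": -1000.0 / (rt_h * 3600.0),
            "Depth": depth,
            "RestingD": resting,
            "Ptactic": ptactic,
            "Direction": direction,
        }))
    return pd.concat(rows, ignore_index=True)
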