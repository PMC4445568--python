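"""Join dives to 20-min trajectory segments and build the model table.

A trajectory segment is the interval between two consecutive regular
nodes of a bout.  Dive metrics are averaged per segment (assignment by
dive start time), behavioural covariates aggregated by majority rules,
horizontal indices carried from the segment's start node, and the
transforms -HS and -1000/RT (RT in seconds) added so that an
intensification of search raises both indices.

Exclusion rules remove segments dominated by haul-out, surface or
shallow-diving time (> 50 %), segments within the residence-time radius
of a haul-out site, and segments in the 'transiting' or 'within_range'
direction categories; every excluded row carries exactly one primary
reason, and per-rule counts are logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .behaviour import classify_trip_direction, ptactic_per_segment
from .tracks import TrackParams, residence_time

__all__ = ["aggregate_dives", "apply_exclusions", "build_model_table",
           "coarsen_resolution"]

logger = logging.getLogger(__name__)

MODEL_COLUMNS = ["animal_id", "bout_id", "node", "time_s", "stBT", "Depth",
                 "RestingD", "Ptactic", "Direction", "HS", "MT", "RT",
                 "neg_HS", "invRT"]


def _overlap(intervals, t0, t1):
    """Total overlap of (start, end) intervals with [t0, t1)."""
    if len(intervals) == 0:
        return 0.0
    s = np.maximum(intervals[:, 0], t0)
    e = np.minimum(intervals[:, 1], t1)
    return float(np.clip(e - s, 0, None).sum())


def aggregate_dives(segments: pd.DataFrame, metrics: pd.DataFrame,
                    dt: float = 1200.0) -> pd.DataFrame:
    """Per-segment dive aggregates.

    ``segments`` needs animal_id, bout_id, node, time_s (the segment start);
    ``metrics`` the per-dive table with qc, stBT, max_depth_m, duration_s,
    benthic (1/0/-1 for unknown) and resting (0/1) columns.  Dives are
    assigned to the segment whose interval contains their start time.

    Returns ``segments`` with stBT, Depth, Ptactic, RestingD and the
    book-keeping columns dive_time_s (QC-ok non-shallow dive time) and
    submerged_time_s (all dive-record time) used by the exclusion rules.
    """
    out = segments.copy()
    n = len(out)
    stbt = np.full(n, np.nan)
    depth = np.full(n, np.nan)
    ptac = np.full(n, np.nan)
    restd = np.full(n, np.nan)
    dive_time = np.zeros(n)
    submerged = np.zeros(n)

    for aid, seg in out.groupby("animal_id", sort=False):
        dv = metrics[metrics["animal_id"] == aid]
        if dv.empty:
            continue
        t0 = seg["time_s"].to_numpy()
        order = np.argsort(t0)
        t_sorted = t0[order]
        ipos = out.index.get_indexer(seg.index)[order]  # global row positions
        starts = dv["start_s"].to_numpy()
        k = np.searchsorted(t_sorted, starts, side="right") - 1
        kc = np.clip(k, 0, None)
        in_seg = (k >= 0) & (starts - t_sorted[kc] < dt)
        target = ipos[kc]
        d_cap = np.minimum(dv["duration_s"].to_numpy(),
                           t_sorted[kc] + dt - starts)
        ok = (dv["qc"] == "ok").to_numpy()
        np.add.at(submerged, target[in_seg], d_cap[in_seg])
        np.add.at(dive_time, target[in_seg & ok], d_cap[in_seg & ok])

        sel = in_seg & ok
        if not sel.any():
            continue
        tmp = pd.DataFrame({
            "row": target[sel],
            "stBT": dv["stBT"].to_numpy()[sel],
            "depth": dv["max_depth_m"].to_numpy()[sel],
            "duration": dv["duration_s"].to_numpy()[sel],
            "benthic": (dv["benthic"].to_numpy()[sel] if "benthic" in dv
                        else np.full(sel.sum(), np.nan)),
            "resting": (dv["resting"].to_numpy()[sel] if "resting" in dv
                        else np.full(sel.sum(), np.nan)),
        })
        g = tmp.groupby("row")
        agg = g.agg(stBT=("stBT", "mean"), depth=("depth", "mean"))
        rows_ = agg.index.to_numpy()
        stbt[rows_] = agg["stBT"].to_numpy()
        depth[rows_] = agg["depth"].to_numpy()
        ptac[rows_] = g["benthic"].agg(ptactic_per_segment).to_numpy()
        rest_time = tmp["duration"].where(tmp["resting"] == 1, 0.0)
        rt_sum = rest_time.groupby(tmp["row"]).sum()
        t_sum = g["duration"].sum()
        restd[rows_] = (rt_sum / t_sum > 0.5).astype(float).to_numpy()

    out["stBT"] = stbt
    out["Depth"] = depth
    out["Ptactic"] = ptac
    out["RestingD"] = restd
    out["dive_time_s"] = dive_time
    out["submerged_time_s"] = submerged
    return out


def apply_exclusions(table: pd.DataFrame, dt: float = 1200.0) -> pd.DataFrame:
    """Flag excluded segments with one primary reason each.

    Rules, in order of precedence:

    1. ``inactive``: haul-out, surface or shallow-diving time exceeds 50 %
       of the segment (equivalently, submerged time in usable dive records
       is at most 50 %);
    2. ``near_haulout``: the segment's node lies within the residence-time
       radius of a haul-out site (RT undefined);
    3. ``direction``: Direction is 'transiting' or 'within_range';
    4. ``no_dives``: no usable dive, so the vertical index is missing.
    """
    out = table.copy()
    # haul-out, surface and shallow-dive time is everything not spent in
    # usable dive records (fully hauled-out segments have no dives at all)
    bad_time = dt - out["dive_time_s"].fillna(0)
    inactive = bad_time > 0.5 * dt
    near = out["RT"].isna()
    direction = out["Direction"].isin(["transiting", "within_range"])
    no_dives = out["stBT"].isna()

    reason = np.full(len(out), "", dtype=object)
    reason[no_dives.to_numpy()] = "no_dives"
    reason[direction.to_numpy()] = "direction"
    reason[near.to_numpy()] = "near_haulout"
    reason[inactive.to_numpy()] = "inactive"
    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    counts = pd.Series(reason[reason != ""]).value_counts().to_dict()
    logger.info("exclusions: %s of %d segments (%.0f %%): %s",
                int(out["excluded"].sum()), len(out),
                100 * out["excluded"].mean() if len(out) else 0, counts)
    return out


def build_model_table(regular: pd.DataFrame, metrics: pd.DataFrame,
                      haulouts: pd.DataFrame, haulout_sites: pd.DataFrame,
                      params: TrackParams = TrackParams(),
                      direction: pd.Series = None) -> pd.DataFrame:
    """Assemble the full per-segment model table.

    ``regular`` must carry HS, MT and RT; ``metrics`` the per-dive table
    with benthic and resting flags.  Haul-out overlap per segment is
    computed here for the activity exclusion rule.
    """
    segs = []
    for (aid, bid), grp in regular.groupby(["animal_id", "bout_id"], sort=False):
        grp = grp.sort_values("node")
        segs.append(grp.iloc[:-1])  # a segment starts at every non-final node
    if not segs:
        return pd.DataFrame(columns=MODEL_COLUMNS)
    seg = pd.concat(segs)
    if direction is None:
        direction = classify_trip_direction(regular, haulouts, haulout_sites,
                                            dt=params.dt)
    seg = seg.assign(Direction=direction.loc[seg.index])
    seg = aggregate_dives(seg, metrics, dt=params.dt)

    # haul-out overlap (events can start mid-segment)
    haul_t = np.zeros(len(seg))
    for aid, sub in seg.groupby("animal_id", sort=False):
        ev = haulouts[haulouts["animal_id"] == aid][["start_s", "end_s"]]
        iv = ev.to_numpy(dtype=float)
        pos = [seg.index.get_loc(i) for i in sub.index]
        for p_, t0 in zip(pos, sub["time_s"].to_numpy()):
            haul_t[p_] = _overlap(iv, t0, t0 + params.dt)
    seg["haulout_time_s"] = haul_t

    seg["neg_HS"] = -seg["HS"]
    with np.errstate(divide="ignore"):
        seg["invRT"] = -1000.0 / (seg["RT"] * 3600.0)
    seg = apply_exclusions(seg, dt=params.dt)
    return seg.reset_index(drop=True)


def coarsen_resolution(regular: pd.DataFrame, metrics: pd.DataFrame,
                       haulouts: pd.DataFrame, haulout_sites: pd.DataFrame,
                       p: int, params: TrackParams = TrackParams()) -> pd.DataFrame:
    """Model table at a coarser temporal resolution (every p-th node).

    Dive variables are averaged over the p constituent fine segments
    (majority for the binary ones); HS, RT and Direction are recomputed
    from the thinned trajectory; MT is the majority of the p fine-scale
    states (p must be odd so a majority always exists).  Incomplete
    trailing blocks are dropped.
    """
    if p % 2 == 0 or p < 1:
        raise ValueError("p must be an odd positive integer")
    coarse_params = TrackParams(
        max_error=params.max_error, sea_gap=params.sea_gap,
        haul_gap=params.haul_gap, min_bout=params.min_bout,
        dt=params.dt * p, rt_radius=params.rt_radius,
        rt_threshold=params.rt_threshold,
    )
    fine = build_model_table(regular, metrics, haulouts, haulout_sites, params)

    rows = []
    thin_all = []
    for (aid, bid), grp in regular.groupby(["animal_id", "bout_id"], sort=False):
        grp = grp.sort_values("node").reset_index(drop=True)
        thin = grp.iloc[::p].copy()
        if len(thin) < 2:
            continue
        thin["node"] = np.arange(len(thin))
        # HS from the thinned positions
        hs = np.full(len(thin), np.nan)
        hs[:-1] = np.hypot(np.diff(thin["x"].to_numpy()),
                           np.diff(thin["y"].to_numpy())) / coarse_params.dt
        thin["HS"] = hs
        thin_all.append(thin)
    if not thin_all:
        return pd.DataFrame(columns=MODEL_COLUMNS)
    thin = pd.concat(thin_all, ignore_index=True)
    thin["RT"] = residence_time(thin, coarse_params, haulout_sites)
    direction = classify_trip_direction(thin, haulouts, haulout_sites,
                                        dt=coarse_params.dt)
    thin = thin.assign(Direction=direction)

    for (aid, bid), grp in thin.groupby(["animal_id", "bout_id"], sort=False):
        grp = grp.sort_values("node")
        f = fine[(fine["animal_id"] == aid) & (fine["bout_id"] == bid)]
        f = f.sort_values("node").reset_index(drop=True)
        for j in range(len(grp) - 1):
            block = f.iloc[j * p:(j + 1) * p]
            if len(block) < p:
                continue
            row = grp.iloc[j]
            mt = int(block["MT"].sum() * 2 > len(block))
            rows.append({
                "animal_id": aid, "bout_id": bid, "node": row["node"],
                "time_s": row["time_s"], "x": row["x"], "y": row["y"],
                "stBT": block["stBT"].mean(),
                "Depth": block["Depth"].mean(),
                "RestingD": (float(block["RestingD"].mean() > 0.5)
                             if block["RestingD"].notna().any() else np.nan),
                "Ptactic": (float(block["Ptactic"].mean() > 0.5)
                            if block["Ptactic"].notna().any() else np.nan),
                "Direction": row["Direction"],
                "HS": row["HS"], "MT": mt, "RT": row["RT"],
                "dive_time_s": block["dive_time_s"].sum(),
                "submerged_time_s": block["submerged_time_s"].sum(),
                "haulout_time_s": block["haulout_time_s"].sum(),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["neg_HS"] = -out["HS"]
    with np.errstate(divide="ignore"):
        out["invRT"] = -1000.0 / (out["RT"] * 3600.0)
    out = apply_exclusions(out, dt=coarse_params.dt)
    return out
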