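"""Behavioural covariates: predatory tactic, trip direction, resting.

Three classifiers derive the behavioural covariates used in the models:

* **Predatory tactic** (benthic vs pelagic): each dive's distance to the
  sea bottom (bathymetry depth at the interpolated dive position minus
  maximum dive depth) is modelled with a mixture of 1-5 normal
  components; the component with mean closest to zero is the benthic
  one, and dives within its upper 95 % quantile (mean + 1.645 sd) are
  benthic.  Negative distances (dive deeper than the modelled bottom)
  are expected: dive location, bathymetry and tidal state all carry
  error.

* **Trip direction**: distance to the haul-out site is smoothed (running
  mean of its first differences over a 6-h window), trips are split
  where the smoothed difference changes sign, and sections are labelled
  outward / inward / within_range / transiting / other using a 2-km
  range around haul-out sites.

* **Resting while diving**: drifting rest dives have slow descents and
  fast ascents, so log dive skewness log(SK) jumps during rest bouts.  A
  penalized mean-shift changepoint segmentation (PELT) of the per-animal
  log(SK) series is followed by a two-component normal mixture over
  segment means; segments in the higher-mean component are resting.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "bottom_distance",
    "BenthicMixtureClassifier",
    "ptactic_per_segment",
    "classify_trip_direction",
    "pelt_mean_shift",
    "RestingDetector",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# benthic / pelagic

def bottom_distance(dives: pd.DataFrame, points: pd.DataFrame, bathymetry) -> pd.Series:
    """Distance (m) between each dive's maximum depth and the sea bottom.

    The dive position is linearly interpolated in time between the two
    bracketing GPS fixes (constant speed on a straight line); the bottom
    depth is the bathymetry value of the cell containing that position.
    Positive values lie above the bottom, negative below the modelled
    bottom.  Dives outside the fix span or the grid get NaN.
    """
    out = pd.Series(np.nan, index=dives.index, name="bottom_distance_m")
    for aid, dv in dives.groupby("animal_id", sort=False):
        fx = points[points["animal_id"] == aid].sort_values("time_s")
        if len(fx) < 2:
            continue
        t = fx["time_s"].to_numpy()
        td = dv["start_s"].to_numpy()
        ok = (td >= t[0]) & (td <= t[-1])
        x = np.interp(td, t, fx["x"].to_numpy())
        y = np.interp(td, t, fx["y"].to_numpy())
        bottom = np.asarray(bathymetry.depth_at(x, y))
        vals = bottom - dv["max_depth_m"].to_numpy()
        vals[~ok] = np.nan
        out.loc[dv.index] = vals
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.info("bottom_distance: %d dives unlocatable", n_missing)
    return out


class BenthicMixtureClassifier:
    """Benthic-dive classifier from the bottom-distance distribution.

    Fits normal mixtures with 1..max_components components (EM, multiple
    seeded starts), keeps the best by BIC, takes the component whose mean
    is closest to zero as the benthic bottom-distance distribution, and
    classifies dives at or below that component's upper 95 % quantile
    (mean + 1.645 sd, the closed normal form) as benthic.

    Attributes (after fit)
    ----------------------
    n_components_ : selected number of components.
    means_, sds_, weights_ : mixture parameters.
    benthic_component_ : index of the benthic component.
    threshold_ : benthic cutoff in metres.
    bic_ : BIC of the selected model.
    """

    def __init__(self, max_components=5, n_init=5, random_state=0,
                 quantile_z=1.645, min_samples=500):
        self.max_components = max_components
        self.n_init = n_init
        self.random_state = random_state
        self.quantile_z = quantile_z
        self.min_samples = min_samples

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("max_components", "n_init", "random_state", "quantile_z",
                 "min_samples")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, distances):
        from sklearn.mixture import GaussianMixture

        x = np.asarray(distances, dtype=float)
        x = x[np.isfinite(x)].reshape(-1, 1)
        if len(x) < self.min_samples:
            warnings.warn(
                f"only {len(x)} bottom distances (< {self.min_samples}); "
                "mixture fit may be unstable"
            )
        if len(x) < 2:
            raise ValueError("too few bottom distances to fit a mixture")
        best = None
        for k in range(1, self.max_components + 1):
            try:
                gm = GaussianMixture(
                    n_components=k, n_init=self.n_init,
                    random_state=self.random_state, reg_covar=1e-4,
                ).fit(x)
            except Exception as exc:  # pragma: no cover - EM failure is rare
                logger.info("mixture K=%d failed: %s", k, exc)
                continue
            bic = gm.bic(x)
            if best is None or bic < best[0]:
                best = (bic, k, gm)
        if best is None:
            raise RuntimeError("all mixture fits failed")
        self.bic_, self.n_components_, gm = best
        self.means_ = gm.means_.ravel()
        self.sds_ = np.sqrt(gm.covariances_.ravel())
        self.weights_ = gm.weights_.ravel()
        self.benthic_component_ = int(np.argmin(np.abs(self.means_)))
        self.threshold_ = float(
            self.means_[self.benthic_component_]
            + self.quantile_z * self.sds_[self.benthic_component_]
        )
        return self

    def predict(self, distances):
        """1 = benthic (distance <= threshold), 0 = pelagic; NaN-safe."""
        x = np.asarray(distances, dtype=float)
        out = np.where(x <= self.threshold_, 1, 0)
        return np.where(np.isfinite(x), out, -1)

    def fit_predict(self, distances):
        return self.fit(distances).predict(distances)


def ptactic_per_segment(benthic_flags) -> float:
    """Majority rule: 1 if more than 50 % of the segment's dives are
    benthic, 0 otherwise (exactly half -> 0); NaN for no dives."""
    flags = np.asarray(benthic_flags, dtype=float)
    flags = flags[np.isfinite(flags) & (flags >= 0)]
    if flags.size == 0:
        return np.nan
    return float(flags.mean() > 0.5)


# ---------------------------------------------------------------------------
# trip direction

def classify_trip_direction(regular: pd.DataFrame, haulouts: pd.DataFrame,
                            haulout_sites: pd.DataFrame,
                            window_h: float = 6.0, range_km: float = 2.0,
                            dt: float = 1200.0) -> pd.Series:
    """Direction label per regular node.

    Nodes between two haul-out events are assigned the site of the last
    and next events.  The first differences of the distance to the last
    site are smoothed with a centred running mean spanning ``window_h``
    hours; a trip is split into sections where the smoothed difference
    changes sign (boundary nodes join the following section), and each
    section is labelled:

    - ``outward``: increasing distance, starting within range of the last site
    - ``inward``: decreasing distance, ending within range of the next site
    - ``within_range``: section entirely within range of a site
    - ``transiting``: starts within range of one site, ends within range of
      the next, spanning the whole interval between haul-outs
    - ``other``: anything else
    """
    labels = pd.Series("other", index=regular.index, name="Direction")
    range_m = range_km * 1000.0
    sites = haulout_sites.set_index("site_id")[["x", "y"]]
    half = max(int(round(window_h * 3600.0 / dt / 2)), 1)

    for aid, grp in regular.groupby("animal_id", sort=False):
        ho = haulouts[haulouts["animal_id"] == aid].sort_values("start_s")
        if ho.empty:
            warnings.warn(f"animal {aid}: no haul-out events; all nodes 'other'")
            continue
        starts = ho["start_s"].to_numpy()
        ends = ho["end_s"].to_numpy()
        site_ids = ho["site_id"].to_numpy()
        grp = grp.sort_values(["bout_id", "time_s"])
        t = grp["time_s"].to_numpy()
        # index of previous / next haul-out event per node
        prev_i = np.searchsorted(ends, t, side="right") - 1
        next_i = np.searchsorted(starts, t, side="left")
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()

        last_xy = np.full((len(t), 2), np.nan)
        next_xy = np.full((len(t), 2), np.nan)
        okp = prev_i >= 0
        okn = next_i < len(starts)
        if okp.any():
            last_xy[okp] = sites.loc[site_ids[prev_i[okp]]].to_numpy()
        if okn.any():
            next_xy[okn] = sites.loc[site_ids[next_i[okn]]].to_numpy()
        # fall back to whichever side exists
        last_xy[~okp] = next_xy[~okp]
        next_xy[~okn] = last_xy[~okn]
        d_last = np.hypot(x - last_xy[:, 0], y - last_xy[:, 1])
        d_next = np.hypot(x - next_xy[:, 0], y - next_xy[:, 1])
        site_d = np.minimum(d_last, d_next)

        # process each inter-haul-out stretch of each bout separately
        key = pd.DataFrame({
            "bout": grp["bout_id"].to_numpy(), "trip": prev_i,
        })
        for (_, _), sel in key.groupby(["bout", "trip"], sort=False):
            pos = sel.index.to_numpy()  # positions into local arrays
            idx = grp.index.to_numpy()[pos]
            if len(pos) < 2:
                continue
            dd = np.diff(d_last[pos], prepend=d_last[pos][0])
            smooth = pd.Series(dd).rolling(2 * half + 1, center=True,
                                           min_periods=1).mean().to_numpy()
            sign = np.sign(smooth)
            # short zero runs are ties at a crossing and join the following
            # section; long zero runs (stationary phases) stand alone
            i = 0
            m = len(sign)
            while i < m:
                if sign[i] == 0:
                    j = i
                    while j < m and sign[j] == 0:
                        j += 1
                    if j - i <= 2:
                        fill = sign[j] if j < m else (sign[i - 1] if i else 1.0)
                        sign[i:j] = fill if fill != 0 else 1.0
                    i = j
                else:
                    i += 1
            # section boundaries at sign changes
            brk = np.nonzero(np.diff(sign) != 0)[0] + 1
            bounds = np.concatenate([[0], brk, [len(pos)]])
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                seg_pos = pos[b0:b1]
                seg_idx = idx[b0:b1]
                if np.all(site_d[seg_pos] <= range_m):
                    labels.loc[seg_idx] = "within_range"
                    continue
                starts_in = d_last[seg_pos[0]] <= range_m
                ends_in = d_next[seg_pos[-1]] <= range_m
                increasing = sign[b0:b1].mean() > 0
                if starts_in and ends_in and b0 == 0 and b1 == len(pos):
                    labels.loc[seg_idx] = "transiting"
                elif increasing and starts_in:
                    labels.loc[seg_idx] = "outward"
                elif (not increasing) and ends_in:
                    # multiple return trips between two haul-outs each get
                    # their own inward section
                    labels.loc[seg_idx] = "inward"
                else:
                    labels.loc[seg_idx] = "other"
    return labels


# ---------------------------------------------------------------------------
# resting while diving

def pelt_mean_shift(x, penalty=None, min_size=5):
    """PELT segmentation of a series under mean shifts (L2 cost).

    Cost of a segment is its sum of squared deviations from the segment
    mean; a changepoint costs ``penalty``.  The default penalty is the
    BIC-style ``2 * sigma^2 * log(n)`` with sigma estimated robustly from
    the median absolute first difference (noise-only under piecewise
    constant means).

    Returns the sorted list of changepoint indices (each index is the
    start of a new segment); an empty list means no shift.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_size:
        return []
    if penalty is None:
        # robust noise sd from first differences (mean shifts are sparse)
        diffs = np.abs(np.diff(x))
        sigma = np.median(diffs) / (np.sqrt(2) * 0.6745)
        if sigma <= 0:
            sigma = max(np.std(x), 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n)

    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i, j):
        # sum_{k=i..j-1} (x_k - mean)^2
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / (j - i)

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cands = [0]
    for tau in range(min_size, n + 1):
        s_new = tau - min_size
        if s_new > 0:
            cands.append(s_new)
        vals = {s: F[s] + cost(s, tau) + penalty for s in cands}
        best_s = min(vals, key=vals.get)
        F[tau] = vals[best_s]
        last[tau] = best_s
        # PELT pruning: s can never win again if even without the penalty
        # its path cost already exceeds the current optimum
        cands = [s for s in cands if vals[s] - penalty <= F[tau]]

    # backtrack
    cps = []
    tau = n
    while tau > 0:
        s = last[tau]
        if s > 0:
            cps.append(s)
        tau = s
    return sorted(cps)


class RestingDetector:
    """Detect resting-while-diving periods from log dive skewness.

    fit(x) segments a per-animal series of log(SK) values of consecutive
    dives with :func:`pelt_mean_shift`, then classifies segment means with
    a two-component normal mixture: the higher-mean component is resting.
    If the series is homogeneous (no changepoints, or component means
    closer than ``min_separation``) every dive is labelled active.

    Attributes (after fit)
    ----------------------
    changepoints_ : list of segment-start indices.
    segment_means_ : per-segment mean log(SK).
    segment_labels_ : per-segment 0 = active / 1 = resting.
    labels_ : per-dive 0/1 labels.
    """

    def __init__(self, penalty=None, min_size=5, min_separation=0.5,
                 min_series=50, random_state=0):
        self.penalty = penalty
        self.min_size = min_size
        self.min_separation = min_separation
        self.min_series = min_series
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("penalty", "min_size", "min_separation", "min_series",
                 "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, log_sk):
        from sklearn.mixture import GaussianMixture

        x = np.asarray(log_sk, dtype=float)
        n = len(x)
        self.labels_ = np.zeros(n, dtype=int)
        self.changepoints_ = []
        self.segment_means_ = np.array([np.nanmean(x)]) if n else np.array([])
        self.segment_labels_ = np.zeros(len(self.segment_means_), dtype=int)
        if n < self.min_series:
            warnings.warn(f"log(SK) series of length {n} < {self.min_series}; "
                          "all dives labelled active")
            return self
        filled = np.where(np.isfinite(x), x, np.nanmedian(x))
        self.changepoints_ = pelt_mean_shift(filled, self.penalty, self.min_size)
        bounds = [0] + list(self.changepoints_) + [n]
        means = np.array([filled[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
        self.segment_means_ = means
        self.segment_labels_ = np.zeros(len(means), dtype=int)
        if len(means) >= 2:
            gm = GaussianMixture(n_components=2, n_init=5,
                                 random_state=self.random_state,
                                 reg_covar=1e-6).fit(means.reshape(-1, 1))
            mu = gm.means_.ravel()
            if abs(mu.max() - mu.min()) >= self.min_separation:
                hi = int(np.argmax(mu))
                comp = gm.predict(means.reshape(-1, 1))
                self.segment_labels_ = (comp == hi).astype(int)
        for lab, a, b in zip(self.segment_labels_, bounds[:-1], bounds[1:]):
            self.labels_[a:b] = lab
        return self

    def fit_predict(self, log_sk):
        return self.fit(log_sk).labels_


def detect_resting(metrics: pd.DataFrame, **kwargs) -> pd.Series:
    """Per-dive resting flag across animals (QC-ok dives with valid SK).

    Runs a :class:`RestingDetector` on each animal's consecutive log(SK)
    series; dives without a valid SK (or failing QC) are labelled 0.
    """
    out = pd.Series(0, index=metrics.index, dtype=int, name="resting")
    for aid, grp in metrics.groupby("animal_id", sort=False):
        grp = grp.sort_values("start_s")
        valid = grp[np.isfinite(grp["log_SK"])]
        if valid.empty:
            continue
        det = RestingDetector(**kwargs)
        out.loc[valid.index] = det.fit_predict(valid["log_SK"].to_numpy())
    return out
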