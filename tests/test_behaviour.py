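"""Behavioural covariates: benthic mixture, trip direction, resting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import forage3d as f3
from forage3d.bathymetry import BathymetryGrid
from forage3d.behaviour import (
    BenthicMixtureClassifier,
    RestingDetector,
    bottom_distance,
    classify_trip_direction,
    pelt_mean_shift,
    ptactic_per_segment,
)


class TestBottomDistance:
    def _grid(self):
        return BathymetryGrid(np.full((10, 10), 50.0), cell_size=100.0)

    def test_dive_at_fix_simple_arithmetic(self):
        fixes = pd.DataFrame({"animal_id": "a00", "time_s": [0.0, 600.0],
                              "x": [450.0, 450.0], "y": [450.0, 450.0]})
        dives = pd.DataFrame({"animal_id": ["a00"], "start_s": [0.0],
                              "max_depth_m": [47.0]})
        d = bottom_distance(dives, fixes, self._grid())
        assert d.iloc[0] == pytest.approx(3.0)

    def test_midpoint_interpolation_between_fixes(self):
        grid = BathymetryGrid(
            np.tile(np.linspace(10, 100, 10), (10, 1)), cell_size=100.0)
        fixes = pd.DataFrame({"animal_id": "a00", "time_s": [0.0, 1000.0],
                              "x": [50.0, 950.0], "y": [450.0, 450.0]})
        dives = pd.DataFrame({"animal_id": ["a00"], "start_s": [500.0],
                              "max_depth_m": [10.0]})
        d = bottom_distance(dives, fixes, grid)
        # midpoint x = 500 falls in column 5: depth 60
        assert d.iloc[0] == pytest.approx(60.0 - 10.0)

    def test_deeper_than_bottom_is_negative(self):
        fixes = pd.DataFrame({"animal_id": "a00", "time_s": [0.0, 600.0],
                              "x": [450.0, 450.0], "y": [450.0, 450.0]})
        dives = pd.DataFrame({"animal_id": ["a00"], "start_s": [100.0],
                              "max_depth_m": [52.0]})
        d = bottom_distance(dives, fixes, self._grid())
        assert d.iloc[0] == pytest.approx(-2.0)

    def test_outside_grid_or_span_is_missing(self):
        fixes = pd.DataFrame({"animal_id": "a00", "time_s": [0.0, 600.0],
                              "x": [450.0, 450.0], "y": [450.0, 450.0]})
        dives = pd.DataFrame({"animal_id": ["a00", "a00"],
                              "start_s": [5000.0, 100.0],
                              "max_depth_m": [10.0, 10.0]})
        d = bottom_distance(dives, fixes, self._grid())
        assert np.isnan(d.iloc[0]) and np.isfinite(d.iloc[1])


class TestBenthicMixture:
    def test_two_component_recovery_and_closed_form_threshold(self):
        """0.5 N(-3, 2^2) + 0.5 N(20, 10^2): recovered means within 0.5,
        threshold within 0.3 of the closed form -3 + 1.645*2 = 0.29."""
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-3, 2, 2500), rng.normal(20, 10, 2500)])
        clf = BenthicMixtureClassifier(random_state=0).fit(x)
        k = clf.benthic_component_
        assert clf.means_[k] == pytest.approx(-3.0, abs=0.5)
        other = np.argmax(clf.means_)
        assert clf.means_[other] == pytest.approx(20.0, abs=1.0)
        assert clf.threshold_ == pytest.approx(0.29, abs=0.3)

    def test_threshold_equals_mean_plus_z_sd(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-3, 2, 2000), rng.normal(25, 8, 2000)])
        clf = BenthicMixtureClassifier(random_state=0).fit(x)
        k = clf.benthic_component_
        closed = clf.means_[k] + 1.645 * clf.sds_[k]
        assert clf.threshold_ == pytest.approx(closed, abs=1e-12)
        # and matches the numerical normal quantile
        num = stats.norm.ppf(0.95, clf.means_[k], clf.sds_[k])
        assert clf.threshold_ == pytest.approx(num, abs=1e-3)

    def test_single_tight_component(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.0, 0.5, 1000)
        clf = BenthicMixtureClassifier(random_state=0).fit(x)
        assert clf.n_components_ == 1
        assert clf.predict(x).mean() >= 0.90

    def test_prediction_rule(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(-3, 2, 2000), rng.normal(25, 8, 2000)])
        clf = BenthicMixtureClassifier(random_state=0).fit(x)
        pred = clf.predict(np.array([clf.threshold_ - 0.01,
                                     clf.threshold_ + 0.01, np.nan]))
        assert list(pred[:2]) == [1, 0] and pred[2] == -1

    def test_too_few_samples_warns(self):
        with pytest.warns(UserWarning, match="bottom distances"):
            BenthicMixtureClassifier(random_state=0).fit(np.r_[-3.0, 0.0, 1.0, 20.0])


class TestPtacticMajority:
    @pytest.mark.parametrize("flags,expected", [
        ([1, 1, 1, 0], 1.0),
        ([1, 1, 0, 0], 0.0),  # exact tie breaks to pelagic
        ([], np.nan),
    ])
    def test_majority_rule(self, flags, expected):
        got = ptactic_per_segment(flags)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected


def _regular(times, x, y, animal="a00", bout=0):
    return pd.DataFrame({
        "animal_id": animal, "bout_id": bout,
        "node": np.arange(len(times)), "time_s": times,
        "x": x, "y": y, "HS": 0.1,
    })


class TestTripDirection:
    def _setup(self, path_km):
        """Track moving along x from the site per the given km waypoints."""
        dt = 1200.0
        n = len(path_km)
        times = np.arange(n) * dt
        reg = _regular(times, np.asarray(path_km) * 1000.0, np.zeros(n))
        ho = pd.DataFrame({"animal_id": ["a00", "a00"],
                           "start_s": [-7200.0, times[-1] + 1200.0],
                           "end_s": [-600.0, times[-1] + 7200.0],
                           "site_id": [0, 0]})
        sites = pd.DataFrame({"site_id": [0], "x": [0.0], "y": [0.0]})
        return reg, ho, sites

    def test_out_and_return_trip(self):
        # leave the site to 8 km, sit still for 10 h, come back; the still
        # phase (longer than the smoothing window) is its own section
        out = np.linspace(0.5, 8, 10)
        still = np.full(30, 8.0)
        back = np.linspace(8, 0.5, 10)
        reg, ho, sites = self._setup(np.concatenate([out, still, back]))
        lab = classify_trip_direction(reg, ho, sites)
        assert (lab.iloc[:8] == "outward").all()
        assert (lab.iloc[20:29] == "other").all()
        assert (lab.iloc[-8:] == "inward").all()

    def test_whole_trip_within_range(self):
        reg, ho, sites = self._setup(np.full(20, 1.5))
        lab = classify_trip_direction(reg, ho, sites)
        assert (lab == "within_range").all()

    def test_no_haulouts_all_other(self):
        reg, _, sites = self._setup(np.linspace(0.5, 8, 20))
        ho = pd.DataFrame(columns=["animal_id", "start_s", "end_s", "site_id"])
        with pytest.warns(UserWarning, match="no haul-out"):
            lab = classify_trip_direction(reg, ho, sites)
        assert (lab == "other").all()

    def test_sections_partition_and_anchor_rules(self):
        """On a noisy trip, sections partition the nodes; every outward
        section starts within 2 km of the site and every inward section
        ends within 2 km of it."""
        rng = np.random.default_rng(3)
        base = np.concatenate([
            np.linspace(0.5, 9, 14), 9 + np.cumsum(rng.normal(0, 0.3, 20)),
            np.linspace(9, 0.5, 14)])
        reg, ho, sites = self._setup(base)
        lab = classify_trip_direction(reg, ho, sites)
        assert lab.notna().all()
        d = np.abs(reg["x"].to_numpy())
        for sec_label, idx in lab.groupby(lab).groups.items():
            pass
        # outward runs start near the site; inward runs end near it
        arr = lab.to_numpy()
        runs = []
        start = 0
        for i in range(1, len(arr) + 1):
            if i == len(arr) or arr[i] != arr[start]:
                runs.append((arr[start], start, i - 1))
                start = i
        for label, a, b in runs:
            if label == "outward":
                assert d[a] <= 2000.0
            if label == "inward":
                assert d[b] <= 2000.0

    def test_matches_hand_computed_running_mean_sections(self):
        """Sections equal those from an independently computed centred
        running mean of the distance differences (30-node fixture with
        sub-window oscillations)."""
        dt = 1200.0
        x_km = np.array([
            0.5, 1.0, 1.6, 1.4, 2.2, 2.9, 2.7, 3.5, 4.1, 3.9,
            4.8, 5.5, 5.3, 6.0, 6.6, 6.4, 6.2, 5.6, 5.8, 5.0,
            4.4, 4.6, 3.8, 3.2, 3.4, 2.6, 2.0, 2.2, 1.4, 0.6])
        reg, ho, sites = self._setup(x_km)
        lab = classify_trip_direction(reg, ho, sites, window_h=6.0)
        # independent computation: pandas-free rolling mean via convolution
        d = x_km * 1000.0
        dd = np.diff(d, prepend=d[0])
        half = 9  # 6 h window at 20-min nodes -> 19-node centred window
        sm = np.array([
            dd[max(0, i - half):i + half + 1].mean() for i in range(len(dd))])
        sign = np.where(sm >= 0, 1.0, -1.0)
        brk = np.nonzero(np.diff(sign) != 0)[0] + 1
        bounds = [0, *brk, len(d)]
        expect = np.empty(len(d), dtype=object)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if sign[a] > 0:
                expect[a:b] = "outward" if d[a] <= 2000 else "other"
            else:
                expect[a:b] = "inward" if d[b - 1] <= 2000 else "other"
        assert list(lab) == list(expect)


class TestChangepoints:
    def test_single_mean_shift_located(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(1.5, 0.2, 100)])
        cps = pelt_mean_shift(x)
        assert len(cps) == 1
        assert abs(cps[0] - 100) <= 2

    def test_homogeneous_series_no_changepoints(self):
        rng = np.random.default_rng(1)
        assert pelt_mean_shift(rng.normal(0, 0.2, 200)) == []

    def test_multiple_shifts(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.2, 80), rng.normal(1.5, 0.2, 60),
                            rng.normal(0.2, 0.2, 80)])
        cps = pelt_mean_shift(x)
        assert len(cps) == 2
        assert abs(cps[0] - 80) <= 2 and abs(cps[1] - 140) <= 2

    def test_short_series_returns_nothing(self):
        assert pelt_mean_shift(np.zeros(6), min_size=5) == []


class TestRestingDetector:
    def test_shifted_block_classified_resting(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(1.5, 0.2, 100)])
        det = RestingDetector(random_state=0).fit(x)
        assert len(det.changepoints_) == 1
        assert abs(det.changepoints_[0] - 100) <= 2
        assert det.labels_[:98].sum() == 0
        assert det.labels_[102:].mean() == 1.0

    def test_homogeneous_series_all_active(self):
        rng = np.random.default_rng(4)
        det = RestingDetector(random_state=0).fit(rng.normal(0, 0.2, 200))
        assert det.labels_.sum() == 0

    def test_short_series_warns_all_active(self):
        with pytest.warns(UserWarning, match="series"):
            det = RestingDetector(random_state=0).fit(np.zeros(10))
        assert det.labels_.sum() == 0

    def test_recall_precision_on_synthetic_dives(self, sim_data, analysis,
                                                 dive_truth_merged):
        """Per-dive resting recall and precision >= 0.9 against the
        generator's labels at default effect sizes."""
        m = dive_truth_merged
        truth = (m["record_class"] == "resting").to_numpy()
        pred = (m["resting"] == 1).to_numpy()
        recall = (pred & truth).sum() / truth.sum()
        precision = (pred & truth).sum() / max(pred.sum(), 1)
        assert recall >= 0.9
        assert precision >= 0.9


class TestEndToEndClassification:
    def test_dive_class_balanced_accuracy(self, dive_truth_merged):
        """Benthic / pelagic / resting recovery >= 0.9 balanced accuracy on
        artefact-bearing synthetic data (QC-passing dives)."""
        from sklearn.metrics import balanced_accuracy_score

        m = dive_truth_merged
        pred = np.where(m["resting"] == 1, "resting",
                        np.where(m["benthic"] == 1, "benthic", "pelagic"))
        assert balanced_accuracy_score(m["record_class"], pred) >= 0.90
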