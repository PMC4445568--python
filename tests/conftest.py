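"""Shared fixtures: one small synthetic deployment reused across tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import forage3d as f3

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    return f3.SimConfig(n_animals=3, days=10.0)


@pytest.fixture(scope="session")
def sim_data(small_config):
    """One 3-animal, 10-day synthetic deployment (default artefact rates)."""
    return f3.simulate_dataset(small_config, seed=11)


@pytest.fixture(scope="session")
def analysis(sim_data):
    """Full processing/classification run on the shared deployment."""
    return f3.run_analysis(
        sim_data.tracks, sim_data.dives, sim_data.haulouts,
        sim_data.bathymetry, sim_data.haulout_sites, random_state=0,
    )


@pytest.fixture(scope="session")
def dive_truth_merged(sim_data, analysis):
    """QC-ok dive metrics joined to ground-truth dive classes."""
    ok = analysis.metrics[analysis.metrics["qc"] == "ok"]
    merged = ok.merge(sim_data.truth_dives, on=["animal_id", "start_s"],
                      suffixes=("", "_t"))
    return merged[merged["record_class"].isin(["benthic", "pelagic", "resting"])]


def make_dive(duration, max_depth, profile=None, animal_id="a00", start_s=0.0):
    """One dive row in the tag's wide format."""
    if profile is None:
        # symmetric v-dive
        tt = np.linspace(0, duration, 11)
        profile = np.interp(tt, [0, duration / 2, duration],
                            [0, max_depth, 0])
    row = {"animal_id": animal_id, "start_s": start_s,
           "duration_s": float(duration), "max_depth_m": float(max_depth)}
    row.update({f"d{k}": float(profile[k]) for k in range(11)})
    return pd.Series(row)


def trapezoid_dive(max_depth, t_desc, bt, t_asc, **kw):
    """Trapezoidal dive sampled at 11 equally spaced times."""
    duration = t_desc + bt + t_asc
    tt = np.linspace(0, duration, 11)
    profile = np.interp(tt, [0, t_desc, t_desc + bt, duration],
                        [0, max_depth, max_depth, 0])
    return make_dive(duration, max_depth, profile, **kw)
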