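"""End-to-end orchestration: simulate -> process -> classify -> assemble -> fit.

`run_analysis` takes the four tag inputs (tracks, dives, haul-outs,
bathymetry plus haul-out sites) and returns every intermediate product up
to the model table; `run_pipeline` adds simulation, model fitting, file
output and a JSON run manifest, and backs the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assemble import build_model_table, coarsen_resolution
from .bathymetry import BathymetryGrid, write_ascii_grid
from .behaviour import BenthicMixtureClassifier, bottom_distance, detect_resting
from .dives import DiveThresholds, compute_dive_metrics
from .models import ForagingModel
from .simulate import SimConfig, SimData, simulate_dataset
from .tracks import TrackParams, process_tracks

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass
class AnalysisResult:
    """All intermediate products of one analysis run."""

    metrics: pd.DataFrame  # per-dive QC + vertical indices + classes
    regular: pd.DataFrame  # regular track with HS, MT, RT
    table: pd.DataFrame  # model table (with exclusion flags)
    benthic_classifier: BenthicMixtureClassifier
    coarse_tables: dict = field(default_factory=dict)

    @property
    def model_table(self) -> pd.DataFrame:
        """Retained (non-excluded) rows, ready for model fitting."""
        return self.table[~self.table["excluded"]].reset_index(drop=True)


def run_analysis(tracks: pd.DataFrame, dives: pd.DataFrame,
                 haulouts: pd.DataFrame, bathymetry: BathymetryGrid,
                 haulout_sites: pd.DataFrame,
                 dive_thresholds: DiveThresholds = DiveThresholds(),
                 track_params: TrackParams = TrackParams(),
                 coarsen: tuple = (),
                 random_state: int = 0) -> AnalysisResult:
    """Run the processing and classification stages on tag data.

    Steps: dive QC and vertical indices; track filtering, regularization,
    movement states, residence time; benthic/pelagic mixture and resting
    changepoint classification; covariate assembly with exclusions.
    ``coarsen`` lists the odd factors p for additional coarse tables.
    """
    metrics = compute_dive_metrics(dives, dive_thresholds)
    regular = process_tracks(tracks, haulouts, haulout_sites, track_params,
                             random_state=random_state)
    ok = metrics["qc"] == "ok"
    dist = bottom_distance(metrics, tracks[tracks["error_m"] <= track_params.max_error]
                           if "error_m" in tracks else tracks, bathymetry)
    metrics["bottom_distance_m"] = dist
    clf = BenthicMixtureClassifier(random_state=random_state)
    clf.fit(dist[ok])
    metrics["benthic"] = clf.predict(dist)
    metrics.loc[~ok, "benthic"] = -1
    metrics["resting"] = detect_resting(metrics[ok]).reindex(
        metrics.index, fill_value=0)
    table = build_model_table(regular, metrics, haulouts, haulout_sites,
                              track_params)
    coarse = {}
    for p in coarsen:
        coarse[p] = coarsen_resolution(regular, metrics, haulouts,
                                       haulout_sites, p, track_params)
    return AnalysisResult(metrics=metrics, regular=regular, table=table,
                          benthic_classifier=clf, coarse_tables=coarse)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict):
    df.to_csv(path, index=False, float_format="%.6g")
    manifest["outputs"][path.name] = {"sha256": _sha256(path), "rows": len(df)}


def run_pipeline(config: SimConfig = None, seed: int = 0, outdir=None,
                 hfis: tuple = ("neg_HS",), fit_kwargs: dict = None,
                 dive_thresholds: DiveThresholds = DiveThresholds(),
                 track_params: TrackParams = TrackParams(),
                 data: SimData = None) -> dict:
    """Full seeded pipeline on synthetic (or supplied) data.

    Returns a manifest dict; if ``outdir`` is given, writes all stage
    outputs (CSV / ASCII grid / JSON) there.
    """
    manifest = {"version": __version__, "seed": seed, "outputs": {},
                "counts": {}}
    if data is None:
        config = config or SimConfig()
        data = simulate_dataset(config, seed=seed)
    manifest["counts"]["fixes"] = len(data.tracks)
    manifest["counts"]["dives"] = len(data.dives)

    result = run_analysis(data.tracks, data.dives, data.haulouts,
                          data.bathymetry, data.haulout_sites,
                          dive_thresholds, track_params, random_state=seed)
    qc_counts = result.metrics["qc"].value_counts().to_dict()
    manifest["counts"]["dive_qc"] = qc_counts
    manifest["counts"]["segments"] = len(result.table)
    manifest["counts"]["segments_retained"] = int((~result.table["excluded"]).sum())
    manifest["counts"]["exclusions"] = (
        result.table.loc[result.table["excluded"], "exclusion_reason"]
        .value_counts().to_dict())

    fits = {}
    fit_kwargs = dict(fit_kwargs or {})
    table = result.model_table
    for hfi in hfis:
        model = ForagingModel(hfi=hfi, random_state=seed, **fit_kwargs)
        try:
            model.fit(table)
        except Exception as exc:
            warnings.warn(f"model fit for {hfi} failed: {exc}")
            continue
        fits[hfi] = model
        manifest.setdefault("models", {})[hfi] = {
            "structure": model.structure_,
            "terms": model.terms_,
            "params": {k: float(v) for k, v in model.params_.items()},
            "boot_se": {k: float(v) for k, v in model.boot_se_.items()},
            "r2_marginal": float(model.r2_marginal_),
            "r2_conditional": float(model.r2_conditional_),
        }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(data.tracks, out / "tracks.csv", manifest)
        _write_csv(data.dives, out / "dives.csv", manifest)
        _write_csv(data.haulouts, out / "haulouts.csv", manifest)
        _write_csv(data.haulout_sites, out / "haulout_sites.csv", manifest)
        _write_csv(data.truth_dives, out / "truth_dives.csv", manifest)
        _write_csv(result.metrics, out / "dive_metrics.csv", manifest)
        _write_csv(result.regular, out / "regular_track.csv", manifest)
        _write_csv(result.table, out / "model_table.csv", manifest)
        write_ascii_grid(data.bathymetry, out / "bathymetry.asc")
        manifest["outputs"]["bathymetry.asc"] = {
            "sha256": _sha256(out / "bathymetry.asc")}
        for hfi, model in fits.items():
            coefs = pd.DataFrame({"estimate": model.params_,
                                  "boot_se": model.boot_se_})
            _write_csv(coefs.reset_index(names="term"),
                       out / f"coefficients_{hfi}.csv", manifest)
            _write_csv(model.trace_, out / f"selection_trace_{hfi}.csv",
                       manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_fits"] = fits
    manifest["_result"] = result
    manifest["_data"] = data
    return manifest
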