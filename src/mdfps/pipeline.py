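"""Two-period country workflow: configuration, stage orchestration, manifest.

The pipeline mirrors the analysis design this package implements: simulate
(optional) -> indicator -> design-weighted descriptives -> multilevel model
(latest period) -> geostatistical model (both periods) -> post-processing
into area summaries, WHO-threshold exceedance probabilities and
between-period change. Every stage's outputs, seeds and wall times are
recorded in a manifest so deterministic stages can be re-run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import SurveyDataset, aggregate_cluster_counts
from .descriptives import descriptives_table
from .geometry import AdminUnits
from .geostat import GeostatBinomial
from .indicator import MethodVocabulary, apply_indicator
from .multilevel import MultilevelLogistic
from .postprocess import (
    area_table,
    change_analysis,
    change_table,
    classify_progress,
    summarize_area,
    aggregate_area,
)
from .rasters import CovariateStack, write_ascii_grid
from .synthetic import GroundTruth, simulate_bundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ["simulate", "indicator", "descriptives", "multilevel", "geostat", "postprocess"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": type(self.cause).__name__, "message": str(self.cause)}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    periods: list[str]
    simulate: dict | None = None
    inputs: dict | None = None  # period -> directory with women_/clusters_ CSVs + rasters
    indicator: dict = field(default_factory=dict)
    descriptives: dict = field(default_factory=dict)
    multilevel: dict = field(default_factory=dict)
    geostat: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.periods) != 2 or self.periods[0] == self.periods[1]:
            raise ValueError("exactly two distinct period labels are required")
        if self.simulate is None and self.inputs is None:
            raise ValueError("either a simulate block or an inputs block is required")
        if self.inputs is not None:
            for period in self.periods:
                d = self.inputs.get(period)
                if d is None or not os.path.isdir(d):
                    raise ValueError(f"inputs for period {period!r} missing or not a directory")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the workflow and return the run manifest (also written to disk)."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "periods": config.periods,
        "stages": {},
        "outputs": [],
        "input_checksums": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        if name not in stages and name != "load":
            return
        t0 = time.perf_counter()
        try:
            produced = fn() or []
        except Exception as exc:  # noqa: BLE001 - converted to a stage-tagged error
            err = PipelineError(name, exc)
            with open(os.path.join(out, "error.json"), "w") as fh:
                json.dump(err.record(), fh, indent=2)
            raise err from exc
        manifest["stages"][name] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": produced,
        }
        manifest["outputs"].extend(produced)

    # ---- simulate or load ------------------------------------------------
    def stage_simulate():
        sim = dict(config.simulate or {})
        truth = GroundTruth(**sim.pop("truth"))
        bundle = simulate_bundle(truth, periods=tuple(config.periods), **sim)
        state["bundle"] = bundle
        produced = []
        for period, survey in bundle.surveys.items():
            survey.write(out)
            produced += [f"women_{period}.csv", f"clusters_{period}.csv"]
            bundle.covariates[period].write(out, prefix=f"{period}_")
            produced += [f"{period}_{nm}.asc" for nm in bundle.covariates[period].names]
            produced += [f"{period}_stack.yaml"]
        bundle.admin_units.to_geojson(os.path.join(out, "admin.geojson"))
        truth.to_yaml(os.path.join(out, "truth.yaml"))
        produced += ["admin.geojson", "truth.yaml"]
        return produced

    def stage_load():
        surveys, stacks = {}, {}
        for period in config.periods:
            d = config.inputs[period]
            surveys[period] = SurveyDataset.read(d, period)
            stacks[period] = CovariateStack.read(d, prefix=f"{period}_")
            for fn in os.listdir(d):
                manifest["input_checksums"][fn] = _sha256(os.path.join(d, fn))
        admin = AdminUnits.from_geojson(os.path.join(config.inputs[config.periods[0]], "admin.geojson"))
        from .synthetic import SyntheticSurveyBundle

        state["bundle"] = SyntheticSurveyBundle(
            surveys=surveys, admin_units=admin, covariates=stacks,
            truth=GroundTruth(beta={"intercept": 0.0}),
        )

    if config.simulate is not None:
        run_stage("simulate", stage_simulate)
    else:
        stage_load()
    bundle = state["bundle"]

    # ---- indicator -------------------------------------------------------
    def stage_indicator():
        vocab_path = config.indicator.get("vocabulary")
        vocab = MethodVocabulary.from_yaml(vocab_path) if vocab_path else MethodVocabulary.default()
        rule = config.indicator.get("pregnancy_rule", "no_demand")
        produced = []
        state["indicator"] = {}
        for period, survey in bundle.surveys.items():
            res, report = apply_indicator(survey.women, vocab, rule)
            state["indicator"][period] = res
            res.to_csv(os.path.join(out, f"indicator_{period}.csv"), index=False)
            with open(os.path.join(out, f"indicator_report_{period}.json"), "w") as fh:
                json.dump(report, fh, indent=2)
            produced += [f"indicator_{period}.csv", f"indicator_report_{period}.json"]
        return produced

    run_stage("indicator", stage_indicator)

    # ---- descriptives ----------------------------------------------------
    def stage_descriptives():
        groupings = config.descriptives.get(
            "groupings",
            ["residence", "age_group", "education", "wealth_quintile"],
        )
        produced = []
        for period, survey in bundle.surveys.items():
            table = descriptives_table(survey, state["indicator"][period], groupings)
            table.to_csv(os.path.join(out, f"coverage_{period}.csv"), index=False)
            produced.append(f"coverage_{period}.csv")
        return produced

    if "indicator" in state:
        run_stage("descriptives", stage_descriptives)

    # ---- multilevel (latest period) --------------------------------------
    def stage_multilevel():
        period = config.periods[-1]
        params = dict(config.multilevel)
        params.setdefault("seed", config.seed)
        model = MultilevelLogistic(**params).fit(bundle.surveys[period], state["indicator"][period])
        state["multilevel"] = model
        table = model.summarize()
        table.to_csv(os.path.join(out, "multilevel_or.csv"), index=False)
        np.save(os.path.join(out, "multilevel_beta_draws.npy"), model.beta_draws_)
        with open(os.path.join(out, "multilevel_diagnostics.json"), "w") as fh:
            json.dump(model.diagnostics_, fh, indent=2)
        return ["multilevel_or.csv", "multilevel_beta_draws.npy", "multilevel_diagnostics.json"]

    if "indicator" in state:
        run_stage("multilevel", stage_multilevel)

    # ---- geostat (both periods) ------------------------------------------
    def stage_geostat():
        params = dict(config.geostat)
        n_surface_draws = params.pop("n_surface_draws", 200)
        produced = []
        state["surfaces"] = {}
        for j, period in enumerate(config.periods):
            p = dict(params)
            p.setdefault("seed", config.seed + j)
            counts = aggregate_cluster_counts(bundle.surveys[period], state["indicator"][period])
            model = GeostatBinomial(**p).fit(counts, bundle.covariates[period])
            surface = model.predict_surface(
                bundle.covariates[period],
                admin=bundle.admin_units,
                n_draws=n_surface_draws,
                seed=config.seed + 100 + j,
                period=period,
            )
            state["surfaces"][period] = surface
            model.summarize().to_csv(os.path.join(out, f"geostat_params_{period}.csv"), index=False)
            write_ascii_grid(
                os.path.join(out, f"prevalence_mean_{period}.asc"),
                surface.grid,
                surface.mean_map(),
            )
            np.save(os.path.join(out, f"surface_samples_{period}.npy"), surface.samples)
            with open(os.path.join(out, f"surface_grid_{period}.json"), "w") as fh:
                json.dump(
                    {"grid": surface.grid.signature(), "n_draws": surface.n_draws,
                     "period": period},
                    fh,
                )
            produced += [
                f"geostat_params_{period}.csv",
                f"prevalence_mean_{period}.asc",
                f"surface_samples_{period}.npy",
                f"surface_grid_{period}.json",
            ]
        return produced

    if "indicator" in state:
        run_stage("geostat", stage_geostat)

    # ---- postprocess ------------------------------------------------------
    def stage_postprocess():
        thr = config.thresholds
        t = thr.get("who_target", 0.75)
        hi, lo = thr.get("progress_hi", 0.9), thr.get("progress_lo", 0.1)
        produced = []
        for period, surface in state["surfaces"].items():
            area_samples, national = aggregate_area(surface, bundle.admin_units)
            summaries = summarize_area(area_samples, t=t, period=period)
            nat = summarize_area({-1: national}, t=t, period=period)
            area_table(summaries + nat).to_csv(
                os.path.join(out, f"area_summary_{period}.csv"), index=False
            )
            write_ascii_grid(
                os.path.join(out, f"ep_{period}.asc"), surface.grid, surface.exceedance_map(t)
            )
            produced += [f"area_summary_{period}.csv", f"ep_{period}.asc"]
        p1, p2 = config.periods
        summaries, national = change_analysis(
            state["surfaces"][p1], state["surfaces"][p2], bundle.admin_units, seed=config.seed
        )
        labels = classify_progress(summaries, hi=hi, lo=lo)
        change_table(summaries + [national], labels).to_csv(
            os.path.join(out, "change_summary.csv"), index=False
        )
        produced.append("change_summary.csv")
        return produced

    if "surfaces" in state:
        run_stage("postprocess", stage_postprocess)

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["state"] = state
    return manifest
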