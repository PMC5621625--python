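"""End-to-end pipeline: simulate/load -> exposure -> fit -> AF -> WAIC -> report.

Each stage writes plain-text artefacts (CSV tables, JSON summaries) under the
configured output directory.  A stage failure aborts with the stage name while
artefacts from completed stages remain on disk.  All randomness descends from
``RunConfig.seed`` through a spawned seed tree, so a repeated run with the
same config is bitwise-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, attribution, model, synthetic
from .data_io import (RunConfig, SurveyDataset, read_adjacency, read_conflict_events,
                      read_geography, read_survey_table, write_conflict_events,
                      write_survey_table)
from .exposure import build_exposure_matrix

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "exposure", "fit", "af", "waic", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _child_seed(root: int, label: str) -> int:
    """Deterministic per-stage seed derived from the run seed.

    Uses a stable byte-level hash of the label (Python's ``hash`` is
    process-randomised and would break run-to-run determinism).
    """
    import zlib

    h = np.random.SeedSequence([root, zlib.crc32(label.encode("utf-8"))])
    return int(h.generate_state(1)[0])


def run_pipeline(config: RunConfig, through: str = "report") -> dict:
    """Run the pipeline up to (and including) stage ``through``.

    Returns a dict of artefact paths written.  With no input paths in the
    config, the simulate stage generates all inputs synthetically.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, str] = {}
    state: dict = {}

    def record(name: str, path: Path):
        artefacts[name] = str(path)

    stage = "simulate"
    try:
        if config.inputs:
            paths = config.inputs
            state["geography"] = read_geography(paths["clusters"], paths["covariates"])
            state["adjacency"] = read_adjacency(
                paths["adjacency"], nodes=state["geography"].cluster_ids)
            state["events"] = read_conflict_events(paths["events"]).events
            state["survey"] = read_survey_table(paths["survey"])
        else:
            sim = config.sim
            truth = state["truth"] = synthetic.TruthParams()
            geography, adjacency = synthetic.generate_geography(
                sim.n_districts, sim.clusters_per_district,
                seed=_child_seed(config.seed, "geography"))
            events = synthetic.simulate_conflict_events(
                geography, truth, sim.start_date, sim.end_date,
                seed=_child_seed(config.seed, "events"))
            survey_dates = pd.date_range(
                pd.Timestamp(sim.start_date) + pd.Timedelta(days=365),
                sim.end_date, periods=sim.n_rounds)
            survey = synthetic.simulate_survey(
                geography, adjacency, events, truth, sim.n_children,
                survey_dates, seed=_child_seed(config.seed, "survey"),
                windows=config.windows, linkage=config.linkage)
            state.update(geography=geography, adjacency=adjacency,
                         events=events, survey=survey)
            inputs_dir = outdir / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            geography.clusters.to_csv(inputs_dir / "clusters.csv", index=False)
            geography.covariates.to_csv(inputs_dir / "covariates.csv", index=False)
            adjacency.to_csv(inputs_dir / "adjacency.csv")
            write_conflict_events(events, inputs_dir / "events.csv")
            write_survey_table(survey, inputs_dir / "survey.csv")
            truth.to_json(inputs_dir / "truth.json")
            for name in ("clusters", "covariates", "adjacency", "events",
                         "survey", "truth"):
                suffix = "json" if name == "truth" else "csv"
                record(f"input_{name}", inputs_dir / f"{name}.{suffix}")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc
    if last < STAGES.index("exposure"):
        return artefacts

    stage = "exposure"
    try:
        survey = state["survey"]
        records = survey.records if isinstance(survey, SurveyDataset) else survey
        survey_index = records[["cluster_id", "survey_date"]].drop_duplicates()
        exposure = build_exposure_matrix(
            state["events"], state["geography"].clusters, survey_index,
            linkage=config.linkage, buffer_km=config.buffer_km,
            windows=config.windows)
        state["exposure"] = exposure
        path = outdir / "exposure.csv"
        out = exposure.copy()
        out["survey_date"] = out["survey_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        record("exposure", path)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    if last < STAGES.index("fit"):
        return artefacts

    mcmc = config.mcmc
    priors = model.PriorSpec(tau_shape=config.hyperpriors.tau_shape,
                             tau_rate=config.hyperpriors.tau_rate,
                             beta_precision=config.hyperpriors.beta_precision)
    for outcome in config.outcomes:
        stage = "fit"
        try:
            designs = {}
            fits = {}
            for variant in ("A", "B"):
                design = model.build_design(
                    state["survey"], state["exposure"], state["geography"],
                    variant=variant, outcome=outcome, cutoff=config.cutoff)
                fit = model.fit_model(
                    design, state["adjacency"], priors=priors,
                    chains=mcmc.chains, iterations=mcmc.iterations,
                    burnin=mcmc.burnin, thinning=mcmc.thinning,
                    seed=_child_seed(config.seed, f"fit-{outcome}-{variant}"))
                designs[variant], fits[variant] = design, fit
            state[f"designs_{outcome}"], state[f"fits_{outcome}"] = designs, fits
            screen = model.screen_collinearity(
                designs["B"].frame().drop(columns=["intercept"]))
            screen.flagged.to_csv(outdir / f"collinearity_{outcome}.csv",
                                  index=False)
            record(f"collinearity_{outcome}", outdir / f"collinearity_{outcome}.csv")
            effects = model.summarize_effects(fits["B"], designs["B"])
            diag = fits["B"].diagnostics()
            effects = effects.merge(diag, on="term", how="left")
            path = outdir / f"effects_{outcome}.csv"
            effects.to_csv(path, index=False, float_format="%.6g")
            record(f"effects_{outcome}", path)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        if last < STAGES.index("af"):
            continue

        stage = "af"
        try:
            factors = [f for f in config.af.factors
                       if attribution._KNOWN_FACTORS.get(f, f) in designs["B"].columns]
            report = attribution.sequential_af(
                fits["B"], designs["B"], factors, scaling=config.af.scaling,
                evi_reference_quantile=config.af.evi_reference_quantile)
            path = outdir / f"af_{outcome}.csv"
            report.table().to_csv(path, index=False)
            record(f"af_{outcome}", path)
            jpath = outdir / f"af_{outcome}.json"
            with open(jpath, "w", encoding="utf-8") as fh:
                json.dump(report.to_dict(), fh, indent=2, default=float)
            record(f"af_{outcome}_json", jpath)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        if last < STAGES.index("waic"):
            continue

        stage = "waic"
        try:
            results = {v: assessment.waic(assessment.pointwise_loglik(fits[v], designs[v]))
                       for v in ("A", "B")}
            delta = assessment.compare_waic(results["A"], results["B"])
            delta.update({f"lppd_{v.lower()}": results[v].lppd for v in results})
            delta.update({f"p_waic_{v.lower()}": results[v].p_waic for v in results})
            path = outdir / f"waic_{outcome}.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(delta, fh, indent=2)
            record(f"waic_{outcome}", path)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        if last < STAGES.index("report"):
            continue

        stage = "report"
        try:
            table = assessment.observed_vs_fitted(fits["B"], designs["B"])
            path = outdir / f"observed_fitted_{outcome}.csv"
            meta = table.attrs
            table.to_csv(path, index=False, float_format="%.6g")
            record(f"observed_fitted_{outcome}", path)
            state[f"calibration_{outcome}"] = meta
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if last >= STAGES.index("report"):
        stage = "report"
        try:
            run_log = {
                "seed": config.seed,
                "config": config.to_dict(),
                "artefacts": dict(artefacts),
                "calibration": {o: state.get(f"calibration_{o}", {})
                                for o in config.outcomes},
            }
            path = outdir / "run_log.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(run_log, fh, indent=2, default=str)
            record("run_log", path)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    return artefacts
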