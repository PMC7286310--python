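"""End-to-end pipeline: simulate -> fit -> flow -> communities -> classify ->
testlinks, driven by a JSON-able configuration dict.

Every stage writes its artifacts under the output directory, and the final
``summary.json`` records the stage outputs, their SHA-256 hashes, the seeds
used and the package version, so a rerun with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import __version__
from .cohort import CohortSpec, make_cohort
from .estimation import FitHyperparams, empirical_covariances, fit_mou_gradient
from .io import (
    sha256_file,
    write_manifest,
    write_mask,
    write_matrix,
    write_timeseries,
)
from .ml import CohortSample, classify_cv, linkwise_tests, vectorize_connectivity
from .netdyn import coparticipation, default_t_grid, detect_communities, dynamic_flow

logger = logging.getLogger("mouec")

STAGE_ORDER = ["simulate", "fit", "flow", "communities", "classify", "testlinks"]

#: stage -> parameters that must be present in the stage's config block
REQUIRED_STAGE_PARAMS: dict[str, list[str]] = {
    "communities": ["t"],
    "classify": ["label_field"],
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


def validate_config(config: dict) -> list[str]:
    """Check stage list and per-stage required parameters; returns stages."""
    if "outdir" not in config:
        raise ConfigError("config must name an 'outdir'")
    if "seed" not in config:
        raise ConfigError("config must name a top-level 'seed'")
    stages = config.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    if stages != STAGE_ORDER[: len(stages)]:
        raise ConfigError(
            f"stages must be a contiguous prefix of {STAGE_ORDER}, got {stages}"
        )
    for stage in stages:
        block = config.get(stage, {})
        for param in REQUIRED_STAGE_PARAMS.get(stage, []):
            if param not in block:
                raise ConfigError(
                    f"stage {stage!r} is missing required parameter {param!r}"
                )
    return stages


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; returns the summary dict."""
    stages = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {
        "package_version": __version__,
        "seed": seed,
        "stages": {},
    }
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        state: dict = {}
        for stage in stages:
            t0 = time.monotonic()
            logger.info("pipeline stage %s: start", stage)
            try:
                outputs = _STAGE_FUNCS[stage](config, state, outdir, seed)
            except Exception:
                logger.exception("pipeline stage %s: FAILED", stage)
                summary["failed_stage"] = stage
                (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
                raise
            summary["stages"][stage] = {
                "outputs": outputs,
                "hashes": {
                    name: sha256_file(outdir / name)
                    for name in outputs
                    if (outdir / name).is_file()
                },
                "elapsed_s": round(time.monotonic() - t0, 3),
            }
            logger.info("pipeline stage %s: done", stage)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary


def _stage_simulate(config, state, outdir, seed):
    block = dict(config.get("simulate", {}))
    block.setdefault("seed", seed)
    spec = CohortSpec(**block)
    sessions, manifest, truth = make_cohort(spec)
    files = []
    for sess, entry in zip(sessions, manifest):
        fname = f"{entry['session_id']}.tsv"
        write_timeseries(sess, outdir / fname)
        entry["file"] = fname
        files.append(fname)
    write_mask(truth.mask, outdir / "mask.csv", truth.group_params.roi_names)
    write_matrix(
        truth.group_params.C,
        outdir / "ground_truth_ec.csv",
        truth.group_params.roi_names,
    )
    write_manifest(manifest, outdir / "manifest.json")
    state["sessions"] = sessions
    state["manifest"] = manifest
    state["truth"] = truth
    state["spec"] = spec
    return files + ["mask.csv", "ground_truth_ec.csv", "manifest.json"]


def _stage_fit(config, state, outdir, seed):
    block = config.get("fit", {})
    lag_tr = int(block.get("lag_tr", 1))
    hp = FitHyperparams(
        rate_c=block.get("rate_c"),
        rate_sigma=block.get("rate_sigma"),
        max_iter=int(block.get("max_iter", 3000)),
        patience=int(block.get("patience", 100)),
    )
    tau = float(block.get("tau", state["spec"].tau))
    mask = state["truth"].mask
    fits = {}
    errors = {}
    for sess, entry in zip(state["sessions"], state["manifest"]):
        cov = empirical_covariances(sess, lag_tr=lag_tr)
        fit = fit_mou_gradient(cov, mask, tau=tau, hp=hp, seed=seed)
        sid = entry["session_id"]
        fits[sid] = fit
        errors[sid] = fit.best_error
        write_matrix(fit.params.C, outdir / f"{sid}_ec.csv", sess.roi_names)
    state["fits"] = fits
    (outdir / "fit_log.json").write_text(
        json.dumps(
            {
                "tau": tau,
                "lag_tr": lag_tr,
                "seed": seed,
                "max_iter": hp.max_iter,
                "patience": hp.patience,
                "best_errors": errors,
            },
            indent=1,
        )
    )
    return [f"{sid}_ec.csv" for sid in fits] + ["fit_log.json"]


def _stage_flow(config, state, outdir, seed):
    block = config.get("flow", {})
    t_grid = default_t_grid(
        t_max=float(block.get("t_max", 20.0)), dt=float(block.get("dt", 0.5))
    )
    flows = {}
    for sid, fit in state["fits"].items():
        flows[sid] = dynamic_flow(fit.params, t_grid, tr=state["spec"].tr)
    state["flows"] = flows
    total = {sid: ft.values.sum(axis=(0, 1)).tolist() for sid, ft in flows.items()}
    (outdir / "total_flow.json").write_text(
        json.dumps({"t_grid": t_grid.tolist(), "total_flow": total}, indent=1)
    )
    return ["total_flow.json"]


def _stage_communities(config, state, outdir, seed):
    block = config["communities"]
    t = float(block["t"])
    n_runs = int(block.get("n_runs", 20))
    partitions = []
    for sid, ft in state["flows"].items():
        partitions.append(detect_communities(ft, t=t, n_runs=n_runs, seed=seed))
    result = coparticipation(partitions)
    write_matrix(result.coparticipation, outdir / "coparticipation.csv")
    (outdir / "partitions.json").write_text(
        json.dumps(
            {
                "t": t,
                "partitions": [
                    {str(k): v for k, v in p.items()} for p in partitions
                ],
            },
            indent=1,
        )
    )
    state["communities"] = result
    return ["coparticipation.csv", "partitions.json"]


def _make_samples(state) -> list[CohortSample]:
    mask = state["truth"].mask
    samples = []
    for entry in state["manifest"]:
        sid = entry["session_id"]
        vec, idx = vectorize_connectivity(state["fits"][sid].params.C, mask)
        samples.append(
            CohortSample(
                features=vec,
                subject_id=entry["subject_id"],
                condition=entry["condition"],
                session_id=sid,
                feature_index=idx,
            )
        )
    return samples


def _stage_classify(config, state, outdir, seed):
    block = config["classify"]
    samples = _make_samples(state)
    result = classify_cv(
        samples,
        label_field=block["label_field"],
        classifier=block.get("classifier", "mlr"),
        scheme=block.get("scheme", "shuffle80_20"),
        n_splits=int(block.get("n_splits", 40)),
        seed=seed,
    )
    state["classification"] = result
    (outdir / "classification.json").write_text(
        json.dumps(
            {
                "label_field": block["label_field"],
                "classifier": result.classifier_name,
                "scheme": result.scheme_name,
                "n_splits": result.n_splits,
                "seed": result.seed,
                "mean_accuracy": result.mean_accuracy,
                "chance_level": result.chance_level,
                "accuracies": result.accuracies.tolist(),
                "classes": result.classes,
                "confusion": result.confusion.tolist(),
            },
            indent=1,
        )
    )
    return ["classification.json"]


def _stage_testlinks(config, state, outdir, seed):
    block = config.get("testlinks", {})
    samples = _make_samples(state)
    result = linkwise_tests(samples, alpha=float(block.get("alpha", 0.05)))
    idx = samples[0].feature_index
    names = state["sessions"][0].roi_names
    lines = ["source,target,p_value,bh_rejected"]
    for (i, j), p, rej in zip(idx, result.p_values, result.bh_rejections):
        lines.append(f"{names[i]},{names[j]},{p:.6g},{int(rej)}")
    (outdir / "linkwise_tests.csv").write_text("\n".join(lines) + "\n")
    state["linktests"] = result
    return ["linkwise_tests.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "flow": _stage_flow,
    "communities": _stage_communities,
    "classify": _stage_classify,
    "testlinks": _stage_testlinks,
}
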