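"""End-to-end analysis pipeline: load or simulate a cohort, derive speeds,
summarise, test, fit, and emit a JSON report.

The report mirrors the study-style analysis: per-subject condition means,
percent speed reductions relative to the 23 m bout (whole cohort and per
amputation group), the ten-test hypothesis battery plus the post hoc
above-knee direction test, fixed-effects linear fits of speed versus
distance and radius, inverse-optimization fits (both versions, both
groups), and model-versus-data speed curves with the 1%-of-minimum cost
bands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cost import EfficiencyParams, bout_total_cost, circle_cost_per_distance, \
    near_optimal_band, optimal_speed_circle, optimal_speed_straight
from .data import CohortDataset, read_dataset
from .inverse import IdentifiabilityError, PreferredSpeedModel
from .simulate import SyntheticConfig, generate_cohort
from . import stats as gstats

__all__ = ["RunConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("gaitcost")


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study's analysis choices
    (efficiencies 0.25/1.2, 1e5 bootstrap resamples, Bonferroni family of
    10, subject-level resampling)."""

    subjects_path: str | None = None
    trials_path: str | None = None
    synthetic: SyntheticConfig | None = None
    eff: EfficiencyParams = field(default_factory=EfficiencyParams)
    fit_versions: tuple = (1, 2)
    groups: tuple = ("above_knee", "below_knee")
    n_boot: int = 100_000
    seed: int = 0
    resample_unit: str = "subjects"
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "eff" in raw and raw["eff"] is not None:
            raw["eff"] = EfficiencyParams(**raw["eff"])
        for key in ("fit_versions", "groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load(config: RunConfig) -> CohortDataset:
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic)
        return generate_cohort(cfg)
    if config.subjects_path and config.trials_path:
        return read_dataset(config.subjects_path, config.trials_path)
    raise ValueError("config needs either CSV paths or a synthetic config")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _model_curves(coeffs, eff, distances, radii, observed):
    """Model-optimal speeds and 1% bands for each design condition, with
    in-band flags for the observed group-mean speeds."""
    out = {"straight": [], "circle": []}
    for D in distances:
        v = optimal_speed_straight(coeffs, eff, D)
        band = near_optimal_band(lambda s: bout_total_cost(coeffs, eff, D, s), v)
        obs = observed["straight"].get(D)
        out["straight"].append({
            "distance_m": D, "v_opt": v, "v_lo": band.v_lo, "v_hi": band.v_hi,
            "observed_mean": obs,
            "observed_in_band": None if obs is None else band.contains(obs),
        })
    for R in radii:
        v = optimal_speed_circle(coeffs, R)
        band = near_optimal_band(
            lambda s: circle_cost_per_distance(coeffs, s, R), v
        )
        obs = observed["circle"].get(R)
        out["circle"].append({
            "radius_m": R, "v_opt": v, "v_lo": band.v_lo, "v_hi": band.v_hi,
            "observed_mean": obs,
            "observed_in_band": None if obs is None else band.contains(obs),
        })
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report dict.

    With ``config.out_dir`` set, also writes ``report.json``, the cohort
    CSVs (if synthetic) and a plain-text log.  Identical config and seed
    give identical reports apart from the timestamp.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline start: seed=%s", config.seed)
    dataset = _load(config)
    logger.info("dataset: %d subjects, %d trials",
                dataset.n_subjects, dataset.n_trials)

    means = gstats.subject_condition_means(dataset)
    distances = sorted(means.straight.columns)
    radii = sorted(means.circle.columns)
    baseline = 23.0 if 23.0 in distances else max(distances)
    short = [D for D in distances if D != baseline]

    reductions = {}
    for D in short:
        reductions[f"straight_{D:g}m"] = gstats.percent_reduction(
            dataset, "straight", D, baseline).to_dict(orient="index")
    for R in radii:
        reductions[f"circle_R{R:g}m"] = gstats.percent_reduction(
            dataset, "circle", R, baseline).to_dict(orient="index")

    battery = gstats.run_hypothesis_battery(
        dataset, n_boot=config.n_boot, seed=config.seed,
        resample_unit=config.resample_unit, distances=short, radii=radii,
        baseline_distance=baseline,
    )

    linear_fits = {}
    s_records = (
        dataset.trials[
            (dataset.trials["task"] == "straight")
            & dataset.trials["distance_m"].isin(short)
        ].groupby(["subject_id", "distance_m"])["speed_m_s"].mean().reset_index()
    )
    try:
        linear_fits["speed_vs_distance"] = gstats.linear_fit_subject_offsets(
            s_records, "distance_m").to_record()
    except ValueError as exc:
        linear_fits["speed_vs_distance"] = {"skipped": True, "reason": str(exc)}
    c_records = (
        dataset.trials[dataset.trials["task"] == "circle"]
        .groupby(["subject_id", "radius_m"])["speed_m_s"].mean().reset_index()
    )
    try:
        linear_fits["speed_vs_radius"] = gstats.linear_fit_subject_offsets(
            c_records, "radius_m").to_record()
    except ValueError as exc:
        linear_fits["speed_vs_radius"] = {"skipped": True, "reason": str(exc)}

    inverse_fits = []
    curves = {}
    for group in config.groups:
        ids = dataset.subjects_in_group(group)
        if not ids:
            inverse_fits.append({"group": group, "skipped": True,
                                 "reason": "no subjects in group"})
            continue
        group_means = {
            "straight": means.straight.loc[
                means.straight.index.isin(ids)].mean().to_dict(),
            "circle": means.circle.loc[
                means.circle.index.isin(ids)].mean().to_dict(),
        }
        for version in config.fit_versions:
            try:
                model = PreferredSpeedModel.from_dataset(
                    dataset, group=group, version=version, eff=config.eff
                )
                res = model.fit()
            except (IdentifiabilityError, ValueError) as exc:
                inverse_fits.append({
                    "group": group, "version": version, "skipped": True,
                    "reason": str(exc),
                })
                continue
            inverse_fits.append(res.to_record())
            curves[f"{group}_v{version}"] = _model_curves(
                res.coeffs, config.eff, distances, radii, group_means
            )
            logger.info("fit %s v%d: %s mse=%.3g", group, version,
                        dict(res.params.round(4)), res.mse)

    report = {
        "metadata": {
            "package": "gaitcost",
            "seed": config.seed,
            "n_boot": config.n_boot,
            "resample_unit": config.resample_unit,
            "eff": {"eta_pos": config.eff.eta_pos, "eta_neg": config.eff.eta_neg},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "provenance": dataset.provenance,
        },
        "dataset": {
            "n_subjects": dataset.n_subjects,
            "n_trials": dataset.n_trials,
            "n_above_knee": len(dataset.subjects_in_group("above_knee")),
            "n_below_knee": len(dataset.subjects_in_group("below_knee")),
            "baseline_distance_m": baseline,
        },
        "condition_means": {
            "straight": {str(k): v for k, v in
                         means.straight.to_dict(orient="index").items()},
            "circle": {str(k): v for k, v in
                       means.circle.to_dict(orient="index").items()},
        },
        "percent_reductions": reductions,
        "hypothesis_tests": [t.to_record() for t in battery],
        "linear_fits": linear_fits,
        "inverse_fits": inverse_fits,
        "model_curves": curves,
    }
    report = _jsonable(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        if config.synthetic is not None:
            dataset.write(out / "subjects.csv", out / "trials.csv",
                          out / "synthetic_config.json")
        log_lines = [
            f"seed={config.seed}",
            f"n_boot={config.n_boot}",
            f"fit_versions={list(config.fit_versions)}",
            f"groups={list(config.groups)}",
            f"n_subjects={dataset.n_subjects}",
            f"n_trials={dataset.n_trials}",
        ]
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        logger.info("report written to %s", out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False))
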