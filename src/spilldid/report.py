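"""End-to-end pipeline orchestration and results-table formatting.

The pipeline runs simulate -> cohort -> exposure -> estimate -> robustness
-> report from a single YAML configuration and a seed, writing CSV/JSON
artifacts plus a manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import assemble_panel, build_cohort, hospital_quarter_volumes
from .config import build_scenario
from .estimation import SpilloverEstimate, TwoStageDiD
from .exposure import compute_exposure_table, specialty_exposure
from .robustness import (
    SubgroupScheme,
    hospital_targeted_shares,
    run_robustness_suite,
    stratify_subgroups,
)
from .simulate import simulate_study, write_study

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class ReportError(ValueError):
    pass


def significance_stars(p: float) -> str:
    """Table-note convention: *p<0.05, **p<0.01, ***p<0.001."""
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def relative_effect(coefficient_pp: float, baseline_pct: float) -> float:
    """Effect as a percent of the pre-policy treated-region mortality rate,
    rounded to one decimal for display."""
    if baseline_pct <= 0:
        raise ReportError(f"baseline must be positive, got {baseline_pct!r}")
    return round(100.0 * coefficient_pp / baseline_pct, 1)


def format_results(
    estimates: list[SpilloverEstimate],
    baseline_pct: float | None = None,
    pretrend_status: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """One row per (model, coefficient) in journal-table style:
    three-decimal estimates, standard errors in parentheses, significance
    stars, optional relative effects and pre-trend status."""
    rename = {"post_indicator": "delta/theta", "x_post": "mu", "z_post": "phi"}
    rows = []
    for est in estimates:
        for term in est.terms:
            p = est.pvalues[term]
            row = {
                "model": est.model,
                "coefficient": rename.get(term, term),
                "estimate_pp": round(est.coef[term], 3),
                "se": f"({est.se[term]:.3f})",
                "stars": significance_stars(p),
                "p_value": p,
                "n_obs": est.n_obs,
                "n_clusters": est.n_clusters,
                "fe_level": est.fe_level,
            }
            if baseline_pct is not None:
                row["relative_effect_pct"] = relative_effect(
                    est.coef[term], baseline_pct
                )
            if pretrend_status is not None:
                status = pretrend_status.get(est.model)
                row["pretrend"] = (
                    "pass" if status else "fail" if status is not None else ""
                )
            rows.append(row)
    return pd.DataFrame(rows)


_KNOWN_SECTIONS = {"scenario", "estimation", "robustness", "report"}


def load_pipeline_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ReportError(f"unknown config sections: {sorted(unknown)}")
    raw.setdefault("scenario", {"name": "null", "overrides": {}})
    raw.setdefault("estimation", {})
    raw.setdefault("robustness", {"variants": "all", "include_pretrend": False})
    raw.setdefault("report", {})
    return raw


def run_pipeline(
    config_path: str | Path | None,
    seed: int,
    outdir: str | Path,
    config: dict | None = None,
) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Every stage writes its artifacts before the next begins, so failures
    leave partial output for debugging; stage errors are re-raised with the
    stage name prefixed.
    """
    if config is None:
        if config_path is not None:
            config = load_pipeline_config(config_path)
        else:
            config = {
                "scenario": {"name": "null", "overrides": {}},
                "estimation": {},
                "robustness": {"variants": "all", "include_pretrend": False},
                "report": {},
            }
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        scen = config["scenario"]
        dgp = build_scenario(scen.get("name", "null"), scen.get("overrides") or {})
        study = simulate_study(dgp, seed)
        write_study(study, out / "data")
        timeline = study.timeline

        stage = "cohort"
        catalogue = {c for c, _ in dgp.condition_catalogue}
        cohort, log = build_cohort(
            study.admissions, study.deaths, timeline, catalogue=catalogue
        )
        volumes = hospital_quarter_volumes(study.admissions)
        panel = assemble_panel(cohort, study.hospitals, timeline)
        panel = panel.merge(volumes, on=["hospital_id", "quarter"], how="left")
        (out / "cohort").mkdir(exist_ok=True)
        (out / "cohort" / "exclusion_log.json").write_text(
            json.dumps(log.to_dict(), indent=2)
        )
        panel.to_csv(out / "cohort" / "panel.csv", index=False)

        stage = "exposure"
        exposure = compute_exposure_table(study.admissions, timeline, variants=True)
        spec_exp = specialty_exposure(study.admissions, timeline)
        (out / "exposure").mkdir(exist_ok=True)
        exposure.to_csv(out / "exposure" / "exposure.csv", index=False)
        spec_exp.to_csv(out / "exposure" / "specialty_exposure.csv", index=False)

        stage = "estimate"
        covariates = config["estimation"].get("covariates")
        estimates: list[SpilloverEstimate] = []
        pretrend_status: dict[str, bool] = {}
        fits = {}
        for model in ("average", "sorting_adjusted", "decomposition"):
            fit = TwoStageDiD(model=model, covariates=covariates).fit(
                panel, exposure=exposure, timeline=timeline
            )
            fits[model] = fit
            est = fit.estimate_
            est.model = model
            estimates.append(est)
        ev = fits["decomposition"].pretrend(exposure)
        pretrend_status["decomposition"] = ev.passes
        ev_avg = fits["average"].pretrend()
        pretrend_status["average"] = ev_avg.passes
        (out / "estimates").mkdir(exist_ok=True)
        ev.coefficients.to_csv(out / "estimates" / "event_study.csv", index=False)
        with open(out / "estimates" / "estimates.json", "w") as fh:
            json.dump([e.to_dict() for e in estimates], fh, indent=2)

        stage = "subgroups"
        shares = hospital_targeted_shares(study.admissions, timeline)
        subgroup_estimates = stratify_subgroups(
            panel, exposure, SubgroupScheme("diagnosis_area"), timeline,
            covariates=covariates,
        )
        subgroup_estimates.update(
            stratify_subgroups(
                panel, exposure,
                SubgroupScheme("targeted_share", shares=shares), timeline,
                covariates=covariates,
            )
        )
        estimates.extend(subgroup_estimates.values())

        stage = "robustness"
        rb = config["robustness"]
        variants = rb.get("variants", "all")
        if variants == "all":
            from .robustness import VARIANT_NAMES as variants  # noqa: N811
        suite = run_robustness_suite(
            panel, exposure, timeline,
            specialty_exposure=spec_exp,
            variants=tuple(variants),
            covariates=covariates,
            include_pretrend=bool(rb.get("include_pretrend", False)),
        )
        (out / "robustness").mkdir(exist_ok=True)
        suite.to_csv(out / "robustness" / "suite.csv", index=False)

        stage = "report"
        treated_pre = panel[
            (panel["treated_region"] == 1) & (panel["post_indicator"] == 0)
        ]
        baseline_pct = config["report"].get(
            "baseline_pct", 100.0 * float(treated_pre["outcome_30d"].mean())
        )
        table = format_results(
            estimates, baseline_pct=baseline_pct, pretrend_status=pretrend_status
        )
        table.to_csv(out / "results_table.csv", index=False)
        manifest = {
            "package_version": __version__,
            "seed": seed,
            "config_hash": dgp.config_hash(),
            "pipeline_config": config,
            "dgp_config": dgp.to_dict(),
            "baseline_pct": baseline_pct,
            "exclusion_log": log.to_dict(),
            "true_effects": dict(
                zip(("theta", "mu", "phi"), dgp.true_effects())
            ),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out
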