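"""Robustness checks: alternative specifications, sample restrictions,
and subgroup stratifications of the spillover decomposition.

Alternative specifications add regressors (specialty exposure, an
interaction between direct and indirect exposure, squared exposures) or
swap the exposure measures (condition-restricted indirect exposure,
share-based measures). Sample restrictions remove the anticipation quarter
or control regions suspected of between-region spillovers; they change
sample membership only, never the estimator, and exposure variables are
never recomputed on the restricted sample — they remain fixed physician
attributes from the full post-policy period so that the zero-exposure
coefficient keeps one interpretation across every variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PolicyTimeline
from .estimation import EstimationError, SpilloverEstimate, TwoStageDiD
from .exposure import _targeted_mask

VARIANT_NAMES = (
    "main",
    "specialty_exposure",
    "interaction",
    "squared",
    "alt_indirect",
    "share_measures",
    "no_anticipation",
    "drop_adjacent_regions",
    "drop_similar_incentive_regions",
)

_RESTRICTIONS = {
    "no_anticipation",
    "drop_adjacent_regions",
    "drop_similar_incentive_regions",
}


class RobustnessError(ValueError):
    pass


@dataclass
class VariantSpec:
    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise RobustnessError(
                f"unknown variant {self.name!r}; known: {list(VARIANT_NAMES)}"
            )


def _restrict(panel: pd.DataFrame, spec: VariantSpec,
              timeline: PolicyTimeline) -> tuple[pd.DataFrame, int]:
    if spec.name == "no_anticipation":
        keep = panel["quarter"] != timeline.anticipation_quarter
    elif spec.name in ("drop_adjacent_regions", "drop_similar_incentive_regions"):
        if "region" not in panel.columns:
            raise RobustnessError(
                f"variant {spec.name!r} needs a 'region' column on the panel"
            )
        tag = ("adjacent" if spec.name == "drop_adjacent_regions"
               else "similar_incentive")
        keep = panel["region"] != tag
    else:
        return panel, 0
    restricted = panel[keep]
    return restricted, int((~keep).sum())


def run_variant(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    spec: VariantSpec,
    timeline: PolicyTimeline,
    specialty_exposure: pd.DataFrame | None = None,
    covariates: dict | None = None,
) -> SpilloverEstimate:
    """Re-run the full two-stage decomposition pipeline under one variant.

    ``specialty_exposure`` (per specialty-hospital ``x_specialty``) is
    required by the ``specialty_exposure`` variant and joined to each
    admission by its specialty of treatment. Restriction variants record
    the exact number of removed rows in ``estimate.meta["removed_rows"]``.
    """
    panel, removed = _restrict(panel, spec, timeline)
    x_col, z_col = "x_direct", "z_indirect"
    extra: dict[str, str] | None = None
    if spec.name == "specialty_exposure":
        if specialty_exposure is None:
            raise RobustnessError(
                "specialty_exposure variant needs the specialty exposure table"
            )
        panel = panel.merge(
            specialty_exposure, on=["hospital_id", "specialty_id"],
            how="left", validate="many_to_one",
        )
        if panel["x_specialty"].isna().any():
            raise EstimationError("specialty exposure missing for some admissions")
        extra = {"xs_post": "x_specialty"}
    elif spec.name == "interaction":
        extra = {"xz_post": "x_direct * z_indirect"}
    elif spec.name == "squared":
        extra = {"x2_post": "x_direct ** 2", "z2_post": "z_indirect ** 2"}
    elif spec.name == "alt_indirect":
        z_col = "z_condition_restricted"
    elif spec.name == "share_measures":
        x_col, z_col = "x_share", "z_share"

    est = TwoStageDiD(
        model="decomposition", covariates=covariates,
        x_col=x_col, z_col=z_col, extra=extra,
    ).fit(panel, exposure=exposure, timeline=timeline)
    result = est.estimate_
    result.model = spec.name
    result.meta["removed_rows"] = removed
    result.meta["restriction"] = spec.name in _RESTRICTIONS
    return result


def turning_point(estimate, quadratic: float | None = None) -> float:
    """Exposure level (targeted patients/quarter) where the quadratic
    direct-exposure profile turns: -linear / (2 * quadratic).

    Accepts either a squared-variant :class:`SpilloverEstimate` or the
    (linear, quadratic) coefficient pair directly.
    """
    if quadratic is None:
        if not isinstance(estimate, SpilloverEstimate):
            raise RobustnessError("pass a SpilloverEstimate or (linear, quadratic)")
        try:
            linear = estimate.coef["x_post"]
            quadratic = estimate.coef["x2_post"]
        except KeyError as err:
            raise RobustnessError(
                "estimate lacks linear/squared direct-exposure terms"
            ) from err
    else:
        linear = float(estimate)
    if quadratic == 0:
        raise RobustnessError(
            "zero quadratic coefficient: turning point is undefined"
        )
    return -linear / (2.0 * quadratic)


@dataclass
class SubgroupScheme:
    """Partition rule for the subgroup analysis.

    ``diagnosis_area`` splits patients by whether their non-targeted
    condition shares a diagnosis area with the targeted conditions.
    ``targeted_share`` splits hospitals at the median post-policy share of
    targeted admissions among treated-region hospitals (ties assigned to
    "below"); ``shares`` maps hospital_id to that share.
    """

    kind: str
    shares: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("diagnosis_area", "targeted_share"):
            raise RobustnessError(f"unknown subgroup scheme {self.kind!r}")
        if self.kind == "targeted_share" and self.shares is None:
            raise RobustnessError("targeted_share scheme needs per-hospital shares")


def hospital_targeted_shares(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.Series:
    """Per-hospital share of targeted admissions over the post period,
    computed from the full (pre-exclusion) admission table."""
    post = admissions[admissions["quarter"].isin(timeline.post_quarters)]
    g = post.groupby("hospital_id")
    total = g.size()
    targ = post[_targeted_mask(post)].groupby("hospital_id").size()
    return (targ.reindex(total.index).fillna(0) / total).rename("targeted_share")


def stratify_subgroups(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    scheme: SubgroupScheme,
    timeline: PolicyTimeline,
    covariates: dict | None = None,
) -> dict[str, SpilloverEstimate]:
    """Run the decomposition pipeline within each subgroup of the scheme.

    Stage 1 is re-fit on each subgroup's control rows. Subgroups partition
    the panel; a subgroup without treated-region rows raises.
    """
    if scheme.kind == "diagnosis_area":
        masks = {
            "same_area": panel["diagnosis_area"] == "same_area",
            "different_area": panel["diagnosis_area"] != "same_area",
        }
    else:
        shares = scheme.shares
        missing = set(panel["hospital_id"]) - set(shares.index)
        if missing:
            raise RobustnessError(f"no targeted share for hospitals: {sorted(missing)}")
        treated_hosp = panel.loc[panel["treated_region"] == 1, "hospital_id"].unique()
        median = float(shares.loc[treated_hosp].median())
        above = panel["hospital_id"].map(shares) > median  # ties go below
        masks = {"above_median_share": above, "below_median_share": ~above}

    out: dict[str, SpilloverEstimate] = {}
    for label, mask in masks.items():
        sub = panel[mask]
        if not (sub["treated_region"] == 1).any():
            raise RobustnessError(f"subgroup {label!r} has no treated-region rows")
        est = TwoStageDiD(model="decomposition", covariates=covariates).fit(
            sub, exposure=exposure, timeline=timeline
        )
        result = est.estimate_
        result.model = f"subgroup:{label}"
        result.meta["subgroup"] = label
        out[label] = result
    return out


def run_robustness_suite(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    timeline: PolicyTimeline,
    specialty_exposure: pd.DataFrame | None = None,
    variants: tuple[str, ...] = VARIANT_NAMES,
    covariates: dict | None = None,
    include_pretrend: bool = False,
) -> pd.DataFrame:
    """One results row per variant, in the declared (deterministic) order.

    Columns: variant, theta/mu/phi estimates with SEs and p-values, any
    extra terms, sample sizes, removed rows, and (optionally) the joint
    pre-trend Wald pass/fail.
    """
    rows = []
    for name in variants:
        spec = VariantSpec(name)
        est = run_variant(
            panel, exposure, spec, timeline,
            specialty_exposure=specialty_exposure, covariates=covariates,
        )
        row: dict = {"variant": name, "n_obs": est.n_obs,
                     "n_clusters": est.n_clusters,
                     "removed_rows": est.meta.get("removed_rows", 0)}
        rename = {"post_indicator": "theta", "x_post": "mu", "z_post": "phi"}
        for term in est.terms:
            label = rename.get(term, term)
            row[f"{label}"] = est.coef[term]
            row[f"{label}_se"] = est.se[term]
            row[f"{label}_p"] = est.pvalues[term]
        if include_pretrend:
            fit = TwoStageDiD(model="decomposition", covariates=covariates).fit(
                _restrict(panel, spec, timeline)[0], exposure=exposure,
                timeline=timeline,
            )
            row["pretrend_pass"] = fit.pretrend(exposure).passes
        rows.append(row)
    return pd.DataFrame(rows)
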