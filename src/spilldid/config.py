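"""Data-generating-process configuration and scenario presets.

The simulator emulates a regional hospital pay-for-performance scheme in
which three emergency conditions are incentivized ("targeted") in one
treated region while the rest of the country serves as a control group.
Spillover effects on non-targeted patients are injected on the probability
scale through three channels:

* an organization-level shift (``true_theta``) affecting every non-targeted
  patient in treated hospitals post-policy, regardless of their physician;
* a direct-exposure slope (``true_mu``) per targeted patient treated per
  quarter by the patient's own physician (learning / effort substitution);
* an indirect-exposure slope (``true_phi``) per targeted patient treated
  per quarter by the physician's specialty peers (knowledge transfer).

All three are expressed in percentage points so that the simulator truth
and the estimator output share one scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any


class ConfigError(ValueError):
    """A DGP configuration field is missing, unknown, or out of range."""


def _default_covariate_effects() -> dict[str, float]:
    # Probability increments per unit of the (centred) covariate.
    return {
        "age_band": 0.012,        # per 10-year band above the sample mean band
        "male": 0.006,
        "comorbidity_flag": 0.008,  # per Elixhauser flag above the mean count
        "deprivation": 0.003,       # per SD of the deprivation score
        "via_ae": 0.010,
        "admitted_from_home": -0.005,
        "weekend": 0.004,
    }


def _default_condition_catalogue() -> list[tuple[str, str]]:
    # 50 non-targeted condition codes; the first 15 share a diagnosis area
    # (circulatory/respiratory) with the targeted conditions.
    catalogue = []
    for i in range(1, 51):
        area = "same_area" if i <= 15 else "different_area"
        catalogue.append((f"NT{i:02d}", area))
    return catalogue


@dataclass
class DGPConfig:
    """Full specification of the synthetic admission/death generator.

    Effects ``true_theta``, ``true_mu``, ``true_phi`` and
    ``anticipation_effect`` are percentage points; every other rate or
    proportion lives in [0, 1].
    """

    n_hospitals: int = 60
    treated_fraction: float = 1 / 3
    region_labels: dict[str, str] | None = None
    physicians_per_hospital: tuple[int, int] = (8, 8)
    specialties_per_hospital: int = 3
    quarters_pre: int = 4
    quarters_post: int = 4
    patients_per_physician_quarter: float = 40.0
    targeted_caseload_shape: float = 0.6
    targeted_caseload_scale: float = 20.0
    baseline_mortality: float = 0.065
    hospital_effect_sd: float = 0.010
    physician_ability_sd: float = 0.010
    secular_trend_per_quarter: float = -0.0005
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    true_theta: float = 0.0
    true_mu: float = 0.0
    true_phi: float = 0.0
    true_mu_quadratic: float = 0.0  # pp per (targeted patients/quarter)^2
    sorting_strength: float = 0.0
    anticipation_effect: float = 0.0
    readmit_near_death_prob: float = 0.05
    targeted_secondary_prob: float = 0.03
    late_death_prob: float = 0.02
    off_primary_specialty_prob: float = 0.2
    condition_catalogue: list[tuple[str, str]] = field(
        default_factory=_default_condition_catalogue
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        def _check_prob(name: str, lo: float = 0.0, hi: float = 1.0,
                        strict: bool = False) -> None:
            v = getattr(self, name)
            ok = lo < v < hi if strict else lo <= v <= hi
            if not ok:
                bounds = f"({lo}, {hi})" if strict else f"[{lo}, {hi}]"
                raise ConfigError(f"{name}={v!r} outside {bounds}")

        if self.n_hospitals < 2:
            raise ConfigError(f"n_hospitals={self.n_hospitals!r}: need at least 2")
        _check_prob("treated_fraction", strict=True)
        lo, hi = self.physicians_per_hospital
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"physicians_per_hospital={self.physicians_per_hospital!r}: "
                "need 1 <= low <= high"
            )
        if self.specialties_per_hospital < 1:
            raise ConfigError("specialties_per_hospital must be >= 1")
        if self.quarters_pre < 2:
            raise ConfigError(f"quarters_pre={self.quarters_pre!r}: need >= 2")
        if self.quarters_post < 1:
            raise ConfigError(f"quarters_post={self.quarters_post!r}: need >= 1")
        if self.patients_per_physician_quarter <= 0:
            raise ConfigError("patients_per_physician_quarter must be > 0")
        if self.targeted_caseload_shape <= 0 or self.targeted_caseload_scale < 0:
            raise ConfigError("targeted caseload gamma law requires shape > 0, scale >= 0")
        _check_prob("baseline_mortality")
        for name in ("hospital_effect_sd", "physician_ability_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("sorting_strength", "readmit_near_death_prob",
                     "targeted_secondary_prob", "late_death_prob",
                     "off_primary_specialty_prob"):
            _check_prob(name)
        if not self.condition_catalogue:
            raise ConfigError("condition_catalogue must be non-empty")
        for code, area in self.condition_catalogue:
            if area not in ("same_area", "different_area"):
                raise ConfigError(
                    f"condition_catalogue area {area!r} for {code!r}: "
                    "expected 'same_area' or 'different_area'"
                )

    # -- derived quantities ----------------------------------------------
    @property
    def n_quarters(self) -> int:
        return self.quarters_pre + self.quarters_post

    @property
    def first_post_quarter(self) -> int:
        return self.quarters_pre

    @property
    def n_treated(self) -> int:
        n = int(round(self.n_hospitals * self.treated_fraction))
        return min(max(n, 1), self.n_hospitals - 1)

    def true_effects(self) -> tuple[float, float, float]:
        """The embedded (theta, mu, phi) in percentage points."""
        return (self.true_theta, self.true_mu, self.true_phi)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["physicians_per_hospital"] = list(self.physicians_per_hospital)
        d["condition_catalogue"] = [list(t) for t in self.condition_catalogue]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Scenario presets operationalising the spillover-mechanism hypotheses.
# ---------------------------------------------------------------------------

SCENARIO_PRESETS: dict[str, dict[str, Any]] = {
    # No spillovers of any kind: the benchmark for size/placebo studies.
    "null": {
        "true_theta": 0.0,
        "true_mu": 0.0,
        "true_phi": 0.0,
        "sorting_strength": 0.0,
        "anticipation_effect": 0.0,
    },
    # Organization-level resource diversion: mortality rises for every
    # non-targeted patient in treated hospitals, independent of exposure.
    "resource_diversion": {
        "true_theta": 0.321,
        "true_mu": 0.0,
        "true_phi": 0.0,
    },
    # Learning by doing: mortality falls with the physician's own targeted
    # caseload.
    "learning": {
        "true_theta": 0.0,
        "true_mu": -0.008,
        "true_phi": 0.0,
    },
    # Knowledge transfer between specialty peers: mortality falls with the
    # peer-weighted indirect exposure.
    "knowledge_transfer": {
        "true_theta": 0.0,
        "true_mu": 0.0,
        "true_phi": -0.004,
    },
    # Patient sorting only: post-policy reallocation of non-targeted
    # patients toward low-ability physicians in treated hospitals, with a
    # larger ability spread so the reallocation is visible.
    "sorting": {
        "true_theta": 0.0,
        "true_mu": 0.0,
        "true_phi": 0.0,
        "sorting_strength": 0.35,
        "physician_ability_sd": 0.020,
    },
    # Headline calibration: organization-level harm plus a learning
    # benefit, matching the study's decomposition estimates.
    "combined": {
        "true_theta": 0.321,
        "true_mu": -0.008,
        "true_phi": 0.0,
    },
}


def build_scenario(name: str, overrides: dict[str, Any] | None = None) -> DGPConfig:
    """Resolve a named scenario preset into a validated :class:`DGPConfig`.

    ``overrides`` win over preset values, which win over dataclass defaults.
    Unknown preset names and unknown/invalid fields raise :class:`ConfigError`.
    """
    if name not in SCENARIO_PRESETS:
        raise ConfigError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIO_PRESETS)}"
        )
    params: dict[str, Any] = dict(SCENARIO_PRESETS[name])
    overrides = overrides or {}
    valid = {f.name for f in dataclasses.fields(DGPConfig)}
    for key in overrides:
        if key not in valid:
            raise ConfigError(f"unknown DGPConfig field {key!r}")
    params.update(overrides)
    if "physicians_per_hospital" in params:
        params["physicians_per_hospital"] = tuple(params["physicians_per_hospital"])
    if "condition_catalogue" in params:
        params["condition_catalogue"] = [
            tuple(t) for t in params["condition_catalogue"]
        ]
    return DGPConfig(**params)
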