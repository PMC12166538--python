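"""Seeded generator of synthetic admission and death tables.

The generator emulates the linked admission/death extract the analysis is
designed for: a treated region vs. rest-of-country hospital split, hetero-
geneous per-physician targeted caseloads (gamma-distributed quarterly
means), patient covariates (age band x sex, 31 comorbidity flags,
deprivation, admission route), a quarterly panel spanning pre- and
post-policy periods, and Bernoulli 30-day mortality built additively on
the probability scale:

    p = baseline + hospital effect + physician ability + trend
        + covariate terms
        + treated * post * (theta + mu * x_direct + phi * z_indirect) / 100
        + treated * 1[final pre quarter] * anticipation / 100

clipped to [0.001, 0.999]. The spillover terms use the *realized*
exposures computed by :mod:`spilldid.exposure` on the generated admission
table, so the simulator truth and the estimation target are the same
object. Post-policy patient sorting reassigns a configurable share of
treated-hospital non-targeted patients from above-median- to
below-median-ability physicians. A share of decedents receive an extra
emergency admission inside their final 30 days to exercise the death-
attribution filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PolicyTimeline
from .config import DGPConfig, build_scenario
from .exposure import direct_exposure, indirect_exposure

STUDY_START = pd.Timestamp("2007-10-01")
N_COMORBIDITY_FLAGS = 31
TARGETED_CODES = ("TARG1", "TARG2", "TARG3")

# centring constants for the covariate contributions (approximate means of
# the generating laws, fixed so the overall rate stays near the baseline)
_CENTRES = {
    "age_band": 5.0,
    "male": 0.45,
    "comorbidity_flag": 2.0,
    "deprivation": 0.0,
    "via_ae": 0.85,
    "admitted_from_home": 0.90,
    "weekend": 2.0 / 7.0,
}

ADMISSION_COLUMNS = [
    "patient_id", "hospital_id", "physician_id", "specialty_id", "quarter",
    "admission_date", "emergency", "condition_code", "diagnosis_area",
    "targeted_primary", "targeted_secondary", "age_years", "sex",
    "deprivation_score", "admitted_from_home", "via_ae", "weekend",
    "contracted_specialty",
] + [f"comorb_{i:02d}" for i in range(1, N_COMORBIDITY_FLAGS + 1)]


@dataclass
class SimulatedStudy:
    """One simulated draw: tables plus the generator's internal trace."""

    admissions: pd.DataFrame
    deaths: pd.DataFrame
    hospitals: pd.DataFrame
    config: DGPConfig
    seed: int
    prob_trace: np.ndarray  # pre-clip probabilities, original rows only

    @property
    def timeline(self) -> PolicyTimeline:
        return PolicyTimeline.from_window(
            self.config.quarters_pre, self.config.quarters_post
        )


def quarter_start(quarter: int) -> pd.Timestamp:
    return STUDY_START + pd.DateOffset(months=3 * int(quarter))


def _make_hospitals(config: DGPConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_hospitals
    ids = [f"H{i:03d}" for i in range(n)]
    treated = np.zeros(n, dtype=bool)
    treated[rng.permutation(n)[: config.n_treated]] = True
    region = np.empty(n, dtype=object)
    region[treated] = "treated"
    controls = np.flatnonzero(~treated)
    shuffled = rng.permutation(controls)
    n_adj = max(1, int(round(0.2 * len(controls))))
    n_sim = max(1, int(round(0.2 * len(controls))))
    region[shuffled[:n_adj]] = "adjacent"
    region[shuffled[n_adj:n_adj + n_sim]] = "similar_incentive"
    region[shuffled[n_adj + n_sim:]] = "other"
    hospitals = pd.DataFrame(
        {
            "hospital_id": ids,
            "region": region,
            "trust_type": rng.choice(
                ["acute", "teaching", "specialist"], size=n, p=[0.6, 0.25, 0.15]
            ),
            "foundation_status": rng.random(n) < 0.5,
            "hospital_effect": rng.normal(0.0, config.hospital_effect_sd, size=n),
        }
    )
    if config.region_labels is not None:
        labels = pd.Series(config.region_labels)
        hospitals["region"] = hospitals["hospital_id"].map(labels).fillna(
            hospitals["region"]
        )
    return hospitals


def _make_physicians(
    config: DGPConfig, hospitals: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = config.physicians_per_hospital
    rows = []
    for h in hospitals["hospital_id"]:
        n_p = int(rng.integers(lo, hi + 1))
        for j in range(n_p):
            rows.append((f"{h}_P{j:02d}", h))
    phys = pd.DataFrame(rows, columns=["physician_id", "hospital_id"])
    n = len(phys)
    phys["ability"] = rng.normal(0.0, config.physician_ability_sd, size=n)
    phys["primary_specialty"] = rng.integers(
        0, config.specialties_per_hospital, size=n
    )
    phys["targeted_rate"] = rng.gamma(
        config.targeted_caseload_shape, config.targeted_caseload_scale, size=n
    )
    return phys


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(np.round(rng.normal(72, 15, size=n)), 19, 99).astype(int)
    minors = rng.random(n) < 0.01
    age[minors] = rng.integers(1, 19, size=int(minors.sum()))
    cov = pd.DataFrame(
        {
            "age_years": age,
            "sex": np.where(rng.random(n) < 0.45, "M", "F"),
            "deprivation_score": rng.normal(0.0, 1.0, size=n),
            "admitted_from_home": rng.random(n) < 0.90,
            "via_ae": rng.random(n) < 0.85,
            "weekend": rng.random(n) < 2.0 / 7.0,
        }
    )
    # Elixhauser-style flags: a Poisson comorbidity count thinned into 31
    # distinct binary indicators
    count = np.minimum(rng.poisson(2.0, size=n), N_COMORBIDITY_FLAGS)
    u = rng.random((n, N_COMORBIDITY_FLAGS))
    order = np.argsort(u, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(N_COMORBIDITY_FLAGS)[None, :], axis=1)
    flags = ranks < count[:, None]
    for i in range(1, N_COMORBIDITY_FLAGS + 1):
        cov[f"comorb_{i:02d}"] = flags[:, i - 1]
    cov["comorbidity_count"] = count
    return cov


def _assign_specialty(
    primary: np.ndarray, n_specialties: int, off_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if n_specialties == 1:
        return primary.copy()
    spec = primary.copy()
    off = rng.random(len(primary)) < off_prob
    shift = rng.integers(1, n_specialties, size=int(off.sum()))
    spec[off] = (spec[off] + shift) % n_specialties
    return spec


def simulate_study(config: DGPConfig, seed: int) -> SimulatedStudy:
    """Generate one full study draw. Deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    timeline = PolicyTimeline.from_window(config.quarters_pre, config.quarters_post)
    hospitals = _make_hospitals(config, rng)
    physicians = _make_physicians(config, hospitals, rng)

    n_phys = len(physicians)
    n_q = config.n_quarters
    # physician-quarter caseload counts
    lam_t = np.repeat(physicians["targeted_rate"].to_numpy(), n_q)
    n_targ = rng.poisson(lam_t).reshape(n_phys, n_q)
    n_nont = rng.poisson(
        config.patients_per_physician_quarter, size=(n_phys, n_q)
    )

    # expand physician-quarter cells into admission rows (targeted stream
    # first, then non-targeted, both in physician-major order)
    def _expand(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = counts.ravel()
        phys_idx = np.repeat(np.arange(n_phys), counts.sum(axis=1))
        quarter = np.repeat(np.tile(np.arange(n_q), n_phys), flat)
        return phys_idx, quarter

    pt_idx, pt_quarter = _expand(n_targ)
    pn_idx, pn_quarter = _expand(n_nont)
    phys_idx = np.concatenate([pt_idx, pn_idx])
    quarter = np.concatenate([pt_quarter, pn_quarter])
    is_targeted_primary = np.zeros(len(phys_idx), dtype=bool)
    is_targeted_primary[: len(pt_idx)] = True
    n_rows = len(phys_idx)

    adm = pd.DataFrame(
        {
            "quarter": quarter.astype(np.int16),
            "targeted_primary": is_targeted_primary,
        }
    )
    adm["physician_id"] = physicians["physician_id"].to_numpy()[phys_idx]
    adm["hospital_id"] = physicians["hospital_id"].to_numpy()[phys_idx]
    primary_spec = physicians["primary_specialty"].to_numpy()[phys_idx]
    spec = _assign_specialty(
        primary_spec, config.specialties_per_hospital,
        config.off_primary_specialty_prob, rng,
    )
    adm["specialty_num"] = spec
    adm["ability"] = physicians["ability"].to_numpy()[phys_idx]

    # conditions: targeted stream draws a targeted code; non-targeted
    # stream draws from the catalogue and may carry a targeted secondary
    codes = np.array([c for c, _ in config.condition_catalogue])
    areas = np.array([a for _, a in config.condition_catalogue])
    pick = rng.integers(0, len(codes), size=n_rows)
    adm["condition_code"] = codes[pick]
    adm["diagnosis_area"] = areas[pick]
    targ_pick = rng.integers(0, len(TARGETED_CODES), size=int(is_targeted_primary.sum()))
    adm.loc[is_targeted_primary, "condition_code"] = np.array(TARGETED_CODES)[targ_pick]
    adm.loc[is_targeted_primary, "diagnosis_area"] = "same_area"
    adm["targeted_secondary"] = (~is_targeted_primary) & (
        rng.random(n_rows) < config.targeted_secondary_prob
    )
    adm["emergency"] = rng.random(n_rows) < 0.92

    cov = _draw_covariates(n_rows, rng)
    adm = pd.concat([adm, cov], axis=1)

    # --- patient sorting: post-policy reassignment in treated hospitals ---
    if config.sorting_strength > 0:
        treated_h = set(hospitals.loc[hospitals["region"] == "treated", "hospital_id"])
        med = physicians.groupby("hospital_id")["ability"].transform("median")
        physicians["_below"] = physicians["ability"] < med
        below_sets = {
            h: grp.index.to_numpy()
            for h, grp in physicians[physicians["_below"]].groupby("hospital_id")
        }
        above = ~physicians["_below"].to_numpy()[phys_idx]
        candidate = (
            adm["hospital_id"].isin(treated_h).to_numpy()
            & (adm["quarter"].to_numpy() >= config.first_post_quarter)
            & ~(adm["targeted_primary"] | adm["targeted_secondary"]).to_numpy()
            & above
        )
        move = candidate & (rng.random(n_rows) < config.sorting_strength)
        move_rows = np.flatnonzero(move)
        if len(move_rows):
            new_phys = np.empty(len(move_rows), dtype=int)
            hosp_arr = adm["hospital_id"].to_numpy()
            for h in treated_h:
                pool = below_sets.get(h)
                here = hosp_arr[move_rows] == h
                if pool is None or not here.any():
                    continue
                new_phys[here] = pool[rng.integers(0, len(pool), size=int(here.sum()))]
            has_pool = np.isin(hosp_arr[move_rows],
                               [h for h in treated_h if h in below_sets])
            move_rows = move_rows[has_pool]
            new_phys = new_phys[has_pool]
            adm.iloc[move_rows, adm.columns.get_loc("physician_id")] = (
                physicians["physician_id"].to_numpy()[new_phys]
            )
            adm.iloc[move_rows, adm.columns.get_loc("ability")] = (
                physicians["ability"].to_numpy()[new_phys]
            )
            adm.iloc[move_rows, adm.columns.get_loc("specialty_num")] = (
                physicians["primary_specialty"].to_numpy()[new_phys]
            )
            primary_spec = primary_spec.copy()
            primary_spec[move_rows] = physicians["primary_specialty"].to_numpy()[new_phys]

    adm["specialty_id"] = "S" + adm["specialty_num"].astype(str).str.zfill(2)
    adm["contracted_specialty"] = adm["specialty_num"].to_numpy() == primary_spec
    adm["patient_id"] = [f"PT{i:07d}" for i in range(n_rows)]

    qstarts = np.array(
        [quarter_start(q).to_datetime64() for q in range(n_q)]
    )
    day_offset = rng.integers(0, 90, size=n_rows)
    adm["admission_date"] = pd.Series(
        qstarts[adm["quarter"].to_numpy()]
    ) + pd.to_timedelta(day_offset, unit="D")

    # --- realized exposures (shared implementation with the estimator) ---
    x = direct_exposure(adm, timeline).set_index(["physician_id", "hospital_id"])
    z = indirect_exposure(adm, timeline).set_index(["physician_id", "hospital_id"])
    key = pd.MultiIndex.from_frame(adm[["physician_id", "hospital_id"]])
    x_row = x["x_direct"].reindex(key).to_numpy()
    z_row = z["z_indirect"].reindex(key).to_numpy()

    # --- mortality probability on the probability scale ---
    hosp_eff = hospitals.set_index("hospital_id")["hospital_effect"]
    treated_map = hospitals.set_index("hospital_id")["region"] == "treated"
    h_eff = hosp_eff.reindex(adm["hospital_id"]).to_numpy()
    is_treated = treated_map.reindex(adm["hospital_id"]).to_numpy()
    post = adm["quarter"].to_numpy() >= config.first_post_quarter

    eff = config.covariate_effects
    band = np.minimum((adm["age_years"].to_numpy() - 19) // 10, 7).clip(min=0)
    cov_term = (
        eff.get("age_band", 0.0) * (band - _CENTRES["age_band"])
        + eff.get("male", 0.0) * ((adm["sex"] == "M").to_numpy() - _CENTRES["male"])
        + eff.get("comorbidity_flag", 0.0)
        * (adm["comorbidity_count"].to_numpy() - _CENTRES["comorbidity_flag"])
        + eff.get("deprivation", 0.0) * adm["deprivation_score"].to_numpy()
        + eff.get("via_ae", 0.0) * (adm["via_ae"].to_numpy() - _CENTRES["via_ae"])
        + eff.get("admitted_from_home", 0.0)
        * (adm["admitted_from_home"].to_numpy() - _CENTRES["admitted_from_home"])
        + eff.get("weekend", 0.0) * (adm["weekend"].to_numpy() - _CENTRES["weekend"])
    )
    p = (
        config.baseline_mortality
        + h_eff
        - adm["ability"].to_numpy()  # abler physicians lose fewer patients
        + config.secular_trend_per_quarter * adm["quarter"].to_numpy()
        + cov_term
        + is_treated * post * (
            config.true_theta / 100.0
            + config.true_mu / 100.0 * x_row
            + config.true_mu_quadratic / 100.0 * x_row**2
            + config.true_phi / 100.0 * z_row
        )
        + is_treated
        * (adm["quarter"].to_numpy() == timeline.anticipation_quarter)
        * (config.anticipation_effect / 100.0)
    )
    prob_trace = p.copy()
    p_clipped = np.clip(p, 0.001, 0.999)

    died30 = rng.random(n_rows) < p_clipped
    death_offset = np.full(n_rows, -1)
    death_offset[died30] = rng.integers(0, 31, size=int(died30.sum()))
    late = (~died30) & (rng.random(n_rows) < config.late_death_prob)
    death_offset[late] = rng.integers(31, 366, size=int(late.sum()))
    has_death = death_offset >= 0

    deaths = pd.DataFrame(
        {
            "patient_id": adm.loc[has_death, "patient_id"].to_numpy(),
            "death_date": adm.loc[has_death, "admission_date"].to_numpy()
            + pd.to_timedelta(death_offset[has_death], unit="D"),
        }
    )

    # --- extra emergency admissions inside decedents' final 30 days ---
    readmit_pool = np.flatnonzero(died30 & (death_offset >= 1))
    take = readmit_pool[
        rng.random(len(readmit_pool)) < config.readmit_near_death_prob
    ]
    if len(take):
        extra = adm.iloc[take].copy()
        gap = rng.integers(1, death_offset[take] + 1)
        extra["admission_date"] = extra["admission_date"] + pd.to_timedelta(gap, unit="D")
        new_q = np.searchsorted(qstarts, extra["admission_date"].to_numpy(), side="right") - 1
        extra["quarter"] = np.minimum(new_q, n_q - 1).astype(np.int16)
        extra["emergency"] = True
        extra["targeted_primary"] = False
        extra["targeted_secondary"] = False
        # readmitted under a random physician of the same hospital
        hosp_groups = {
            h: grp.index.to_numpy() for h, grp in physicians.groupby("hospital_id")
        }
        new_idx = np.array(
            [
                hosp_groups[h][rng.integers(0, len(hosp_groups[h]))]
                for h in extra["hospital_id"]
            ]
        )
        extra["physician_id"] = physicians["physician_id"].to_numpy()[new_idx]
        spec_num = physicians["primary_specialty"].to_numpy()[new_idx]
        extra["specialty_num"] = spec_num
        extra["specialty_id"] = "S" + pd.Series(spec_num, index=extra.index).astype(str).str.zfill(2)
        extra["contracted_specialty"] = True
        pick = rng.integers(0, len(codes), size=len(extra))
        extra["condition_code"] = codes[pick]
        extra["diagnosis_area"] = areas[pick]
        adm = pd.concat([adm, extra], ignore_index=True)

    adm = adm[ADMISSION_COLUMNS].reset_index(drop=True)
    for col in ("emergency", "targeted_primary", "targeted_secondary",
                "admitted_from_home", "via_ae", "weekend", "contracted_specialty"):
        adm[col] = adm[col].astype(bool)

    hospitals_out = hospitals[
        ["hospital_id", "region", "trust_type", "foundation_status"]
    ].copy()
    return SimulatedStudy(
        admissions=adm,
        deaths=deaths.reset_index(drop=True),
        hospitals=hospitals_out,
        config=config,
        seed=seed,
        prob_trace=prob_trace,
    )


def simulate_panel(
    config: DGPConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Admission and death tables for one draw (see :func:`simulate_study`)."""
    study = simulate_study(config, seed)
    return study.admissions, study.deaths


def true_effects(config: DGPConfig) -> tuple[float, float, float]:
    """The embedded (theta, mu, phi) in percentage points."""
    return config.true_effects()


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write admissions/deaths/hospitals as CSV plus a reproducibility
    manifest (config hash, full config, seed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    adm = study.admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"]).dt.strftime("%Y-%m-%d")
    adm.to_csv(out / "admissions.csv", index=False)
    deaths = study.deaths.copy()
    deaths["death_date"] = pd.to_datetime(deaths["death_date"]).dt.strftime("%Y-%m-%d")
    deaths.to_csv(out / "deaths.csv", index=False)
    study.hospitals.to_csv(out / "hospitals.csv", index=False)
    manifest = {
        "seed": study.seed,
        "config_hash": study.config.config_hash(),
        "config": study.config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_study(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_study`."""
    d = Path(indir)
    adm = pd.read_csv(d / "admissions.csv", parse_dates=["admission_date"])
    deaths = pd.read_csv(d / "deaths.csv", parse_dates=["death_date"])
    hospitals = pd.read_csv(d / "hospitals.csv")
    return adm, deaths, hospitals


__all__ = [
    "SimulatedStudy", "simulate_study", "simulate_panel", "true_effects",
    "write_study", "read_study", "build_scenario",
]
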