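"""Cohort construction: 30-day mortality outcome, inclusion/exclusion
filters, the balanced physician panel, and analysis-panel assembly.

The analysis sample is built from admission-level records of non-targeted
emergency patients. Filters are applied sequentially, in a fixed order, and
an exclusion log records how many rows each rule removed *given* the rules
before it (counts are order-dependent by construction):

1. ``age``         — patients under 19 removed;
2. ``catalogue``   — condition code not in the non-targeted catalogue;
3. ``targeted``    — a targeted primary or secondary diagnosis;
4. ``attribution`` — admissions after the first emergency admission inside
                     the patient's final 30 days of life (the first such
                     admission keeps the death);
5. ``unbalanced``  — physician-hospital pairs without at least one retained
                     admission in every quarter of the study window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MORTALITY_WINDOW_DAYS = 30  # inclusive: death on day 30 counts
MIN_AGE = 19


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class PolicyTimeline:
    """Partition of the quarterly study window into pre and post periods."""

    quarters: tuple[int, ...]
    first_post_quarter: int

    def __post_init__(self) -> None:
        q = self.quarters
        if len(q) == 0:
            raise CohortError("timeline window has zero quarters")
        if list(q) != list(range(q[0], q[0] + len(q))):
            raise CohortError("quarters must be contiguous and ordered")
        if not (q[0] < self.first_post_quarter <= q[-1]):
            raise CohortError(
                "first_post_quarter must split the window into non-empty "
                "pre and post periods"
            )

    @classmethod
    def from_window(cls, quarters_pre: int, quarters_post: int) -> "PolicyTimeline":
        return cls(
            quarters=tuple(range(quarters_pre + quarters_post)),
            first_post_quarter=quarters_pre,
        )

    @property
    def pre_quarters(self) -> tuple[int, ...]:
        return tuple(t for t in self.quarters if t < self.first_post_quarter)

    @property
    def post_quarters(self) -> tuple[int, ...]:
        return tuple(t for t in self.quarters if t >= self.first_post_quarter)

    @property
    def anticipation_quarter(self) -> int:
        """The final pre-policy quarter (pilot period)."""
        return self.pre_quarters[-1]

    def post_indicator(self, quarter: pd.Series) -> pd.Series:
        return (quarter >= self.first_post_quarter).astype(np.int8)


@dataclass
class ExclusionLog:
    """Sequential removal counts, one entry per filter rule."""

    input_rows: int = 0
    age: int = 0
    catalogue: int = 0
    targeted: int = 0
    attribution: int = 0
    unbalanced: int = 0

    @property
    def output_rows(self) -> int:
        return self.input_rows - (
            self.age + self.catalogue + self.targeted
            + self.attribution + self.unbalanced
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "input_rows": self.input_rows,
            "age": self.age,
            "catalogue": self.catalogue,
            "targeted": self.targeted,
            "attribution": self.attribution,
            "unbalanced": self.unbalanced,
            "output_rows": self.output_rows,
        }


def flag_mortality_30d(admissions: pd.DataFrame, deaths: pd.DataFrame) -> pd.Series:
    """30-day mortality indicator per admission.

    ``outcome = 1`` iff the patient has a registered death date and
    ``0 <= death_date - admission_date <= 30`` days (day 30 inclusive).
    Raises :class:`CohortError` if any patient carries more than one death
    date, listing the offending keys.
    """
    if len(deaths):
        dup = deaths.loc[deaths["patient_id"].duplicated(), "patient_id"]
        if len(dup):
            raise CohortError(
                "duplicate death dates for patients: "
                f"{sorted(dup.unique().tolist())}"
            )
    merged = admissions[["patient_id", "admission_date"]].merge(
        deaths[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    delta = (
        pd.to_datetime(merged["death_date"]) - pd.to_datetime(merged["admission_date"])
    ).dt.days
    out = ((delta >= 0) & (delta <= MORTALITY_WINDOW_DAYS)).astype(np.int8)
    out.index = admissions.index
    out.name = "outcome_30d"
    return out


def _attribution_drop_mask(admissions: pd.DataFrame, deaths: pd.DataFrame) -> pd.Series:
    """True for admissions that occur after the first *emergency* admission
    within the patient's last 30 days of life.

    The earliest emergency admission in that window is kept (it is the one
    the death is attributed to); every admission strictly later in the
    window is dropped. Ties on date are broken by stable input order.
    """
    drop = pd.Series(False, index=admissions.index)
    if not len(deaths):
        return drop
    cols = admissions[["patient_id", "admission_date", "emergency"]].copy()
    cols["admission_date"] = pd.to_datetime(cols["admission_date"])
    cols = cols.merge(
        deaths[["patient_id", "death_date"]], on="patient_id", how="left"
    ).set_index(admissions.index)
    cols["death_date"] = pd.to_datetime(cols["death_date"])
    in_window = (
        cols["death_date"].notna()
        & (cols["admission_date"] >= cols["death_date"] - pd.Timedelta(days=MORTALITY_WINDOW_DAYS))
        & (cols["admission_date"] <= cols["death_date"])
    )
    w = cols[in_window].copy()
    if not len(w):
        return drop
    # stable order within patient: by date, then original row position
    w["_pos"] = np.arange(len(w))
    w = w.sort_values(["patient_id", "admission_date", "_pos"], kind="stable")
    w["_rank"] = w.groupby("patient_id").cumcount()
    # rank of the first emergency admission per patient (inf if none)
    emerg = w[w["emergency"].astype(bool)]
    first_emerg = emerg.groupby("patient_id")["_rank"].min()
    w = w.join(first_emerg.rename("_first_emerg"), on="patient_id")
    drop_idx = w.index[w["_rank"] > w["_first_emerg"].fillna(np.inf)]
    drop.loc[drop_idx] = True
    return drop


def apply_exclusions(
    admissions: pd.DataFrame,
    deaths: pd.DataFrame,
    catalogue: set[str] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the age / condition-catalogue / targeted-diagnosis /
    death-attribution filters in order; return the retained rows and the
    sequential exclusion log.

    ``catalogue`` is the set of admissible non-targeted condition codes;
    when ``None``, the codes present among non-targeted admissions define
    it (every code passes).
    """
    log = ExclusionLog(input_rows=len(admissions))
    df = admissions

    keep = df["age_years"] >= MIN_AGE
    log.age = int((~keep).sum())
    df = df[keep]

    if catalogue is not None:
        keep = df["condition_code"].isin(catalogue)
        log.catalogue = int((~keep).sum())
        df = df[keep]

    keep = ~(df["targeted_primary"].astype(bool) | df["targeted_secondary"].astype(bool))
    log.targeted = int((~keep).sum())
    df = df[keep]

    drop = _attribution_drop_mask(df, deaths)
    log.attribution = int(drop.sum())
    df = df[~drop]

    return df.copy(), log


def enforce_balanced_panel(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.DataFrame:
    """Keep only physician-hospital pairs with >= 1 admission in every
    quarter of the study window; drop all rows of non-qualifying pairs."""
    window = set(timeline.quarters)
    if not window:
        raise CohortError("timeline window has zero quarters")
    present = (
        admissions[admissions["quarter"].isin(window)]
        .groupby(["physician_id", "hospital_id"])["quarter"]
        .nunique()
    )
    qualifying = present[present == len(window)].index
    idx = pd.MultiIndex.from_frame(admissions[["physician_id", "hospital_id"]])
    return admissions[idx.isin(qualifying)].copy()


def build_cohort(
    admissions: pd.DataFrame,
    deaths: pd.DataFrame,
    timeline: PolicyTimeline,
    catalogue: set[str] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full filter chain: exclusions, balanced panel, outcome flag."""
    filtered, log = apply_exclusions(admissions, deaths, catalogue=catalogue)
    balanced = enforce_balanced_panel(filtered, timeline)
    log.unbalanced = len(filtered) - len(balanced)
    balanced["outcome_30d"] = flag_mortality_30d(balanced, deaths)
    return balanced, log


def assemble_panel(
    admissions: pd.DataFrame,
    hospital_attrs: pd.DataFrame,
    timeline: PolicyTimeline,
    deaths: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join hospital attributes and policy indicators onto filtered
    admissions, producing the analysis panel.

    Requires every admission's hospital to appear exactly once in
    ``hospital_attrs`` (columns ``hospital_id``, ``region``, ``trust_type``,
    ``foundation_status``). ``treated_region`` is 1 for the treated region
    tag, 0 otherwise; ``post_indicator`` comes from the timeline.
    """
    unknown = set(admissions["hospital_id"]) - set(hospital_attrs["hospital_id"])
    if unknown:
        raise CohortError(f"admissions reference unknown hospitals: {sorted(unknown)}")
    if hospital_attrs["hospital_id"].duplicated().any():
        raise CohortError("hospital_attrs has duplicate hospital_id rows")
    panel = admissions.merge(
        hospital_attrs[["hospital_id", "region", "trust_type", "foundation_status"]],
        on="hospital_id",
        how="left",
        validate="many_to_one",
    ).set_index(admissions.index)
    panel["treated_region"] = (panel["region"] == "treated").astype(np.int8)
    panel["post_indicator"] = timeline.post_indicator(panel["quarter"])
    if "outcome_30d" not in panel.columns:
        if deaths is None:
            raise CohortError(
                "admissions lack outcome_30d and no deaths table was given"
            )
        panel["outcome_30d"] = flag_mortality_30d(panel, deaths)
    return panel


def hospital_quarter_volumes(admissions: pd.DataFrame) -> pd.DataFrame:
    """Per hospital-quarter emergency and elective admission volumes
    (time-varying hospital covariates for the outcome model)."""
    g = admissions.groupby(["hospital_id", "quarter"], observed=True)
    vol = g.agg(
        emergency_volume=("emergency", "sum"),
        total_volume=("emergency", "size"),
    ).reset_index()
    vol["elective_volume"] = vol["total_volume"] - vol["emergency_volume"]
    return vol[["hospital_id", "quarter", "emergency_volume", "elective_volume"]]
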