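"""Physician exposure to the incentivized (targeted) conditions.

Direct exposure ``x_direct`` is the physician's mean number of targeted
patients per quarter over the post-policy period. Indirect exposure
``z_indirect`` is the specialty-weighted average of the direct exposure of
the physician's peers:

    z_p = sum_s (n_ps / N_p) * sum_{q != p} [n_qs / (N_s - n_ps)] * x_q

where n_ps counts the patients physician p treated in specialty s during
the post period, N_p = sum_s n_ps, and N_s is the specialty total. The
outer weights spread p's caseload over their specialties; the inner
weights average peers by their share of the specialty's remaining
caseload. A specialty where p works alone contributes zero.

All counts are admission-level over the post-policy period only; exposure
is a fixed physician-hospital attribute, not a time-varying regressor. A
patient is targeted if either the primary or a secondary diagnosis is a
targeted condition. Peer weights count all patients, targeted included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import PolicyTimeline

KEY = ["physician_id", "hospital_id"]


class ExposureError(ValueError):
    pass


def _targeted_mask(admissions: pd.DataFrame) -> pd.Series:
    return admissions["targeted_primary"].astype(bool) | admissions[
        "targeted_secondary"
    ].astype(bool)


def _post_rows(admissions: pd.DataFrame, timeline: PolicyTimeline) -> pd.DataFrame:
    post = set(timeline.post_quarters)
    if not post:
        raise ExposureError("post period is empty")
    return admissions[admissions["quarter"].isin(post)]


def direct_exposure(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.DataFrame:
    """Mean targeted patients per post-policy quarter, per physician-hospital.

    Quarters with no targeted patients contribute zeros: the denominator is
    always the number of post-policy quarters. Physician-hospital pairs
    present anywhere in ``admissions`` but without targeted post-period
    patients get ``x_direct = 0``.
    """
    n_post = len(timeline.post_quarters)
    post = _post_rows(admissions, timeline)
    targeted_counts = (
        post[_targeted_mask(post)].groupby(KEY, observed=True).size()
    )
    universe = admissions[KEY].drop_duplicates()
    out = universe.copy()
    out["x_direct"] = (
        targeted_counts.reindex(pd.MultiIndex.from_frame(universe)).fillna(0).values
        / n_post
    )
    return out.reset_index(drop=True)


def _post_counts(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-period caseload counts: per (physician, hospital, specialty)
    and per (physician, hospital)."""
    post = _post_rows(admissions, timeline)
    nps = (
        post.groupby(KEY + ["specialty_id"], observed=True)
        .size()
        .rename("n_ps")
        .reset_index()
    )
    np_tot = nps.groupby(KEY, observed=True)["n_ps"].sum().rename("n_p").reset_index()
    return nps, np_tot


def indirect_exposure(
    admissions: pd.DataFrame,
    timeline: PolicyTimeline,
    peer_exposure: pd.DataFrame | None = None,
    value_col: str = "x_direct",
    out_col: str = "z_indirect",
) -> pd.DataFrame:
    """Peer-weighted indirect exposure per physician-hospital.

    ``peer_exposure`` supplies each peer's exposure value (defaults to
    :func:`direct_exposure` on the same admissions); passing the share-based
    measure instead yields the share variant. Physicians with no peers in
    any of their specialties get 0. A physician-hospital pair with no
    post-period patients cannot be weighted and raises.
    """
    if peer_exposure is None:
        peer_exposure = direct_exposure(admissions, timeline)
    nps, np_tot = _post_counts(admissions, timeline)

    universe = admissions[KEY].drop_duplicates()
    missing = universe.merge(np_tot, on=KEY, how="left")
    empty = missing[missing["n_p"].isna()]
    if len(empty):
        raise ExposureError(
            "physician-hospital pairs with zero post-period patients: "
            f"{[tuple(r) for r in empty[KEY].itertuples(index=False)]}"
        )

    df = nps.merge(np_tot, on=KEY)
    df = df.merge(peer_exposure[KEY + [value_col]], on=KEY, how="left")
    if df[value_col].isna().any():
        raise ExposureError("peer_exposure does not cover every physician")

    grp = df.groupby(["hospital_id", "specialty_id"], observed=True)
    df["N_s"] = grp["n_ps"].transform("sum")
    # sum over the whole specialty of n_qs * x_q; subtract own term for peers
    df["_wx"] = df["n_ps"] * df[value_col]
    df["T_s"] = grp["_wx"].transform("sum")
    denom = df["N_s"] - df["n_ps"]
    inner = np.where(denom > 0, (df["T_s"] - df["_wx"]) / denom.replace(0, 1), 0.0)
    df["_contrib"] = (df["n_ps"] / df["n_p"]) * inner
    z = df.groupby(KEY, observed=True)["_contrib"].sum().rename(out_col).reset_index()
    out = universe.merge(z, on=KEY, how="left").fillna({out_col: 0.0})
    return out.reset_index(drop=True)


def specialty_exposure(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.DataFrame:
    """Mean targeted patients per post quarter, per specialty-hospital."""
    n_post = len(timeline.post_quarters)
    post = _post_rows(admissions, timeline)
    targeted = (
        post[_targeted_mask(post)]
        .groupby(["hospital_id", "specialty_id"], observed=True)
        .size()
    )
    universe = admissions[["hospital_id", "specialty_id"]].drop_duplicates()
    out = universe.copy()
    out["x_specialty"] = (
        targeted.reindex(pd.MultiIndex.from_frame(universe)).fillna(0).values / n_post
    )
    return out.reset_index(drop=True)


def condition_restricted_indirect(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.DataFrame:
    """Indirect exposure restricted to peers treating shared conditions.

    Within each specialty, the peer set of physician p is restricted to
    physicians q with at least one post-period admission whose condition
    code p also treated in that specialty; the within-specialty weights are
    renormalized over the restricted peer set. An empty restricted set
    contributes zero.
    """
    x = direct_exposure(admissions, timeline).set_index(KEY)["x_direct"]
    post = _post_rows(admissions, timeline)
    nps, np_tot = _post_counts(admissions, timeline)
    np_map = np_tot.set_index(KEY)["n_p"]

    # condition sets per (hospital, specialty, physician)
    cond_sets = (
        post.groupby(["hospital_id", "specialty_id", "physician_id"], observed=True)[
            "condition_code"
        ]
        .agg(lambda s: frozenset(s))
        .to_dict()
    )

    universe = admissions[KEY].drop_duplicates()
    z = {tuple(r): 0.0 for r in universe.itertuples(index=False)}
    for (h, s), block in nps.groupby(["hospital_id", "specialty_id"], observed=True):
        phys = block["physician_id"].to_numpy()
        n_arr = block["n_ps"].to_numpy(dtype=float)
        conds = [cond_sets.get((h, s, p), frozenset()) for p in phys]
        xs = np.array([x.get((p, h), 0.0) for p in phys])
        for i, p in enumerate(phys):
            share = (p, h)
            peers = np.array(
                [j for j in range(len(phys)) if j != i and conds[i] & conds[j]],
                dtype=int,
            )
            if len(peers) == 0:
                continue
            w = n_arr[peers]
            inner = float(np.dot(w, xs[peers]) / w.sum())
            z[share] += (n_arr[i] / float(np_map[share])) * inner
    out = universe.copy()
    out["z_condition_restricted"] = [
        z[tuple(r)] for r in universe.itertuples(index=False)
    ]
    return out.reset_index(drop=True)


def share_exposure(
    admissions: pd.DataFrame, timeline: PolicyTimeline
) -> pd.DataFrame:
    """Share-based exposure: targeted / all post-period patients, and the
    peer-weighted average of that share."""
    post = _post_rows(admissions, timeline)
    g = post.groupby(KEY, observed=True)
    counts = g.agg(total=("quarter", "size")).reset_index()
    targ = (
        post[_targeted_mask(post)].groupby(KEY, observed=True).size().rename("targ")
    )
    counts = counts.merge(targ, on=KEY, how="left").fillna({"targ": 0})
    universe = admissions[KEY].drop_duplicates()
    counts = universe.merge(counts, on=KEY, how="left")
    if counts["total"].isna().any() or (counts["total"] == 0).any():
        bad = counts.loc[
            counts["total"].isna() | (counts["total"] == 0), KEY
        ]
        raise ExposureError(
            "physician-hospital pairs with zero post-period patients: "
            f"{[tuple(r) for r in bad.itertuples(index=False)]}"
        )
    counts["x_share"] = counts["targ"] / counts["total"]
    shares = counts[KEY + ["x_share"]]
    z = indirect_exposure(
        admissions, timeline, peer_exposure=shares,
        value_col="x_share", out_col="z_share",
    )
    return shares.merge(z, on=KEY)


def compute_exposure_table(
    admissions: pd.DataFrame,
    timeline: PolicyTimeline,
    variants: bool = True,
) -> pd.DataFrame:
    """All exposure measures in one frame keyed (physician_id, hospital_id).

    With ``variants=False`` only the main ``x_direct``/``z_indirect`` pair
    is computed (the robustness variants are comparatively expensive).
    """
    table = direct_exposure(admissions, timeline)
    table = table.merge(indirect_exposure(admissions, timeline), on=KEY)
    if variants:
        table = table.merge(condition_restricted_indirect(admissions, timeline), on=KEY)
        table = table.merge(share_exposure(admissions, timeline), on=KEY)
    return table
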