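"""Two-stage difference-in-differences estimation with fixed-effect
absorption and cluster-robust inference.

Stage 1 fits a two-way fixed-effects linear probability model of 30-day
mortality on control-region admissions:

    Y_iht = A_h' a_t + B_ht b + C_iht g + eta_h + sigma_t + e_iht

(hospital attributes interacted with quarter, time-varying hospital
covariates, patient covariates, hospital and quarter intercepts). The
fitted covariate and time coefficients — explicitly excluding the control
hospital intercepts, which have no counterpart for treated hospitals —
predict each treated-region patient's expected mortality; the gap

    ytilde = Y - Yhat

is then regressed, within the treated region only, on the post-policy
indicator (average spillover, delta) or on the exposure decomposition

    ytilde = theta*D + mu*X*D + phi*Z*D + pi_ph + e

with physician-hospital fixed effects absorbed. Exposures are not demeaned:
theta is the effect on patients of zero-exposure physicians by
construction. Coefficients are reported in percentage points (probability
scale x 100) with CR1 hospital-clustered standard errors.

Fixed effects are absorbed by within-group demeaning (exact for one-way
structures); collinear design columns are dropped deterministically,
first-come kept. Levels absorbed in either stage cancel in the second
stage, so the missing treated-hospital intercepts from stage 1 are
harmless by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator

from .cohort import PolicyTimeline


class EstimationError(ValueError):
    pass


class CollinearityError(EstimationError):
    """Requested regressors are collinear after fixed-effect absorption."""


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

class DesignBuilder:
    """Reproducible design-matrix construction with frozen category sets.

    ``numeric`` columns enter as-is (booleans cast to float); ``categorical``
    columns expand to dummies with the first (sorted) level as reference;
    ``by_quarter`` entries interact a column with quarter dummies (reference
    quarter excluded) — categorical columns contribute level x quarter
    dummies, numeric columns contribute value x quarter columns. Transforming
    rows with a category level unseen at fit time raises (no silent
    extrapolation).
    """

    def __init__(
        self,
        numeric: list[str] | None = None,
        categorical: list[str] | None = None,
        by_quarter: list[str] | None = None,
        quarter_col: str = "quarter",
    ) -> None:
        self.numeric = list(numeric or [])
        self.categorical = list(categorical or [])
        self.by_quarter = list(by_quarter or [])
        self.quarter_col = quarter_col
        self.categories_: dict[str, list] = {}
        self.quarters_: list[int] = []

    def fit(self, df: pd.DataFrame, domain: pd.DataFrame | None = None) -> "DesignBuilder":
        """Freeze category sets and the quarter window.

        ``domain``, when given, supplies the category universe (e.g. the
        full panel when fitting on control rows only): levels absent from
        the fit data then yield all-zero columns that the collinearity
        filter removes, instead of unseen-level errors at predict time.
        """
        src = df if domain is None else domain
        for col in self.categorical + [
            c for c in self.by_quarter if not pd.api.types.is_numeric_dtype(df[c])
        ]:
            self.categories_[col] = sorted(src[col].astype(str).unique())
        self.quarters_ = sorted(src[self.quarter_col].unique().tolist())
        return self

    def _dummies(self, df: pd.DataFrame, col: str, drop_first: bool) -> pd.DataFrame:
        levels = self.categories_[col]
        vals = df[col].astype(str)
        unseen = set(vals.unique()) - set(levels)
        if unseen:
            raise EstimationError(
                f"column {col!r} has levels unseen at fit time: {sorted(unseen)}"
            )
        use = levels[1:] if drop_first else levels
        out = pd.DataFrame(
            {f"{col}[{lv}]": (vals == lv).to_numpy(float) for lv in use},
            index=df.index,
        )
        return out

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        q = df[self.quarter_col]
        unseen_q = set(q.unique()) - set(self.quarters_)
        if unseen_q:
            raise EstimationError(f"quarters unseen at fit time: {sorted(unseen_q)}")
        qarr = q.to_numpy()
        for t in self.quarters_[1:]:
            cols[f"q[{t}]"] = (qarr == t).astype(float)
        for col in self.numeric:
            cols[col] = df[col].to_numpy(dtype=float)
        for col in self.categorical:
            block = self._dummies(df, col, drop_first=True)
            for c in block.columns:
                cols[c] = block[c].to_numpy()
        for col in self.by_quarter:
            if col in self.categories_:
                base = self._dummies(df, col, drop_first=True)
                base_cols = {c: base[c].to_numpy() for c in base.columns}
            else:
                base_cols = {col: df[col].to_numpy(dtype=float)}
            for t in self.quarters_[1:]:
                mask = (qarr == t).astype(float)
                for c, v in base_cols.items():
                    cols[f"{c}:q[{t}]"] = v * mask
        names = list(cols)
        M = np.column_stack([cols[c] for c in names]) if names else np.empty((len(df), 0))
        nan_cols = np.isnan(M).any(axis=0)
        if nan_cols.any():
            bad = [names[i] for i in np.flatnonzero(nan_cols)]
            raise EstimationError(f"design contains missing values in {bad}")
        return pd.DataFrame(M, columns=names, index=df.index)

    def fit_transform(self, df: pd.DataFrame,
                      domain: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.fit(df, domain=domain).transform(df)


def prepare_features(panel: pd.DataFrame) -> pd.DataFrame:
    """Add derived covariates used by the default specification
    (10-year age band and its interaction with sex)."""
    out = panel.copy()
    band = np.minimum((out["age_years"].to_numpy() - 19) // 10, 7).clip(min=0)
    out["age_band"] = band
    out["age_band_sex"] = out["sex"].astype(str) + band.astype(str)
    comorb = [c for c in out.columns if c.startswith("comorb_")]
    if comorb and "comorbidity_count" not in out.columns:
        out["comorbidity_count"] = out[comorb].to_numpy(dtype=float).sum(axis=1)
    return out


def default_covariates(panel: pd.DataFrame, physician_level: bool = False
                       ) -> dict[str, list[str]]:
    """Default stage-1 covariate specification, keyed for DesignBuilder.

    Patient level: age-band x sex dummies, deprivation, admission route
    flags, the 31 comorbidity flags. Hospital level: per-quarter volumes
    when present. Physician/specialty level (sorting adjustment): specialty
    dummies and the contracted-specialty flag.
    """
    comorb = [c for c in panel.columns if c.startswith("comorb_")]
    numeric = [
        c
        for c in (
            "deprivation_score", "via_ae", "admitted_from_home", "weekend",
            "emergency_volume", "elective_volume",
        )
        if c in panel.columns
    ] + comorb
    categorical = ["age_band_sex"]
    if physician_level:
        if "contracted_specialty" in panel.columns:
            numeric.append("contracted_specialty")
        if "specialty_id" in panel.columns:
            categorical.append("specialty_id")
    return {"numeric": numeric, "categorical": categorical}


# ---------------------------------------------------------------------------
# numerics: collinearity-aware OLS and fixed-effect absorption
# ---------------------------------------------------------------------------

def drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-9,
                   gram: np.ndarray | None = None) -> tuple[list[int], list[str]]:
    """Greedy first-come column selection to full rank.

    Incremental Cholesky on the Gram matrix: a column is kept iff its
    residual norm after projection on the kept set exceeds ``tol`` relative
    to its own norm. Returns (kept indices, dropped names).
    """
    n, k = X.shape
    G = X.T @ X if gram is None else gram
    kept: list[int] = []
    dropped: list[str] = []
    R = np.zeros((k, k))  # upper-triangular factor over kept columns
    m = 0
    for j in range(k):
        gjj = G[j, j]
        if gjj <= tol:
            dropped.append(names[j])
            continue
        if m == 0:
            d = gjj
            r = np.empty(0)
        else:
            r = np.linalg.solve(R[:m, :m].T, G[np.ix_(kept, [j])]).ravel()
            d = gjj - r @ r
        if d > tol * gjj:
            R[:m, m] = r
            R[m, m] = np.sqrt(d)
            kept.append(j)
            m += 1
        else:
            dropped.append(names[j])
    return kept, dropped


def _group_codes(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    if len(cols) == 1:
        return pd.factorize(df[cols[0]])[0]
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "\x1f" + df[c].astype(str)
    return pd.factorize(key)[0]


def _demean(M: np.ndarray, codes: np.ndarray) -> np.ndarray:
    n_groups = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if M.ndim == 1:
        sums = np.bincount(codes, weights=M, minlength=n_groups)
        return M - (sums / counts)[codes]
    n = len(codes)
    ind = sparse.csr_matrix(
        (np.ones(n), (codes, np.arange(n))), shape=(n_groups, n)
    )
    means = (ind @ M) / counts[:, None]
    return M - means[codes]


def cluster_vcov(
    X: np.ndarray,
    residuals: np.ndarray,
    clusters: np.ndarray,
    n_params: int | None = None,
) -> np.ndarray:
    """CR1 cluster-robust sandwich variance for OLS coefficients.

    V = c * (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1 with
    c = G/(G-1) * (N-1)/(N-K). ``n_params`` is K, the total parameter count
    including any absorbed fixed-effect levels (defaults to X's column
    count). Requires at least two clusters and no missing cluster ids.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    clusters = np.asarray(clusters)
    if pd.isna(clusters).any():
        raise EstimationError("cluster ids contain missing values")
    codes, uniq = pd.factorize(clusters)
    G = len(uniq)
    if G < 2:
        raise EstimationError(f"need >= 2 clusters, got {G}")
    n, k = X.shape
    K = n_params if n_params is not None else k
    bread = np.linalg.inv(X.T @ X)
    Xe = X * e[:, None]
    # per-cluster score sums
    S = np.zeros((G, k))
    for j in range(k):
        S[:, j] = np.bincount(codes, weights=Xe[:, j], minlength=G)
    meat = S.T @ S
    c = (G / (G - 1)) * ((n - 1) / (n - K))
    V = c * bread @ meat @ bread
    return (V + V.T) / 2.0


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class SpilloverEstimate:
    """Second-stage coefficients in percentage points with CR1 inference."""

    model: str
    terms: list[str]
    coef: dict[str, float]          # percentage points
    se: dict[str, float]
    pvalues: dict[str, float]
    vcov: np.ndarray                # percentage-point scale
    n_obs: int
    n_clusters: int
    fe_level: str
    dropped_groups: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "fe_level": self.fe_level,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "terms": {
                t: {"coef": self.coef[t], "se": self.se[t], "p": self.pvalues[t]}
                for t in self.terms
            },
        }


@dataclass
class EventStudyResult:
    """Pre-policy event-study path with a joint Wald pre-trend test and a
    separate linear-trend test."""

    coefficients: pd.DataFrame      # term, coef (pp), se (pp), p
    wald_stat: float
    wald_df: int
    wald_p: float
    trend_slope: float              # pp per quarter
    trend_se: float
    trend_p: float
    reference_quarter: int
    n_obs: int
    n_clusters: int

    @property
    def passes(self) -> bool:
        """Conventional pass/fail at the 5% level (both tests)."""
        return self.wald_p >= 0.05 and self.trend_p >= 0.05


# ---------------------------------------------------------------------------
# estimators (sklearn-style)
# ---------------------------------------------------------------------------

_FE_COLS = {
    "hospital": ["hospital_id"],
    "physician_hospital": ["physician_id", "hospital_id"],
}


class ControlOutcomeModel(BaseEstimator):
    """Stage-1 two-way fixed-effects linear probability model.

    Parameters
    ----------
    covariates : dict with ``numeric``/``categorical`` lists, or None for
        the default specification.
    fe : "hospital" or "physician_hospital" — the absorbed intercept level.
    attr_by_quarter : hospital attribute columns interacted with quarter
        dummies (time-varying effects of time-invariant attributes).
    exposure_by_quarter : numeric columns (physician exposures) interacted
        with quarter dummies; used by the decomposition pipeline so that
        untreated potential outcomes may vary with exposure.
    """

    def __init__(
        self,
        covariates: dict | None = None,
        fe: str = "hospital",
        attr_by_quarter: tuple[str, ...] = ("trust_type", "foundation_status"),
        exposure_by_quarter: tuple[str, ...] = (),
        outcome: str = "outcome_30d",
    ) -> None:
        self.covariates = covariates
        self.fe = fe
        self.attr_by_quarter = attr_by_quarter
        self.exposure_by_quarter = exposure_by_quarter
        self.outcome = outcome

    def fit(self, df: pd.DataFrame,
            domain: pd.DataFrame | None = None) -> "ControlOutcomeModel":
        if self.fe not in _FE_COLS:
            raise EstimationError(f"unknown fe level {self.fe!r}")
        if len(df) == 0:
            raise EstimationError("no control rows to fit stage 1 on")
        df = prepare_features(df)
        if domain is not None:
            domain = prepare_features(domain)
        cov = self.covariates
        if cov is None:
            cov = default_covariates(df, physician_level=self.fe == "physician_hospital")
        y = df[self.outcome].to_numpy(dtype=float)
        if np.all(y == y[0]):
            warnings.warn("stage-1 outcome is constant; fit is degenerate")
        attrs = [c for c in self.attr_by_quarter if c in df.columns]
        builder = DesignBuilder(
            numeric=cov.get("numeric", []),
            categorical=cov.get("categorical", []),
            by_quarter=attrs + list(self.exposure_by_quarter),
        )
        X = builder.fit_transform(df, domain=domain)
        Xarr = X.to_numpy(dtype=float)
        codes = _group_codes(df, _FE_COLS[self.fe])
        Xd = _demean(Xarr, codes)
        yd = _demean(y, codes)
        gram = Xd.T @ Xd
        kept, dropped = drop_collinear(Xd, list(X.columns), gram=gram)
        if dropped:
            warnings.warn(f"stage 1 dropped {len(dropped)} collinear columns")
        Xk = Xd[:, kept]
        beta = np.linalg.solve(gram[np.ix_(kept, kept)], Xk.T @ yd)
        self.builder_ = builder
        self.columns_ = [X.columns[i] for i in kept]
        self.dropped_ = dropped
        self.coef_ = pd.Series(beta, index=self.columns_)
        self.residuals_ = yd - Xk @ beta
        n_groups = int(codes.max() + 1)
        # clustered sampling variance of the slope coefficients; consumed
        # by the pre-trend test to propagate stage-1 uncertainty
        if df["hospital_id"].nunique() >= 2 and len(kept):
            self.vcov_ = cluster_vcov(
                Xk, self.residuals_, df["hospital_id"].to_numpy(),
                n_params=len(kept) + n_groups,
            )
        else:
            self.vcov_ = np.zeros((len(kept), len(kept)))
        # control-hospital (or physician-hospital) intercepts
        xb = Xarr[:, kept] @ beta
        resid_level = y - xb
        fe_codes, fe_keys = pd.factorize(
            pd.MultiIndex.from_frame(df[_FE_COLS[self.fe]])
            if len(_FE_COLS[self.fe]) > 1
            else df[_FE_COLS[self.fe][0]]
        )
        means = np.bincount(fe_codes, weights=resid_level) / np.bincount(fe_codes)
        self.eta_ = pd.Series(means, index=fe_keys)
        self.n_obs_ = len(df)
        self.n_groups_ = n_groups
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Expected mortality from covariate and time coefficients only —
        the absorbed intercepts are deliberately excluded (treated
        hospitals have none; the second stage absorbs levels)."""
        df = prepare_features(df)
        X = self.builder_.transform(df)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise EstimationError(f"design is missing fitted columns: {missing}")
        return X[self.columns_].to_numpy(dtype=float) @ self.coef_.to_numpy()


class GapRegression(BaseEstimator):
    """Absorbed-OLS regression of the mortality gap on post-policy terms
    with CR1 hospital-clustered inference.

    ``terms`` are column names in the frame passed to :meth:`fit`.
    Fixed-effect groups without variation in the post indicator are dropped
    (their coefficient contribution is nil and they bias the within
    transform); a requested term that is collinear after absorption raises
    :class:`CollinearityError`.
    """

    def __init__(
        self,
        terms: tuple[str, ...] = ("post",),
        fe: str = "physician_hospital",
        cluster: str = "hospital_id",
        model_tag: str = "",
        post_col: str = "post_indicator",
        allow_degenerate: bool = False,
    ) -> None:
        self.terms = terms
        self.fe = fe
        self.cluster = cluster
        self.model_tag = model_tag
        self.post_col = post_col
        self.allow_degenerate = allow_degenerate

    def fit(self, df: pd.DataFrame, outcome: str = "ytilde") -> "GapRegression":
        if self.fe not in _FE_COLS:
            raise EstimationError(f"unknown fe level {self.fe!r}")
        if len(df) == 0:
            raise EstimationError("empty gap panel")
        codes = _group_codes(df, _FE_COLS[self.fe])
        post = df[self.post_col].to_numpy(dtype=float)
        span = pd.DataFrame({"g": codes, "p": post}).groupby("g")["p"].agg(["min", "max"])
        good = span.index[span["min"] < span["max"]].to_numpy()
        dropped_groups = int(codes.max() + 1 - len(good))
        if dropped_groups:
            warnings.warn(
                f"dropping {dropped_groups} fixed-effect groups without "
                "pre/post variation"
            )
            keep = np.isin(codes, good)
            df = df[keep]
            codes = _group_codes(df, _FE_COLS[self.fe])
        if len(df) == 0:
            raise EstimationError("no groups with pre/post variation")
        X = df[list(self.terms)].to_numpy(dtype=float)
        y = df[outcome].to_numpy(dtype=float)
        Xd = _demean(X, codes)
        yd = _demean(y, codes)
        kept, dropped = drop_collinear(Xd, list(self.terms))
        if dropped and not self.allow_degenerate:
            raise CollinearityError(
                f"terms {dropped} are collinear after absorbing {self.fe} "
                "fixed effects; with zero-variance exposures use the "
                "average-spillover model instead"
            )
        if dropped:
            warnings.warn(
                f"dropping collinear terms {dropped}; the model collapses "
                "onto the remaining terms"
            )
            self.terms = tuple(t for t in self.terms if t not in dropped)
        Xk = Xd[:, kept]
        beta = np.linalg.solve(Xk.T @ Xk, Xk.T @ yd)
        resid = yd - Xk @ beta
        n_groups = int(codes.max() + 1)
        V = cluster_vcov(
            Xk, resid, df[self.cluster].to_numpy(),
            n_params=len(self.terms) + n_groups,
        )
        G = df[self.cluster].nunique()
        se = np.sqrt(np.diag(V))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        tstat = np.where((se == 0) & (beta == 0), 0.0, tstat)
        pvals = 2 * stats.t.sf(np.abs(tstat), df=G - 1)
        # percentage-point reporting scale
        self.coef_ = dict(zip(self.terms, 100.0 * beta))
        self.se_ = dict(zip(self.terms, 100.0 * se))
        self.pvalues_ = dict(zip(self.terms, pvals))
        self.vcov_ = 100.0 * 100.0 * V
        self.n_obs_ = len(df)
        self.n_clusters_ = int(G)
        self.dropped_groups_ = dropped_groups
        self.beta_prob_ = beta  # probability scale, for internal reuse
        self.residuals_ = resid
        self._Xd = Xk
        self._codes = codes
        self._rows = df.index
        self._vcov_prob = V
        return self

    def estimate(self) -> SpilloverEstimate:
        return SpilloverEstimate(
            model=self.model_tag or "+".join(self.terms),
            terms=list(self.terms),
            coef=self.coef_,
            se=self.se_,
            pvalues=self.pvalues_,
            vcov=self.vcov_,
            n_obs=self.n_obs_,
            n_clusters=self.n_clusters_,
            fe_level=self.fe,
            dropped_groups=self.dropped_groups_,
        )


# ---------------------------------------------------------------------------
# spec-surface functions
# ---------------------------------------------------------------------------

def fit_stage1(
    panel: pd.DataFrame,
    covariates: dict | None = None,
    fe: str = "hospital",
    exposure_by_quarter: tuple[str, ...] = (),
    domain: pd.DataFrame | None = None,
    attr_by_quarter: tuple[str, ...] = ("trust_type", "foundation_status"),
) -> ControlOutcomeModel:
    """Fit the stage-1 control-outcome model on control-region rows."""
    if "treated_region" in panel.columns and panel["treated_region"].any():
        raise EstimationError("stage 1 must be fit on control-region rows only")
    model = ControlOutcomeModel(
        covariates=covariates, fe=fe, exposure_by_quarter=exposure_by_quarter,
        attr_by_quarter=attr_by_quarter,
    )
    return model.fit(panel, domain=domain)


def predict_gap(fit: ControlOutcomeModel, treated: pd.DataFrame) -> pd.DataFrame:
    """Attach ``ytilde`` (actual minus expected mortality) to treated rows."""
    gaps = treated.copy()
    gaps["ytilde"] = treated[fit.outcome].to_numpy(dtype=float) - fit.predict(treated)
    if not np.isfinite(gaps["ytilde"]).all():
        raise EstimationError("non-finite mortality gaps")
    return gaps


def estimate_average_spillover(
    gaps: pd.DataFrame,
    timeline: PolicyTimeline,
    fe_level: str = "hospital",
) -> SpilloverEstimate:
    """Average spillover delta: gap regressed on the post indicator."""
    reg = GapRegression(
        terms=("post_indicator",), fe=fe_level,
        model_tag=f"average[{fe_level}]",
    ).fit(gaps)
    return reg.estimate()


def _decomposition_frame(
    gaps: pd.DataFrame,
    exposure: pd.DataFrame,
    x_col: str = "x_direct",
    z_col: str = "z_indirect",
    extra: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    df = gaps.merge(
        exposure, on=["physician_id", "hospital_id"], how="left",
        validate="many_to_one", suffixes=("", "_exp"),
    ).set_index(gaps.index)
    for col in (x_col, z_col):
        if df[col].isna().any():
            raise EstimationError(f"exposure column {col!r} missing for some physicians")
    D = df["post_indicator"].to_numpy(dtype=float)
    df["x_post"] = df[x_col].to_numpy(dtype=float) * D
    df["z_post"] = df[z_col].to_numpy(dtype=float) * D
    terms = ["post_indicator", "x_post", "z_post"]
    for name, expr in (extra or {}).items():
        df[name] = df.eval(expr).to_numpy(dtype=float) * D
        terms.append(name)
    return df, terms


def estimate_decomposition(
    gaps: pd.DataFrame,
    exposure: pd.DataFrame,
    timeline: PolicyTimeline,
    x_col: str = "x_direct",
    z_col: str = "z_indirect",
    extra: dict[str, str] | None = None,
    model_tag: str = "decomposition",
) -> SpilloverEstimate:
    """Exposure decomposition: theta (zero-exposure effect), mu (direct
    slope), phi (indirect slope), plus optional extra interaction terms
    given as ``{name: pandas-eval expression}`` each multiplied by the
    post indicator."""
    df, terms = _decomposition_frame(gaps, exposure, x_col, z_col, extra)
    reg = GapRegression(
        terms=tuple(terms), fe="physician_hospital", model_tag=model_tag,
    ).fit(df)
    est = reg.estimate()
    est.meta["term_map"] = {"theta": "post_indicator", "mu": "x_post", "phi": "z_post"}
    return est


def _stage1_correction(
    reg: GapRegression, stage1: "ControlOutcomeModel | None", df: pd.DataFrame
) -> np.ndarray:
    """Variance of the stage-2 coefficients induced by stage-1 sampling
    noise (probability scale).

    The mortality gap carries the stage-1 prediction error, a shock common
    to every treated observation in a quarter that hospital-clustered
    stage-2 variance cannot see. Since the stage-2 estimator is linear in
    the stage-1 coefficients, that component is B V1 B' with
    B = (X2'X2)^-1 X2' P, P the treated rows' stage-1 design (demeaned like
    the stage-2 design) and V1 the stage-1 clustered coefficient variance;
    the two stages use disjoint samples, so the pieces add.
    """
    if stage1 is None:
        return np.zeros((reg._Xd.shape[1], reg._Xd.shape[1]))
    P = stage1.builder_.transform(prepare_features(df.loc[reg._rows]))
    Parr = P[stage1.columns_].to_numpy(dtype=float)
    Pd = _demean(Parr, reg._codes)
    B = np.linalg.solve(reg._Xd.T @ reg._Xd, reg._Xd.T @ Pd)
    return B @ stage1.vcov_ @ B.T


def pretrend_event_study(
    gaps: pd.DataFrame,
    exposure: pd.DataFrame | None,
    timeline: PolicyTimeline,
    x_col: str = "x_direct",
    z_col: str = "z_indirect",
    stage1: "ControlOutcomeModel | None" = None,
) -> EventStudyResult:
    """Quarter-specific pre-policy contrasts with a joint Wald test.

    The reference quarter is the final pre-policy quarter; its coefficient
    is identically zero by construction. In decomposition mode (exposure
    given) each pre quarter also carries direct- and indirect-exposure
    interaction paths, all jointly tested. The linear-trend check regresses
    the gap on a pre-policy linear term in event time. When the fitted
    stage-1 model is supplied, its sampling uncertainty is propagated into
    the test variance (see :func:`_stage1_correction`); the Wald statistic
    is referred to an F(q, G-1) distribution.
    """
    present = set(gaps["quarter"].unique())
    pre = [t for t in timeline.pre_quarters if t in present]
    if len(pre) < 2:
        raise EstimationError("need >= 2 pre-policy quarters for a pre-trend test")
    ref = pre[-1]  # last observed pre-policy quarter
    decompose = exposure is not None
    if decompose:
        df, base_terms = _decomposition_frame(gaps, exposure, x_col, z_col)
        fe = "physician_hospital"
    else:
        df = gaps.copy()
        base_terms = ["post_indicator"]
        fe = "hospital"
    q = df["quarter"].to_numpy()
    pre_terms: list[str] = []
    for t in pre:
        if t == ref:
            continue
        dummy = (q == t).astype(float)
        name = f"pre_q{t}"
        df[name] = dummy
        pre_terms.append(name)
        if decompose:
            df[f"pre_q{t}_x"] = dummy * df[x_col].to_numpy(dtype=float)
            df[f"pre_q{t}_z"] = dummy * df[z_col].to_numpy(dtype=float)
            pre_terms += [f"pre_q{t}_x", f"pre_q{t}_z"]
    terms = tuple(pre_terms + base_terms)
    reg = GapRegression(terms=terms, fe=fe, model_tag="event_study").fit(df)
    Vfull = reg._vcov_prob + _stage1_correction(reg, stage1, df)

    idx = [list(terms).index(t) for t in pre_terms]
    b = np.array([reg.beta_prob_[i] for i in idx])
    V = Vfull[np.ix_(idx, idx)]
    qdf = len(pre_terms)
    G = reg.n_clusters_
    if np.any(b):
        wald = float(b @ np.linalg.lstsq(V, b, rcond=None)[0])
    else:
        wald = 0.0
    wald = max(wald, 0.0)
    fstat = wald / qdf
    wald_p = float(stats.f.sf(fstat, qdf, G - 1))

    # separate linear pre-trend: event-time slope over the pre period
    df["pre_trend"] = np.where(q < timeline.first_post_quarter, q - ref, 0.0)
    lin_terms = tuple(["pre_trend"] + base_terms)
    lin = GapRegression(terms=lin_terms, fe=fe, model_tag="pre_trend").fit(df)
    Vlin = lin._vcov_prob + _stage1_correction(lin, stage1, df)
    trend_se = float(np.sqrt(Vlin[0, 0]))
    if trend_se > 0:
        trend_t = lin.beta_prob_[0] / trend_se
    else:
        trend_t = 0.0 if lin.beta_prob_[0] == 0 else np.inf
    trend_p = float(2 * stats.t.sf(abs(trend_t), df=G - 1))

    se_full = np.sqrt(np.diag(Vfull))
    coef_rows = [
        {
            "term": t,
            "quarter": int(t.split("_")[1][1:]) if t.startswith("pre_q") else None,
            "coef_pp": reg.coef_[t],
            "se_pp": 100.0 * se_full[i],
            "p": reg.pvalues_[t],
        }
        for i, t in enumerate(terms)
    ]
    return EventStudyResult(
        coefficients=pd.DataFrame(coef_rows),
        wald_stat=wald,
        wald_df=qdf,
        wald_p=wald_p,
        trend_slope=lin.coef_["pre_trend"],
        trend_se=100.0 * trend_se,
        trend_p=trend_p,
        reference_quarter=ref,
        n_obs=reg.n_obs_,
        n_clusters=reg.n_clusters_,
    )


# ---------------------------------------------------------------------------
# the composite two-stage estimator
# ---------------------------------------------------------------------------

class TwoStageDiD(BaseEstimator):
    """End-to-end two-stage DiD estimator over an analysis panel.

    model="average"          : hospital FE both stages, patient+hospital
                               covariates; reports delta.
    model="sorting_adjusted" : physician-hospital FE both stages,
                               physician/specialty covariates added;
                               reports delta.
    model="decomposition"    : as sorting_adjusted plus exposure-by-quarter
                               adjustment in stage 1 and the exposure
                               interactions in stage 2; reports theta, mu,
                               phi (and any extra interaction terms).
    """

    def __init__(
        self,
        model: str = "decomposition",
        covariates: dict | None = None,
        x_col: str = "x_direct",
        z_col: str = "z_indirect",
        extra: dict[str, str] | None = None,
        adjust_stage1_exposure: bool = True,
    ) -> None:
        self.model = model
        self.covariates = covariates
        self.x_col = x_col
        self.z_col = z_col
        self.extra = extra
        self.adjust_stage1_exposure = adjust_stage1_exposure

    def fit(
        self,
        panel: pd.DataFrame,
        exposure: pd.DataFrame | None = None,
        timeline: PolicyTimeline | None = None,
    ) -> "TwoStageDiD":
        if self.model not in ("average", "sorting_adjusted", "decomposition"):
            raise EstimationError(f"unknown model {self.model!r}")
        if timeline is None:
            quarters = tuple(sorted(panel["quarter"].unique()))
            first_post = int(panel.loc[panel["post_indicator"] == 1, "quarter"].min())
            timeline = PolicyTimeline(quarters=quarters, first_post_quarter=first_post)
        fe = "hospital" if self.model == "average" else "physician_hospital"
        exposure_by_quarter: tuple[str, ...] = ()
        if self.model == "decomposition":
            if exposure is None:
                raise EstimationError("decomposition requires an exposure table")
            if self.adjust_stage1_exposure:
                cols = ["physician_id", "hospital_id", self.x_col, self.z_col]
                panel = panel.merge(
                    exposure[cols].drop_duplicates(),
                    on=["physician_id", "hospital_id"], how="left",
                    validate="many_to_one", suffixes=("", "_exp"),
                )
                if panel[self.x_col].isna().any():
                    raise EstimationError("exposure missing for some physicians")
                exposure_by_quarter = (self.x_col, self.z_col)
        controls = panel[panel["treated_region"] == 0]
        treated = panel[panel["treated_region"] == 1]
        if len(controls) == 0:
            raise EstimationError("no control-region rows")
        if len(treated) == 0:
            raise EstimationError("no treated-region rows")

        self.stage1_ = fit_stage1(
            controls, covariates=self.covariates, fe=fe,
            exposure_by_quarter=exposure_by_quarter, domain=panel,
        )
        self.gaps_ = predict_gap(self.stage1_, treated)
        self.timeline_ = timeline
        if self.model == "decomposition":
            self.estimate_ = estimate_decomposition(
                self.gaps_, exposure, timeline,
                x_col=self.x_col, z_col=self.z_col, extra=self.extra,
            )
        else:
            self.estimate_ = estimate_average_spillover(
                self.gaps_, timeline, fe_level=fe
            )
        return self

    def pretrend(self, exposure: pd.DataFrame | None = None) -> EventStudyResult:
        if self.model != "decomposition":
            exposure = None
        return pretrend_event_study(
            self.gaps_, exposure, self.timeline_,
            x_col=self.x_col, z_col=self.z_col, stage1=self.stage1_,
        )
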