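"""Estimator numerics: stage-1 fits and predictions, fixed-effect
absorption vs explicit dummy regression, CR1 clustered variance vs a
loop-over-clusters oracle, closed-form DiD equivalence, and the event
study."""

import numpy as np
import pandas as pd
import pytest

import spilldid as sd
from spilldid.cohort import PolicyTimeline
from spilldid.estimation import (
    CollinearityError,
    EstimationError,
    GapRegression,
    _decomposition_frame,
    drop_collinear,
)

NO_COVARIATES = {"numeric": [], "categorical": []}


def make_gap_frame(rng, n=500, n_hosp=6, n_phys=12, n_quarters=4, first_post=2):
    df = pd.DataFrame(
        {
            "hospital_id": rng.choice([f"H{i}" for i in range(n_hosp)], n),
            "quarter": rng.integers(0, n_quarters, n),
        }
    )
    df["physician_id"] = [
        f"{h}_P{p}" for h, p in zip(df["hospital_id"], rng.integers(0, n_phys // n_hosp, n))
    ]
    df["post_indicator"] = (df["quarter"] >= first_post).astype(int)
    df["ytilde"] = rng.normal(0, 0.1, n)
    return df


def control_panel(rng, n_hosp=4, n_quarters=4, rows_per_cell=30):
    rows = []
    for h in range(n_hosp):
        for q in range(n_quarters):
            for i in range(rows_per_cell):
                rows.append(
                    {
                        "hospital_id": f"H{h}",
                        "physician_id": f"H{h}_P{i % 3}",
                        "quarter": q,
                        "age_years": int(rng.integers(19, 95)),
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "deprivation_score": rng.normal(),
                        "outcome_30d": int(rng.random() < 0.1),
                        "treated_region": 0,
                        "trust_type": "acute",
                        "foundation_status": bool(h % 2),
                    }
                )
    return pd.DataFrame(rows)


class TestStageOne:
    def test_no_regressor_fit_reproduces_group_means(self, rng):
        """With an empty design the fitted value is the absorbed group
        mean; for a single hospital that is the control mean mortality."""
        panel = control_panel(rng, n_hosp=1)
        fit = sd.fit_stage1(
            panel, covariates=NO_COVARIATES, fe="hospital",
        )
        # quarter dummies remain; fitted + residual = outcome
        pred = fit.predict(panel)
        resid_level = panel["outcome_30d"].to_numpy() - pred
        eta = fit.eta_.iloc[0]
        assert np.allclose(resid_level - fit.residuals_, eta)

    def test_residuals_orthogonal_to_retained_regressors(self, rng):
        panel = control_panel(rng, n_hosp=5, rows_per_cell=50)
        fit = sd.fit_stage1(panel, fe="hospital")
        X = fit.builder_.transform(
            sd.estimation.prepare_features(panel)
        )[fit.columns_].to_numpy(dtype=float)
        from spilldid.estimation import _demean, _group_codes

        codes = _group_codes(panel, ["hospital_id"])
        Xd = _demean(X, codes)
        dots = np.abs(Xd.T @ fit.residuals_) / len(panel)
        assert dots.max() <= 1e-8

    def test_saturated_two_cell_design_fits_exactly(self):
        panel = pd.DataFrame(
            {
                "hospital_id": ["H0"] * 4,
                "physician_id": ["P0"] * 4,
                "quarter": [0, 0, 1, 1],
                "age_years": [50] * 4,
                "sex": ["F"] * 4,
                "outcome_30d": [0.2, 0.2, 0.5, 0.5],
                "treated_region": [0] * 4,
            }
        )
        fit = sd.fit_stage1(panel, covariates=NO_COVARIATES, fe="hospital")
        assert np.allclose(fit.residuals_, 0.0)

    def test_zero_control_rows_raises(self):
        with pytest.raises(EstimationError, match="no control rows"):
            sd.fit_stage1(pd.DataFrame(columns=["outcome_30d"]))

    def test_constant_outcome_warns(self, rng):
        panel = control_panel(rng, n_hosp=2, rows_per_cell=5)
        panel["outcome_30d"] = 1
        with pytest.warns(UserWarning, match="constant"):
            sd.fit_stage1(panel, covariates=NO_COVARIATES)

    def test_treated_rows_rejected(self, rng):
        panel = control_panel(rng, n_hosp=2, rows_per_cell=5)
        panel["treated_region"] = 1
        with pytest.raises(EstimationError, match="control-region rows only"):
            sd.fit_stage1(panel)


class TestPredictGap:
    def test_quarter_mean_prediction_up_to_absorbed_level(self, rng):
        """With no covariates the prediction tracks control quarter means:
        ytilde differs from (Y - control quarter mean) by a constant (the
        absorbed level, removed again by stage-2 fixed effects)."""
        controls = control_panel(rng, n_hosp=3)
        fit = sd.fit_stage1(
            controls, covariates=NO_COVARIATES, fe="hospital", attr_by_quarter=()
        )
        treated = control_panel(rng, n_hosp=2).assign(treated_region=1)
        gaps = sd.predict_gap(fit, treated)
        qmeans = controls.groupby("quarter")["outcome_30d"].mean()
        alt = treated["outcome_30d"].to_numpy() - qmeans.loc[
            treated["quarter"]
        ].to_numpy()
        diff = gaps["ytilde"].to_numpy() - alt
        assert np.allclose(diff, diff[0])

    def test_unseen_categorical_level_raises_by_name(self, rng):
        controls = control_panel(rng)
        fit = sd.fit_stage1(
            controls,
            covariates={"numeric": [], "categorical": ["sex"]},
        )
        treated = control_panel(rng, n_hosp=1).assign(treated_region=1)
        treated["sex"] = "X"
        with pytest.raises(EstimationError, match="sex.*X"):
            sd.predict_gap(fit, treated)

    def test_outcome_equal_to_prediction_gives_zero_gap(self, rng):
        controls = control_panel(rng, n_hosp=2)
        fit = sd.fit_stage1(controls, covariates=NO_COVARIATES, fe="hospital")
        treated = control_panel(rng, n_hosp=1).assign(treated_region=1)
        treated["outcome_30d"] = fit.predict(treated)
        gaps = sd.predict_gap(fit, treated)
        assert np.allclose(gaps["ytilde"], 0.0)


class TestAverageSpillover:
    def test_two_by_two_closed_form(self):
        """Equal-cell 2x2 toy: delta-hat is the mean within-hospital
        post-minus-pre change, ((0.10-0.09)+(0.08-0.10))/2 = -0.005."""
        rows = []
        cells = {
            ("A", 0): 0.09, ("A", 1): 0.10,
            ("B", 0): 0.10, ("B", 1): 0.08,
        }
        for (h, post), mean in cells.items():
            for _ in range(10):
                rows.append(
                    {
                        "hospital_id": h,
                        "physician_id": f"{h}_P0",
                        "quarter": post,
                        "post_indicator": post,
                        "ytilde": mean,
                    }
                )
        gaps = pd.DataFrame(rows)
        tl = PolicyTimeline.from_window(2, 1)
        est = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        assert est.coef["post_indicator"] == pytest.approx(-0.5)  # pp scale
        assert est.coef["post_indicator"] / 100 == pytest.approx(-0.005)

    def test_equivalence_with_explicit_dummy_ols(self, rng):
        gaps = make_gap_frame(rng, n=500)
        tl = PolicyTimeline.from_window(2, 2)
        est = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        # independent oracle: explicit hospital dummies, plain lstsq
        D = pd.get_dummies(gaps["hospital_id"], dtype=float)
        X = np.column_stack([gaps["post_indicator"].to_numpy(float), D.to_numpy()])
        beta = np.linalg.lstsq(X, gaps["ytilde"].to_numpy(), rcond=None)[0]
        assert est.coef["post_indicator"] / 100 == pytest.approx(beta[0], abs=1e-10)

    def test_constant_shift_invariance(self, rng):
        gaps = make_gap_frame(rng)
        tl = PolicyTimeline.from_window(2, 2)
        base = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        shifted = sd.estimate_average_spillover(
            gaps.assign(ytilde=gaps["ytilde"] + 5.0), tl, fe_level="hospital"
        )
        assert shifted.coef["post_indicator"] == pytest.approx(
            base.coef["post_indicator"], abs=1e-9
        )


class TestDecomposition:
    def test_zero_variance_exposures_raise_collinearity_error(self, rng):
        gaps = make_gap_frame(rng)
        exposure = (
            gaps[["physician_id", "hospital_id"]]
            .drop_duplicates()
            .assign(x_direct=0.0, z_indirect=0.0)
        )
        tl = PolicyTimeline.from_window(2, 2)
        with pytest.raises(CollinearityError, match="average-spillover"):
            sd.estimate_decomposition(gaps, exposure, tl)

    def test_degenerate_exposures_collapse_onto_average_model(self, rng):
        """With zero-variance exposures the decomposition nests the
        average model exactly: allowing the collapse reproduces delta-hat
        under physician-hospital fixed effects."""
        gaps = make_gap_frame(rng)
        exposure = (
            gaps[["physician_id", "hospital_id"]]
            .drop_duplicates()
            .assign(x_direct=0.0, z_indirect=0.0)
        )
        tl = PolicyTimeline.from_window(2, 2)
        df, terms = _decomposition_frame(gaps, exposure)
        with pytest.warns(UserWarning, match="collinear"):
            reg = GapRegression(
                terms=tuple(terms), fe="physician_hospital",
                allow_degenerate=True,
            ).fit(df)
        avg = sd.estimate_average_spillover(gaps, tl, fe_level="physician_hospital")
        assert reg.coef_["post_indicator"] == pytest.approx(
            avg.coef["post_indicator"], abs=1e-10
        )

    def test_equivalence_with_explicit_dummy_ols(self, rng):
        gaps = make_gap_frame(rng, n=400)
        units = gaps[["physician_id", "hospital_id"]].drop_duplicates()
        exposure = units.assign(
            x_direct=rng.gamma(1.0, 10.0, len(units)),
            z_indirect=rng.gamma(1.0, 5.0, len(units)),
        )
        tl = PolicyTimeline.from_window(2, 2)
        est = sd.estimate_decomposition(gaps, exposure, tl)
        df, terms = _decomposition_frame(gaps, exposure)
        D = pd.get_dummies(df["physician_id"] + "/" + df["hospital_id"], dtype=float)
        X = np.column_stack([df[terms].to_numpy(float), D.to_numpy()])
        beta = np.linalg.lstsq(X, df["ytilde"].to_numpy(), rcond=None)[0]
        for i, t in enumerate(terms):
            assert est.coef[t] / 100 == pytest.approx(beta[i], abs=1e-10)


class TestClusterVcov:
    def test_matches_loop_over_clusters_oracle(self, rng):
        n, k, G = 300, 3, 6
        X = rng.normal(size=(n, k))
        e = rng.normal(size=n)
        clusters = rng.integers(0, G, n)
        V = sd.cluster_vcov(X, e, clusters)
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((k, k))
        for g in range(G):
            s = X[clusters == g].T @ e[clusters == g]
            meat += np.outer(s, s)
        c = (G / (G - 1)) * ((n - 1) / (n - k))
        assert np.allclose(V, c * bread @ meat @ bread, atol=1e-10)

    def test_singleton_clusters_reduce_to_hc_scaling(self, rng):
        n, k = 40, 2
        X = rng.normal(size=(n, k))
        e = rng.normal(size=n)
        V = sd.cluster_vcov(X, e, np.arange(n))
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (X * e[:, None] ** 2).T @ X @ bread
        scale = (n / (n - 1)) * ((n - 1) / (n - k))
        assert np.allclose(V, scale * hc0, atol=1e-12)

    def test_single_cluster_raises(self, rng):
        with pytest.raises(EstimationError, match="clusters"):
            sd.cluster_vcov(rng.normal(size=(10, 1)), rng.normal(size=10),
                            np.zeros(10))

    def test_duplicating_clusters_leaves_coefficients_unchanged(self, rng):
        gaps = make_gap_frame(rng, n=200)
        tl = PolicyTimeline.from_window(2, 2)
        base = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        doubled = pd.concat([gaps, gaps], ignore_index=True)
        dup = sd.estimate_average_spillover(doubled, tl, fe_level="hospital")
        assert dup.coef["post_indicator"] == pytest.approx(
            base.coef["post_indicator"], abs=1e-10
        )

    def test_variance_matrix_is_symmetric_psd(self, rng):
        gaps = make_gap_frame(rng)
        tl = PolicyTimeline.from_window(2, 2)
        est = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        V = est.vcov
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-12
        for i, t in enumerate(est.terms):
            assert est.se[t] == pytest.approx(np.sqrt(V[i, i]))


class TestTwoStagePipeline:
    def test_closed_form_did_on_two_group_two_period_panel(self, rng):
        """No covariates, two groups, two periods: the pipeline's
        delta-hat equals the four-cell difference in means."""
        rows = []
        means = {
            ("C1", 0, 0): 0.10, ("C1", 1, 0): 0.07,
            ("C2", 0, 0): 0.05, ("C2", 1, 0): 0.04,
            ("T1", 0, 1): 0.12, ("T1", 1, 1): 0.13,
            ("T2", 0, 1): 0.20, ("T2", 1, 1): 0.16,
        }
        for (h, q, tr), m in means.items():
            for i in range(40):
                rows.append(
                    {
                        "hospital_id": h,
                        "physician_id": f"{h}_P0",
                        "quarter": q,
                        "age_years": 60,
                        "sex": "F",
                        "outcome_30d": int(i < m * 100),
                        "treated_region": tr,
                        "post_indicator": q,
                        "region": "treated" if tr else "other",
                        "trust_type": "acute",
                        "foundation_status": False,
                    }
                )
        panel = pd.DataFrame(rows)
        tl = PolicyTimeline.from_window(1, 1)
        # oracle: four cell means
        cells = panel.groupby(["treated_region", "quarter"])["outcome_30d"].mean()
        did = (cells[1, 1] - cells[1, 0]) - (cells[0, 1] - cells[0, 0])
        fit = sd.TwoStageDiD(model="average", covariates=NO_COVARIATES).fit(
            panel, timeline=tl
        )
        assert fit.estimate_.coef["post_indicator"] / 100 == pytest.approx(
            did, abs=1e-12
        )

    def test_scale_contract_percentage_points(self, rng):
        gaps = make_gap_frame(rng)
        tl = PolicyTimeline.from_window(2, 2)
        est = sd.estimate_average_spillover(gaps, tl, fe_level="hospital")
        reg = GapRegression(terms=("post_indicator",), fe="hospital").fit(gaps)
        assert est.coef["post_indicator"] == pytest.approx(
            100.0 * reg.beta_prob_[0]
        )


class TestEventStudy:
    def test_identical_pre_means_give_zero_wald(self):
        rows = []
        for h in ("A", "B"):
            for q in range(4):
                for _ in range(5):
                    rows.append(
                        {
                            "hospital_id": h,
                            "physician_id": f"{h}_P0",
                            "quarter": q,
                            "post_indicator": int(q >= 2),
                            "ytilde": 0.1 if h == "A" else 0.2,
                        }
                    )
        gaps = pd.DataFrame(rows)
        tl = PolicyTimeline.from_window(2, 2)
        ev = sd.pretrend_event_study(gaps, None, tl)
        assert ev.wald_stat == 0.0
        pre = ev.coefficients[ev.coefficients["term"].str.startswith("pre_q")]
        assert np.allclose(pre["coef_pp"], 0.0)

    def test_wald_nonnegative_on_noise(self, rng):
        gaps = make_gap_frame(rng, n=400)
        tl = PolicyTimeline.from_window(2, 2)
        ev = sd.pretrend_event_study(gaps, None, tl)
        assert ev.wald_stat >= 0.0
        assert 0.0 <= ev.wald_p <= 1.0

    def test_single_pre_quarter_raises(self, rng):
        gaps = make_gap_frame(rng, n_quarters=2, first_post=1)
        tl = PolicyTimeline.from_window(1, 1)
        with pytest.raises(EstimationError, match="pre-policy quarters"):
            sd.pretrend_event_study(gaps, None, tl)

    def test_reference_quarter_not_in_coefficients(self, rng):
        gaps = make_gap_frame(rng)
        tl = PolicyTimeline.from_window(2, 2)
        ev = sd.pretrend_event_study(gaps, None, tl)
        assert ev.reference_quarter == 1
        assert "pre_q1" not in set(ev.coefficients["term"])


class TestDropCollinear:
    def test_first_come_kept(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        X = np.column_stack([a, b, a + b, a - 2 * b])
        kept, dropped = drop_collinear(X, ["a", "b", "a+b", "a-2b"])
        assert kept == [0, 1]
        assert dropped == ["a+b", "a-2b"]

    def test_zero_column_dropped(self, rng):
        X = np.column_stack([np.zeros(50), rng.normal(size=50)])
        kept, dropped = drop_collinear(X, ["zero", "x"])
        assert kept == [1] and dropped == ["zero"]
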