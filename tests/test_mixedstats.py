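"""Mixed-model engine: closed forms, external oracles, selection, Spearman."""

import warnings

import numpy as np
import pandas as pd
import pytest

import retmap as rm
from retmap.mixedstats import (
    CANDIDATE_TERMS,
    LMMSpec,
    NoGroupingVariance,
    RankDeficientDesign,
    dredge_bic,
    fit_lmm,
    spearman_matrix,
    univariate_suite,
)


def oracle_fixture_frame() -> pd.DataFrame:
    """Deterministic 8-patient table; external oracle values frozen below."""
    rng = np.random.default_rng(np.random.SeedSequence(20240613))
    rows = []
    for i in range(8):
        b = rng.normal(0, 1.2)
        age = rng.uniform(55, 85)
        for j in range(30):
            x1 = rng.normal(30, 5)
            x2 = rng.normal(60, 12)
            dev = "MAIA" if (j % 2) else "MP3"
            y = 24 + 0.05 * x1 + 0.03 * x2 - 3.3 * (dev == "MAIA") + b + rng.normal(0, 1.8)
            rows.append((f"p{i}", dev, 1 + (j % 2), x1, x2, age, y))
    return pd.DataFrame(rows, columns=["eye_id", "device", "run", "EZ", "ONL", "age", "db"])


# Reference estimates computed once with R lme4 (bobyqa, rhoend 1e-12) on the
# frame above, model db ~ device + EZ + ONL + (1 | eye_id).
LME4_ORACLE = {
    "ML": {
        "beta": [24.798807549569, -3.291097726008, 0.020160025627, 0.027432040742],
        "sigma_b": 1.222193633922,
        "sigma_e": 1.716841334782,
        "loglik": -481.40281510,
    },
    "REML": {
        "beta": [24.796968210615, -3.291036611513, 0.020069885793, 0.027505962756],
        "sigma_b": 1.312067931833,
        "sigma_e": 1.728026650200,
        "loglik": -488.45464378,
    },
}


class TestFitLMM:
    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_matches_lme4_reference(self, method):
        """Estimates agree with the stored lme4 fit to 1e-6 relative."""
        fit = fit_lmm(oracle_fixture_frame(), LMMSpec(("device", "EZ", "ONL"), method=method))
        ref = LME4_ORACLE[method]
        np.testing.assert_allclose(fit.beta, ref["beta"], rtol=1e-6)
        assert fit.sigma_b == pytest.approx(ref["sigma_b"], rel=1e-6)
        assert fit.sigma_e == pytest.approx(ref["sigma_e"], rel=1e-6)
        assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-5)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_matches_statsmodels_live(self, method):
        """Independent cross-check against statsmodels MixedLM on the same
        data; the profiled 1-D optimiser must do at least as well."""
        smf = pytest.importorskip("statsmodels.formula.api")
        df = oracle_fixture_frame()
        fit = fit_lmm(df, LMMSpec(("device", "EZ", "ONL"), method=method))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(
                "db ~ C(device, Treatment('MP3')) + EZ + ONL", df, groups=df["eye_id"]
            ).fit(reml=(method == "REML"))
        assert fit.loglik >= res.llf - 1e-6
        sm_beta = [
            res.params["Intercept"],
            res.params["C(device, Treatment('MP3'))[T.MAIA]"],
            res.params["EZ"],
            res.params["ONL"],
        ]
        np.testing.assert_allclose(fit.beta, sm_beta, rtol=1e-4)

    def test_balanced_one_way_closed_form(self):
        """Balanced random-intercept ANOVA has textbook closed-form MLEs:
        REML gives sigma_e^2 = MSW, sigma_b^2 = (MSB - MSW)/k; ML shrinks
        MSB by (m-1)/m."""
        rng = np.random.default_rng(10)
        m, k = 6, 10
        y = np.concatenate([rng.normal(3.0, 1.0, k) + rng.normal(0, 2.0) for _ in range(m)])
        df = pd.DataFrame({"db": y, "eye_id": np.repeat(np.arange(m), k)})
        gm = y.reshape(m, k).mean(axis=1)
        grand = y.mean()
        msw = np.sum((y.reshape(m, k) - gm[:, None]) ** 2) / (m * (k - 1))
        msb = k * np.sum((gm - grand) ** 2) / (m - 1)

        reml = fit_lmm(df, LMMSpec((), method="REML"))
        assert reml.beta[0] == pytest.approx(grand, rel=1e-8)
        assert reml.sigma_e**2 == pytest.approx(msw, rel=1e-6)
        assert reml.sigma_b**2 == pytest.approx((msb - msw) / k, rel=1e-6)

        ml = fit_lmm(df, LMMSpec((), method="ML"))
        assert ml.sigma_e**2 == pytest.approx(msw, rel=1e-6)
        assert ml.sigma_b**2 == pytest.approx(((m - 1) / m * msb - msw) / k, rel=1e-6)

    def test_independent_data_reduces_to_ols(self):
        """With no between-group variance the GLS fit collapses to OLS."""
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"db": y, "EZ": x, "eye_id": np.arange(n) % 20})
        # scramble groups so they carry no signal
        fit = fit_lmm(df, LMMSpec(("EZ",), method="ML"))
        X = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=2e-4)
        assert fit.sigma_b < 0.1

    def test_wald_ci_contains_estimate_and_bic_identity(self):
        fit = fit_lmm(oracle_fixture_frame(), LMMSpec(("EZ",), method="ML"))
        assert (fit.ci_low <= fit.beta).all() and (fit.beta <= fit.ci_high).all()
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.k_params * np.log(fit.n_obs))
        assert fit.k_params == 2 + 2  # intercept + EZ + two variance parameters

    def test_missing_rows_dropped(self):
        df = oracle_fixture_frame()
        df.loc[df.index[:35], "EZ"] = np.nan
        fit = fit_lmm(df, LMMSpec(("EZ",), method="ML"))
        assert fit.n_obs == len(df) - 35

    def test_rank_deficient_raises(self):
        df = oracle_fixture_frame()
        df["EZ2"] = df["EZ"]
        with pytest.raises(RankDeficientDesign):
            fit_lmm(df, LMMSpec(("EZ", "EZ2"), method="ML"))

    def test_single_patient_warns_boundary(self):
        df = oracle_fixture_frame().query("eye_id == 'p0'")
        with pytest.warns(NoGroupingVariance):
            fit = fit_lmm(df, LMMSpec(("EZ",), method="ML"))
        assert fit.sigma_b == pytest.approx(0.0, abs=1e-3)

    def test_ml_and_reml_converge_with_many_groups(self):
        """REML's small-sample correction vanishes as the number of patients
        grows: the ML and REML fits approach each other."""
        spec_ml = LMMSpec(("device", "EZ", "ONL"), method="ML")
        spec_reml = LMMSpec(("device", "EZ", "ONL"), method="REML")

        def gap(n_eyes):
            pw = rm.simulate_pointwise(seed=1, n_eyes=n_eyes)
            ml = fit_lmm(pw, spec_ml)
            reml = fit_lmm(pw, spec_reml)
            return max(np.abs(ml.beta - reml.beta).max(),
                       abs(ml.sigma_b - reml.sigma_b))

        g10, g60 = gap(10), gap(60)
        assert g60 < g10
        assert g60 < 0.08


class TestUnivariateSuite:
    def test_rows_and_models(self, pointwise20):
        table = univariate_suite(pointwise20)
        assert set(table["term"]) >= set(CANDIDATE_TERMS)
        assert "EZ:eccentricity" in set(table["term"])
        assert len(table) == len(CANDIDATE_TERMS) + 4

    def test_known_device_effect_recovered(self, pointwise20):
        table = univariate_suite(pointwise20).set_index("term")
        est = table.loc["device", "estimate"]
        assert est == pytest.approx(-3.335, abs=0.25)
        assert table.loc["device", "p_value"] < 1e-6

    def test_run_effect_small_and_often_nonsignificant(self, pointwise20):
        # generating run effect is 0.168 dB with SE ~ 0.07: a weak signal
        table = univariate_suite(pointwise20).set_index("term")
        assert abs(table.loc["run", "estimate"]) < 0.6

    def test_eccentricity_negative_marginal_effect(self, pointwise20):
        """Eccentricity has no direct generating effect; its strong negative
        univariate slope arises entirely through layer topography."""
        table = univariate_suite(pointwise20).set_index("term")
        assert table.loc["eccentricity", "estimate"] < -0.1
        assert table.loc["eccentricity", "p_value"] < 1e-6

    def test_type_one_error_of_within_eye_term(self):
        """Null generator: the univariate run test rejects at ~5%."""
        null = rm.SensitivityModel(
            beta0=28.0, beta_EZ=0, beta_ONL=0, beta_GCL=0, beta_RNFL=0,
            beta_device=0, beta_run=0,
        )
        cfg = rm.PipelineConfig(model=null)
        rej = 0
        nrep = 120
        for s in np.random.SeedSequence(99).spawn(nrep):
            pw = rm.simulate_pointwise(config=cfg, seed=int(s.generate_state(1)[0] % 2**31))
            fit = fit_lmm(pw, LMMSpec(("run",), method="REML"))
            rej += fit.p_values[fit.terms.index("run")] < 0.05
        assert 0.01 <= rej / nrep <= 0.10


class TestDredge:
    def test_number_of_models(self, pointwise20):
        ranking, _ = dredge_bic(pointwise20, ("device", "EZ", "ONL", "RNFL"))
        assert len(ranking) == 16  # 2^4
        assert ranking["BIC"].is_monotonic_increasing

    def test_full_candidate_set_is_256_models(self, pointwise20):
        ranking, best = dredge_bic(pointwise20)
        assert len(ranking) == 256  # 2^8
        assert best.method == "REML"

    def test_single_strong_predictor_always_selected(self):
        """Selection consistency: with one strong true predictor the winner
        is exactly that predictor."""
        rng = np.random.default_rng(12)
        wins = 0
        for _ in range(20):
            n_g, k = 15, 40
            g = np.repeat(np.arange(n_g), k)
            x1 = rng.normal(size=n_g * k)
            x2 = rng.normal(size=n_g * k)
            x3 = rng.normal(size=n_g * k)
            b = rng.normal(0, 1.0, n_g)[g]
            y = 5 + 2.0 * x1 + b + rng.normal(0, 1.0, n_g * k)
            df = pd.DataFrame({"db": y, "EZ": x1, "ONL": x2, "GCL": x3, "eye_id": g})
            ranking, _ = dredge_bic(df, ("EZ", "ONL", "GCL"))
            wins += ranking["terms"].iloc[0] == "EZ"
        assert wins == 20

    def test_ties_break_towards_fewer_terms(self, pointwise20):
        ranking, _ = dredge_bic(pointwise20, ("device", "EZ"))
        tied = ranking.assign(BICr=ranking["BIC"].round(6)).groupby("BICr")
        for _, grp in tied:
            assert grp["n_terms"].is_monotonic_increasing


class TestSpearman:
    def test_monotone_pair_is_one(self):
        df = pd.DataFrame({"EZ": [1, 2, 3, 4.0], "ONL": [10, 20, 25, 40.0],
                           "eccentricity": [4, 3, 2, 1.0], "age": [1, 1, 2, 2.0],
                           "GCL": [1, 2, 3, 4.0], "RNFL": [4, 3, 2, 1.0]})
        S = spearman_matrix(df)
        assert S.loc["EZ", "ONL"] == pytest.approx(1.0)
        assert S.loc["EZ", "eccentricity"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(10, 6)),
                          columns=["eccentricity", "age", "EZ", "ONL", "GCL", "RNFL"])
        df.iloc[2, 2] = df.iloc[3, 2]  # introduce a tie
        S = spearman_matrix(df)
        for a in df.columns:
            for b in df.columns:
                ra = df[a].rank().to_numpy()
                rb = df[b].rank().to_numpy()
                oracle = np.corrcoef(ra, rb)[0, 1]
                assert S.loc[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"EZ": np.ones(10), "ONL": np.arange(10.0),
                           "eccentricity": np.arange(10.0), "age": np.arange(10.0),
                           "GCL": np.arange(10.0), "RNFL": np.arange(10.0)})
        with pytest.warns(UserWarning, match="constant"):
            S = spearman_matrix(df)
        assert np.isnan(S.loc["EZ", "ONL"])

    def test_pairwise_complete_counts(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=["eccentricity", "age", "EZ", "ONL", "GCL", "RNFL"])
        df.loc[:4, "EZ"] = np.nan
        S = spearman_matrix(df)  # must not raise; EZ pairs use 45 rows
        assert np.isfinite(S.loc["EZ", "ONL"])
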