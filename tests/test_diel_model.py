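"""Diel multinomial mixed model: limits, recovery, selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from dielkit import diel_model, synthetic


def _category_frame(n=3000, n_areas=4, area_sd=0.3, seed=0, slopes=None):
    cfg_kw = {} if slopes is None else {"nocturnality_slope_per_guild": slopes}
    cfg = synthetic.SyntheticConfig(seed=seed, **cfg_kw)
    _, truth = synthetic.generate_community(cfg, include_filtered_decoys=False)
    return truth, synthetic.simulate_diel_categories(truth, n, n_areas=n_areas, area_sd=area_sd, rng=seed + 1)


class TestFitting:
    def test_balanced_intercept_only_predicts_thirds(self):
        """With equal category counts an intercept-only model puts ~1/3 everywhere."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "diel_category": np.repeat(["day", "night", "twilight"], 400),
                "protected_area": rng.choice(["A", "B", "C"], 1200),
                "logmass": 0.0,
                "guild": "herbivore",
            }
        )
        m = diel_model.fit_diel_model(df, formula="1")
        pred = diel_model.predict_probabilities(m, df.iloc[[0]][["logmass", "guild"]], n_draws=50, seed=1)
        for cat in ("day", "night", "twilight"):
            assert pred[f"p_{cat}"].iloc[0] == pytest.approx(1 / 3, abs=0.05)

    def test_sigma_to_zero_limit_matches_fixed_effects_mnlogit(self):
        """With a single area (variances pinned at zero) the fit reproduces the
        plain multinomial logit from an independent implementation."""
        sm = pytest.importorskip("statsmodels.api")
        truth, df = _category_frame(n=2000, n_areas=1, area_sd=0.0, seed=3)
        with pytest.warns(UserWarning, match="single protected area"):
            ours = diel_model.fit_diel_model(df, formula="logmass")
        import patsy
        X = patsy.dmatrix("logmass", df)
        y = pd.Categorical(df["diel_category"], categories=["day", "night", "twilight"]).codes
        ref = sm.MNLogit(y, np.asarray(X)).fit(disp=0, tol=1e-10)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)
        ref_params = ref.params.T.ravel()  # (night terms..., twilight terms...)
        np.testing.assert_allclose(ours.coef["estimate"].to_numpy(), ref_params, atol=1e-4)

    def test_random_intercept_variance_recovered(self):
        truth, df = _category_frame(n=20000, n_areas=12, area_sd=0.5, seed=5)
        m = diel_model.fit_diel_model(df, formula="logmass * C(guild)")
        assert 0.25 < m.sigma_night < 0.9
        assert m.stage == "ML"
        assert m.converged

    def test_empty_category_is_a_fit_error(self):
        df = pd.DataFrame(
            {
                "diel_category": ["day"] * 50 + ["night"] * 50,
                "protected_area": "A",
                "logmass": np.linspace(-1, 1, 100),
                "guild": "omnivore",
            }
        )
        with pytest.raises(diel_model.FitError, match="twilight"):
            diel_model.fit_diel_model(df, formula="logmass")

    def test_slope_recovery_within_two_se(self):
        """Guild-specific night slopes land within 2 SE of the generating values."""
        truth, df = _category_frame(n=10000, n_areas=8, seed=11)
        m = diel_model.fit_diel_model(df, formula="logmass * C(guild)")
        sl = diel_model.guild_night_slopes(m, sorted(truth.guild_slopes))
        for _, r in sl.iterrows():
            assert abs(r["slope"] - truth.guild_slopes[r["guild"]]) < 2 * r["se"]


class TestSelection:
    def test_candidate_set_is_the_nested_ladder(self):
        cands = diel_model.candidate_set()
        assert len(cands) == 5
        assert set(cands) == {"intercept_only", "mass", "guild", "mass_plus_guild", "mass_by_guild"}

    def test_delta_aic_and_supported_set(self):
        def fake(name, aic, k):
            return diel_model.DielModel(
                formula=name, coef=pd.DataFrame(), vcov=np.eye(1), sigma_night=0, sigma_twilight=0,
                loglik=-(aic - 2 * k) / 2, aic=aic, n_obs=10, n_groups=2, k_params=k,
                design_info=None, converged=True,
            )
        fits = {"a": fake("a", 100.0, 3), "b": fake("b", 101.5, 4), "c": fake("c", 110.0, 5)}
        rank = diel_model.select_model(fits)
        assert rank.best == "a"
        assert rank.supported == ["a", "b"]
        assert rank.table["delta_aic"].iloc[0] == 0.0

    def test_single_model_is_trivially_best(self):
        truth, df = _category_frame(n=500, n_areas=2, seed=7)
        fits = diel_model.fit_candidates(df, {"mass": "logmass"})
        assert diel_model.select_model(fits).best == "mass"

    def test_interaction_wins_when_it_generates_the_data(self):
        truth, df = _category_frame(n=8000, n_areas=8, seed=13)
        rank = diel_model.select_model(diel_model.fit_candidates(df))
        assert rank.best == "mass_by_guild"


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        truth, df = _category_frame(n=6000, n_areas=6, seed=17)
        return truth, diel_model.fit_diel_model(df, formula="logmass * C(guild)"), df

    def test_probabilities_sum_to_one(self, fitted):
        _, m, df = fitted
        grid = pd.DataFrame({"guild": "herbivore", "logmass": np.linspace(-1, 2.5, 30)})
        pred = diel_model.predict_probabilities(m, grid, n_draws=100, seed=2)
        total = pred[["p_day", "p_night", "p_twilight"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        for cat in ("day", "night", "twilight"):
            assert ((pred[f"p_{cat}_lo"] <= pred[f"p_{cat}"] + 1e-9)
                    & (pred[f"p_{cat}"] <= pred[f"p_{cat}_hi"] + 1e-9)).all()

    def test_positive_night_slope_is_monotone_in_mass(self, fitted):
        truth, m, df = fitted
        # herbivores were generated with a positive nocturnality slope
        grid = pd.DataFrame({"guild": "herbivore", "logmass": np.linspace(-1, 2.5, 20)})
        pred = diel_model.predict_probabilities(m, grid, n_draws=10, seed=3)
        assert (np.diff(pred["p_night"]) > 0).all()

    def test_unknown_guild_errors(self, fitted):
        _, m, _ = fitted
        with pytest.raises(Exception):
            diel_model.predict_probabilities(m, pd.DataFrame({"guild": ["whale"], "logmass": [0.0]}))

    def test_extrapolation_flagged(self, fitted):
        _, m, df = fitted
        lo = df["logmass"].min()
        grid = pd.DataFrame({"guild": "herbivore", "logmass": [lo - 1.0, df["logmass"].median()]})
        pred = diel_model.predict_probabilities(m, grid, n_draws=10, seed=4)
        assert bool(pred["extrapolated"].iloc[0]) and not bool(pred["extrapolated"].iloc[1])


class TestNocturnalityRatio:
    @pytest.mark.parametrize("a,b,expected", [(0.60, 0.13, 4.6), (0.81, 0.21, 3.9), (0.4, 0.4, 1.0)])
    def test_reported_to_one_decimal(self, a, b, expected):
        assert diel_model.nocturnality_ratio(a, b) == expected

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            diel_model.nocturnality_ratio(0.5, 0.0)
        with pytest.raises(ValueError):
            diel_model.nocturnality_ratio(1.2, 0.5)
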