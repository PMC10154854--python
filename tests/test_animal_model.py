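"""Threshold animal model: design building, sampler, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest

import broodsex as bx
from broodsex.animal_model import (
    DESK_SETTINGS,
    MCMCSettings,
    ModelSpec,
    STUDY_SETTINGS,
    PosteriorSamples,
    Prior,
    build_model,
    diagnostics,
    effective_sample_size,
    gibbs_sample,
    heritability_liability,
    pmcmc,
    posterior_summary,
    potential_scale_reduction,
)


def _fixed_only_phenotypes(n, mu, rng, origin_levels=("FF",)):
    y = (mu + rng.standard_normal(n)) > 0
    return pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "sex": np.where(y, "male", "female"),
            "block": 1,
            "parental_origin": [origin_levels[k % len(origin_levels)] for k in range(n)],
            "dam": None,
        }
    )


class TestBuildModel:
    def test_reference_coding_of_origin_factor(self, rng):
        phen = _fixed_only_phenotypes(200, 0.0, rng, ("FF", "FM", "MF", "MM"))
        model = build_model(phen, None, ModelSpec(fixed_effects=("parental_origin",), random_effects=()))
        assert model.x_names == [
            "intercept",
            "parental_origin[FM]",
            "parental_origin[MF]",
            "parental_origin[MM]",
        ]

    def test_single_level_factor_dropped_with_warning(self, rng):
        phen = _fixed_only_phenotypes(50, 0.0, rng)
        with pytest.warns(UserWarning, match="single level"):
            model = build_model(phen, None, ModelSpec(fixed_effects=("block",), random_effects=()))
        assert model.x_names == ["intercept"]

    def test_orphan_phenotype_rejected(self, rng):
        ds = bx.simulate_broods(
            [bx.CrossPlan("c", "d", "s")], bx.GeneticConfig(), seed=1
        )
        phen = ds.phenotypes.copy()
        phen.loc[len(phen)] = {"id": "stranger", "sex": "male", "block": 1,
                               "parental_origin": "FF", "dam": "d"}
        with pytest.raises(ValueError, match="orphan phenotype"):
            build_model(phen, ds.pedigree, ModelSpec(fixed_effects=()))


class TestSettingsAccounting:
    def test_study_scale_settings_retain_1080(self):
        assert STUDY_SETTINGS.retained_per_chain == 180
        assert STUDY_SETTINGS.total_retained == 1080

    @pytest.mark.parametrize(
        "chains,iters,burn,thin",
        [(2, 1000, 100, 7), (3, 5000, 0, 11), (1, 999, 998, 1)],
    )
    def test_retained_draw_arithmetic(self, chains, iters, burn, thin):
        s = MCMCSettings(chains, iters, burn, thin)
        assert s.total_retained == chains * ((iters - burn) // thin)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(1, 100, 100, 1)
        with pytest.raises(ValueError):
            MCMCSettings(1, 100, 10, 0)


class TestSampler:
    def test_retained_counts_match_settings(self, rng):
        phen = _fixed_only_phenotypes(80, 0.2, rng)
        model = build_model(phen, None, ModelSpec(fixed_effects=(), random_effects=()))
        s = gibbs_sample(model, MCMCSettings(3, 200, 50, 7, seed=0))
        assert s.beta.shape == (3, (200 - 50) // 7, 1)

    def test_probit_regression_posterior_matches_mle(self, rng):
        import statsmodels.api as sm

        phen = _fixed_only_phenotypes(1500, 0.4, rng)
        model = build_model(phen, None, ModelSpec(fixed_effects=(), random_effects=()))
        s = gibbs_sample(model, MCMCSettings(2, 1500, 300, 2, seed=1))
        draws = s.stacked("beta:intercept")
        y = (phen["sex"] == "male").to_numpy(dtype=float)
        mle = sm.Probit(y, np.ones((len(y), 1))).fit(disp=0).params[0]
        assert abs(draws.mean() - mle) < 3 * draws.std()

    def test_degenerate_variance_priors_collapse_to_probit(self):
        # with variance components pinned to ~0 the model must match plain
        # Bayesian probit regression on the same records (KS on draws < 0.1)
        ds = bx.simulate_diallel_dataset(
            seed=30, n_f1_per_cell=2, n_backcrosses=8,
            brood_sizes=bx.BroodSizeDistribution(mean=15.0),
        )
        spec = ModelSpec(fixed_effects=())
        settings = MCMCSettings(1, 4500, 500, 2, seed=2)
        pinned = Prior(v_animal=1e-8, nu_animal=1e8, v_dam=1e-8, nu_dam=1e8)
        s_pin = gibbs_sample(build_model(ds.phenotypes, ds.pedigree, spec), settings, pinned)
        assert s_pin.stacked("sigma2_a").max() < 1e-4
        s_probit = gibbs_sample(
            build_model(ds.phenotypes, None, ModelSpec(fixed_effects=(), random_effects=())),
            settings,
        )
        from scipy.stats import ks_2samp

        d = ks_2samp(s_pin.stacked("beta:intercept"), s_probit.stacked("beta:intercept")).statistic
        assert d < 0.1

    def test_chain_order_does_not_change_summaries(self, rng):
        phen = _fixed_only_phenotypes(100, 0.0, rng)
        model = build_model(phen, None, ModelSpec(fixed_effects=(), random_effects=()))
        s = gibbs_sample(model, MCMCSettings(3, 400, 100, 3, seed=3))
        swapped = PosteriorSamples(
            beta=s.beta[::-1].copy(), sigma2_a=None, sigma2_m=None,
            x_names=s.x_names, settings=s.settings, design_matrix=s.design_matrix,
        )
        a = posterior_summary(s.stacked("beta:intercept"))
        b = posterior_summary(swapped.stacked("beta:intercept"))
        assert a == b


class TestDiagnostics:
    def test_iid_ess_near_n(self, rng):
        x = rng.standard_normal(1000)
        assert 800 <= effective_sample_size(x) <= 1200

    def test_ar1_ess_matches_closed_form(self, rng):
        rho, n = 0.9, 40_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert abs(effective_sample_size(x) - expected) / expected < 0.3

    def test_identical_chains_psrf_one(self, rng):
        c = rng.standard_normal(500)
        assert potential_scale_reduction(np.stack([c, c])) == pytest.approx(1.0, abs=1e-6)

    def test_diagnostics_bundle(self, rng):
        phen = _fixed_only_phenotypes(60, 0.0, rng)
        model = build_model(phen, None, ModelSpec(fixed_effects=(), random_effects=()))
        s = gibbs_sample(model, MCMCSettings(2, 300, 100, 2, seed=4))
        d = diagnostics(s)
        assert d.ess["beta:intercept"] <= d.total_retained
        assert d.psrf["beta:intercept"] >= 1.0 - 1e-12


class TestPosteriorSummaries:
    def test_pmcmc_floor_symmetric_and_counts(self):
        assert pmcmc(np.ones(200)) == pytest.approx(1 / 200)
        x = np.concatenate([np.ones(50), -np.ones(50)])
        assert pmcmc(x) == 1.0
        draws = np.concatenate([np.full(1078, 0.5), [-0.1, -0.2]])
        assert pmcmc(draws) == pytest.approx(4 / 1080)
        assert pmcmc(draws) < 0.006

    def test_hpd_on_uniform_grid(self):
        s = posterior_summary(np.arange(1.0, 101.0))
        assert s.mean == pytest.approx(50.5)
        assert s.hpd_high - s.hpd_low == pytest.approx(95)

    def test_hpd_of_constant_draws(self):
        s = posterior_summary(np.full(50, 3.3))
        assert s.mean == pytest.approx(3.3)
        assert s.hpd_low == 3.3 and s.hpd_high == 3.3

    def test_hpd_matches_normal_quantiles(self, rng):
        s = posterior_summary(rng.standard_normal(100_000))
        assert s.hpd_low == pytest.approx(-1.96, abs=0.05)
        assert s.hpd_high == pytest.approx(1.96, abs=0.05)


class TestHeritability:
    def _samples(self, sa, sm, beta, X):
        n = len(sa)
        return PosteriorSamples(
            beta=np.asarray(beta, dtype=float).reshape(1, n, -1),
            sigma2_a=np.asarray(sa, dtype=float).reshape(1, n),
            sigma2_m=np.asarray(sm, dtype=float).reshape(1, n),
            x_names=[f"b{j}" for j in range(np.shape(beta)[-1])],
            settings=MCMCSettings(1, 20, 0, 1),
            design_matrix=X,
        )

    def test_basic_arithmetic(self):
        X = np.ones((10, 1))
        s = self._samples([1.0] * 12, [0.0] * 12, [[0.0]] * 12, X)
        assert heritability_liability(s, "random_only") == pytest.approx([0.5] * 12)

    def test_zero_coefficients_make_modes_agree(self):
        X = np.column_stack([np.ones(20), np.repeat([0, 1], 10)])
        s = self._samples([0.4] * 12, [0.1] * 12, [[0.3, 0.0]] * 12, X)
        np.testing.assert_allclose(
            heritability_liability(s, "random_only"),
            heritability_liability(s, "with_fixed"),
        )

    def test_fixed_effect_variance_lowers_h2(self):
        X = np.column_stack([np.ones(20), np.repeat([0, 1], 10)])
        s = self._samples([0.4] * 12, [0.1] * 12, [[0.0, 2.0]] * 12, X)
        h_r = heritability_liability(s, "random_only")
        h_f = heritability_liability(s, "with_fixed")
        assert (h_f < h_r).all()

    def test_design_required(self):
        s = self._samples([0.4] * 12, [0.1] * 12, [[0.0]] * 12, None)
        s = PosteriorSamples(s.beta, s.sigma2_a, s.sigma2_m, s.x_names, s.settings, None)
        with pytest.raises(ValueError, match="design required"):
            heritability_liability(s, "with_fixed")
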