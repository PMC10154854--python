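"""Crossing-design enumeration and liability-model simulators."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import broodsex as bx
from broodsex.simulate import SimPopulation, _line_shift


class TestDesignEnumeration:
    def test_small_diallel_brute_force(self):
        # 1 block, 2 + 2 families: all ordered pairs minus within-family
        design = bx.CrossDesign(n_blocks=1, families_per_line_per_block=2)
        crosses = bx.enumerate_f1_design(design)
        counts = Counter(c.cross_type for c in crosses)
        assert counts == {"FF": 2, "MM": 2, "FM": 4, "MF": 4}
        # brute force: with 2 + 2 families every ordered distinct-family pair
        # is a legal cross, so the total is 4 * 3
        fams = {c.dam_family for c in crosses} | {c.sire_family for c in crosses}
        expected = {(d, s) for d in fams for s in fams if d != s}
        assert {(c.dam_family, c.sire_family) for c in crosses} == expected
        assert len(crosses) == 12

    def test_within_family_allowed_tiny_case(self):
        design = bx.CrossDesign(
            n_blocks=1, families_per_line_per_block=1, within_family_allowed=True
        )
        crosses = bx.enumerate_f1_design(design)
        assert Counter(c.cross_type for c in crosses) == {
            "FF": 1, "MM": 1, "FM": 1, "MF": 1,
        }

    def test_backcross_counts(self):
        assert bx.enumerate_backcross_design(0, 8)[0] == 0
        n, pairs = bx.enumerate_backcross_design(3, 2, reciprocal=False)
        assert n == 6 and len(pairs) == 6
        assert all(d == "f1_dam" for _, _, d in pairs)


class TestSimulateBroods:
    def test_pure_noise_null_sex_ratio(self):
        crosses = [bx.CrossPlan(f"c{i}", f"d{i}", f"s{i}") for i in range(400)]
        gen = bx.GeneticConfig(sigma2_a=0.0, sigma2_m=0.0)
        ds = bx.simulate_broods(crosses, gen, seed=1)
        df = ds.broods_frame()
        n = (df.n_male + df.n_female).sum()
        assert n > 10_000
        p = df.n_male.sum() / n
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_extreme_intercept_all_male(self):
        crosses = [bx.CrossPlan("c", "d", "s")]
        ds = bx.simulate_broods(crosses, bx.GeneticConfig(mu=50.0), seed=2)
        assert ds.broods[0].n_female == 0 and ds.broods[0].n_male > 0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="invalid config"):
            bx.GeneticConfig(sigma2_a=-0.1)

    def test_offspring_mean_is_midparent(self):
        gen = bx.GeneticConfig(sigma2_a=0.5, sigma2_m=0.0)
        pop = SimPopulation(gen)
        rng = np.random.default_rng(3)
        pop.add_founder("d", "female", rng)
        pop.add_founder("s", "male", rng)
        mid = 0.5 * (pop.bv[0] + pop.bv[1])
        ids = pop.spawn_brood("d", "s", 20_000, rng, prefix="b")
        bvs = np.array(pop.bv[2:])
        se = np.sqrt(gen.sigma2_a / 2 / len(ids))
        assert abs(bvs.mean() - mid) < 3 * se
        # Mendelian-sampling variance for non-inbred parents is sigma2_a / 2
        assert np.var(bvs) == pytest.approx(gen.sigma2_a / 2, rel=0.05)

    def test_sex_probability_reflects_total_liability_variance(self):
        # P(male) = Phi(mu / sqrt(sigma2_a + sigma2_m + 1)) across founder crosses
        gen = bx.GeneticConfig(sigma2_a=0.6, sigma2_m=0.2, mu=0.5)
        crosses = [bx.CrossPlan(f"c{i}", f"d{i}", f"s{i}") for i in range(600)]
        ds = bx.simulate_broods(crosses, gen, seed=4)
        df = ds.broods_frame()
        n = (df.n_male + df.n_female).sum()
        p_obs = df.n_male.sum() / n
        from scipy.stats import norm

        p_exp = norm.cdf(gen.mu / np.sqrt(gen.sigma2_a + gen.sigma2_m + 1.0))
        # offspring within a brood are correlated; allow inflated error
        assert abs(p_obs - p_exp) < 6 * np.sqrt(p_exp * (1 - p_exp) / n)

    def test_bit_reproducible_for_fixed_seed(self):
        crosses = [bx.CrossPlan(f"c{i}", f"d{i}", f"s{i}") for i in range(20)]
        a = bx.simulate_broods(crosses, bx.GeneticConfig(), seed=9).broods_frame()
        b = bx.simulate_broods(crosses, bx.GeneticConfig(), seed=9).broods_frame()
        pd.testing.assert_frame_equal(a, b)


class TestTruncationSelection:
    def test_no_heritable_variation_no_response(self):
        sel = bx.SelectionConfig(
            n_generations=4, n_families_screened=30, n_selected=6,
            brood_sizes=bx.BroodSizeDistribution(mean=25.0),
        )
        gen = bx.GeneticConfig(sigma2_a=0.0, sigma2_m=0.0)
        res = bx.simulate_truncation_selection(sel, gen, seed=5)
        means = res.summaries["mean_bsr_screened"]
        n_per_gen = 30 * 25
        for m in means:
            assert abs(m - 0.5) < 3 * np.sqrt(0.25 / n_per_gen)

    def test_selection_separates_lines(self):
        sel_kwargs = dict(
            n_generations=4, n_families_screened=20, n_selected=4,
            brood_sizes=bx.BroodSizeDistribution(mean=20.0),
        )
        gen = bx.GeneticConfig(sigma2_a=0.35, sigma2_m=0.05)
        wins = 0
        reps = 30
        for seed in range(reps):
            up = bx.simulate_truncation_selection(
                bx.SelectionConfig(direction="male-biased", **sel_kwargs), gen, seed=seed
            )
            dn = bx.simulate_truncation_selection(
                bx.SelectionConfig(direction="female-biased", **sel_kwargs), gen, seed=10_000 + seed
            )
            m = up.summaries["mean_bsr_screened"].iloc[-1]
            f = dn.summaries["mean_bsr_screened"].iloc[-1]
            wins += m > f
        assert wins >= 28

    def test_full_truncation_means_no_selection_differential(self):
        sel = bx.SelectionConfig(
            n_generations=4, n_families_screened=24, n_selected=24,
            brood_sizes=bx.BroodSizeDistribution(mean=25.0),
        )
        gen = bx.GeneticConfig(sigma2_a=0.35, sigma2_m=0.05)
        res = bx.simulate_truncation_selection(sel, gen, seed=6)
        last = res.summaries["mean_bsr_screened"].iloc[-1]
        # brood sex ratios are correlated within families; generous band
        assert abs(last - 0.5) < 0.12


@pytest.fixture(scope="module")
def ds():
    return bx.simulate_diallel_dataset(
        seed=8, n_f1_per_cell=3, n_backcrosses=20,
        brood_sizes=bx.BroodSizeDistribution(mean=20.0),
    )


class TestDiallelDataset:
    def test_every_brood_parent_in_pedigree(self, ds):
        ids = set(ds.pedigree.ids)
        for b in ds.broods:
            assert b.dam in ids and b.sire in ids
            assert b.n_male >= 0 and b.n_female >= 0

    def test_f1_cross_types_all_present(self, ds):
        types = {b.cross_type for b in ds.broods}
        assert {"FF", "FM", "MF", "MM"} <= types
        assert any(t.startswith("BC-") for t in types)
        assert any(t.startswith("parental-") for t in types)

    def test_phenotyped_individuals_have_dams_in_pedigree(self, ds):
        ids = set(ds.pedigree.ids)
        assert set(ds.phenotypes["id"]) <= ids
        assert ds.phenotypes["dam"].notna().all()

    def test_line_means_diverge_in_parental_generation(self, ds):
        df = ds.broods_frame()
        par = df[df.cross_type.str.startswith("parental")]
        bsr = par.n_male / (par.n_male + par.n_female)
        m = bsr[par.cross_type == "parental-M"].mean()
        f = bsr[par.cross_type == "parental-F"].mean()
        assert m > 0.5 > f

    def test_line_shift_calibration(self):
        gen = bx.GeneticConfig()
        s = _line_shift(0.64, gen)
        from scipy.stats import norm

        p = norm.cdf(s / np.sqrt(gen.sigma2_a + gen.sigma2_m + 1))
        assert p == pytest.approx(0.64, abs=1e-12)
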