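"""Differential variability: both statistics, their nulls and invariances."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from agevar import (ExpressionMatrix, SampleMetadata, SimulationConfig,
                    dv_classify, dvar_continuous, dvar_grouped, iqr,
                    null_iqr_distribution, simulate_dataset)


def _matrix(values, sample_ids):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])],
        columns=sample_ids))


def _group_meta(young_ages, old_ages, middle_ages=()):
    ages = np.concatenate([young_ages, middle_ages, old_ages])
    ids = [f"s{j}" for j in range(len(ages))]
    return SampleMetadata(pd.DataFrame({"age": ages}, index=ids)), ids


class TestDvarContinuous:
    def test_exact_linear_gene_degenerate(self):
        ages = np.linspace(22, 78, 20)
        ids = [f"s{j}" for j in range(20)]
        meta = SampleMetadata(pd.DataFrame({"age": ages}, index=ids))
        expr = _matrix(1.0 + 2.0 * ages ** 0.25, ids)
        res = dvar_continuous(expr, meta)[0]
        assert res.degenerate and res.dvar_rho == 0.0 and res.p_value == 1.0

    def test_age_reversal_flips_sign(self, rng):
        ages = np.linspace(22, 78, 30)
        ids = [f"s{j}" for j in range(30)]
        meta = SampleMetadata(pd.DataFrame({"age": ages}, index=ids))
        meta_rev = SampleMetadata(pd.DataFrame({"age": 100 - ages},
                                               index=ids))
        x = rng.normal(0, 1 + (ages - 20) / 40, (5, 30))
        expr = _matrix(x, ids)
        # residuals must be identical for the flip to be exact: use a pure
        # intercept model (exponent on a constant age effect of zero slope)
        fwd = dvar_continuous(expr, meta, exponent=0.25)
        # fitting on reversed age changes residuals; instead check the
        # Spearman antisymmetry directly on |residuals|
        from agevar.de import fit_gene_model
        from agevar.stats import spearman
        fits = fit_gene_model(expr, meta)
        for fit, f in zip(fits, fwd):
            flipped = spearman(np.abs(fit.residuals), 100 - ages)
            assert flipped.estimate == pytest.approx(-f.dvar_rho, abs=1e-12)

    def test_planted_step_genes_mostly_positive(self):
        cfg = SimulationConfig(n_genes=150, n_samples=147, frac_de=0.0,
                               frac_dv=1.0, frac_dv_increase=1.0,
                               gamma_low=2.0, gamma_high=2.0,
                               trend_shape="step", batch_scale=0.0,
                               covariate_scale=0.0, seed=31)
        expr, meta, _ = simulate_dataset(cfg)
        res = dvar_continuous(expr, meta)
        frac_pos = np.mean([r.dvar_rho > 0 for r in res])
        assert frac_pos >= 0.90


class TestNullIqrDistribution:
    def test_full_size_subsample_is_constant(self, rng):
        young = rng.normal(0, 1, 12)
        null, exhaustive = null_iqr_distribution(young, 12, B=50, seed=1)
        assert exhaustive  # C(12,12) = 1 subset
        np.testing.assert_allclose(null, iqr(young))

    def test_exhaustive_matches_brute_force_enumeration(self, rng):
        young = rng.normal(0, 1, 10)
        null, exhaustive = null_iqr_distribution(young, 4, seed=0,
                                                 exhaustive_limit=500)
        assert exhaustive and null.size == 210
        oracle = sorted(iqr(np.array(sub))
                        for sub in combinations(young, 4))
        np.testing.assert_allclose(np.sort(null), oracle, atol=1e-12)

    def test_seed_contract(self, rng):
        young = rng.normal(0, 1, 40)
        a, _ = null_iqr_distribution(young, 15, B=200, seed=3,
                                     exhaustive_limit=10)
        b, _ = null_iqr_distribution(young, 15, B=200, seed=3,
                                     exhaustive_limit=10)
        c, _ = null_iqr_distribution(young, 15, B=200, seed=4,
                                     exhaustive_limit=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_small_subsample_rejected(self):
        with pytest.raises(ValueError):
            null_iqr_distribution(np.arange(10.0), 1, B=10, seed=0)


class TestDvarGrouped:
    def _setup(self, rng, n_genes=4, n_young=12, n_old=5):
        meta, ids = _group_meta(np.linspace(21, 39, n_young),
                                np.linspace(61, 79, n_old),
                                middle_ages=np.array([50.0]))
        x = rng.normal(0, 1, (n_genes, n_young + 1 + n_old))
        return _matrix(x, ids), meta

    def test_location_and_scale_invariance_exact(self, rng):
        expr, meta = self._setup(rng)
        base = dvar_grouped(expr, meta, B=200, seed=5)
        shifted = ExpressionMatrix(expr.data + 7.5)
        scaled = ExpressionMatrix(expr.data * 3.25)
        for other in (dvar_grouped(shifted, meta, B=200, seed=5),
                      dvar_grouped(scaled, meta, B=200, seed=5)):
            for r0, r1 in zip(base, other):
                assert r1.dvar_iqr == pytest.approx(r0.dvar_iqr, abs=1e-12)
                assert r1.p_empirical == r0.p_empirical

    def test_single_gene_rescaling_invariant(self, rng):
        expr, meta = self._setup(rng)
        modified = expr.data.copy()
        modified.iloc[2] *= 42.0
        base = dvar_grouped(expr, meta, B=200, seed=5)[2]
        mod = dvar_grouped(ExpressionMatrix(modified), meta, B=200, seed=5)[2]
        assert mod.dvar_iqr == pytest.approx(base.dvar_iqr, abs=1e-12)
        assert mod.p_empirical == base.p_empirical

    def test_dvar_formula_identity_and_lower_bound(self, rng):
        expr, meta = self._setup(rng, n_genes=30)
        for r in dvar_grouped(expr, meta, B=300, seed=8):
            assert r.dvar_iqr == pytest.approx(
                (r.iqr_old - r.iqr_young_mean) / r.iqr_young_mean, abs=1e-12)
            assert r.dvar_iqr >= -1.0

    def test_exhaustive_p_matches_subset_oracle(self, rng):
        # 10 young, 4 old -> 210 subsets enumerated exactly
        meta, ids = _group_meta(np.linspace(21, 39, 10),
                                np.linspace(61, 79, 4))
        x = rng.normal(0, 1, (3, 14))
        expr = _matrix(x, ids)
        results = dvar_grouped(expr, meta, B=10, seed=0,
                               exhaustive_limit=500)
        age = meta.age
        young_vals = x[:, age <= 40]
        old_vals = x[:, age >= 60]
        for i, r in enumerate(results):
            assert r.exhaustive and r.n_resamples == 210
            null = np.array([iqr(np.array(s))
                             for s in combinations(young_vals[i], 4)])
            obs = iqr(old_vals[i])
            hi = (1 + np.sum(null >= obs)) / 211
            lo = (1 + np.sum(null <= obs)) / 211
            assert r.p_empirical == pytest.approx(min(1, 2 * min(hi, lo)),
                                                  abs=1e-12)
            assert r.dvar_iqr == pytest.approx(
                (obs - null.mean()) / null.mean(), abs=1e-12)

    def test_zero_young_iqr_degenerate_excluded_from_fdr(self, rng):
        expr, meta = self._setup(rng, n_genes=3)
        data = expr.data.copy()
        data.iloc[1] = 5.0  # constant gene: young IQR 0
        results = dvar_grouped(ExpressionMatrix(data), meta, B=100, seed=2)
        assert results[1].degenerate
        assert np.isnan(results[1].q_value)
        assert not results[0].degenerate and np.isfinite(results[0].q_value)

    def test_effect_size_limit_two_fold_spread(self):
        # old SD = 2 x young -> E[dvar] near k - 1 = 1
        cfg = SimulationConfig(n_genes=200, n_samples=147, frac_de=0.0,
                               frac_dv=1.0, frac_dv_increase=1.0,
                               gamma_low=1.0, gamma_high=1.0,
                               trend_shape="step", batch_scale=0.0,
                               covariate_scale=0.0, seed=13)
        expr, meta, _ = simulate_dataset(cfg)
        res = dvar_grouped(expr, meta, B=500, seed=13)
        mean_dvar = np.mean([r.dvar_iqr for r in res])
        assert mean_dvar == pytest.approx(1.0, abs=0.2)


class TestDvClassify:
    def test_all_zero_flagged(self):
        from agevar.dv import DVContinuousResult
        res = [DVContinuousResult(f"g{i}", 0.0, 1.0, 1.0) for i in range(10)]
        summary = dv_classify(res)
        assert summary["all_zero"] and summary["fraction_positive"] == 0.0

    def test_symmetric_null_wilcoxon_non_significant(self, clean_null_dataset):
        expr, meta, _ = clean_null_dataset
        res = dvar_continuous(expr, meta)
        summary = dv_classify(res)
        assert summary["wilcoxon_p"] > 0.05
        assert 0.4 < summary["fraction_positive"] < 0.6

    def test_planted_two_to_one_sign_ratio(self):
        cfg = SimulationConfig(n_genes=600, n_samples=147, frac_de=0.0,
                               frac_dv=0.3, frac_dv_increase=2 / 3,
                               gamma_low=3.0, gamma_high=3.0,
                               trend_shape="step", batch_scale=0.0,
                               covariate_scale=0.0, seed=19)
        expr, meta, _ = simulate_dataset(cfg)
        summary = dv_classify(dvar_grouped(expr, meta, B=500, seed=19))
        ratio = summary["n_increase"] / max(summary["n_decrease"], 1)
        assert 1.3 < ratio < 3.0
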