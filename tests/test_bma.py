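"""The averaging core: subset fits, enumeration, Occam's window, iteration."""
import logging
import math

import numpy as np
import pytest

from atherobma import (
    GeneratorConfig,
    enumerate_bma,
    fit_subset,
    generate_cohort,
    ibma_select,
    occam_window,
    preprocess_cohort,
    rank_variables,
    run_all_indexes,
)
from atherobma.bma import CollinearityError, SubsetModelFit
from atherobma.synthetic import protein_names

from _oracles import bma_oracle, ols_fit, univariate_r2_order


class TestFitSubset:
    def test_null_model(self, rng):
        y = rng.normal(size=12)
        X = rng.normal(size=(12, 3))
        fit = fit_subset(y, X, [False, False, False])
        assert fit.intercept == pytest.approx(y.mean())
        assert fit.rss == pytest.approx(((y - y.mean()) ** 2).sum())
        assert fit.coefficients.size == 0

    def test_perfect_fit_keeps_bic_finite(self):
        x = np.arange(10.0)
        y = 2.0 * x
        fit = fit_subset(y, x[:, None], [True])
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert np.isfinite(fit.bic)

    def test_matches_independent_normal_equations(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 3))
        fit = fit_subset(y, X, [True, True, True])
        intercept, slopes, rss = ols_fit(y, X)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)
        assert np.allclose(fit.coefficients, slopes, atol=1e-8)
        assert fit.rss == pytest.approx(rss, abs=1e-8)

    def test_collinear_subset_names_variables(self, rng):
        x = rng.normal(size=15)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError, match="dup"):
            fit_subset(rng.normal(size=15), X, [True, True], names=["dup_a", "dup_b"])

    def test_small_sample_cap(self, rng):
        y = rng.normal(size=5)
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="cap"):
            fit_subset(y, X, [True] * 4)


class TestEnumerate:
    def test_pmp_normalization(self, rng):
        y = rng.normal(size=25)
        X = rng.normal(size=(25, 4))
        res = enumerate_bma(y, X)
        assert sum(m.pmp for m in res.models) == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_predictor_not_included(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        X = rng.normal(size=(100, 1))
        res = enumerate_bma(y, X)
        assert res.inclusion_prob.iloc[0] < 0.5

    def test_matches_bruteforce_oracle(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 5))
        y = y + X[:, 0] - 0.5 * X[:, 2]
        ref_incl, ref_coef = bma_oracle(y, X)
        res = enumerate_bma(y, X, occam_ratio=math.inf)
        assert np.abs(res.inclusion_prob.to_numpy() - ref_incl).max() <= 1e-10
        assert np.abs(res.avg_coefficient.to_numpy() - ref_coef).max() <= 1e-10

    def test_refuses_large_p(self, rng):
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 21))
        with pytest.raises(ValueError, match="ibma_select"):
            enumerate_bma(y, X)

    def test_averaging_identity(self, rng):
        """avg coefficient = inclusion prob x conditional mean slope."""
        y = rng.normal(size=25)
        X = rng.normal(size=(25, 4))
        y = y + 0.8 * X[:, 1]
        res = enumerate_bma(y, X)
        for j, name in enumerate(res.names):
            cond = sum(
                m.pmp * m.coefficients[list(np.flatnonzero(m.mask)).index(j)]
                for m in res.models
                if m.mask[j]
            )
            incl = res.inclusion_prob[name]
            assert res.avg_coefficient[name] == pytest.approx(cond, abs=1e-12)
            if incl > 0:
                assert res.avg_coefficient[name] == pytest.approx(
                    incl * (cond / incl), abs=1e-12
                )

    def test_monotone_signal_response(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        noise = rng.normal(size=30)
        nuisance = rng.normal(size=(30, 2))
        X = np.column_stack([x, nuisance])
        previous = -1.0
        for c in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0):
            res = enumerate_bma(c * x + noise, X)
            incl = float(res.inclusion_prob.iloc[0])
            assert incl >= previous - 1e-12
            previous = incl


class TestOccamWindow:
    @staticmethod
    def _models_from_pmps(pmps):
        return [
            SubsetModelFit(mask=np.array([True]), intercept=0.0,
                           coefficients=np.array([0.0]), rss=1.0,
                           bic=-2.0 * math.log(p))
            for p in pmps
        ]

    def test_hand_computed_ratios(self):
        models = self._models_from_pmps([0.6, 0.35, 0.05])
        assert len(occam_window(models, ratio=20)) == 3  # 0.6/0.05 = 12 <= 20
        kept = occam_window(models, ratio=10)  # 12 > 10 drops the weakest
        assert len(kept) == 2
        assert sum(m.pmp for m in kept) == pytest.approx(1.0, abs=1e-12)
        assert kept[0].pmp == pytest.approx(0.6 / 0.95)

    def test_ratio_one_keeps_only_best(self):
        kept = occam_window(self._models_from_pmps([0.6, 0.35, 0.05]), ratio=1.0)
        assert len(kept) == 1
        assert kept[0].pmp == pytest.approx(1.0)

    def test_infinite_ratio_keeps_all(self):
        assert len(occam_window(self._models_from_pmps([0.9, 0.1]), math.inf)) == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            occam_window([], ratio=2.0)
        with pytest.raises(ValueError):
            occam_window(self._models_from_pmps([1.0]), ratio=0.5)


class TestRankVariables:
    def test_perfect_predictor_first(self, rng):
        y = rng.normal(size=20)
        X = np.column_stack([rng.normal(size=20), y, rng.normal(size=20)])
        assert rank_variables(y, X, ["a", "target", "b"])[0] == "target"

    def test_tie_break_lexicographic(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        assert rank_variables(y, np.column_stack([x, x]), ["b", "a"])[:2] == ["a", "b"]

    def test_matches_squared_correlation_sort(self, rng):
        y = rng.normal(size=25)
        X = rng.normal(size=(25, 6))
        names = [f"v{j}" for j in range(6)]
        assert rank_variables(y, X, names) == univariate_r2_order(y, X, names)


class TestIbmaSelect:
    def test_single_window_equals_enumeration(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 5))
        y = y + X[:, 3]
        full = enumerate_bma(y, X, names=list("abcde"))
        iterated = ibma_select(y, X, names=list("abcde"), window_size=5)
        assert (iterated.inclusion_prob == full.inclusion_prob).all()
        assert (iterated.avg_coefficient == full.avg_coefficient).all()
        assert iterated.retained == full.retained

    def test_exhaustive_equivalence_without_window_pressure(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 7))
        y = y - X[:, 0] + 0.5 * X[:, 5]
        ref_incl, ref_coef = bma_oracle(y, X)
        res = ibma_select(y, X, window_size=7, occam_ratio=math.inf)
        assert np.abs(res.inclusion_prob.to_numpy() - ref_incl).max() <= 1e-10
        assert np.abs(res.avg_coefficient.to_numpy() - ref_coef).max() <= 1e-10

    def test_recovers_planted_effects_among_many_candidates(self):
        rng = np.random.default_rng(12)
        n, p = 40, 50
        X = rng.normal(size=(n, p))
        names = [f"v{j:02d}" for j in range(p)]
        y = X[:, 3] + X[:, 17] - X[:, 31] + rng.normal(scale=0.3, size=n)
        res = ibma_select(y, X, names=names)
        for planted in ("v03", "v17", "v31"):
            assert planted in res.retained

    def test_shrinkage_sets_unretained_coefficients_to_zero(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 30))
        X[:, 4] = y + rng.normal(scale=0.2, size=40)
        res = ibma_select(y, X)
        absent = [v for v in res.names if res.inclusion_prob[v] == 0.0]
        assert absent  # iteration pruned something
        for v in absent:
            assert res.avg_coefficient[v] == 0.0

    def test_null_false_positive_rate_is_low(self):
        """All-noise candidates: mean retained count stays near the
        false-positive rate the 0.5 retention threshold implies."""
        counts = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            y = rng.normal(size=40)
            X = rng.normal(size=(40, 20))
            counts.append(len(ibma_select(y, X).retained))
        assert np.mean(counts) <= 2.0  # 10% of the 20 candidates

    def test_window_size_caps(self, rng):
        y = rng.normal(size=6)
        X = rng.normal(size=(6, 8))
        with pytest.raises(ValueError, match="small-sample"):
            ibma_select(y, X, window_size=5)
        with pytest.raises(ValueError, match="retention_threshold"):
            ibma_select(y, X, window_size=2, retention_threshold=1.5)


class TestRunAllIndexes:
    def test_shape_contract(self, default_dataset):
        results = run_all_indexes(default_dataset)
        assert set(results) == {"IT_mean", "IT_median", "LA_mean", "LA_median"}

    def test_noise_free_planted_effect_retained_everywhere(self):
        target = protein_names(15)[0]
        cfg = GeneratorConfig(
            n_cntl=4, n_hf=10, n_hhf=10, n_proteins=15, noise_sd=0.0,
            true_effect_map={target: 1.0},
            lesion_pattern={"CNTL": "diffuse", "HF": "diffuse", "HHF": "diffuse"},
            seed=5,
        )
        ds = preprocess_cohort(generate_cohort(cfg))
        results = run_all_indexes(ds)
        for index, res in results.items():
            assert target in res.retained, index
            assert res.avg_coefficient[target] > 0

    def test_small_group_run_logs_window_cap(self, default_dataset, caplog):
        with caplog.at_level(logging.INFO, logger="atherobma.bma"):
            results = run_all_indexes(default_dataset, group_filter="HF")
        assert set(results) == {"IT_mean", "IT_median", "LA_mean", "LA_median"}
        assert "window size capped" in caplog.text
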