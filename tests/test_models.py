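"""Expression models: enumeration, OLS, model selection, LASSO, LOO rules."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methnet.circuits import MethylationMatrix
from methnet.models import (
    GeneModel,
    enumerate_site_sets,
    fit_linear_model,
    lasso_model,
    loo_validate,
    prediction_success,
    select_best_model,
)
from methnet.reporter import bh_adjust
from methnet.simulate import SimulationConfig, simulate_cohort


def make_meth(beta_matrix, samples=None):
    n_sites, n_samples = beta_matrix.shape
    idx = pd.Index([f"s{i}" for i in range(n_sites)], name="site_id")
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(n_sites) * 100 + 1000}, index=idx
    )
    cols = samples or [f"T{j}" for j in range(n_samples)]
    return MethylationMatrix(sites, pd.DataFrame(beta_matrix, index=idx, columns=cols))


class TestEnumerateSiteSets:
    def test_complete_data_count_is_binomial_sum(self, rng):
        meth = make_meth(rng.uniform(0, 1, (8, 15)))
        sets = enumerate_site_sets(list(meth.beta.index), meth, max_k=4, min_complete=12)
        expected = sum(math.comb(8, k) for k in range(1, 5))
        assert len(sets) == expected
        assert len(set(sets)) == len(sets)

    def test_single_site(self, rng):
        meth = make_meth(rng.uniform(0, 1, (1, 15)))
        assert enumerate_site_sets(["s0"], meth) == [("s0",)]

    def test_jointly_incomplete_pair_excluded(self, rng):
        beta = rng.uniform(0, 1, (2, 15))
        beta[0, :2] = np.nan  # s0 observed in 13
        beta[1, 2:4] = np.nan  # s1 observed in 13; joint complete = 11
        meth = make_meth(beta)
        sets = enumerate_site_sets(["s0", "s1"], meth, min_complete=12)
        assert ("s0",) in sets and ("s1",) in sets
        assert ("s0", "s1") not in sets

    def test_no_candidates_warns(self, rng):
        meth = make_meth(rng.uniform(0, 1, (1, 15)))
        with pytest.warns(UserWarning):
            assert enumerate_site_sets([], meth) == []


def ols_oracle(x, y):
    """Closed-form simple-regression slope/intercept via normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return y.mean() - slope * x.mean(), slope


class TestFitLinearModel:
    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 1, 15)
        y = 3.0 - 2.0 * x + rng.normal(0, 0.3, 15)
        meth = make_meth(x[None, :])
        model = fit_linear_model(("s0",), meth, pd.Series(y, index=meth.samples))
        b0, b1 = ols_oracle(x, y)
        assert model.intercept == pytest.approx(b0, abs=1e-10)
        assert model.coefs[0] == pytest.approx(b1, abs=1e-10)

    def test_perfect_linear_fit(self, rng):
        x = rng.uniform(0, 1, 15)
        meth = make_meth(x[None, :])
        model = fit_linear_model(("s0",), meth, pd.Series(5 + 2 * x, index=meth.samples))
        assert model.r_model == pytest.approx(1.0)
        assert model.p_model == pytest.approx(0.0, abs=1e-12)

    def test_collinear_design_rejected(self, rng):
        x = rng.uniform(0, 1, 15)
        meth = make_meth(np.vstack([x, x]))  # duplicated predictor
        model = fit_linear_model(
            ("s0", "s1"), meth, pd.Series(1 + x, index=meth.samples)
        )
        assert not model.rank_ok

    def test_too_few_complete_samples_raises(self, rng):
        beta = rng.uniform(0, 1, (1, 15))
        beta[0, :5] = np.nan
        meth = make_meth(beta)
        with pytest.raises(ValueError, match="complete"):
            fit_linear_model(("s0",), meth, pd.Series(np.ones(15), index=meth.samples),
                             min_complete=12)

    def test_null_f_pvalues_roughly_uniform(self, rng):
        # under independence the overall F-test p-value is Uniform(0,1)
        from scipy.stats import kstest

        pvals = []
        for _ in range(300):
            x = rng.uniform(0, 1, (2, 20))
            y = rng.normal(0, 1, 20)
            meth = make_meth(x)
            m = fit_linear_model(("s0", "s1"), meth, pd.Series(y, index=meth.samples))
            pvals.append(m.p_model)
        assert kstest(pvals, "uniform").pvalue > 1e-3


def brute_force_best(models, q_max=0.05):
    valid = [m for m in models if m.rank_ok and np.isfinite(m.p_model)]
    if not valid:
        return None
    qs = bh_adjust([m.p_model for m in valid])
    sig = [(m, q) for m, q in zip(valid, qs) if q < q_max]
    if not sig:
        return None
    return sorted(sig, key=lambda t: (-t[0].r2, len(t[0].site_ids), t[0].site_ids))[0][0]


class TestSelectBestModel:
    def _fit_all(self, meth, y, max_k=4, min_complete=10):
        sets = enumerate_site_sets(
            list(meth.beta.index), meth, max_k=max_k, min_complete=min_complete
        )
        out = []
        for s in sets:
            try:
                out.append(fit_linear_model(s, meth, y, min_complete=min_complete))
            except ValueError:
                pass
        return out

    def test_equals_exhaustive_brute_force(self, rng):
        for trial in range(5):
            n_sites = int(rng.integers(3, 8))
            beta = rng.uniform(0, 1, (n_sites, 18))
            y = pd.Series(
                2 + beta[0] - 0.8 * beta[-1] + rng.normal(0, 0.2, 18),
            )
            meth = make_meth(beta)
            y.index = meth.samples
            models = self._fit_all(meth, y)
            best = select_best_model("g", [m for m in models], q_max=0.05)
            oracle = brute_force_best(models)
            if oracle is None:
                assert best is None
            else:
                assert best.site_ids == oracle.site_ids

    def test_tie_break_prefers_smaller_model(self):
        def fake(sites, r, p):
            return GeneModel(
                gene_id="g", site_ids=sites, intercept=0.0,
                coefs=np.zeros(len(sites)), coef_se=np.zeros(len(sites)),
                n_complete=20, r_model=r, p_model=p,
            )

        small = fake(("a", "b"), 0.9, 1e-6)
        large = fake(("a", "b", "c"), 0.9, 1e-6)
        best = select_best_model("g", [large, small])
        assert best.site_ids == ("a", "b")

    def test_synergy_flag_set_for_additive_signal(self, rng):
        x1, x2 = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        y = pd.Series(1 + x1 - x2 + rng.normal(0, 0.05, 20))
        meth = make_meth(np.vstack([x1, x2]))
        y.index = meth.samples
        best = select_best_model("g", self._fit_all(meth, y))
        assert best.site_ids == ("s0", "s1")
        assert best.synergic

    def test_no_significant_model_returns_none(self, rng):
        beta = rng.uniform(0, 1, (3, 15))
        y = pd.Series(rng.normal(0, 1, 15))
        meth = make_meth(beta)
        y.index = meth.samples
        models = self._fit_all(meth, y)
        assert select_best_model("g", models) is brute_force_best(models)


class TestLasso:
    def test_strong_single_site_selected(self, rng):
        hits = 0
        for rep in range(20):
            beta = rng.uniform(0, 1, (6, 24))
            y = pd.Series(3 + 2.5 * beta[2] + rng.normal(0, 0.1, 24))
            meth = make_meth(beta)
            y.index = meth.samples
            m = lasso_model("g", list(meth.beta.index), meth, y, seed=rep)
            if m is not None and "s2" in m.site_ids:
                hits += 1
        assert hits >= 18  # the driving site is found in >= 90% of replicates

    def test_constant_response_fully_shrinks(self, rng):
        beta = rng.uniform(0, 1, (4, 20))
        meth = make_meth(beta)
        y = pd.Series(np.full(20, 2.0), index=meth.samples)
        assert lasso_model("g", list(meth.beta.index), meth, y) is None

    def test_planted_four_unit_model_size(self):
        # four single-site units drive expression: the penalised model should
        # select close to the four planted drivers plus few spurious sites
        sizes = []
        for rep in range(10):
            cfg = SimulationConfig(
                seed=900 + rep, n_genes=1, base_pos_units=2, base_neg_units=2,
                extra_pos_unit_prob=0.0, extra_neg_unit_prob=0.0,
                sites_per_unit_min=1, sites_per_unit_lambda=0.0,
                unit_weight_range=(1.0, 1.5), site_sd=0.02, expr_sd=0.15,
                missing_rate=0.0, n_null_sites_per_gene=6,
                n_reference_samples=200,
            )
            meth, expr, genes, truth = simulate_cohort(cfg)
            m = lasso_model(
                "G000", list(meth.beta.index), meth, expr.loc["G000"], seed=rep
            )
            sizes.append(0 if m is None else len(m.site_ids))
        assert 2 <= np.mean(sizes) <= 6  # within +/-2 of the planted 4


class TestLeaveOneOut:
    def test_success_boundary_inclusive(self):
        assert prediction_success(1.0)
        assert prediction_success(0.999)
        assert not prediction_success(1.0000001)

    def test_noiseless_cohort_fully_predictable(self):
        cfg = SimulationConfig(
            seed=41, n_genes=3, n_samples=16, unit_coupling=1.0,
            sites_per_unit_min=2, sites_per_unit_lambda=0.5,
            site_sd=0.0, expr_sd=0.0, missing_rate=0.0,
            n_null_sites_per_gene=4, n_reference_samples=500,
        )
        meth, expr, genes, truth = simulate_cohort(cfg)
        predictions, report = loo_validate(meth, expr, genes)
        modeled = predictions[predictions["had_model"]]
        assert len(modeled) > 0
        assert modeled["success"].all()
        assert (modeled["abs_log2_error"] < 1e-6).all()
        modeled_genes = report[report["rounds_with_model"] > 0]
        assert modeled_genes["verified"].all()

    def test_irregular_flag_matches_one_sd_rule(self):
        cfg = SimulationConfig(
            seed=43, n_genes=2, n_samples=14, unit_coupling=1.0,
            sites_per_unit_min=2, sites_per_unit_lambda=0.5,
            site_sd=0.0, expr_sd=0.0, missing_rate=0.0,
            n_null_sites_per_gene=2, n_reference_samples=500,
        )
        meth, expr, genes, truth = simulate_cohort(cfg)
        predictions, _ = loo_validate(meth, expr, genes)
        mean = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        for row in predictions.itertuples(index=False):
            expected = abs(row.observed - mean[row.gene_id]) > sd[row.gene_id]
            assert row.irregular == expected
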