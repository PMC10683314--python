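"""Circuit inference: Spearman primitive, domain mapping, exclusion filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from methnet.circuits import (
    MethylationMatrix,
    blood_filter,
    canonical_filter,
    cnv_block_association,
    map_circuits,
    secondary_filter,
    spearman,
)
from methnet.intervals import GeneAnnotation


def spearman_oracle(x, y):
    """Rank both vectors (average ranks for ties), then Pearson."""
    xr, yr = rankdata(x), rankdata(y)
    return float(np.corrcoef(xr, yr)[0, 1])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n), 1)
            rho, _, n_obs = spearman(x, y)
            assert n_obs == n
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_pairwise_complete_and_min_obs(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, np.nan, 10.0])
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, np.nan])
        rho, p, n = spearman(x, y)
        assert n == 8 and rho == pytest.approx(1.0)
        rho, p, n = spearman(x[:8], y[:8], min_obs=9)
        assert n == 8 and np.isnan(rho)

    def test_constant_vector_flagged(self):
        assert np.isnan(spearman(np.ones(10), np.arange(10.0))[0])


def _cohort(n=24, seed=5):
    """Hand-built cohort: one gene, one strong site, null sites, for filters."""
    rng = np.random.default_rng(seed)
    samples = [f"T{i}" for i in range(n)]
    m = rng.uniform(0, 1, n)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "pos": [1_050_000, 1_400_000, 2_000_001 + 1_000_000],
        },
        index=pd.Index(["sA", "sB", "sFar"], name="site_id"),
    )
    beta = pd.DataFrame(
        [m, rng.uniform(0, 1, n), rng.uniform(0, 1, n)],
        index=sites.index,
        columns=samples,
    )
    expr = pd.DataFrame({s: [0.0] for s in samples}, index=["G1"])
    expr.loc["G1"] = 5 + 2 * m
    gene = GeneAnnotation("G1", "chr1", "+", 1_500_000, 1_500_000, 1_520_000)
    return MethylationMatrix(sites, beta), expr, [gene]


class TestMapCircuits:
    def test_planted_monotone_association_retained(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        row = circuits.set_index("site_id").loc["sA"]
        assert row["rho"] == pytest.approx(1.0)
        assert bool(row["retained"])

    def test_site_beyond_domain_never_tested(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        assert "sFar" not in set(circuits["site_id"])  # tss_distance > 1 Mb

    def test_invariant_to_sample_order_and_monotone_transform(self):
        meth, expr, genes = _cohort()
        base = map_circuits(meth, expr, genes).set_index("site_id")["rho"]
        perm = list(np.random.default_rng(0).permutation(meth.samples))
        shuffled = map_circuits(
            MethylationMatrix(meth.sites, meth.beta[perm]), expr[perm], genes
        ).set_index("site_id")["rho"]
        assert np.allclose(base.sort_index(), shuffled.sort_index())
        transformed = map_circuits(meth, 2.0 ** expr, genes).set_index("site_id")["rho"]
        assert np.allclose(base.sort_index(), transformed.sort_index())

    def test_too_few_shared_samples_rejected(self):
        meth, expr, genes = _cohort(n=10)
        with pytest.raises(ValueError, match="shared samples"):
            map_circuits(meth, expr, genes)

    def test_filters_only_add_flags(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        before = circuits[["gene_id", "site_id", "rho", "p", "q", "stat_ok"]].copy()
        ptprc = expr.loc["G1"] * 0 + np.random.default_rng(1).normal(size=24)
        filtered = blood_filter(circuits, meth, ptprc)
        filtered = secondary_filter(filtered, genes, expr)
        after = filtered[["gene_id", "site_id", "rho", "p", "q", "stat_ok"]]
        pd.testing.assert_frame_equal(before, after)


class TestBloodFilter:
    def test_tracking_site_flagged_weak_site_kept(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        ptprc = pd.Series(
            meth.beta.loc["sA"].to_numpy(), index=meth.samples
        )  # rho = 1 with sA
        out = blood_filter(circuits, meth, ptprc)
        flags = out.set_index("site_id")["blood_filtered"]
        assert bool(flags["sA"])
        rho_b, _, _ = spearman(
            meth.beta.loc["sB"].to_numpy(), ptprc.to_numpy()
        )
        assert bool(flags["sB"]) == (rho_b**2 > 0.1)
        assert not out.set_index("site_id")["retained"]["sA"]

    def test_constant_ptprc_is_inert(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        out = blood_filter(circuits, meth, pd.Series(1.0, index=meth.samples))
        assert not out["blood_filtered"].any()

    def test_missing_ptprc_warns_and_skips(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        with pytest.warns(UserWarning):
            out = blood_filter(circuits, meth, None)
        assert not out["blood_filtered"].any()


class TestSecondaryFilter:
    def _with_other_gene(self, other_expr_corr):
        meth, expr, genes = _cohort()
        # place another gene whose promoter contains site sA (pos 1_050_000)
        other = GeneAnnotation("G2", "chr1", "+", 1_051_000, 1_051_000, 1_060_000)
        if other_expr_corr:
            expr.loc["G2"] = expr.loc["G1"] * 1.5 + 1
        else:
            expr.loc["G2"] = np.random.default_rng(3).normal(size=24)
        return meth, expr, genes + [other]

    def test_correlated_neighbor_flags_site(self):
        meth, expr, genes = self._with_other_gene(other_expr_corr=True)
        circuits = map_circuits(meth, expr, genes[:1])
        out = secondary_filter(circuits, genes, expr)
        assert bool(out.set_index("site_id")["secondary_filtered"]["sA"])

    def test_uncorrelated_neighbor_keeps_site(self):
        meth, expr, genes = self._with_other_gene(other_expr_corr=False)
        circuits = map_circuits(meth, expr, genes[:1])
        out = secondary_filter(circuits, genes, expr)
        assert not out["secondary_filtered"].any()

    def test_site_outside_any_other_gene_kept(self):
        meth, expr, genes = _cohort()
        circuits = map_circuits(meth, expr, genes)
        out = secondary_filter(circuits, genes, expr)
        assert not out["secondary_filtered"].any()


class TestCanonicalFilter:
    def _circuits(self, sign):
        return pd.DataFrame(
            {
                "gene_id": ["G1"],
                "site_id": ["s1"],
                "chrom": ["chr1"],
                "pos": [10_000],
                "sign": [sign],
                "stat_ok": [True],
                "blood_filtered": [False],
                "secondary_filtered": [False],
                "canonical_mismatch": [False],
                "retained": [True],
            }
        )

    def _elements(self, group, start=9_900, sensitive=True):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [start],
                "end": [start + 500],
                "cls": ["enhancer"],
                "sensitive": [sensitive],
                "group": [group],
            }
        )

    def test_negative_circuit_matching_group_i_kept(self):
        out = canonical_filter(self._circuits("negative"), self._elements("I"))
        assert not out["canonical_mismatch"].iloc[0]

    def test_positive_circuit_near_group_ii_flagged(self):
        out = canonical_filter(self._circuits("positive"), self._elements("II"))
        assert bool(out["canonical_mismatch"].iloc[0])
        assert not bool(out["retained"].iloc[0])

    def test_no_element_within_max_dist_kept(self):
        out = canonical_filter(
            self._circuits("positive"), self._elements("II", start=11_000)
        )
        assert not out["canonical_mismatch"].iloc[0]

    def test_insensitive_element_kept(self):
        out = canonical_filter(
            self._circuits("positive"),
            self._elements("unclassified", sensitive=False),
        )
        assert not out["canonical_mismatch"].iloc[0]


class TestCnvBlocks:
    def _inputs(self, n=12, constant=False, n_available=None, seed=9):
        rng = np.random.default_rng(seed)
        samples = [f"T{i}" for i in range(n)]
        tcn_vals = np.full(n, 2.0) if constant else rng.integers(1, 6, n).astype(float)
        if n_available is not None:
            tcn_vals[n_available:] = np.nan
        tcn = pd.DataFrame(
            [{"chrom": "chr1", "start": 1_400_000, "end": 1_405_000,
              **dict(zip(samples, tcn_vals))}]
        )
        expr = pd.DataFrame(
            {s: [v] for s, v in zip(samples, 3 + 0.9 * np.nan_to_num(tcn_vals, nan=2.0)
                                    + rng.normal(0, 0.1, n))},
            index=["G1"],
        )
        gene = GeneAnnotation("G1", "chr1", "+", 1_500_000, 1_500_000, 1_520_000)
        return tcn, expr, [gene]

    def test_planted_linear_relation_significant(self):
        tcn, expr, genes = self._inputs()
        out = cnv_block_association(tcn, expr, genes)
        assert len(out) == 1
        assert out["pearson_r"].iloc[0] > 0.9
        assert out["pearson_q"].iloc[0] < 0.05

    def test_constant_tcn_skipped(self):
        tcn, expr, genes = self._inputs(constant=True)
        assert len(cnv_block_association(tcn, expr, genes)) == 0

    def test_fewer_than_min_n_samples_skipped(self):
        tcn, expr, genes = self._inputs(n_available=5)
        assert len(cnv_block_association(tcn, expr, genes)) == 0
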