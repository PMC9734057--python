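"""QTL scan: OLS oracle agreement, empirical P arithmetic, Storey q,
window rules, conditional selection, control matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circpath import qtl
from circpath.simulate import ScenarioConfig, simulate_cohort, simulate_genotypes
from circpath.types import CovariateTable, ExpressionMatrix, GenotypeMatrix

from conftest import snp_frame


def _expr(values, loci_rows, role="circRNA"):
    loci = pd.DataFrame(
        loci_rows, columns=["feature_id", "chrom", "start", "end", "strand"]
    ).set_index("feature_id")
    return ExpressionMatrix(values, loci, role)


class TestResidualize:
    def _cohort(self, n=20, k=3, f=5, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        cov = CovariateTable(
            pd.DataFrame(
                rng.standard_normal((n, k)),
                index=samples,
                columns=[f"c{j}" for j in range(k)],
            )
        )
        vals = pd.DataFrame(
            rng.standard_normal((f, n)),
            index=[f"f{j}" for j in range(f)],
            columns=samples,
        )
        expr = _expr(vals, [(f"f{j}", "chr1", 1, 2, "+") for j in range(f)])
        return expr, cov

    def test_matches_projection_matrix_oracle(self):
        """Residuals equal (I - H) y from the explicit hat matrix."""
        expr, cov = self._cohort(20, 10, 5, seed=1)
        out = qtl.residualize(expr, cov)
        X = np.column_stack([np.ones(20), cov.data.to_numpy()])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for f in expr.feature_ids:
            y = expr.values.loc[f].to_numpy()
            np.testing.assert_allclose(
                out.values.loc[f].to_numpy(), (np.eye(20) - H) @ y, atol=1e-10
            )

    def test_intercept_only_mean_centers(self):
        expr, _ = self._cohort(15, 1, 2, seed=2)
        cov0 = CovariateTable(pd.DataFrame(index=expr.sample_ids))
        out = qtl.residualize(expr, cov0)
        np.testing.assert_allclose(
            out.values.to_numpy(),
            expr.values.to_numpy() - expr.values.to_numpy().mean(axis=1, keepdims=True),
            atol=1e-12,
        )

    def test_feature_equal_to_covariate_vanishes(self):
        expr, cov = self._cohort(12, 2, 1, seed=3)
        vals = expr.values.copy()
        vals.iloc[0] = cov.data["c0"].to_numpy()
        expr = ExpressionMatrix(vals, expr.loci, expr.role)
        out = qtl.residualize(expr, cov)
        assert np.max(np.abs(out.values.iloc[0].to_numpy())) < 1e-10

    def test_residuals_orthogonal_to_covariates(self):
        expr, cov = self._cohort(30, 4, 3, seed=4)
        out = qtl.residualize(expr, cov)
        R = out.values.to_numpy()
        C = cov.data.to_numpy()
        scale = np.linalg.norm(R) * np.linalg.norm(C)
        assert np.max(np.abs(R @ C)) / scale < 1e-8


class TestAdditiveTest:
    def test_perfect_fit(self):
        g = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        beta, se, t, p = qtl.additive_test(2 * g, g)
        assert beta == pytest.approx(2.0)
        assert p < 1e-300 or p == np.finfo(float).tiny

    def test_orthogonal_vectors_give_zero_slope_p_one(self):
        g = np.array([0.0, 0, 1, 1, 2, 2])
        y = np.array([1.0, -1, 1, -1, 1, -1])  # orthogonal to centered g
        beta, se, t, p = qtl.additive_test(y, g)
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        """Fixed 8-sample vectors reproduce a from-scratch OLS + t-CDF oracle."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            g = rng.integers(0, 3, 8).astype(float)
            if g.var() == 0:
                continue
            y = rng.standard_normal(8)
            beta, se, t, p = qtl.additive_test(y, g)
            # independent oracle: solve [1 g] normal equations explicitly
            X = np.column_stack([np.ones(8), g])
            bh = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bh
            s2 = resid @ resid / 6
            seh = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            th = bh[1] / seh
            ph = 2 * stats.t.sf(abs(th), 6)
            assert beta == pytest.approx(bh[1], abs=1e-10)
            assert se == pytest.approx(seh, abs=1e-10)
            assert t == pytest.approx(th, abs=1e-10)
            assert p == pytest.approx(ph, abs=1e-10)

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            qtl.additive_test(np.arange(6.0), np.ones(6))


class TestEmpiricalP:
    def test_printed_formula_examples(self):
        # null {0.2, 0.4, 0.6}, observed 0.5 -> (1+2)/4
        assert qtl.empirical_p(0.5, np.array([0.2, 0.4, 0.6])) == pytest.approx(0.75)
        # smaller than all 10,000 null values -> floor 1/10001
        null = np.linspace(0.01, 1, 10_000)
        assert qtl.empirical_p(0.001, null) == pytest.approx(1 / 10_001)
        # observed 1 with all null below -> (1+10000)/10001 = 1
        assert qtl.empirical_p(1.0, null * 0.99) == pytest.approx(1.0)

    def test_ties_count_as_not_smaller(self):
        assert qtl.empirical_p(0.4, np.array([0.4, 0.4, 0.4])) == pytest.approx(1 / 4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.floats(0, 1),
    )
    def test_equals_brute_force_count(self, null, p_obs):
        null = np.array(null)
        expected = (1 + sum(1 for v in null if v < p_obs)) / (null.size + 1)
        assert qtl.empirical_p(p_obs, null) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=50))
    def test_monotone_in_observed_p(self, null):
        null = np.array(null)
        grid = np.linspace(0, 1, 21)
        emp = qtl.empirical_p(grid, null)
        assert np.all(np.diff(emp) >= 0)


class TestStoreyQ:
    def test_pi0_one_reduces_to_bh(self):
        """With pi0 = 1 (few features) Storey q equals BH-adjusted p."""
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.9, 0.5, 0.02, 0.4, 0.01, 0.6, 0.3])  # < 10 -> pi0 = 1
        q = qtl.storey_q(p)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_q_is_pi0_times_bh(self):
        """Independent decomposition: q = clip(pi0_hat * BH(p))."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = np.concatenate([np.full(5, 0.001), rng.uniform(size=95)])
        q = qtl.storey_q(p)
        pi0 = qtl.estimate_pi0(p)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, np.clip(pi0 * bh, 0, 1), atol=1e-12)

    def test_planted_signals_called(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([np.full(5, 0.001), rng.uniform(size=95)])
        q = qtl.storey_q(p)
        assert (q[:5] < 0.05).all()

    def test_constant_p_gives_constant_q(self):
        q = qtl.storey_q(np.full(20, 0.3))
        assert np.allclose(q, q[0])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = qtl.storey_q(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def _toy_geno(positions, dosages, samples=None):
    samples = samples or [f"s{i}" for i in range(dosages.shape[0])]
    ids = list(positions.index)
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=samples, columns=ids), positions
    )


class TestWindows:
    def test_cis_window_boundary_inclusive(self):
        pos = snp_frame(
            [
                ("at_edge", "chr1", 1_000_000 - 200_000),  # exactly 200 kb from donor
                ("outside", "chr1", 1_005_000 + 200_001),  # 200,001 bp beyond both
                ("other_chrom", "chr2", 1_000_000),
            ]
        )
        rng = np.random.default_rng(9)
        g = _toy_geno(pos, rng.integers(0, 3, (10, 3)).astype(float))
        circ = _expr(
            pd.DataFrame(
                rng.standard_normal((1, 10)), index=["c1"], columns=g.sample_ids
            ),
            [("c1", "chr1", 1_000_000, 1_005_000, "+")],
        )
        mask = qtl.cis_pair_mask(g, circ)
        assert mask[list(pos.index).index("at_edge"), 0]
        assert not mask[list(pos.index).index("outside"), 0]
        assert not mask[list(pos.index).index("other_chrom"), 0]

    def test_trans_distance_strictly_greater(self):
        pos = snp_frame(
            [
                ("inside", "chr1", 10_000_500),
                ("at_5mb", "chr1", 10_001_000 + 5_000_000),  # gap exactly 5 Mb
                ("beyond", "chr1", 10_001_000 + 5_000_001),
                ("diff_chrom", "chr2", 500),
            ]
        )
        rng = np.random.default_rng(10)
        g = _toy_geno(pos, rng.integers(0, 3, (10, 4)).astype(float))
        gene = _expr(
            pd.DataFrame(
                rng.standard_normal((1, 10)), index=["g1"], columns=g.sample_ids
            ),
            [("g1", "chr1", 10_000_000, 10_001_000, "+")],
            role="gene",
        )
        mask = qtl.trans_pair_mask(g, gene)
        ids = list(pos.index)
        assert not mask[ids.index("inside"), 0]
        assert not mask[ids.index("at_5mb"), 0]
        assert mask[ids.index("beyond"), 0]
        assert mask[ids.index("diff_chrom"), 0]


class TestNull:
    def test_same_seed_identical(self, null_cohort):
        circ_r = qtl.residualize(null_cohort.circ_expr, null_cohort.covariates)
        mask = qtl.cis_pair_mask(null_cohort.genotypes, circ_r)
        a = qtl.build_null(circ_r, null_cohort.genotypes, mask, n_perm=20, seed=3)
        b = qtl.build_null(circ_r, null_cohort.genotypes, mask, n_perm=20, seed=3)
        np.testing.assert_array_equal(a.null_p, b.null_p)
        c = qtl.build_null(circ_r, null_cohort.genotypes, mask, n_perm=20, seed=4)
        assert not np.array_equal(a.null_p, c.null_p)

    def test_null_is_per_feature_minimum_of_scan(self, null_cohort):
        """A permutation's entries equal the per-feature min p of a scan on
        the identically permuted expression matrix (independent recompute)."""
        circ_r = qtl.residualize(null_cohort.circ_expr, null_cohort.covariates)
        mask = qtl.cis_pair_mask(null_cohort.genotypes, circ_r)
        null = qtl.build_null(circ_r, null_cohort.genotypes, mask, n_perm=3, seed=11)
        rng = np.random.default_rng(11)
        for b in range(3):
            perm = rng.permutation(len(circ_r.sample_ids))
            vals = circ_r.values.to_numpy()[:, perm]
            permuted = ExpressionMatrix(
                pd.DataFrame(
                    vals, index=circ_r.feature_ids, columns=circ_r.sample_ids
                ),
                circ_r.loci,
                circ_r.role,
            )
            scan = qtl.cis_scan(permuted, null_cohort.genotypes)
            mins = scan.groupby("feature_id")["p_nominal"].min()
            for j, f in enumerate(null.unit_ids):
                if f in mins.index:
                    assert null.null_p[b, j] == pytest.approx(mins[f], rel=1e-9)


class TestCisPower:
    def test_planted_snp_is_min_p(self):
        """Planted cis SNP (beta 0.8, maf 0.3, n=105) wins its window >=90%."""
        wins = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            pos = snp_frame(
                [(f"s{j}", "chr1", 1_000_000 + j * 1_000) for j in range(5)]
            )
            g = simulate_genotypes(105, pos, mafs=[0.3] * 5, seed=1000 + r)
            dos = g.dosages.to_numpy()
            y = 0.8 * dos[:, 0] + rng.standard_normal(105)
            circ = _expr(
                pd.DataFrame(y[None, :], index=["c1"], columns=g.sample_ids),
                [("c1", "chr1", 1_000_000, 1_002_000, "+")],
            )
            scan = qtl.cis_scan(circ, g)
            wins += scan.loc[scan["p_nominal"].idxmin(), "snp_id"] == "s0"
        assert wins / reps >= 0.90


class TestConditionalSelection:
    def test_perfect_ld_copies_collapse_to_one(self):
        rng = np.random.default_rng(12)
        base = rng.integers(0, 3, 200).astype(float)
        dosages = np.column_stack([base] * 6)
        pos = snp_frame([(f"s{j}", "chr1", 100 + j) for j in range(6)])
        g = _toy_geno(pos, dosages)
        y = 0.8 * base + rng.standard_normal(200)
        kept = qtl.conditional_selection([f"s{j}" for j in range(6)], g, y)
        assert len(kept) == 1

    def test_two_independent_signals_both_selected(self):
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(2000 + r)
            g1 = rng.binomial(2, 0.3, 500).astype(float)
            g2 = rng.binomial(2, 0.3, 500).astype(float)
            pos = snp_frame([("a", "chr1", 100), ("b", "chr1", 200)])
            g = _toy_geno(pos, np.column_stack([g1, g2]))
            y = 0.8 * g1 + 0.8 * g2 + rng.standard_normal(500)
            kept = qtl.conditional_selection(["a", "b"], g, y)
            hits += set(kept) == {"a", "b"}
        assert hits / reps >= 0.95

    def test_single_snp_returned_unchanged(self):
        rng = np.random.default_rng(13)
        base = rng.integers(0, 3, 50).astype(float)
        g = _toy_geno(snp_frame([("only", "chr1", 100)]), base[:, None])
        assert qtl.conditional_selection(["only"], g, rng.standard_normal(50)) == ["only"]

    def test_never_selects_collinear_pair(self):
        rng = np.random.default_rng(14)
        base = rng.binomial(2, 0.4, 300).astype(float)
        # second SNP nearly identical (r2 > 0.9)
        twin = base.copy()
        flip = rng.choice(300, 5, replace=False)
        twin[flip] = rng.integers(0, 3, 5)
        other = rng.binomial(2, 0.4, 300).astype(float)
        pos = snp_frame([("a", "chr1", 1), ("b", "chr1", 2), ("c", "chr1", 3)])
        g = _toy_geno(pos, np.column_stack([base, twin, other]))
        y = 0.9 * base + 0.9 * other + rng.standard_normal(300)
        kept = qtl.conditional_selection(["a", "b", "c"], g, y)
        D = g.dosages[kept].to_numpy()
        if len(kept) > 1:
            corr = np.corrcoef(D.T)
            off = corr[~np.eye(len(kept), dtype=bool)]
            assert np.all(off**2 <= 0.9)


class TestControlSnps:
    def _setup(self, seed=15):
        rng = np.random.default_rng(seed)
        cohort = simulate_cohort(
            ScenarioConfig(
                n_samples=105, n_snps=120, n_circ=1, n_genes=1,
                beta_cis=1.0, scenario="MEDIATION", seed=seed,
            )
        )
        circ_r = qtl.residualize(cohort.circ_expr, cohort.covariates)
        assoc = qtl.cis_scan(circ_r, cohort.genotypes)
        return cohort, circ_r, assoc

    def test_exact_duplicate_preferred(self):
        cohort, circ_r, assoc = self._setup()
        top = assoc.loc[[assoc["p_nominal"].idxmin()]].reset_index(drop=True)
        ctrl = qtl.select_control_snps(top, assoc, cohort.genotypes, circ_r)
        if not ctrl.empty:
            # chosen control minimizes distance difference within MAF tolerance
            assert (ctrl["d_maf"] <= 0.05).all()

    def test_no_eligible_pool_returns_empty(self):
        cohort, circ_r, assoc = self._setup()
        fake = assoc.copy()
        fake["p_nominal"] = 1e-6  # every SNP "associated": empty pool
        top = assoc.loc[[assoc["p_nominal"].idxmin()]].reset_index(drop=True)
        ctrl = qtl.select_control_snps(top, fake, cohort.genotypes, circ_r)
        assert ctrl.empty

    def test_matched_maf_close_on_null_pool(self):
        """Controls drawn from ~100 null SNPs track circQTL MAFs within 0.02."""
        cohort, circ_r, assoc = self._setup(seed=16)
        mins = assoc.groupby("snp_id")["p_nominal"].min()
        strong = assoc[assoc["p_nominal"] < 1e-4]
        if strong.empty:
            pytest.skip("no strong circQTL in this seed (unexpected)")
        tops = strong.loc[[strong["p_nominal"].idxmin()]].reset_index(drop=True)
        ctrl = qtl.select_control_snps(tops, assoc, cohort.genotypes, circ_r)
        assert not ctrl.empty
        maf = cohort.genotypes.maf
        d = abs(
            maf[ctrl["snp_id"]].to_numpy().mean()
            - maf[ctrl["control_snp_id"]].to_numpy().mean()
        )
        assert d <= 0.02
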