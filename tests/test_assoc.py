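"""Partial correlations, Fisher-z intervals, BH-FDR, and the edge-wise map."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fcedge import (
    AssocSpec,
    bh_fdr,
    fisher_ci,
    partial_correlation,
    partial_p,
    run_edgewise,
)


def precision_matrix_partial_r(x, y, cov):
    """Independent oracle: partial correlation from the inverse correlation
    matrix of [x, y, covariates]."""
    M = np.column_stack([x, y, cov])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


class TestPartialCorrelation:
    def test_exact_anticorrelation_without_covariates(self):
        assert partial_correlation([0, 1, 2, 3], [3, 2, 1, 0]) == pytest.approx(-1.0)

    def test_hand_residualization_example(self):
        r = partial_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], [[1, 1, 2, 2, 3]])
        assert r == pytest.approx(0.980, abs=5e-4)

    def test_covariate_equal_to_x_is_degenerate(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(x, x[::-1], x)

    def test_collinear_covariate_named(self, rng):
        x, y = rng.normal(size=(2, 30))
        c1 = rng.normal(size=30)
        with pytest.raises(ValueError, match="c_dup"):
            partial_correlation(
                x, y, np.column_stack([c1, 2 * c1]), covariate_names=["c1", "c_dup"]
            )

    def test_matches_precision_matrix_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(20, 60)
            k = rng.integers(1, 5)
            x, y = rng.normal(size=(2, n))
            cov = rng.normal(size=(n, k))
            assert partial_correlation(x, y, cov) == pytest.approx(
                precision_matrix_partial_r(x, y, cov), abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        n = 80
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "c1", "c2"])
        ours = partial_correlation(df.x, df.y, df[["c1", "c2"]].to_numpy())
        theirs = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        ax=st.floats(0.1, 10), bx=st.floats(-5, 5),
        ay=st.floats(0.1, 10), ac=st.floats(0.1, 10),
    )
    def test_invariant_to_affine_rescaling(self, ax, bx, ay, ac):
        rng = np.random.default_rng(99)
        x, y, c = rng.normal(size=(3, 40))
        base = partial_correlation(x, y, c)
        scaled = partial_correlation(ax * x + bx, ay * y, ac * c + 1.0)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestPartialP:
    def test_null_center_gives_p_one(self):
        assert partial_p(0.0, 50, 3) == pytest.approx(1.0)

    def test_reported_effect_is_highly_significant(self):
        # r = -.35 at n = 108 with 4 covariates
        assert partial_p(-0.35, 108, 4) < 0.001

    def test_matches_classical_pearson_test_without_covariates(self, rng):
        x, y = rng.normal(size=(2, 20))
        r, p_ref = stats.pearsonr(x, y)
        assert partial_p(r, 20, 0) == pytest.approx(p_ref, rel=1e-10)

    def test_perfect_correlation_convention(self):
        assert partial_p(1.0, 30, 2) == 0.0

    def test_fisher_method_available(self):
        p_t = partial_p(0.3, 108, 4, method="t")
        p_z = partial_p(0.3, 108, 4, method="fisher")
        assert p_t != p_z and 0 < p_z < 1


class TestFisherCI:
    @pytest.mark.parametrize(
        "r,lo,hi",
        [(-0.35, -0.51, -0.17), (-0.38, -0.53, -0.20), (-0.31, -0.47, -0.12)],
    )
    def test_reproduces_reported_intervals(self, r, lo, hi):
        """95% CI via atanh(r) +- 1.96/sqrt(n-k-3) at n=108, k=4."""
        lo_hat, hi_hat = fisher_ci(r, n=108, k=4)
        assert round(lo_hat, 2) == lo
        assert round(hi_hat, 2) == hi

    def test_symmetric_about_zero(self):
        lo, hi = fisher_ci(0.0, 50, 2)
        assert lo == pytest.approx(-hi)

    def test_contains_point_estimate(self, rng):
        for r in rng.uniform(-0.9, 0.9, 20):
            lo, hi = fisher_ci(r, 40, 3)
            assert lo < r < hi
            assert -1 < lo < hi < 1

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_ci(0.2, 7, 4)

    def test_empirical_coverage_bivariate_normal(self):
        """Nominal 95% interval covers the true correlation 93-97% of the
        time for bivariate normal samples at n = 108 (2000 replicates)."""
        rng = np.random.default_rng(2024)
        rho, n, hits = 0.4, 108, 0
        n_rep = 2000
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        for _ in range(n_rep):
            xy = rng.standard_normal((n, 2)) @ L.T
            r = np.corrcoef(xy, rowvar=False)[0, 1]
            lo, hi = fisher_ci(r, n, 0)
            hits += lo <= rho <= hi
        assert 0.93 <= hits / n_rep <= 0.97


class TestBHFDR:
    def step_up_oracle(self, p):
        """Direct step-up enumeration, independent of statsmodels."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.9])
        assert np.allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.9])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_ties_collapse(self):
        assert np.allclose(bh_fdr([0.04] * 5), [0.04] * 5)

    def test_matches_enumeration_oracle_on_random_input(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            assert np.allclose(bh_fdr(p), self.step_up_oracle(p), atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestRunEdgewise:
    def make_tables(self, rng, n=60, m=6):
        edges = pd.DataFrame(
            rng.normal(size=(n, m)),
            index=pd.Index([f"sub-{i:03d}" for i in range(n)], name="subject_id"),
            columns=[f"e{j}__f{j}" for j in range(m)],
        )
        pheno = pd.DataFrame(
            {
                "subject_id": edges.index,
                "score": rng.normal(100, 15, n),
                "mean_motion": rng.uniform(0.02, 0.2, n),
                "age": rng.normal(74, 6, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "tbv": rng.normal(1.1e6, 1e5, n),
            }
        )
        return edges, pheno

    def test_agrees_with_scalar_partial_correlation(self, rng):
        edges, pheno = self.make_tables(rng)
        spec = AssocSpec(score_name="score")
        tab = run_edgewise(edges, pheno, spec).table.set_index("edge")
        cov = pheno[list(spec.covariate_names)].to_numpy()
        for e in edges.columns:
            r_ref = partial_correlation(
                edges[e].to_numpy(), pheno["score"].to_numpy(), cov
            )
            assert tab.loc[e, "r_partial"] == pytest.approx(r_ref, abs=1e-12)

    def test_row_count_and_invariants(self, rng):
        edges, pheno = self.make_tables(rng, m=10)
        tab = run_edgewise(edges, pheno, AssocSpec(score_name="score")).table
        assert len(tab) == 10
        assert list(tab.edge) == sorted(tab.edge)
        assert np.all(tab.q >= tab.p - 1e-15)
        assert np.all((tab.ci_low < tab.r_partial) & (tab.r_partial < tab.ci_high))
        assert np.all(tab.significant == (tab.q < 0.05))

    def test_listwise_deletion_records_complete_n(self, rng):
        edges, pheno = self.make_tables(rng)
        pheno.loc[3, "score"] = np.nan
        pheno.loc[5, "tbv"] = np.nan
        res = run_edgewise(edges, pheno, AssocSpec(score_name="score"))
        assert res.n == len(edges) - 2
        assert res.table.n.unique().tolist() == [res.n]

    def test_missing_phenotype_column_rejected(self, rng):
        edges, pheno = self.make_tables(rng)
        with pytest.raises(ValueError, match="lacks columns"):
            run_edgewise(edges, pheno.drop(columns=["tbv"]),
                         AssocSpec(score_name="score"))

    def test_duplicate_covariates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            AssocSpec(score_name="s", covariate_names=("age", "age"))
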