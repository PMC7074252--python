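"""QC, Hardy-Weinberg, kinship, mixed-model and diagnostics checks.

The Hardy-Weinberg implementation is checked against an exact
rational-arithmetic enumeration oracle; the mixed model against ordinary
least squares (kinship = identity) and a dense grid-search REML oracle.
"""

import numpy as np
import pytest
from scipy import stats

from eclemap import gwas
from oracles import hwe_oracle
from eclemap.genio import (
    GenotypeMatrix,
    MarkerMap,
    ValidationError,
    make_sample_table,
)


class TestHweExactTest:
    def test_monomorphic_site_is_one(self):
        assert gwas.hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize("triple", [(3, 5, 2), (25, 50, 25), (0, 8, 0)])
    def test_matches_enumeration_oracle(self, triple):
        assert gwas.hwe_exact_test(*triple) == pytest.approx(
            hwe_oracle(*triple), rel=1e-9
        )

    def test_modal_het_count_gives_one(self):
        # (25, 50, 25): 50 hets is the modal count, so p must be exactly 1
        assert gwas.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_exhaustive_small_tables(self):
        """Every genotype triple with total <= 30 agrees with the exact
        rational enumeration."""
        for n in range(1, 31):
            for n_het in range(n + 1):
                for n_hom_alt in range(n - n_het + 1):
                    n_hom_ref = n - n_het - n_hom_alt
                    got = gwas.hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
                    want = hwe_oracle(n_hom_ref, n_het, n_hom_alt)
                    assert got == pytest.approx(want, rel=1e-8, abs=1e-12), (
                        n_hom_ref,
                        n_het,
                        n_hom_alt,
                    )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            gwas.hwe_exact_test(0, 0, 0)


class TestQcFilter:
    def test_nothing_removed_when_clean(self):
        mm = MarkerMap(
            ["a", "b"], np.array(["1", "1"], dtype=object), [100, 200]
        )
        calls = np.array(
            [[0, 0], [1, 1], [2, 2], [1, 1], [0, 2], [2, 0]], dtype=np.int8
        )
        g = GenotypeMatrix(
            [f"s{i}" for i in range(6)], mm, calls, [("A", "C")] * 2
        )
        t = make_sample_table(
            g.samples, ["B"] * 6, ["case"] * 2 + ["control"] * 4
        )
        res = gwas.qc_filter(g, t, gwas.QcConfig())
        assert res.removals == []
        assert res.genotypes.n_markers == 2

    def test_marker_call_rate_rule(self):
        # marker "a": genotyped in 8 of 10 samples (call rate 0.8)
        n, m = 10, 10
        clean = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1], dtype=np.int8)
        calls = np.tile(clean[:, None], (1, m))
        calls[8, 0] = -1
        calls[9, 0] = -1
        mm = MarkerMap(
            [("a" if j == 0 else f"b{j}") for j in range(m)],
            np.array(["1"] * m, dtype=object),
            (np.arange(m) + 1) * 100,
        )
        g = GenotypeMatrix(
            [f"s{i}" for i in range(n)], mm, calls, [("A", "C")] * m
        )
        t = make_sample_table(g.samples, ["B"] * n, ["control"] * n)
        res = gwas.qc_filter(g, t, gwas.QcConfig())
        assert {(r.identifier, r.rule) for r in res.removals} == {
            ("a", "marker-call-rate")
        }

    def test_toy_matrix_matches_hand_enumerated_removals(self, toy_matrix):
        g, t = toy_matrix
        cfg = gwas.QcConfig(hwe_p_floor_controls=0.05)
        res = gwas.qc_filter(g, t, cfg)
        assert res.removed_ids("sample-call-rate") == {"s0"}
        assert res.removed_ids("marker-call-rate") == {"mk1"}
        assert res.removed_ids("maf") == {"mk2"}
        assert res.removed_ids("hwe-controls") == {"mk3"}
        assert res.genotypes.markers.ids == ["mk0", "mk4", "mk5"] + [
            f"mk{j}" for j in range(6, 10)
        ]

    def test_idempotent(self, toy_matrix):
        g, t = toy_matrix
        cfg = gwas.QcConfig(hwe_p_floor_controls=0.05)
        first = gwas.qc_filter(g, t, cfg)
        second = gwas.qc_filter(first.genotypes, first.samples, cfg)
        assert second.removals == []
        assert second.genotypes.markers.ids == first.genotypes.markers.ids

    def test_all_samples_removed_is_explicit_failure(self):
        mm = MarkerMap(["a"], np.array(["1"], dtype=object), [100])
        g = GenotypeMatrix(
            ["s1", "s2"],
            mm,
            np.full((2, 1), -1, dtype=np.int8),
            [("A", "C")],
        )
        t = make_sample_table(["s1", "s2"], ["B", "B"], ["case", "control"])
        with pytest.raises(ValidationError):
            gwas.qc_filter(g, t, gwas.QcConfig())


def _matrix_from_calls(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    mm = MarkerMap(
        [f"m{j}" for j in range(m)],
        np.array(["1"] * m, dtype=object),
        (np.arange(m) + 1) * 1000,
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], mm, calls, [("A", "C")] * m
    )


class TestKinship:
    def test_duplicate_samples_have_ibs_one(self):
        g = _matrix_from_calls([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        k = gwas.kinship(g, "ibs")
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_have_ibs_zero(self):
        g = _matrix_from_calls([[0, 0, 0], [2, 2, 2]])
        k = gwas.kinship(g, "ibs")
        assert k.values[0, 1] == pytest.approx(0.0)

    def test_centered_grm_matches_hand_computation(self):
        calls = np.array(
            [[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0], [1, 2, 1, 1]],
            dtype=np.int8,
        )
        g = _matrix_from_calls(calls)
        k = gwas.kinship(g, "centered-grm")
        # independent elementwise computation
        x = calls.astype(float)
        p = x.mean(axis=0) / 2
        denom = sum(2 * pj * (1 - pj) for pj in p)
        expect = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expect[i, j] = (
                    sum(
                        (x[i, m] - 2 * p[m]) * (x[j, m] - 2 * p[m])
                        for m in range(4)
                    )
                    / denom
                )
        np.testing.assert_allclose(k.values, expect, atol=1e-12)

    def test_disjoint_missingness_is_an_error_for_ibs(self):
        g = _matrix_from_calls([[0, -1], [-1, 2]])
        with pytest.raises(ValidationError, match="no called markers"):
            gwas.kinship(g, "ibs")


class TestLmmScan:
    def test_identity_kinship_equals_ols(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        n, m = 25, 40
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g = _matrix_from_calls(calls)
        y = (rng.random(n) < 0.4).astype(float)
        K = gwas.KinshipMatrix(np.eye(n), g.samples, "ibs")
        res = gwas.lmm_scan(g, y, K)
        for j in range(m):
            if res["monomorphic"][j]:
                continue
            X = statsmodels.add_constant(calls[:, j].astype(float))
            ols = statsmodels.OLS(y, X).fit()
            assert res["p_value"][j] == pytest.approx(
                ols.pvalues[1], abs=1e-8
            )

    def test_scale_invariance_of_identity_case(self):
        rng = np.random.default_rng(8)
        n, m = 20, 10
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g = _matrix_from_calls(calls)
        y = rng.normal(size=n)
        p1 = gwas.lmm_scan(
            g, y, gwas.KinshipMatrix(np.eye(n), g.samples, "ibs")
        )["p_value"]
        p2 = gwas.lmm_scan(
            g, y, gwas.KinshipMatrix(3.7 * np.eye(n), g.samples, "ibs")
        )["p_value"]
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_reml_delta_matches_grid_search_oracle(self):
        """8-sample block-structured kinship: the 1-D REML optimum must land
        within one step of a 10^4-point log-spaced grid search."""
        rng = np.random.default_rng(11)
        n = 8
        block = np.kron(np.eye(2), np.ones((4, 4)))
        K = 0.6 * block + 0.4 * np.eye(n)
        x = rng.integers(0, 3, size=n).astype(float)
        u = rng.multivariate_normal(np.zeros(n), K)
        y = 0.4 * x + u + 0.8 * rng.normal(size=n)
        dhat = gwas.reml_delta(y, x, K)
        grid = np.logspace(-5, 5, 10_000)
        s, U = np.linalg.eigh(K)
        yr, x1r = U.T @ y, U.T @ np.ones(n)
        xr = (U.T @ x).reshape(-1, 1)
        crit, *_ = gwas._reml_profile(yr, x1r, xr, s, grid)
        best = grid[int(np.argmin(crit[:, 0]))]
        step = 10 / (10_000 - 1)  # log10 spacing
        assert abs(np.log10(dhat) - np.log10(best)) <= step

    def test_non_psd_kinship_reports_smallest_eigenvalue(self):
        g = _matrix_from_calls([[0, 1], [1, 2], [2, 0]])
        bad = np.array(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 2.0], [0.0, 2.0, 1.0]]
        )
        with pytest.raises(ValidationError, match="eigenvalue"):
            gwas.lmm_scan(
                g,
                np.array([0.0, 1.0, 0.0]),
                gwas.KinshipMatrix(bad, g.samples, "ibs"),
            )

    def test_null_pvalues_are_uniform(self):
        """Permuted exchangeable (Gaussian) phenotype on 2,000 markers:
        Kolmogorov-Smirnov uniformity at alpha = 0.01 (a binary outcome
        leaves even exact OLS mildly off the F reference at n = 43)."""
        rng = np.random.default_rng(12)
        n, m = 43, 2000
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g = _matrix_from_calls(calls)
        y = rng.normal(size=n)
        rng.shuffle(y)
        A = rng.random((n, 20))
        K = gwas.KinshipMatrix(
            A @ A.T / 20 + 0.5 * np.eye(n), g.samples, "ibs"
        )
        res = gwas.lmm_scan(g, y, K)
        p = res.loc[~res["monomorphic"], "p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestAllelicChisq:
    def test_equal_counts_give_zero_statistic(self):
        g = _matrix_from_calls([[0, 1], [2, 1], [0, 1], [2, 1]])
        y = np.array([1, 1, 0, 0])
        res = gwas.allelic_chisq_scan(g, y)
        assert res["statistic"][0] == pytest.approx(0.0)
        assert res["p_value"][0] == pytest.approx(1.0)

    def test_known_counts_match_closed_form(self):
        # case A=30,a=10; control A=10,a=30 -> chi2 = 80*(900-100)^2 / (40*40*40*40)
        calls = np.array([[2]] * 15 + [[1]] * 0 + [[0]] * 5, dtype=np.int8)
        calls = np.vstack([calls, np.array([[0]] * 15 + [[2]] * 5)])
        g = _matrix_from_calls(calls)
        y = np.array([1] * 20 + [0] * 20)
        res = gwas.allelic_chisq_scan(g, y)
        expect = 80 * (30 * 30 - 10 * 10) ** 2 / (40 * 40 * 40 * 40)
        assert res["statistic"][0] == pytest.approx(expect)
        assert res["p_value"][0] == pytest.approx(
            stats.chi2.sf(expect, 1)
        )

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(5)
        g = _matrix_from_calls(rng.integers(0, 3, size=(12, 8)))
        y = (rng.random(12) < 0.5).astype(int)
        a = gwas.allelic_chisq_scan(g, y)["statistic"]
        b = gwas.allelic_chisq_scan(g, 1 - y)["statistic"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_monomorphic_marker_flagged_with_p_one(self):
        g = _matrix_from_calls([[0], [0], [0], [0]])
        res = gwas.allelic_chisq_scan(g, np.array([1, 1, 0, 0]))
        assert bool(res["monomorphic"][0])
        assert res["p_value"][0] == 1.0


class TestInflationAndThresholds:
    def test_all_half_pvalues_give_lambda_one(self):
        assert gwas.genomic_inflation(np.full(100, 0.5)) == pytest.approx(
            1.0
        )

    def test_uniform_pvalues_give_lambda_near_one(self):
        rng = np.random.default_rng(1)
        lam = gwas.genomic_inflation(rng.random(10_000))
        assert 0.95 < lam < 1.05

    def test_halving_statistics_halves_lambda(self):
        chi = stats.chi2.rvs(1, size=1000, random_state=3)
        p_full = stats.chi2.sf(chi, 1)
        p_half = stats.chi2.sf(chi / 2, 1)
        lam_full = gwas.genomic_inflation(p_full)
        lam_half = gwas.genomic_inflation(p_half)
        assert lam_half == pytest.approx(lam_full / 2, rel=1e-9)

    def test_bonferroni_reproduces_study_scale_threshold(self):
        suggestive, bonf = gwas.significance_thresholds(116_891)
        assert f"{bonf:.1e}" == "4.3e-07"
        assert suggestive == 5e-5

    @pytest.mark.parametrize(
        "n,alpha,expect", [(1, 0.05, 0.05), (100, 0.05, 5e-4)]
    )
    def test_bonferroni_division(self, n, alpha, expect):
        assert gwas.significance_thresholds(n, alpha=alpha)[
            1
        ] == pytest.approx(expect)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            gwas.genomic_inflation(np.array([]))
        with pytest.raises(ValidationError):
            gwas.significance_thresholds(0)


class TestClassicalMds:
    def test_equilateral_embedding(self):
        d = 1 - np.eye(3) * 0.6 - 0.4 * np.eye(3)  # off-diag 1, diag 0
        coords = gwas.classical_mds(d, n_dims=2, is_distance=True)
        dists = [
            np.linalg.norm(coords[i] - coords[j])
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert max(dists) - min(dists) < 1e-8

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords = gwas.classical_mds(d, n_dims=2, is_distance=True)
        d2 = np.linalg.norm(
            coords[:, None, :] - coords[None, :, :], axis=2
        )
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_pairwise_distances_invariant_to_sign_flips(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords = gwas.classical_mds(d, n_dims=2, is_distance=True)
        flipped = coords * np.array([-1.0, 1.0])
        d1 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        d2 = np.linalg.norm(flipped[:, None] - flipped[None, :], axis=2)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            gwas.classical_mds(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestHweProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_exact_test_matches_oracle_and_is_symmetric(self, hr, het, ha):
        """p in (0, 1], invariant under swapping the homozygote labels, and
        equal to the rational-enumeration oracle."""
        if hr + het + ha == 0:
            return
        p = gwas.hwe_exact_test(hr, het, ha)
        assert 0 < p <= 1
        assert gwas.hwe_exact_test(ha, het, hr) == pytest.approx(p, rel=1e-9)
        assert p == pytest.approx(hwe_oracle(hr, het, ha), rel=1e-8, abs=1e-12)
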