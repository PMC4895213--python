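"""Unit and property tests for the correlation-influence computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depna.core import (
    CorrelationMatrix,
    SingularTripleError,
    compute_correlations,
    compute_dependency_matrix,
    compute_influence_tensor,
    correlation_influence,
    depna,
    influenced_degree,
    influencing_degree,
    partial_correlation,
)
from depna.timeseries import NodeTimeSeries


def brute_pearson(x, y):
    """Element-by-element evaluation of the Pearson formula."""
    mx, my = x.mean(), y.mean()
    sx = np.sqrt(((x - mx) ** 2).mean())
    sy = np.sqrt(((y - my) ** 2).mean())
    return ((x - mx) * (y - my)).mean() / (sx * sy)


def residual_partial_corr(x, i, k, j):
    """Correlate the residuals of i and k after regression on j."""
    zj = x[j] - x[j].mean()
    res = []
    for a in (i, k):
        za = x[a] - x[a].mean()
        res.append(za - (za @ zj) / (zj @ zj) * zj)
    return np.corrcoef(res[0], res[1])[0, 1]


def corr_from_offdiag(c01, c02, c12):
    return CorrelationMatrix(
        ["a", "b", "c"],
        np.array([[1, c01, c02], [c01, 1, c12], [c02, c12, 1.0]]),
    )


class TestCorrelations:
    def test_perfect_correlation_and_anticorrelation(self):
        ts = NodeTimeSeries(
            ["x", "x2", "y"],
            np.array([[1.0, 2, 3], [2, 4, 6], [3, 2, 1]]),
        )
        C = compute_correlations(ts).values
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(C), 1.0)

    def test_matches_brute_force_formula(self):
        samples = np.array(
            [
                [0.2, 1.5, -0.7, 0.9, 2.1, -1.3],
                [1.1, 0.3, 0.8, -0.4, 1.7, 0.5],
                [-0.6, 2.2, 0.1, 1.4, -0.9, 0.7],
            ]
        )
        ts = NodeTimeSeries(["a", "b", "c"], samples)
        C = compute_correlations(ts).values
        for i in range(3):
            for k in range(3):
                expected = brute_pearson(samples[i], samples[k])
                assert C[i, k] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_node_named(self):
        ts = NodeTimeSeries(
            ["a", "flat", "c"],
            np.vstack(
                [np.arange(5.0), np.ones(5), np.arange(5.0) ** 2]
            ),
            require_variance=False,
        )
        with pytest.raises(ValueError, match="flat"):
            compute_correlations(ts)


class TestPartialCorrelation:
    def test_uncorrelated_conditioner_changes_nothing(self):
        C = corr_from_offdiag(0.5, 0.0, 0.0)
        assert partial_correlation(C, 0, 1, 2) == pytest.approx(0.5)

    def test_textbook_value(self):
        # (0.8 - 0.36) / sqrt(0.64 * 0.64)
        C = corr_from_offdiag(0.8, 0.6, 0.6)
        assert partial_correlation(C, 0, 1, 2) == pytest.approx(0.6875)

    def test_symmetric_in_first_two_arguments(self):
        C = corr_from_offdiag(0.3, -0.5, 0.7)
        assert partial_correlation(C, 0, 1, 2) == partial_correlation(C, 1, 0, 2)

    def test_repeated_index_rejected(self):
        C = corr_from_offdiag(0.3, 0.2, 0.1)
        with pytest.raises(ValueError, match="distinct"):
            partial_correlation(C, 0, 0, 2)

    def test_singular_triple_raises(self):
        C = corr_from_offdiag(0.3, 1.0, 0.2)
        with pytest.raises(SingularTripleError):
            partial_correlation(C, 0, 1, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((5, 200))
        ts = NodeTimeSeries([f"n{i}" for i in range(5)], x)
        C = compute_correlations(ts)
        for i, k, j in [(0, 1, 2), (3, 4, 0), (2, 0, 4), (1, 3, 2)]:
            assert partial_correlation(C, i, k, j) == pytest.approx(
                residual_partial_corr(x, i, k, j), abs=1e-10
            )


class TestCorrelationInfluence:
    def test_no_shared_dependence_gives_zero(self):
        C = corr_from_offdiag(0.5, 0.0, 0.0)
        assert correlation_influence(C, 0, 1, 2) == pytest.approx(0.0)

    def test_partial_share_of_correlation(self):
        C = corr_from_offdiag(0.8, 0.6, 0.6)
        assert correlation_influence(C, 0, 1, 2) == pytest.approx(0.1125)

    def test_fully_explained_correlation(self):
        # C(i,k) = C(i,j) * C(k,j): conditioning removes everything
        C = corr_from_offdiag(0.81, 0.9, 0.9)
        assert correlation_influence(C, 0, 1, 2) == pytest.approx(0.81)


class TestDependencyMatrix:
    def test_identity_correlation_gives_zero(self):
        C = CorrelationMatrix(list("abcd"), np.eye(4))
        D = compute_dependency_matrix(C)
        assert np.all(D.values == 0.0)

    def test_three_nodes_single_term(self):
        C = corr_from_offdiag(0.5, 0.3, -0.2)
        D = compute_dependency_matrix(C, negative_mode="signed")
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                k = 3 - i - j
                expected = correlation_influence(C, i, k, j)
                assert D.values[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", ["clip_to_zero", "absolute", "signed"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_triple_enumeration(
        self, gaussian_panel_factory, mode, seed
    ):
        ts = gaussian_panel_factory(n_nodes=6, seed=seed)
        C = compute_correlations(ts)
        D = compute_dependency_matrix(C, negative_mode=mode)
        n = 6
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                terms = []
                for k in range(n):
                    if k in (i, j):
                        continue
                    d = correlation_influence(C, i, k, j)
                    if mode == "clip_to_zero":
                        d = max(d, 0.0)
                    elif mode == "absolute":
                        d = abs(d)
                    terms.append(d)
                assert D.values[i, j] == pytest.approx(
                    np.mean(terms), abs=1e-12
                )

    def test_negative_triple_contributes_zero_under_clipping(self):
        # opposite-sign loadings on the conditioner: d(0,1|2) < 0
        C = corr_from_offdiag(0.0, 0.6, -0.6)
        assert correlation_influence(C, 0, 1, 2) < 0
        D = compute_dependency_matrix(C, negative_mode="clip_to_zero")
        assert D.values[0, 2] == 0.0

    def test_divisor_conventions_scale_result(self, gaussian_panel_factory):
        C = compute_correlations(gaussian_panel_factory(n_nodes=5))
        d2 = compute_dependency_matrix(C, divisor="n_minus_2").values
        dn = compute_dependency_matrix(C, divisor="n").values
        assert np.allclose(dn * 5, d2 * 3, atol=1e-12)

    def test_singular_triple_identified(self):
        x = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 1,
                       np.random.default_rng(0).standard_normal(6),
                       np.random.default_rng(1).standard_normal(6)])
        ts = NodeTimeSeries(list("abcd"), x)
        C = compute_correlations(ts)
        with pytest.raises(SingularTripleError):
            compute_dependency_matrix(C)


class TestDegrees:
    def test_zero_matrix_gives_zero_degrees(self):
        C = CorrelationMatrix(list("abc"), np.eye(3))
        D = compute_dependency_matrix(C)
        assert np.all(influencing_degree(D) == 0)
        assert np.all(influenced_degree(D) == 0)

    def test_conservation(self, gaussian_panel_factory):
        for seed in range(5):
            ts = gaussian_panel_factory(seed=seed)
            _, D, prof = depna(ts)
            total = D.values.sum()
            assert prof.influencing.sum() == pytest.approx(total, abs=1e-10)
            assert prof.influenced.sum() == pytest.approx(total, abs=1e-10)

    def test_influenced_is_influencing_of_transpose(
        self, gaussian_panel_factory
    ):
        from depna.core import DependencyMatrix

        _, D, _ = depna(gaussian_panel_factory())
        Dt = DependencyMatrix(D.node_ids, D.values.T, D.negative_mode)
        assert np.array_equal(influenced_degree(D), influencing_degree(Dt))


class TestPipeline:
    def test_deterministic(self, gaussian_panel_factory):
        ts = gaussian_panel_factory()
        r1 = depna(ts)
        r2 = depna(ts)
        assert np.array_equal(r1.dependency.values, r2.dependency.values)

    def test_permutation_equivariance(self, gaussian_panel_factory):
        ts = gaussian_panel_factory(n_nodes=5, seed=3)
        perm = [3, 0, 4, 1, 2]
        permuted = ts.reorder([ts.node_ids[p] for p in perm])
        D = depna(ts).dependency.values
        Dp = depna(permuted).dependency.values
        assert np.array_equal(Dp, D[np.ix_(perm, perm)])

    def test_null_degrees_small_at_long_t(self):
        # Monte-Carlo null at N=4, T=1000: degrees stay below 0.15
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ts = NodeTimeSeries(list("abcd"), rng.standard_normal((4, 1000)))
            _, _, prof = depna(ts)
            assert prof.influencing.max() < 0.15
            assert prof.influenced.max() < 0.15

    def test_null_degrees_shrink_with_timepoints(self):
        medians = {}
        for T in (100, 2000):
            vals = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                ts = NodeTimeSeries(
                    list("abcd"), rng.standard_normal((4, T))
                )
                _, _, prof = depna(ts)
                vals.append(np.median(prof.influencing))
            medians[T] = np.median(vals)
        assert medians[2000] < medians[100]


class TestInfluenceTensor:
    def test_symmetric_in_pair_and_masked(self, gaussian_panel_factory):
        C = compute_correlations(gaussian_panel_factory(n_nodes=5))
        tensor = compute_influence_tensor(C)
        v, m = tensor.values, tensor.valid_mask
        assert np.allclose(
            v.transpose(1, 0, 2), v, atol=1e-12
        )  # d(i,k|j) = d(k,i|j)
        idx = np.indices(m.shape)
        degenerate = (
            (idx[0] == idx[1]) | (idx[0] == idx[2]) | (idx[1] == idx[2])
        )
        assert not m[degenerate].any()
        assert np.all(v[degenerate] == 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    n_nodes=st.integers(3, 7),
    n_time=st.integers(30, 120),
)
def test_invariants_on_random_panels(seed, n_nodes, n_time):
    """Conservation, nonnegativity and zero diagonal on arbitrary panels."""
    rng = np.random.default_rng(seed)
    ts = NodeTimeSeries(
        [f"n{i}" for i in range(n_nodes)],
        rng.standard_normal((n_nodes, n_time)),
    )
    _, D, prof = depna(ts)
    assert np.all(D.values >= 0)
    assert np.all(np.diag(D.values) == 0)
    assert prof.influencing.sum() == pytest.approx(
        D.values.sum(), abs=1e-10
    )
    assert prof.influenced.sum() == pytest.approx(D.values.sum(), abs=1e-10)
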