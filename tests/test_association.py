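"""Pearson screens, bipartite networks, distances and Mantel tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domchemodiv.association import (
    _pairwise_pearson,
    build_network,
    distance_matrix,
    mantel,
    partial_mantel,
    pearson_with_p,
)
from domchemodiv.errors import SampleMismatchError, ValidationError, ZeroVarianceError


def _frame(arr, prefix):
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_t_closed_form_r09_n15(self):
        """r = 0.9, n = 15: t = r sqrt(n-2)/sqrt(1-r^2) = 7.44453,
        two-sided p = 4.87e-6 on 13 df."""
        t = 0.9 * np.sqrt(13) / np.sqrt(1 - 0.81)
        assert t == pytest.approx(7.444531726816601, abs=1e-9)
        p = 2 * stats.t.sf(t, 13)
        assert p == pytest.approx(4.87197094873557e-06, rel=1e-6)
        # an actual sample with r == 0.9 reproduces this p through the API
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        e = rng.normal(size=15)
        e -= e.mean() + (e - e.mean()) @ (x - x.mean()) / ((x - x.mean()) ** 2).sum() * 0
        # construct y with empirical correlation exactly 0.9
        xs = (x - x.mean()) / x.std()
        es = e - e.mean()
        es -= (es @ xs) / (xs @ xs) * xs
        es /= es.std()
        y = 0.9 * xs + np.sqrt(1 - 0.81) * es
        r, pv = pearson_with_p(x, y)
        assert r == pytest.approx(0.9, abs=1e-12)
        assert pv == pytest.approx(4.87197094873557e-06, rel=1e-6)

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_with_p(np.ones(10), np.arange(10.0))

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1, 2, 3], [1, 2, 3])

    def test_pairwise_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 12))
        y = rng.normal(size=(5, 12))
        r, p = _pairwise_pearson(x, y)
        for i in range(6):
            for j in range(5):
                r_ref, p_ref = stats.pearsonr(x[i], y[j])
                assert r[i, j] == pytest.approx(r_ref, abs=1e-12)
                assert p[i, j] == pytest.approx(p_ref, rel=1e-9)


class TestNetwork:
    def test_sample_mismatch_listed(self):
        dom = _frame(np.random.default_rng(0).normal(size=(3, 5)), "d")
        otu = dom.copy()
        otu.columns = ["s0", "s1", "s2", "s3", "zz"]
        with pytest.raises(SampleMismatchError, match="zz"):
            build_network(dom, otu, 3, 3, 0.05)

    def test_edge_invariance_to_sample_order_and_scale(self):
        rng = np.random.default_rng(2)
        dom = _frame(rng.lognormal(size=(8, 10)), "d")
        otu = _frame(rng.lognormal(size=(8, 10)), "o")
        net = build_network(dom, otu, 8, 8, 0.2)
        perm = ["s3", "s1", "s7", "s0", "s2", "s9", "s8", "s5", "s4", "s6"]
        net_perm = build_network(dom[perm], otu[perm], 8, 8, 0.2)
        net_scaled = build_network(dom * 7.3, otu * 0.2, 8, 8, 0.2)
        key = lambda n: set(zip(n.edges.dom_id, n.edges.otu_id))
        assert key(net) == key(net_perm) == key(net_scaled)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        dom = _frame(rng.normal(size=(10, 8)), "d")
        otu = _frame(rng.normal(size=(10, 8)), "o")
        n_loose = len(build_network(dom, otu, 10, 10, 0.10).edges)
        n_tight = len(build_network(dom, otu, 10, 10, 0.01).edges)
        assert n_tight <= n_loose

    def test_fdr_never_adds_edges(self):
        rng = np.random.default_rng(4)
        dom = _frame(rng.normal(size=(10, 8)), "d")
        otu = _frame(rng.normal(size=(10, 8)), "o")
        raw = build_network(dom, otu, 10, 10, 0.05)
        adj = build_network(dom, otu, 10, 10, 0.05, fdr=True)
        raw_pairs = set(zip(raw.edges.dom_id, raw.edges.otu_id))
        adj_pairs = set(zip(adj.edges.dom_id, adj.edges.otu_id))
        assert adj_pairs <= raw_pairs

    def test_edge_signs_and_summary(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=10)
        dom = _frame(np.vstack([base, rng.normal(size=10)]), "d")
        otu = _frame(np.vstack([base + rng.normal(scale=0.05, size=10),
                                -base + rng.normal(scale=0.05, size=10)]), "o")
        net = build_network(dom, otu, 2, 2, 0.001)
        assert (net.edges.p < 0.001).all()
        for row in net.edges.itertuples():
            assert row.sign == ("positive" if row.r > 0 else "negative")
        s = net.summary
        assert s["pairs_tested"] == 4
        assert s["n_edges"] == len(net.edges)

    def test_zero_variance_feature_skipped(self):
        rng = np.random.default_rng(6)
        dom = _frame(np.vstack([np.ones(8), rng.normal(size=8)]), "d")
        otu = _frame(rng.normal(size=(2, 8)), "o")
        net = build_network(dom, otu, 2, 2, 0.9)
        assert "d0" not in set(net.edges.dom_id)


class TestDistances:
    def test_identical_samples_zero(self):
        m = _frame(np.tile([[1.0], [2.0]], (1, 3)), "f")
        d = distance_matrix(m, "bray_curtis")
        assert np.allclose(d, 0)

    def test_bray_curtis_disjoint(self):
        m = _frame(np.array([[1.0, 0.0], [0.0, 1.0]]), "f")
        d = distance_matrix(m, "bray_curtis")
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_euclidean_zscore_two_samples(self):
        m = _frame(np.array([[3.0, 5.0]]), "f")  # z-scores (-1, 1)
        d = distance_matrix(m, "euclidean")
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(7)
        m = _frame(rng.lognormal(size=(6, 5)), "f")
        d = distance_matrix(m, "bray_curtis").to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_unknown_metric(self):
        with pytest.raises(ValidationError):
            distance_matrix(_frame(np.ones((2, 3)), "f"), "manhattan")


def _fixture_distances():
    """The deterministic trio used for the external-reference check."""
    rng = np.random.default_rng(2024)
    base = rng.normal(size=(5, 8))
    x = base + rng.normal(scale=0.5, size=(5, 8))
    y = base + rng.normal(scale=0.5, size=(5, 8))
    z = rng.normal(size=(5, 8))
    cols = [f"s{i}" for i in range(8)]
    return (
        distance_matrix(pd.DataFrame(x, columns=cols), "euclidean"),
        distance_matrix(pd.DataFrame(y, columns=cols), "euclidean"),
        distance_matrix(pd.DataFrame(z, columns=cols), "euclidean"),
    )


class TestMantel:
    def test_identity_gives_r_one_minimal_p(self):
        dx, _, _ = _fixture_distances()
        res = mantel(dx, dx, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_matches_external_references(self):
        """r frozen from two independent implementations on the same
        fixture: R vegan mantel/mantel.partial and skbio mantel
        (both report r = 0.4389961878; vegan partial r = 0.4390588223)."""
        dx, dy, dz = _fixture_distances()
        assert mantel(dx, dy, n_perm=9, seed=0).r == pytest.approx(0.4389961878, abs=1e-9)
        assert partial_mantel(dx, dy, dz, n_perm=9, seed=0).r == pytest.approx(
            0.4390588223, abs=1e-9
        )

    def test_skbio_agreement_on_random_matrices(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(8)
        for _ in range(5):
            a = distance_matrix(_frame(rng.normal(size=(4, 7)), "f"), "euclidean")
            b = distance_matrix(_frame(rng.normal(size=(4, 7)), "f"), "euclidean")
            ids = list(a.columns)
            r_ref = sk_mantel(
                DistanceMatrix(a.to_numpy(), ids=ids),
                DistanceMatrix(b.to_numpy(), ids=ids),
                method="pearson",
                permutations=0,
            )[0]
            assert mantel(a, b, n_perm=9, seed=0).r == pytest.approx(r_ref, abs=1e-10)

    def test_seeded_reproducibility(self):
        dx, dy, _ = _fixture_distances()
        a = mantel(dx, dy, n_perm=199, seed=11)
        b = mantel(dx, dy, n_perm=199, seed=11)
        assert (a.r, a.p) == (b.r, b.p)

    def test_asymmetric_input_rejected(self):
        bad = np.arange(16.0).reshape(4, 4)
        good = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            mantel(bad, good)

    def test_p_never_zero(self):
        dx, dy, _ = _fixture_distances()
        res = mantel(dx, dy, n_perm=99, seed=1)
        assert res.p >= 1 / 100

    def test_partial_with_control_equal_to_second_matrix(self):
        dx, dy, _ = _fixture_distances()
        res = partial_mantel(dx, dy, dy, n_perm=49, seed=0)
        assert abs(res.r) < 1e-12

    def test_partial_reduces_to_plain_when_control_uncorrelated(self):
        # residualizing on an independent matrix moves r only slightly
        dx, dy, dz = _fixture_distances()
        plain = mantel(dx, dy, n_perm=9, seed=0).r
        part = partial_mantel(dx, dy, dz, n_perm=9, seed=0).r
        assert part == pytest.approx(plain, abs=0.05)
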