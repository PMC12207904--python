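import numpy as np
import pandas as pd
import pytest

from domstat import PeakTable, idme, sample_kk_dk, sparcc, threshold_network
from domstat.darknet import clr_pearson


def _lognormal_pool(p, n, seed):
    rng = np.random.default_rng(seed)
    X = np.exp(rng.normal(0, 1, size=(p, n)))
    return pd.DataFrame(X, index=[f"c{i}" for i in range(p)],
                        columns=[f"s{j}" for j in range(n)])


@pytest.fixture(scope="module")
def planted_pair():
    """50 independent components plus one pair in a nearly fixed ratio."""
    rng = np.random.default_rng(3)
    n = 200
    base = np.exp(rng.normal(0, 1.0, size=(50, n)))
    shared = rng.normal(0, 1.0, size=n)
    a = np.exp(shared + rng.normal(0, 0.3, size=n))
    b = np.exp(shared + rng.normal(0, 0.3, size=n))
    X = np.vstack([a, b, base])
    ids = ["pair_a", "pair_b"] + [f"c{i}" for i in range(50)]
    return pd.DataFrame(X, index=ids, columns=[f"s{j}" for j in range(n)])


class TestSparcc:
    def test_planted_correlation_recovered(self, planted_pair):
        rho = sparcc(planted_pair)
        assert rho.loc["pair_a", "pair_b"] > 0.5

    def test_null_correlations_small(self):
        rho = sparcc(_lognormal_pool(50, 200, seed=4))
        off = rho.to_numpy()[~np.eye(50, dtype=bool)]
        assert np.abs(off).max() < 0.35

    def test_sample_order_invariance(self, planted_pair):
        shuffled = planted_pair[planted_pair.columns[::-1]]
        r1 = sparcc(planted_pair)
        r2 = sparcc(shuffled)
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_sign_agrees_with_clr_pearson(self, planted_pair):
        r_sparcc = sparcc(planted_pair).loc["pair_a", "pair_b"]
        r_clr = clr_pearson(planted_pair).loc["pair_a", "pair_b"]
        assert np.sign(r_sparcc) == np.sign(r_clr)
        assert r_clr > 0.5

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4 components"):
            sparcc(_lognormal_pool(3, 20, 0))
        with pytest.raises(ValueError, match="8 samples"):
            sparcc(_lognormal_pool(10, 5, 0))
        bad = _lognormal_pool(5, 20, 0)
        bad.iloc[0] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            sparcc(bad)

    def test_diagonal_is_one(self, planted_pair):
        rho = sparcc(planted_pair)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)
        assert np.abs(rho.to_numpy()).max() <= 1.0 + 1e-12


class TestThreshold:
    def _corr(self, vals):
        ids = [f"n{i}" for i in range(len(vals))]
        m = np.array(vals, dtype=float)
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_negative_rho_kept_by_absolute_value(self):
        corr = self._corr([[1.0, -0.45], [-0.45, 1.0]])
        net = threshold_network(corr, rho_min=0.30)
        assert net.adjacency.iloc[0, 1]

    def test_weak_edges_dropped(self):
        corr = self._corr([[1.0, 0.1, -0.2], [0.1, 1.0, 0.05], [-0.2, 0.05, 1.0]])
        net = threshold_network(corr, rho_min=0.30)
        assert net.adjacency.to_numpy().sum() == 0
        assert len(net.adjacency) == 3  # isolated nodes retained

    def test_zero_threshold_complete_graph(self):
        corr = self._corr([[1.0, 0.01, 0.2], [0.01, 1.0, -0.3], [0.2, -0.3, 1.0]])
        net = threshold_network(corr, rho_min=0.0)
        assert net.adjacency.to_numpy().sum() == 6  # 3 undirected edges

    def test_mean_degree_matches_networkx(self, planted_pair):
        net = threshold_network(sparcc(planted_pair), rho_min=0.2)
        g = net.graph()
        assert net.mean_degree() == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes())


class TestSampling:
    def test_half_replacement_of_ten(self):
        kk, dk = sample_kk_dk([f"k{i}" for i in range(20)],
                              [f"d{i}" for i in range(20)],
                              n_nodes=10, dark_ratio="half", rng=0)
        assert len(kk) == len(dk) == 10
        dark = [n for n in dk if n.startswith("d")]
        known = [n for n in dk if n.startswith("k")]
        assert len(dark) == 5 and len(known) == 5
        assert set(known) <= set(kk)  # paired replacement

    def test_observed_ratio_arithmetic(self):
        known = [f"k{i}" for i in range(6000)]
        dark = [f"d{i}" for i in range(6000)]
        _, dk = sample_kk_dk(known[:5474] , dark[:5779], n_nodes=400,
                             dark_ratio="observed", rng=1)
        n_dark = sum(1 for n in dk if n.startswith("d"))
        assert n_dark == round(400 * 5779 / (5779 + 5474))  # = 205

    def test_insufficient_pool(self):
        with pytest.raises(ValueError, match="pool too small"):
            sample_kk_dk(["k1"], ["d1"], n_nodes=10)


@pytest.fixture(scope="module")
def pools(study):
    return study["peaks"], study["dark"]


class TestIdme:
    def test_partition_sums_to_total(self, pools):
        known, dark = pools
        res = idme(known, dark, n_nodes=80, n_replicates=10, seed=0)
        assert res.idme_intra + res.idme_inter + res.idme_kk_change == \
            pytest.approx(res.idme, abs=1e-9)

    def test_independent_dark_reduces_connectivity(self, pools):
        known, dark = pools
        res = idme(known, dark, n_nodes=80, n_replicates=10, seed=0)
        assert res.idme < 0

    def test_seeded_determinism(self, pools):
        known, dark = pools
        r1 = idme(known, dark, n_nodes=60, n_replicates=5, seed=3)
        r2 = idme(known, dark, n_nodes=60, n_replicates=5, seed=3)
        assert r1.as_dict() == r2.as_dict()

    def test_ratio_arithmetic(self, pools):
        known, dark = pools
        res = idme(known, dark, n_nodes=60, n_replicates=5, seed=1)
        assert res.idme == pytest.approx((res.m_dk / res.m_kk - 1) * 100)

    def test_degree_is_2e_over_n(self, pools):
        known, dark = pools
        res = idme(known, dark, n_nodes=50, n_replicates=3, seed=2)
        # every replicate row stores 2E/N values; they must be nonnegative
        # multiples of 2/N
        vals = res.replicates["m_kk"].to_numpy() * 50 / 2
        assert np.allclose(vals, np.round(vals))


def test_idme_per_sample_restricts_pools(study):
    from domstat.darknet import idme_per_sample
    out = idme_per_sample(study["peaks"], study["dark"],
                          metadata=study["metadata"],
                          n_nodes=30, n_replicates=2, seed=0)
    assert len(out) == 36
    assert {"idme", "idme_intra", "idme_inter", "idme_kk_change"} <= set(out.columns)
    resid = (out["idme_intra"] + out["idme_inter"] + out["idme_kk_change"]
             - out["idme"]).abs()
    assert (resid < 1e-9).all()
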