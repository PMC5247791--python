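"""Local partial correlation: neighborhoods, cap, inversion, network."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_dataset
from dcnet.lpc import (
    build_lpc_network,
    cap_neighborhood,
    local_partial_corr,
    neighborhood,
)
from dcnet.networks import build_network, pearson_with_p


def first_order_partial(r_ac, r_ab, r_bc):
    """Closed-form partial correlation of (A, C) given B."""
    return (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))


class TestNeighborhood:
    def test_two_hop_genes_excluded(self):
        """Genes correlated only with the neighbors stay out of the sub-matrix."""
        g = nx.Graph()
        g.add_edge("X2", "X5")
        for nbr in ("X3", "X6"):
            g.add_edge("X2", nbr)
        for nbr in ("X8", "X9"):
            g.add_edge("X5", nbr)
        # second shell: correlated with neighbors but with neither pair member
        g.add_edge("X3", "X1")
        g.add_edge("X6", "X4")
        g.add_edge("X9", "X7")
        assert neighborhood(g, ("X2", "X5")) == {"X3", "X6", "X8", "X9"}

    def test_isolated_pair(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        assert neighborhood(g, ("a", "b")) == set()

    def test_star_centered_on_pair_member(self):
        g = nx.Graph()
        leaves = {f"l{i}" for i in range(5)}
        for leaf in leaves:
            g.add_edge("hub", leaf)
        assert neighborhood(g, ("hub", "l0")) == leaves - {"l0"}


class TestCapNeighborhood:
    def corr_map(self, neighbors, strength):
        return {g: (strength[g], 0.0) for g in neighbors}

    def test_below_cap_unchanged(self):
        nbrs = {f"n{i}" for i in range(5)}
        out = cap_neighborhood(nbrs, self.corr_map(nbrs, {g: 0.5 for g in nbrs}), n=12)
        assert out == nbrs

    def test_truncates_to_half_n_by_strength(self):
        nbrs = {f"n{i}" for i in range(8)}
        strength = {f"n{i}": 0.1 * (i + 1) for i in range(8)}
        out = cap_neighborhood(nbrs, self.corr_map(nbrs, strength), n=6)
        assert out == {"n7", "n6", "n5"}  # top 3 = floor(6/2)

    def test_uses_max_of_both_correlations(self):
        nbrs = {"weak_i_strong_j", "medium"}
        corr = {"weak_i_strong_j": (0.1, 0.9), "medium": (0.5, 0.5)}
        out = cap_neighborhood(nbrs | {f"x{i}" for i in range(7)},
                               {**corr, **{f"x{i}": (0.2, 0.2) for i in range(7)}},
                               n=4)
        assert out == {"weak_i_strong_j", "medium"}

    def test_ties_break_lexicographically(self):
        nbrs = {f"n{i}" for i in range(8)}
        out = cap_neighborhood(nbrs, self.corr_map(nbrs, {g: 0.5 for g in nbrs}), n=6)
        assert out == {"n0", "n1", "n2"}


class TestLocalPartialCorr:
    def test_empty_conditioning_set_is_pearson(self):
        r = 0.45
        sub = np.array([[1.0, r], [r, 1.0]])
        pr, p = local_partial_corr(sub, n=20)
        assert pr == pytest.approx(r, abs=1e-12)
        # df = n - 2 reduces to the Pearson p-value formula
        res = pearson_with_p(*_correlated_xy(r, 20))
        t = r * np.sqrt(18 / (1 - r * r))
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(t, 18), rel=1e-12)

    def test_first_order_closed_form_zero(self):
        # r_AC = r_AB * r_BC -> conditional independence
        sub = np.array(
            [[1.0, 0.36, 0.6],
             [0.36, 1.0, 0.6],
             [0.6, 0.6, 1.0]]
        )
        pr, p = local_partial_corr(sub, n=50)
        assert pr == pytest.approx(first_order_partial(0.36, 0.6, 0.6), abs=1e-12)
        assert pr == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_pair(self, rng):
        a = rng.standard_normal((4, 4))
        spd = a @ a.T + 4 * np.eye(4)
        d = np.sqrt(np.diag(spd))
        corr = spd / np.outer(d, d)
        pr1, _ = local_partial_corr(corr, n=30, pair_indices=(0, 1))
        perm = [1, 0, 2, 3]
        pr2, _ = local_partial_corr(corr[np.ix_(perm, perm)], n=30, pair_indices=(0, 1))
        assert pr1 == pytest.approx(pr2, abs=1e-12)

    def test_saturated_equals_global_precision(self, rng):
        """Conditioning on all remaining variables = global partial correlation."""
        for _ in range(20):
            k = rng.integers(3, 11)
            a = rng.standard_normal((k, k))
            spd = a @ a.T + k * np.eye(k)
            d = np.sqrt(np.diag(spd))
            corr = spd / np.outer(d, d)
            omega = np.linalg.inv(corr)
            expected = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
            pr, _ = local_partial_corr(corr, n=100)
            assert pr == pytest.approx(expected, abs=1e-10)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError):
            local_partial_corr(np.eye(6), n=6)  # df = 6 - 4 - 2 = 0
        local_partial_corr(np.eye(5), n=6)  # df = 1 is allowed


def _correlated_xy(r, n, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return x, y


def chain_dataset(rng, n=100, r=0.7):
    """Gaussian chain A - B - C with A independent of C given B."""
    b = rng.standard_normal(n)
    a = r * b + np.sqrt(1 - r * r) * rng.standard_normal(n)
    c = r * b + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return make_dataset(np.vstack([a, b, c]), genes=["A", "B", "C"], n_a=0)


class TestBuildLpcNetwork:
    DIRS = {"A": "UP", "B": "UP", "C": "UP"}

    def test_chain_indirect_edge_removed(self, rng):
        ds = chain_dataset(rng)
        marginal = build_network([ds], self.DIRS, "B", k_required=1)
        lpc = build_lpc_network([ds], self.DIRS, "B", k_required=1)
        assert marginal.has_edge("A", "C")
        assert lpc.has_edge("A", "B") and lpc.has_edge("B", "C")
        assert not lpc.has_edge("A", "C")

    def test_two_variables_equal_threshold_pearson(self, rng):
        x, y = _correlated_xy(0.6, 40)
        ds = make_dataset(np.vstack([x, y]), genes=["A", "B"], n_a=0)
        lpc = build_lpc_network([ds], {"A": "UP", "B": "UP"}, "B", k_required=1)
        res = pearson_with_p(x, y)
        assert lpc.has_edge("A", "B")
        assert lpc.graph.edges["A", "B"]["combined_p"] == pytest.approx(res.p, rel=1e-9)

    def test_small_sample_dataset_skipped(self, rng):
        ds = chain_dataset(rng, n=5)
        lpc = build_lpc_network([ds], self.DIRS, "B", k_required=1)
        assert lpc.n_edges == 0

    def test_deterministic(self, rng):
        ds = chain_dataset(rng)
        n1 = build_lpc_network([ds], self.DIRS, "B", k_required=1)
        n2 = build_lpc_network([ds], self.DIRS, "B", k_required=1)
        assert n1.edge_table().equals(n2.edge_table())
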