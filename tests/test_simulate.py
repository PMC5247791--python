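"""Synthetic truth generation and dataset sampling."""

import numpy as np
import pytest

from dcnet.simulate import TruthConfig, generate_truth, sample_datasets


@pytest.fixture(scope="module")
def truth():
    return generate_truth(seed=5)


class TestGenerateTruth:
    def test_deterministic_under_seed(self, truth):
        again = generate_truth(seed=5)
        assert truth.genes == again.genes
        assert truth.deg_truth == again.deg_truth
        assert truth.dcp_truth == again.dcp_truth
        assert np.array_equal(truth.corr_A, again.corr_A)

    def test_null_config_has_exchangeable_conditions(self):
        t = generate_truth(
            TruthConfig(n_causal=0, n_gain=0, n_loss=0, n_shared=0, n_deg=0), seed=3
        )
        assert np.array_equal(t.corr_A, t.corr_B)
        assert not t.dcp_truth and not t.deg_truth

    def test_planted_entries_match_matrices(self, truth):
        pos = {g: i for i, g in enumerate(truth.genes)}
        for (gi, gj), (kind, ra, rb) in truth.dcp_truth.items():
            i, j = pos[gi], pos[gj]
            assert truth.corr_A[i, j] == pytest.approx(ra, abs=0.02)
            assert truth.corr_B[i, j] == pytest.approx(rb, abs=0.02)
            if kind == "gain":
                assert (ra, rb) == (0.0, truth.config.r_planted)
            else:
                assert (ra, rb) == (truth.config.r_planted, 0.0)

    def test_matrices_are_valid_correlations(self, truth):
        for c in (truth.corr_A, truth.corr_B):
            assert np.allclose(np.diag(c), 1.0)
            assert np.allclose(c, c.T)
            assert np.linalg.eigvalsh(c)[0] > -1e-10

    def test_causal_genes_are_gain_hubs(self, truth):
        for hub in truth.causal_genes:
            assert any(hub in pair for pair in truth.gain_pairs())
            assert truth.deg_truth[hub][0] in ("UP", "DN")

    def test_gain_pairs_share_direction(self, truth):
        """PUC-consistency: positively correlated planted pairs are
        co-regulated."""
        for gi, gj in truth.gain_pairs() | truth.loss_pairs():
            assert truth.deg_truth[gi][0] == truth.deg_truth[gj][0]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_gain=7),                 # not n_causal * C(k,2)
            dict(n_deg=10),                 # structure does not fit
            dict(r_planted=1.5),
            dict(n_causal=0, n_gain=10),
        ],
    )
    def test_infeasible_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_truth(TruthConfig(**bad), seed=0)


class TestSampleDatasets:
    def test_deterministic_under_seed(self, truth):
        d1 = sample_datasets(truth, seed=9)
        d2 = sample_datasets(truth, seed=9)
        for a, b in zip(d1, d2):
            assert a.values.equals(b.values)

    def test_planted_correlation_realized(self, truth):
        """Empirical correlation of a planted r = 0.8 pair at n = 200."""
        pos = {g: i for i, g in enumerate(truth.genes)}
        devs = []
        for rep in range(5):
            ds = sample_datasets(truth, m_datasets=1, n_per_condition=200, seed=100 + rep)[0]
            xb = ds.condition_matrix("B")
            R = np.corrcoef(xb)
            for gi, gj in truth.gain_pairs():
                devs.append(R[pos[gi], pos[gj]])
        devs = np.asarray(devs)
        assert np.all(np.abs(devs - 0.8) < 0.1)

    def test_deg_mean_shift_applied_to_b_only(self, truth):
        ds = sample_datasets(truth, m_datasets=1, n_per_condition=400, seed=17)[0]
        gene = sorted(truth.deg_truth)[0]
        direction, eff = truth.deg_truth[gene]
        a = ds.values.loc[gene, ds.condition_samples("A")].mean()
        b = ds.values.loc[gene, ds.condition_samples("B")].mean()
        shift = b - a
        assert shift == pytest.approx(eff if direction == "UP" else -eff, abs=0.25)

    def test_paired_design_reduces_difference_variance(self, truth):
        """Shared per-pair intercepts shrink paired-difference variance
        below the 2-sigma^2 of independent samples."""
        ratios = []
        for rep in range(20):
            ds = sample_datasets(truth, m_datasets=1, n_per_condition=60,
                                 paired=True, seed=200 + rep)[0]
            xa, xb = ds.paired_matrices()
            paired_var = np.var(xb - xa, axis=1, ddof=1).mean()
            ratios.append(paired_var / 2.0)
        assert np.mean(ratios) < 0.97  # strictly below independent-sample variance

    def test_unpaired_has_no_pairing_metadata(self, truth):
        ds = sample_datasets(truth, m_datasets=1, paired=False, seed=3)[0]
        assert ds.pairing is None

    def test_heterogeneity_zero_keeps_full_structure(self, truth):
        """With h = 0 every condition-B sample carries the full gain blocks."""
        pos = {g: i for i, g in enumerate(truth.genes)}
        ds = sample_datasets(truth, m_datasets=1, n_per_condition=300,
                             heterogeneity=0.0, seed=23)[0]
        R = np.corrcoef(ds.condition_matrix("B"))
        rs = [R[pos[i], pos[j]] for i, j in truth.gain_pairs()]
        assert min(rs) > 0.6

    def test_heterogeneity_attenuates_gain_correlations(self, truth):
        pos = {g: i for i, g in enumerate(truth.genes)}
        ds = sample_datasets(truth, m_datasets=1, n_per_condition=300,
                             heterogeneity=0.5, seed=23)[0]
        R = np.corrcoef(ds.condition_matrix("B"))
        rs = [R[pos[i], pos[j]] for i, j in truth.gain_pairs()]
        assert np.mean(rs) < 0.7
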