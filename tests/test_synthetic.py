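"""Planted-truth construction, cohort sampling and recovery scoring."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from uratenet.synthetic import (CovariateSpec, SyntheticTruth,
                                edge_recovery_metrics, generate_cohort,
                                generate_truth)
from uratenet.containers import AbundanceMatrix
from uratenet.pcor import partial_correlation_matrix


def pcor_from_covariance(sigma):
    """Independent oracle: invert the correlation form of a covariance and
    read partial correlations off the resulting precision matrix."""
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    om = np.linalg.inv(corr)
    dd = np.sqrt(np.diag(om))
    r = -om / np.outer(dd, dd)
    np.fill_diagonal(r, 1.0)
    return r


class TestGenerateTruth:
    def test_empty_support_gives_diagonal_precision(self):
        # find a seed whose Bernoulli draws plant no edge at p=3
        for seed in range(50):
            t = generate_truth(3, 0.34, (0.2, 0.3), seed=seed)
            if not t.planted_edges:
                off = t.precision[~np.eye(3, dtype=bool)]
                assert np.all(off == 0.0)
                assert t.planted_pcor == {}
                return
        pytest.fail("no empty-support seed found in 50 tries")

    def test_seeded_determinism(self):
        a = generate_truth(12, 0.2, (0.2, 0.4), seed=7)
        b = generate_truth(12, 0.2, (0.2, 0.4), seed=7)
        np.testing.assert_array_equal(a.precision, b.precision)
        assert a.planted_edges == b.planted_edges
        assert a.planted_pcor == b.planted_pcor

    def test_planted_magnitudes_in_range_and_oracle_consistent(self):
        t = generate_truth(10, 0.2, (0.2, 0.4), seed=1)
        assert t.planted_edges
        sigma = np.linalg.inv(t.precision)
        r_oracle = pcor_from_covariance(sigma)
        for (i, j), rho in t.planted_pcor.items():
            assert 0.2 <= abs(rho) <= 0.4
            assert r_oracle[i, j] == pytest.approx(rho, abs=1e-10)

    def test_non_edges_have_zero_precision_and_zero_pcor(self):
        t = generate_truth(10, 0.2, (0.2, 0.4), seed=1)
        sigma = np.linalg.inv(t.precision)
        r_oracle = pcor_from_covariance(sigma)
        for i in range(10):
            for j in range(i + 1, 10):
                if (i, j) not in t.planted_edges:
                    assert t.precision[i, j] == 0.0
                    assert abs(r_oracle[i, j]) < 1e-10

    def test_unit_latent_variances(self):
        t = generate_truth(15, 0.1, (0.2, 0.4), seed=3)
        sigma = np.linalg.inv(t.precision)
        np.testing.assert_allclose(np.diag(sigma), 1.0, atol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_truth(2, 0.5, (0.2, 0.4), seed=0)
        with pytest.raises(ValueError):
            generate_truth(10, 0.2, (0.5, 0.4), seed=0)
        with pytest.raises(ValueError):
            generate_truth(10, 1e-4, (0.2, 0.4), seed=0)   # expected edges < 1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(p=st.integers(5, 20), seed=st.integers(0, 10_000))
    def test_pcor_consistency_property(self, p, seed):
        """Inverting the covariance always reproduces planted_pcor to 1e-10."""
        t = generate_truth(p, 0.2, (0.1, 0.5), seed=seed)
        r_oracle = pcor_from_covariance(np.linalg.inv(t.precision))
        for (i, j), rho in t.planted_pcor.items():
            assert abs(r_oracle[i, j] - rho) < 1e-10


def single_edge_truth(p, rho, seed=0):
    """Hand-built truth with one planted edge of exact partial correlation."""
    omega = np.eye(p)
    omega[0, 1] = omega[1, 0] = -rho
    s = np.sqrt(np.diag(np.linalg.inv(omega)))
    omega = omega * np.outer(s, s)
    d = np.sqrt(np.diag(omega))
    pc = float(-omega[0, 1] / (d[0] * d[1]))
    t = SyntheticTruth(precision=omega, planted_edges=frozenset({(0, 1)}),
                       planted_pcor={(0, 1): pc}, covariate_effects={},
                       duplicate_spec=None, seed=seed)
    t.validate()
    return t


class TestGenerateCohort:
    def test_zero_missing_rate_gives_no_missing_cells(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2)
        c = generate_cohort(t, 50, missing_rate=0.0, seed=5)
        assert not c.abundance.missing_mask.any()

    def test_missing_fraction_near_request(self):
        t = generate_truth(20, 0.1, (0.2, 0.4), seed=2)
        c = generate_cohort(t, 600, missing_rate=0.1, seed=5)
        assert c.abundance.missing_mask.mean() == pytest.approx(0.1, abs=0.02)

    def test_censoring_removes_lowest_intensities(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2)
        c = generate_cohort(t, 400, missing_rate=0.15, seed=5,
                            missing_mechanism="censor")
        mask = c.abundance.missing_mask
        assert mask.mean() == pytest.approx(0.15, abs=0.02)
        # censoring acts per analyte: every column loses ~the same fraction
        col_frac = mask.mean(axis=0)
        assert np.all(np.abs(col_frac - 0.15) < 0.05)

    def test_seeded_determinism(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2)
        a = generate_cohort(t, 60, missing_rate=0.05, seed=9)
        b = generate_cohort(t, 60, missing_rate=0.05, seed=9)
        np.testing.assert_array_equal(a.abundance.values, b.abundance.values)
        assert a.covariates.table.equals(b.covariates.table)

    def test_row_counts_align(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2)
        c = generate_cohort(t, 75, seed=9)
        assert c.abundance.n_samples == len(c.covariates.table) == 75

    def test_duplicate_pair_correlation_matches_target(self):
        t = generate_truth(10, 0.15, (0.2, 0.4), seed=4,
                           duplicate_spec=(1, 0.60))
        c = generate_cohort(t, 5000, missing_rate=0.0, runday_effect_sd=0.0,
                            seed=11)
        log_x = np.log(c.abundance.values)
        src = log_x[:, 1]
        dup = log_x[:, c.metabolite_index[c.duplicate_id]]
        r = np.corrcoef(src, dup)[0, 1]
        assert 0.55 <= r <= 0.65

    def test_planted_pcor_recovered_at_large_n(self):
        """Monte-Carlo: a single planted edge of pcor 0.3 is estimated
        within +-0.05 from the sampled cohort at n=5000."""
        t = single_edge_truth(20, 0.3)
        c = generate_cohort(t, 5000, missing_rate=0.0, runday_effect_sd=0.0,
                            seed=21)
        log_x = np.log(c.abundance.values)
        m = AbundanceMatrix(c.abundance.sample_ids, c.abundance.metabolite_ids,
                            log_x, c.abundance.runday, stage="imputed")
        res = partial_correlation_matrix(m)
        assert res.r[0, 1] == pytest.approx(t.planted_pcor[(0, 1)], abs=0.05)

    def test_planted_pcor_rmse_converges(self):
        """Full-conditional estimates converge to planted values: RMSE over
        all planted edges below 0.05 at n=5000, p=20, no missingness."""
        t = generate_truth(20, 0.1, (0.2, 0.4), seed=8)
        c = generate_cohort(t, 5000, missing_rate=0.0, runday_effect_sd=0.0,
                            seed=9)
        m = AbundanceMatrix(c.abundance.sample_ids, c.abundance.metabolite_ids,
                            np.log(c.abundance.values), c.abundance.runday,
                            stage="imputed")
        res = partial_correlation_matrix(m)
        errs = [res.r[i, j] - rho for (i, j), rho in t.planted_pcor.items()]
        assert np.sqrt(np.mean(np.square(errs))) < 0.05

    def test_covariate_effect_shifts_log_mean(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2,
                           covariate_effects={(0, "sex"): 1.5})
        c = generate_cohort(t, 4000, missing_rate=0.0, runday_effect_sd=0.0,
                            seed=13)
        log_x = np.log(c.abundance.values[:, 0])
        sex = c.covariates.table["sex"].to_numpy()
        diff = log_x[sex == 1].mean() - log_x[sex == 0].mean()
        assert diff == pytest.approx(1.5, abs=0.15)

    def test_rejects_tiny_cohort(self):
        t = generate_truth(8, 0.2, (0.2, 0.4), seed=2)
        with pytest.raises(ValueError):
            generate_cohort(t, 5, seed=1)


class TestEdgeRecoveryMetrics:
    def graph_of(self, edges):
        g = nx.Graph()
        g.add_nodes_from(f"m{i}" for i in range(6))
        for i, j in edges:
            g.add_edge(f"m{i}", f"m{j}", pcor=0.3)
        return g

    def truth_of(self, edges):
        omega = np.eye(6)
        for i, j in edges:
            omega[i, j] = omega[j, i] = -0.1
        return SyntheticTruth(precision=omega, planted_edges=frozenset(edges),
                              planted_pcor={e: 0.1 for e in edges},
                              covariate_effects={}, duplicate_spec=None, seed=0)

    INDEX = {f"m{i}": i for i in range(6)}

    def test_perfect_recovery(self):
        edges = {(0, 1), (2, 3)}
        rep = edge_recovery_metrics(self.graph_of(edges), self.truth_of(edges),
                                    self.INDEX)
        assert rep.tpr == 1.0 and rep.fdp == 0.0

    def test_empty_recovery(self):
        rep = edge_recovery_metrics(self.graph_of(set()),
                                    self.truth_of({(0, 1)}), self.INDEX)
        assert rep.tpr == 0.0 and rep.fdp == 0.0

    def test_partial_recovery_set_arithmetic(self):
        planted = {(0, 1), (1, 2), (3, 4)}
        recovered = {(0, 1), (4, 5)}     # one hit, one false
        rep = edge_recovery_metrics(self.graph_of(recovered),
                                    self.truth_of(planted), self.INDEX)
        assert rep.tpr == pytest.approx(1 / 3)
        assert rep.fdp == pytest.approx(1 / 2)

    def test_unmapped_node_raises(self):
        with pytest.raises(KeyError):
            edge_recovery_metrics(self.graph_of({(0, 1)}),
                                  self.truth_of({(0, 1)}), {"m0": 0})

    def test_signed_errors_reported(self):
        edges = {(0, 1)}
        g = self.graph_of(edges)          # estimated pcor 0.3 vs planted 0.1
        rep = edge_recovery_metrics(g, self.truth_of(edges), self.INDEX)
        assert rep.edge_errors[(0, 1)] == pytest.approx(0.2)
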