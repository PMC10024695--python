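"""Connectivity assembly, surrogate nulls, bootstrap and clustering."""

import itertools

import numpy as np
import pytest

from cokurt import hos, networks
from cokurt.synthetic import cohort


def make_subject(rng, p=4, n=3000):
    return (rng.standard_normal((p, n)) + 1j * rng.standard_normal((p, n))) / np.sqrt(2)


class TestBuildConnectivity:
    def test_identical_channels_unit_power_corr(self, rng):
        x = make_subject(rng, p=1)[0]
        sig = np.vstack([x, x + 0j])
        _, g = networks.build_connectivity([sig])
        assert g.power_corr[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_entrywise_additivity(self, rng):
        subs = [make_subject(rng) for _ in range(3)]
        sets, group = networks.build_connectivity(subs)
        for s in sets + [group]:
            total = s.coh_term + s.cokurtosis_term + s.conjcoh_term
            np.testing.assert_allclose(s.power_corr, total, atol=1e-10)

    def test_planted_blocks_in_cokurtosis_term(self):
        blocks = np.repeat([0, 1], 3)
        subs, _ = cohort(3, 6, 20_000, blocks=blocks, seed=1)
        _, g = networks.build_connectivity(subs)
        iu = np.triu_indices(6, k=1)
        same = blocks[iu[0]] == blocks[iu[1]]
        assert g.cokurtosis_term[iu][same].mean() > 5 * abs(g.cokurtosis_term[iu][~same].mean())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            networks.build_connectivity([])


class TestSeedMap:
    def test_constant_matrix(self):
        m = np.full((5, 5), 0.3)
        np.testing.assert_allclose(networks.seed_map(m), 0.3)

    def test_block_elevation_and_threshold(self):
        m = np.zeros((6, 6))
        m[:3, :3] = 1.0
        sm = networks.seed_map(m)
        assert sm[:3].min() > sm[3:].max()
        thr = networks.seed_map(m, threshold_at_mean=True)
        assert np.all(thr[3:] == 0.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            networks.seed_map(np.zeros((3, 4)))


class TestSurrogates:
    def test_gaussian_surrogate_matches_cross_spectrum(self, rng):
        sig = make_subject(rng, p=3, n=20_000)
        sig[1] = 0.7 * sig[0] + 0.5 * sig[1]
        surr = networks.gaussian_surrogate(sig, rng)
        rho_emp = hos.coherence(sig[0], sig[1])
        rho_sur = hos.coherence(surr[0], surr[1])
        assert abs(rho_sur) == pytest.approx(abs(rho_emp), abs=0.05)

    def test_surrogate_cokurtosis_contribution_near_zero(self, rng):
        # coherent AND bursty cohort: the raw signals have a large cokurtosis
        # fraction, but Gaussian surrogates retain only the coherence part
        blocks = np.repeat([0, 1], 2)
        subs, _ = cohort(1, 4, 8000, blocks=blocks, seed=2)
        sig = subs[0]
        sig[1] = 0.8 * sig[0] + 0.6 * sig[1]  # plant strong coherence
        sig[3] = 0.8 * sig[2] + 0.6 * sig[3]
        raw = networks.pooled_contributions([sig])
        assert raw["cokurtosis"] > 0.2
        null = networks.surrogate_null(sig, n_surrogates=30, seed=3)
        assert abs(null["contributions"][:, 1].mean()) < 0.15
        assert null["contributions"][:, 0].mean() > 0.8
        assert null["diff_p95"] > 0

    def test_null_percentile_shrinks_with_samples(self, rng):
        sig_small = make_subject(rng, p=3, n=1000)
        sig_large = make_subject(rng, p=3, n=16_000)
        p_small = networks.surrogate_null(sig_small, n_surrogates=25, seed=4)["diff_p95"]
        p_large = networks.surrogate_null(sig_large, n_surrogates=25, seed=4)["diff_p95"]
        assert p_large < p_small

    def test_empirical_gaussian_cohort_within_null_band(self, rng):
        """Zero planted cokurtosis: observed r - |rho|^2 sits inside the null."""
        sig = make_subject(rng, p=4, n=4000)
        _, g = networks.build_connectivity([sig])
        iu = np.triu_indices(4, k=1)
        obs = (g.power_corr - g.coherence_sq)[iu]
        null = networks.surrogate_null(sig, n_surrogates=60, seed=5)
        assert obs.max() <= np.percentile(null["diff_null"], 99.9)

    def test_phase_randomization_preserves_spectrum(self, rng):
        from scipy import signal as sps

        data = np.cumsum(rng.standard_normal((2, 4096)), axis=1)
        surr = networks.phase_randomize(data, rng)
        f, p0 = sps.periodogram(data[0])
        _, p1 = sps.periodogram(surr[0])
        np.testing.assert_allclose(p0[1:], p1[1:], rtol=1e-6)


class TestBootstrap:
    def test_identical_subjects_zero_se(self, rng):
        s = make_subject(rng, p=3, n=2000)
        out = networks.bootstrap_contributions([s.copy(), s.copy(), s.copy()],
                                               n_boot=50, seed=0)
        assert out["se"]["coherence"] == pytest.approx(0.0, abs=1e-12)
        assert out["se"]["cokurtosis"] == pytest.approx(0.0, abs=1e-12)

    def test_two_subject_exhaustive_enumeration(self, rng):
        """Bootstrap SE over 2 subjects matches brute-force enumeration of
        the 4 equally likely resamples."""
        s1, s2 = make_subject(rng, p=3, n=1500), make_subject(rng, p=3, n=1500)
        vals = []
        for pick in itertools.product([s1, s2], repeat=2):
            vals.append(networks.pooled_contributions(list(pick))["cokurtosis"])
        exact_sd = np.std(vals, ddof=1)
        out = networks.bootstrap_contributions([s1, s2], n_boot=4000, seed=1)
        assert out["se"]["cokurtosis"] == pytest.approx(exact_sd, rel=0.25)

    def test_se_shrinks_with_cohort_size(self, rng):
        # heterogeneous cohort: per-subject coherence differs, so the pooled
        # contribution varies across subjects and its SE scales ~1/sqrt(n)
        def subject(g):
            s = make_subject(rng, p=3, n=1500)
            s[1] = g * s[0] + np.sqrt(1 - g**2) * s[1]
            return s

        subs12 = [subject(g) for g in rng.uniform(0.1, 0.9, 12)]
        se12 = networks.bootstrap_contributions(subs12, n_boot=150, seed=2)["se"]["coherence"]
        se3 = networks.bootstrap_contributions(subs12[:3], n_boot=150, seed=2)["se"]["coherence"]
        assert se12 < se3

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            networks.bootstrap_contributions([make_subject(rng)], n_boot=10)


class TestClustering:
    def test_three_planted_blocks_selected_and_recovered(self):
        blocks = np.repeat([0, 1, 2], 4)
        subs, _ = cohort(4, 12, 15_000, blocks=blocks, seed=7)
        _, g = networks.build_connectivity(subs)
        res = networks.cluster_networks(g.cokurtosis, seed=0)
        assert res.k == 3
        # assignments match blocks up to relabeling
        for b in range(3):
            members = res.assignments[blocks == b]
            assert len(set(members)) == 1
        assert len({res.assignments[blocks == b][0] for b in range(3)}) == 3

    def test_inertia_curve_non_increasing(self, rng):
        m = rng.standard_normal((10, 10))
        m = m + m.T
        res = networks.cluster_networks(m, seed=1)
        assert np.all(np.diff(res.inertia_curve) <= 1e-9)

    def test_deterministic_given_seed(self, rng):
        m = rng.standard_normal((8, 8))
        m = m + m.T
        a = networks.cluster_networks(m, seed=3)
        b = networks.cluster_networks(m, seed=3)
        assert a.k == b.k
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            networks.cluster_networks(np.ones((5, 5)))
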