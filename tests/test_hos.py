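"""Higher-order statistics: moments, cumulants and the exact decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cokurt import hos
from cokurt.synthetic import gaussian_pair

from conftest import random_complex_pair


def brute_force_cumulant(x1, x2, x3, x4):
    """Independent oracle: fourth-order cumulant from raw moment sums.

    Plain Python accumulation, no shared code with the implementation.
    """
    n = len(x1)
    m1234 = sum(a * b * c * d for a, b, c, d in zip(x1, x2, x3, x4)) / n
    pair = lambda u, v: sum(a * b for a, b in zip(u, v)) / n
    return (
        m1234
        - pair(x1, x2) * pair(x3, x4)
        - pair(x1, x3) * pair(x2, x4)
        - pair(x1, x4) * pair(x2, x3)
    )


class TestJointMoment:
    def test_constant_ones_identity(self):
        x = np.ones(16, dtype=complex)
        assert hos.joint_moment(x, x, x, x, demean=False) == pytest.approx(1.0)

    def test_isserlis_fourth_moment_circular_gaussian(self, rng):
        # mu(x, x, xbar, xbar) -> 2 sigma^4 for a circular complex Gaussian
        sigma2 = 2.0
        reps = 50
        vals = []
        for _ in range(reps):
            x = np.sqrt(sigma2 / 2) * (rng.standard_normal(5000) + 1j * rng.standard_normal(5000))
            vals.append(hos.joint_moment(x, x, np.conj(x), np.conj(x), demean=False).real)
        se = np.std(vals) / np.sqrt(reps)
        assert abs(np.mean(vals) - 2 * sigma2**2) < 5 * se

    def test_permutation_symmetry(self, rng):
        args = [rng.standard_normal(64) + 1j * rng.standard_normal(64) for _ in range(4)]
        ref = hos.joint_moment(*args)
        perm = rng.permutation(4)
        assert hos.joint_moment(*[args[i] for i in perm]) == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch_and_empty_raise(self):
        with pytest.raises(ValueError):
            hos.joint_moment(np.ones(4, complex), np.ones(5, complex))
        with pytest.raises(ValueError):
            hos.joint_moment(np.array([], complex))


class TestJointCumulant:
    def test_gaussian_cumulant_vanishes(self, rng):
        reps, n = 40, 4000
        vals = []
        for _ in range(reps):
            x = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
            vals.append(hos.joint_cumulant(x, x, np.conj(x), np.conj(x)).real)
        se = np.std(vals) / np.sqrt(reps)
        assert abs(np.mean(vals)) < 5 * se

    def test_constant_modulus_normalized_cumulant(self, rng):
        # |x| = a with uniform phase: mu(x,x,xbar,xbar)=a^4, mu(x,xbar)=a^2,
        # mu(x,x)~0 -> normalized kappa = (a^4 - 2a^4)/a^4 = -1
        n = 4096
        a = 1.7
        x = a * np.exp(2j * np.pi * np.arange(n) / n)  # equispaced phases: <x^2> = 0 exactly
        k = hos.normalized_cumulant(x, x, np.conj(x), np.conj(x), demean=False)
        assert k.real == pytest.approx(-1.0, abs=1e-12)
        assert abs(k.imag) < 1e-12

    def test_linearity_in_each_argument(self, rng):
        args = [rng.standard_normal(128) + 1j * rng.standard_normal(128) for _ in range(4)]
        base = hos.joint_cumulant(*args)
        c = 2.5 - 1.25j
        scaled = hos.joint_cumulant(c * args[0], *args[1:])
        assert scaled == pytest.approx(c * base, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x, y = random_complex_pair(rng, n=int(rng.integers(8, 200)))
            ours = hos.joint_cumulant(x, y, np.conj(x), np.conj(y))
            xd, yd = x - x.mean(), y - y.mean()
            ref = brute_force_cumulant(list(xd), list(yd), list(np.conj(xd)), list(np.conj(yd)))
            assert ours == pytest.approx(ref, abs=1e-12 * max(1, abs(ref)))

    def test_zero_power_argument_raises(self):
        z = np.zeros(8, complex)
        x = np.ones(8, complex)
        with pytest.raises(ValueError):
            hos.normalized_cumulant(z, x, x, x, demean=False)


class TestSecondOrder:
    def test_coherence_self_and_rotated(self, rng):
        x = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        assert hos.coherence(x, x) == pytest.approx(1.0 + 0j, abs=1e-12)
        assert hos.coherence(x, 1j * x) == pytest.approx(-1j, abs=1e-12)

    def test_independent_gaussians_low_coherence(self, rng):
        x, y = gaussian_pair(0.0, 10_000, seed=7)
        assert abs(hos.coherence(x, y)) < 0.05

    def test_power_correlation_scale_invariance(self, rng):
        x, _ = random_complex_pair(rng, n=500, kind="bursty")
        assert hos.power_correlation(x, x) == pytest.approx(1.0)
        assert hos.power_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_constant_envelope_power_correlation_undefined(self):
        x = np.exp(2j * np.pi * np.arange(64) / 64)
        with pytest.raises(ValueError, match="constant power envelope"):
            hos.power_correlation(x, x, demean=False)

    def test_real_signal_circularity_is_one(self, rng):
        x = rng.standard_normal(512).astype(complex)
        assert hos.circularity_coefficient(x) == pytest.approx(1.0 + 0j, abs=1e-12)


class TestFourthOrder:
    def test_proper_gaussian_pair_all_vanish(self, rng):
        reps, n = 40, 5000
        kx, kxy, cc = [], [], []
        for i in range(reps):
            x, y = gaussian_pair(0.5, n, seed=1000 + i)
            kx.append(hos.kurtosis(x))
            kxy.append(hos.cokurtosis(x, y))
            cc.append(abs(hos.conjugate_coherence(x, y)))
        for vals, target in ((kx, 0.0), (kxy, 0.0)):
            se = np.std(vals) / np.sqrt(reps)
            assert abs(np.mean(vals) - target) < 5 * se
        assert np.mean(cc) < 3 / np.sqrt(n)  # |rho_conj| ~ Rayleigh with scale 1/sqrt(n)

    def test_cokurtosis_of_signal_with_itself_is_kurtosis(self, rng):
        x, _ = random_complex_pair(rng, n=300, kind="bursty")
        assert hos.cokurtosis(x, x) == pytest.approx(hos.kurtosis(x), abs=1e-12)

    def test_planted_cokurtosis_recovered(self):
        from cokurt.synthetic import bursting_pair

        reps = 60
        est = []
        truth = None
        for i in range(reps):
            x, y, truth = bursting_pair(0.05, 4.0, p_shared=0.05, n=20_000, seed=i)
            est.append(hos.cokurtosis(x, y))
        se = np.std(est) / np.sqrt(reps)
        assert abs(np.mean(est) - truth.cokurtosis) < 3 * se

    def test_phase_rotation_invariance(self, rng):
        x, y = random_complex_pair(rng, n=400, kind="improper")
        phi, psi = 0.7, -1.3
        xr, yr = np.exp(1j * phi) * x, np.exp(1j * psi) * y
        assert abs(hos.coherence(xr, yr)) == pytest.approx(abs(hos.coherence(x, y)), rel=1e-10)
        assert hos.kurtosis(xr) == pytest.approx(hos.kurtosis(x), rel=1e-10)
        assert hos.cokurtosis(xr, yr) == pytest.approx(hos.cokurtosis(x, y), rel=1e-10)
        assert hos.power_correlation(xr, yr) == pytest.approx(hos.power_correlation(x, y), rel=1e-10)
        # conjugate coherence rotates by e^{i(phi+psi)} instead
        assert hos.conjugate_coherence(xr, yr) == pytest.approx(
            np.exp(1j * (phi + psi)) * hos.conjugate_coherence(x, y), rel=1e-10
        )


class TestDecomposition:
    def test_identity_against_direct_estimate(self, rng):
        for _ in range(200):
            x, y = random_complex_pair(rng)
            try:
                d = hos.decompose(x, y)
                r = hos.power_correlation(x, y)
            except ValueError:
                continue
            assert abs(d.reconstructed_r - r) <= 1e-10 * max(1.0, abs(r))
            assert d.reconstructed_r == pytest.approx(
                d.term_coherence + d.term_cokurtosis + d.term_conj_coherence, abs=1e-14
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(8, 400))
    def test_identity_property(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = random_complex_pair(rng, n=n)
        try:
            d = hos.decompose(x, y)
            r = hos.power_correlation(x, y)
        except ValueError:
            return
        assert abs(d.reconstructed_r - r) <= 1e-10 * max(1.0, abs(r))

    def test_self_pair_reconstructs_one(self, rng):
        x, _ = random_complex_pair(rng, n=256, kind="bursty")
        assert hos.decompose(x, x).reconstructed_r == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_limit_terms(self):
        x, y = gaussian_pair(0.6, 200_000, seed=11)
        d = hos.decompose(x, y)
        assert d.term_cokurtosis == pytest.approx(0.0, abs=0.02)
        assert d.term_conj_coherence == pytest.approx(0.0, abs=0.01)
        assert d.reconstructed_r == pytest.approx(0.36, abs=0.03)


class TestDerivedMeasures:
    def test_nongauss_self_pair_super_gaussian(self, rng):
        x, _ = random_complex_pair(rng, n=2000, kind="bursty")
        kx = hos.kurtosis(x)
        assert kx > 0
        assert hos.nongauss_power_correlation(x, x) == pytest.approx(kx / (1 + kx), rel=1e-10)

    def test_gaussian_nongauss_near_zero(self):
        x, y = gaussian_pair(0.4, 100_000, seed=3)
        assert abs(hos.nongauss_power_correlation(x, y)) < 0.05

    def test_relative_contribution_limits_and_recomputation(self, rng):
        x, y = gaussian_pair(0.6, 100_000, seed=5)
        assert hos.relative_contribution(x, y) == pytest.approx(1.0, abs=0.05)
        # incoherent co-bursting pair: coherence contributes ~nothing
        from cokurt.synthetic import bursting_pair

        xb, yb, _ = bursting_pair(0.05, 4.0, p_shared=0.05, g_bg=0.0, n=50_000, seed=6)
        assert hos.relative_contribution(xb, yb) < 0.1
        # recomputation oracle on a mixed pair
        xm, ym = random_complex_pair(rng, n=1500, kind="bursty")
        rho2 = abs(hos.coherence(xm, ym)) ** 2
        kxy = hos.cokurtosis(xm, ym)
        assert hos.relative_contribution(xm, ym) == pytest.approx(rho2 / (rho2 + kxy), rel=1e-10)

    def test_summary_bundle_consistency(self, rng):
        x, y = random_complex_pair(rng, n=600, kind="coherent")
        s = hos.summarize(x, y)
        assert s.n_samples == 600
        assert s.power_corr == pytest.approx(hos.power_correlation(x, y), rel=1e-12)
        row = s.as_row()
        assert set(row) == set(hos.HOSummary._COLUMNS)
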