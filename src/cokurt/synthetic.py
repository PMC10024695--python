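"""Synthetic signal generators with closed-form ground truth.

Every statistic in the package is testable against these generators without
any external data: proper bivariate Gaussian pairs with prescribed coherence,
two-state bursting pairs with analytically known (co)kurtosis, improper
(non-circular) signals, multi-subject cohorts with planted block structure,
and toy forward models for the beamformer.

All generators require an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurstingTruth",
    "gaussian_pair",
    "bursting_pair",
    "bursting_truth",
    "bursting_truth_brute_force",
    "improper_signal",
    "cohort",
    "toy_forward",
]


def _rng(seed):
    if seed is None:
        raise ValueError("seed is mandatory for synthetic generators")
    return np.random.default_rng(seed)


def _proper_gaussian(n: int, rng) -> np.ndarray:
    """Unit-power proper complex Gaussian white noise."""
    return (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2.0)


def gaussian_pair(g: float, n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Proper bivariate complex Gaussian pair with coherence magnitude ``g``.

    Theoretical values: K_x = K_y = K_{x,y} = 0, power correlation r = g^2
    (the Gaussian relation between envelope correlation and coherence).
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("coherence magnitude g must lie in [0, 1]")
    rng = _rng(seed)
    x = _proper_gaussian(n, rng)
    w = _proper_gaussian(n, rng)
    y = g * x + np.sqrt(1.0 - g * g) * w
    return x, y


@dataclass
class BurstingTruth:
    """Theoretical moments of the two-state bursting pair."""

    coherence_sq: float
    kurtosis: float       # K_x = K_y (symmetric construction)
    cokurtosis: float
    power_corr: float
    nongauss_power_corr: float


def _burst_state_probs(p_b: float, p_shared: float) -> np.ndarray:
    """Joint probabilities of (b_x, b_y) in order (0,0), (0,1), (1,0), (1,1)."""
    if not (0.0 <= p_b <= 1.0 and 0.0 <= p_shared <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_shared > p_b or p_shared < max(0.0, 2 * p_b - 1.0):
        raise ValueError("p_shared incompatible with marginal burst probability")
    p11 = p_shared
    p10 = p01 = p_b - p_shared
    p00 = 1.0 - 2 * p_b + p_shared
    return np.array([p00, p01, p10, p11])


def bursting_truth_brute_force(
    p_b: float, A: float, p_shared: float, g_bg: float
) -> BurstingTruth:
    """Expected moments by explicit expectation over the 4 burst states.

    For each joint burst state the pair is conditionally proper Gaussian with
    amplitude gains (s_x, s_y) in {1, A}; conditional moments follow from
    Isserlis' theorem for proper Gaussians (E|u|^2 = 1, E|u|^4 = 2,
    E[u vbar] = g, E|u|^2|v|^2 = 1 + g^2).  Marginalizing over the states
    gives the exact unconditional moments.  Serves as the independent oracle
    for :func:`bursting_truth`.
    """
    probs = _burst_state_probs(p_b, p_shared)
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    g = g_bg
    m2x = m2y = 0.0       # E|x|^2
    cross = 0.0           # E[x ybar]
    m4x = m4y = 0.0       # E|x|^4
    m22 = 0.0             # E|x|^2 |y|^2
    for p, (bx, by) in zip(probs, states):
        sx = A if bx else 1.0
        sy = A if by else 1.0
        m2x += p * sx**2
        m2y += p * sy**2
        cross += p * sx * sy * g
        m4x += p * sx**4 * 2.0
        m4y += p * sy**4 * 2.0
        m22 += p * sx**2 * sy**2 * (1.0 + g * g)
    # conjugate moments E[x^2], E[xy] vanish (proper carriers)
    kx = (m4x - 2.0 * m2x**2) / m2x**2
    ky = (m4y - 2.0 * m2y**2) / m2y**2
    kxy = (m22 - m2x * m2y - abs(cross) ** 2) / (m2x * m2y)
    coh_sq = abs(cross) ** 2 / (m2x * m2y)
    var_px = m4x - m2x**2
    var_py = m4y - m2y**2
    cov = m22 - m2x * m2y
    r = cov / np.sqrt(var_px * var_py)
    re = kxy / np.sqrt((1 + kx) * (1 + ky))
    return BurstingTruth(
        coherence_sq=float(coh_sq),
        kurtosis=float(kx),
        cokurtosis=float(kxy),
        power_corr=float(r),
        nongauss_power_corr=float(re),
    )


def bursting_truth(p_b: float, A: float, p_shared: float, g_bg: float) -> BurstingTruth:
    """Closed-form moments of the two-state bursting pair.

    Direct mixture-moment algebra: with gain variables s in {1, A},
    E[s^2] = 1 + p_b (A^2-1), E[s^4] = 1 + p_b (A^4-1),
    E[s_x s_y] = 1 + 2 p_b (A-1) + p_shared (A-1)^2,
    E[s_x^2 s_y^2] = 1 + 2 p_b (A^2-1) + p_shared (A^2-1)^2.
    """
    _burst_state_probs(p_b, p_shared)  # validate
    g = g_bg
    m2 = 1.0 + p_b * (A**2 - 1.0)
    m4 = 1.0 + p_b * (A**4 - 1.0)
    sxy = 1.0 + 2.0 * p_b * (A - 1.0) + p_shared * (A - 1.0) ** 2
    sx2y2 = 1.0 + 2.0 * p_b * (A**2 - 1.0) + p_shared * (A**2 - 1.0) ** 2
    coh_sq = (sxy * g) ** 2 / m2**2
    kx = (2.0 * m4 - 2.0 * m2**2) / m2**2
    kxy = (sx2y2 * (1.0 + g * g) - m2**2 - (sxy * g) ** 2) / m2**2
    var_p = 2.0 * m4 - m2**2
    cov = sx2y2 * (1.0 + g * g) - m2**2
    r = cov / var_p
    re = kxy / (1.0 + kx)
    return BurstingTruth(
        coherence_sq=float(coh_sq),
        kurtosis=float(kx),
        cokurtosis=float(kxy),
        power_corr=float(r),
        nongauss_power_corr=float(re),
    )


def bursting_pair(
    p_b: float,
    A: float,
    p_shared: float | None = None,
    g_bg: float = 0.0,
    n: int = 10000,
    seed=None,
    markov_sojourn: float | None = None,
) -> tuple[np.ndarray, np.ndarray, BurstingTruth]:
    """Two-state amplitude-modulated proper Gaussian pair.

    Each sample of each channel is in a background (gain 1) or burst
    (gain ``A``) state; bursts occur with marginal probability ``p_b`` and
    jointly with probability ``p_shared`` (default ``p_b**2``, independent).
    The carriers are proper Gaussian with background coherence ``g_bg``.
    Burst states are i.i.d. per sample by default; ``markov_sojourn`` (in
    samples) switches to a two-state Markov chain with that mean burst
    sojourn, keeping the same marginal and joint rates (temporally extended
    bursts; the marginal fourth-order moments are unchanged).

    Returns ``(x, y, truth)`` with the closed-form expected statistics.
    """
    if A < 1.0:
        raise ValueError("burst gain A must be >= 1")
    if p_shared is None:
        p_shared = p_b * p_b
    probs = _burst_state_probs(p_b, p_shared)
    rng = _rng(seed)
    u = _proper_gaussian(n, rng)
    w = _proper_gaussian(n, rng)
    v = g_bg * u + np.sqrt(1.0 - g_bg**2) * w
    if markov_sojourn is None:
        state = rng.choice(4, size=n, p=probs)
    else:
        state = _markov_states(probs, n, markov_sojourn, rng)
    bx = (state >= 2).astype(float)
    by = (state % 2 == 1).astype(float)
    sx = 1.0 + (A - 1.0) * bx
    sy = 1.0 + (A - 1.0) * by
    truth = bursting_truth(p_b, A, p_shared, g_bg)
    return sx * u, sy * v, truth


def _markov_states(probs: np.ndarray, n: int, sojourn: float, rng) -> np.ndarray:
    """Joint burst-state chain with geometric sojourns, stationary dist ``probs``."""
    if sojourn < 1.0:
        raise ValueError("mean sojourn must be >= 1 sample")
    leave = 1.0 / sojourn
    states = np.empty(n, dtype=np.int64)
    s = rng.choice(4, p=probs)
    for t in range(n):
        states[t] = s
        if rng.random() < leave:
            s = rng.choice(4, p=probs)
    return states


def improper_signal(circ_coeff: float, n: int, seed=None) -> np.ndarray:
    """Complex Gaussian with prescribed circularity coefficient ``<x^2>/<|x|^2>``.

    Built from unequal real/imaginary variances: Var(Re) = (1+c)/2,
    Var(Im) = (1-c)/2 for real c in [-1, 1]; c = 1 gives a purely real
    signal, c = 0 a proper one.
    """
    if not -1.0 <= circ_coeff <= 1.0:
        raise ValueError("circularity coefficient must lie in [-1, 1]")
    rng = _rng(seed)
    a = np.sqrt((1.0 + circ_coeff) / 2.0)
    b = np.sqrt((1.0 - circ_coeff) / 2.0)
    return a * rng.standard_normal(n) + 1j * b * rng.standard_normal(n)


def cohort(
    n_subjects: int,
    n_regions: int,
    n_samples: int,
    blocks=None,
    p_b: float = 0.05,
    A: float = 4.0,
    seed=None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Multi-subject region signals with planted block-structured co-bursting.

    ``blocks`` assigns each region to a block (length ``n_regions``; default:
    no structure, block label -1 = independent).  Regions within a block share
    a common burst indicator, so their pairwise cokurtosis is positive;
    between-block pairs burst independently (zero expected cokurtosis).

    Returns ``(subject_signals, block_labels)`` where ``subject_signals`` is a
    list of (n_regions x n_samples) complex arrays.
    """
    rng = _rng(seed)
    if blocks is None:
        blocks = -np.ones(n_regions, dtype=int)
    blocks = np.asarray(blocks, dtype=int)
    if blocks.size != n_regions:
        raise ValueError("blocks must have one label per region")
    subjects = []
    for _ in range(n_subjects):
        sig = np.empty((n_regions, n_samples), dtype=complex)
        block_bursts = {
            b: (rng.random(n_samples) < p_b).astype(float)
            for b in np.unique(blocks[blocks >= 0])
        }
        for j in range(n_regions):
            u = _proper_gaussian(n_samples, rng)
            if blocks[j] >= 0:
                bj = block_bursts[blocks[j]]
            else:
                bj = (rng.random(n_samples) < p_b).astype(float)
            sig[j] = (1.0 + (A - 1.0) * bj) * u
        subjects.append(sig)
    return subjects, blocks


def toy_forward(
    n_sensors: int,
    n_vertices: int,
    n_samples: int,
    snr: float = 10.0,
    active_vertex: int = 0,
    seed=None,
):
    """Toy forward model: leadfield G (sensors x 3*vertices), one active source.

    The active vertex carries an amplitude-modulated complex oscillation along
    a random unit orientation; sensor data are X = G s + noise with noise
    power set by ``snr`` (signal power / noise power at the sensors).

    Returns ``(G, X, source_ts, orientation)``.
    """
    rng = _rng(seed)
    G = rng.standard_normal((n_sensors, 3 * n_vertices))
    orientation = rng.standard_normal(3)
    orientation /= np.linalg.norm(orientation)
    t = np.arange(n_samples)
    envelope = 1.0 + 0.5 * np.sin(2 * np.pi * t / max(n_samples / 8, 2))
    carrier = np.exp(2j * np.pi * 0.1 * t)
    source_ts = envelope * carrier * _proper_gaussian(n_samples, rng)
    s = np.zeros((3 * n_vertices, n_samples), dtype=complex)
    s[3 * active_vertex : 3 * active_vertex + 3] = np.outer(orientation, source_ts)
    X_clean = G @ s
    sig_pow = np.mean(np.abs(X_clean) ** 2)
    noise = _proper_gaussian(n_sensors * n_samples, rng).reshape(n_sensors, n_samples)
    noise *= np.sqrt(sig_pow / (snr * np.mean(np.abs(noise) ** 2)))
    return G, X_clean + noise, source_ts, orientation
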