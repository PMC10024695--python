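"""Connectivity matrices, surrogate nulls, bootstrap and subnetwork clustering.

Builds the per-subject and group-level decomposition matrices (power
correlation = coherence term + cokurtosis term + conjugate-coherence term,
entrywise), seed maps, cross-spectrum-matched Gaussian surrogate nulls for
the difference r - |rho|^2, bootstrap standard errors of the pooled relative
contributions, and k-means subnetwork extraction from the cokurtosis matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import hos

__all__ = [
    "ConnectivitySet",
    "ClusterResult",
    "build_connectivity",
    "seed_map",
    "gaussian_surrogate",
    "phase_randomize",
    "surrogate_null",
    "pooled_contributions",
    "bootstrap_contributions",
    "cluster_networks",
]


@dataclass
class ConnectivitySet:
    """Aligned p x p matrices of the power-correlation decomposition.

    ``power_corr = coh_term + cokurtosis_term + conjcoh_term`` holds
    entrywise to numerical precision (the decomposition identity).
    """

    power_corr: np.ndarray
    coh_term: np.ndarray
    cokurtosis_term: np.ndarray
    conjcoh_term: np.ndarray
    contribution_coh: np.ndarray
    cokurtosis: np.ndarray
    coherence_sq: np.ndarray
    subject: str = "group"
    band: str = ""
    labels: list = field(default_factory=list)


def _subject_connectivity(signals: np.ndarray, subject: str, band: str) -> ConnectivitySet:
    sig = np.atleast_2d(np.asarray(signals, dtype=complex))
    sig = sig - sig.mean(axis=1, keepdims=True)
    p = sig.shape[0]
    mats = {k: np.zeros((p, p)) for k in
            ("power_corr", "coh_term", "cokurtosis_term", "conjcoh_term",
             "contribution_coh", "cokurtosis", "coherence_sq")}
    for i in range(p):
        for j in range(i, p):
            d = hos.decompose(sig[i], sig[j], demean=False)
            rho2 = abs(hos.coherence(sig[i], sig[j], demean=False)) ** 2
            kxy = hos.cokurtosis(sig[i], sig[j], demean=False)
            denom = rho2 + kxy
            c = rho2 / denom if denom != 0.0 else np.nan
            for key, val in (
                ("power_corr", d.reconstructed_r),
                ("coh_term", d.term_coherence),
                ("cokurtosis_term", d.term_cokurtosis),
                ("conjcoh_term", d.term_conj_coherence),
                ("contribution_coh", c),
                ("cokurtosis", kxy),
                ("coherence_sq", rho2),
            ):
                mats[key][i, j] = mats[key][j, i] = val
    return ConnectivitySet(subject=subject, band=band, **mats)


def build_connectivity(subject_signals, band: str = "") -> tuple[list[ConnectivitySet], ConnectivitySet]:
    """Per-subject decomposition matrices plus their group average.

    ``subject_signals`` is a sequence of (regions x samples) complex arrays.
    """
    subjects = list(subject_signals)
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    sets = [
        _subject_connectivity(s, subject=f"sub{i}", band=band)
        for i, s in enumerate(subjects)
    ]
    group = ConnectivitySet(
        power_corr=np.mean([s.power_corr for s in sets], axis=0),
        coh_term=np.mean([s.coh_term for s in sets], axis=0),
        cokurtosis_term=np.mean([s.cokurtosis_term for s in sets], axis=0),
        conjcoh_term=np.mean([s.conjcoh_term for s in sets], axis=0),
        contribution_coh=np.mean([s.contribution_coh for s in sets], axis=0),
        cokurtosis=np.mean([s.cokurtosis for s in sets], axis=0),
        coherence_sq=np.mean([s.coherence_sq for s in sets], axis=0),
        subject="group",
        band=band,
    )
    return sets, group


def seed_map(matrix: np.ndarray, threshold_at_mean: bool = False) -> np.ndarray:
    """Row means excluding the diagonal; optional below-mean thresholded view."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("square matrix required")
    p = m.shape[0]
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    means = off.sum(axis=1) / max(p - 1, 1)
    if threshold_at_mean:
        out = means.copy()
        out[out < means.mean()] = 0.0
        return out
    return means


def gaussian_surrogate(signals: np.ndarray, rng, ridge: float = 1e-12) -> np.ndarray:
    """Proper complex Gaussian draw matched to the empirical cross-spectrum.

    Second-order structure (coherence matrix) is preserved; all higher-order
    structure is destroyed, so cumulants of the surrogate vanish in
    expectation.  A ridge stabilizes the Cholesky factor of near-singular
    cross-spectral matrices (logged via exception message otherwise).
    """
    sig = np.atleast_2d(np.asarray(signals, dtype=complex))
    sig = sig - sig.mean(axis=1, keepdims=True)
    p, n = sig.shape
    C = sig @ sig.conj().T / n
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        Lc = np.linalg.cholesky(C + ridge * np.trace(C).real / p * np.eye(p))
    w = (rng.standard_normal((p, n)) + 1j * rng.standard_normal((p, n))) / np.sqrt(2.0)
    return Lc @ w


def phase_randomize(data: np.ndarray, rng) -> np.ndarray:
    """Joint phase randomization of real multichannel time series.

    Adds one common random phase sequence to all channels' Fourier
    coefficients: auto- and cross-spectra are preserved exactly while the
    samples become (asymptotically) jointly Gaussian.  The time-domain
    counterpart of :func:`gaussian_surrogate`.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[-1]
    F = np.fft.rfft(data, axis=-1)
    ph = rng.uniform(0.0, 2.0 * np.pi, F.shape[-1])
    ph[0] = 0.0
    if n % 2 == 0:
        ph[-1] = 0.0
    return np.fft.irfft(F * np.exp(1j * ph), n=n, axis=-1)


def surrogate_null(
    signals: np.ndarray,
    n_surrogates: int = 100,
    seed: int = 0,
) -> dict:
    """Null distributions of r - |rho|^2 and the relative contributions.

    Re-runs the full decomposition on ``n_surrogates`` cross-spectrum-matched
    proper Gaussian surrogates of the (channels x samples) complex signals.
    Returns pooled upper-triangle null values of the difference, their 95th
    percentile, and the pooled contribution fractions per surrogate.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    diffs = []
    contribs = []
    for _ in range(n_surrogates):
        surr = gaussian_surrogate(signals, rng)
        _, g = build_connectivity([surr])
        iu = np.triu_indices_from(g.power_corr, k=1)
        diffs.append((g.power_corr - g.coherence_sq)[iu])
        contribs.append(pooled_contributions([surr]))
    diffs = np.concatenate(diffs)
    return {
        "diff_null": diffs,
        "diff_p95": float(np.percentile(diffs, 95)),
        "contributions": np.array(
            [[c["coherence"], c["cokurtosis"], c["conj_coherence"]] for c in contribs]
        ),
    }


def pooled_contributions(subject_signals) -> dict:
    """Relative contributions pooled over all region pairs and subjects.

    Each of the three decomposition terms is summed over the upper triangle
    of every subject's matrices and divided by the total sum — the pooled
    counterpart of the per-pair relative contribution.
    """
    sets, _ = build_connectivity(subject_signals)
    tot_coh = tot_kur = tot_cc = 0.0
    for s in sets:
        iu = np.triu_indices_from(s.power_corr, k=1)
        tot_coh += s.coh_term[iu].sum()
        tot_kur += s.cokurtosis_term[iu].sum()
        tot_cc += s.conjcoh_term[iu].sum()
    total = tot_coh + tot_kur + tot_cc
    if total == 0.0:
        raise ValueError("zero total power correlation; contributions undefined")
    return {
        "coherence": tot_coh / total,
        "cokurtosis": tot_kur / total,
        "conj_coherence": tot_cc / total,
    }


def bootstrap_contributions(
    subject_signals,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap (over subjects) standard errors of the pooled contributions."""
    subjects = list(subject_signals)
    if len(subjects) < 2:
        raise ValueError("bootstrapping needs at least two subjects")
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        c = pooled_contributions([subjects[i] for i in idx])
        reps[b] = (c["coherence"], c["cokurtosis"], c["conj_coherence"])
    point = pooled_contributions(subjects)
    return {
        "point": point,
        "se": {
            "coherence": float(reps[:, 0].std(ddof=1)),
            "cokurtosis": float(reps[:, 1].std(ddof=1)),
            "conj_coherence": float(reps[:, 2].std(ddof=1)),
        },
        "replicates": reps,
    }


@dataclass
class ClusterResult:
    """k-means subnetworks of a connectivity matrix's columns."""

    k: int
    centers: np.ndarray           # k x p subnetwork maps
    assignments: np.ndarray       # length p, labels in 0..k-1
    inertia_curve: np.ndarray     # within-cluster SS for k = 1..k_max


def cluster_networks(
    matrix: np.ndarray,
    k_max: int = 10,
    n_replicates: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """Subnetworks by k-means over the matrix columns, k chosen by elbow.

    For each k in 1..k_max, the best of ``n_replicates`` seeded restarts
    (lowest within-cluster sum of squares) is kept; the elbow is the k
    maximizing the second difference of the within-SS curve (interior k
    only).  Euclidean distance on raw columns.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("square matrix required")
    if not np.isfinite(m).all():
        raise ValueError("matrix must be finite")
    if np.ptp(m) == 0.0:
        raise ValueError("constant matrix cannot be clustered")
    cols = m.T  # observations = columns
    k_max = min(k_max, cols.shape[0])
    inertia = np.empty(k_max)
    fits = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_replicates, random_state=seed)
        km.fit(cols)
        inertia[k - 1] = km.inertia_
        fits.append(km)
    if k_max >= 3:
        second_diff = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
        k_best = int(np.argmax(second_diff)) + 2  # interior k = 2..k_max-1
    else:
        k_best = k_max
    km = fits[k_best - 1]
    return ClusterResult(
        k=k_best,
        centers=km.cluster_centers_,
        assignments=km.labels_,
        inertia_curve=inertia,
    )
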