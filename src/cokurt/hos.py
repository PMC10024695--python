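"""Higher-order statistics of complex signal pairs.

The central object of the package: the exact, finite-sample decomposition of
the power-envelope correlation between two zero-mean complex signals ``x`` and
``y`` (time-frequency coefficients or analytic signals) into three additive
contributions,

    r_{x,y} = ( |rho_{x,y}|^2 + K_{x,y} + |rho_{x,ybar}|^2 ) / D,
    D       = sqrt( (1 + K_x + |rho_{x,xbar}|^2) (1 + K_y + |rho_{y,ybar}|^2) ),

where ``rho`` is coherence, ``K`` kurtosis/cokurtosis (normalized fourth-order
cumulants), and ``rho_{x,ybar}`` the conjugate coherence.  The identity is an
algebraic rearrangement of the sample Pearson correlation of |x|^2 and |y|^2;
it holds exactly for every finite pair of signals, with no distributional or
stationarity assumptions.

All estimators here are plain sample moments: the identity is a statement
about sample quantities, so bias-corrected cumulant estimators would break it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComplexSignal",
    "HOSummary",
    "Decomposition",
    "demean",
    "joint_moment",
    "joint_cumulant",
    "normalized_cumulant",
    "coherence",
    "power_correlation",
    "kurtosis",
    "cokurtosis",
    "conjugate_coherence",
    "circularity_coefficient",
    "decompose",
    "nongauss_power_correlation",
    "relative_contribution",
    "summarize",
]

#: relative tolerance for the imaginary residue of theoretically real cumulants
_IMAG_RTOL = 1e-9
_IMAG_ATOL = 1e-12


@dataclass
class ComplexSignal:
    """A zero-mean complex sample sequence with a channel/region label.

    Thin container; every statistic in this module also accepts a bare
    ``ndarray``.  Fourth-order statistics need at least 4 samples.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if self.values.size < 4:
            raise ValueError("fourth-order statistics need at least 4 samples")

    def __len__(self) -> int:
        return self.values.size


def _as_array(x, demean_flag: bool = True) -> np.ndarray:
    v = x.values if isinstance(x, ComplexSignal) else np.asarray(x, dtype=complex)
    v = v.ravel()
    if v.size == 0:
        raise ValueError("empty signal")
    if demean_flag:
        v = v - v.mean()
    return v


def demean(x) -> np.ndarray:
    """Subtract the (complex) sample mean."""
    return _as_array(x, demean_flag=True)


def _power(v: np.ndarray) -> float:
    p = float(np.mean(np.abs(v) ** 2))
    if p == 0.0:
        raise ValueError("zero-power signal")
    return p


def joint_moment(*signals, demean: bool = True) -> complex:
    """Joint moment ``mu(x1,...,xd) = <x1 * ... * xd>``.

    Symmetric under permutation of its arguments and linear in each.  For the
    fourth-order statistics of this package ``d`` is 2 or 4; arbitrary ``d``
    is accepted.
    """
    if len(signals) == 0:
        raise ValueError("need at least one argument")
    arrs = [_as_array(s, demean) for s in signals]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("length mismatch between arguments")
    prod = arrs[0].copy()
    for a in arrs[1:]:
        prod *= a
    return complex(prod.mean())


def joint_cumulant(x1, x2, x3, x4, demean: bool = True) -> complex:
    """Fourth-order joint cumulant of four zero-mean complex variables.

    ``kappa = mu(1,2,3,4) - mu(1,2)mu(3,4) - mu(1,3)mu(2,4) - mu(1,4)mu(2,3)``
    (zero-mean case; the third- and first-order terms of the general formula
    vanish).  Symmetric and multilinear, zero for jointly Gaussian inputs.
    """
    a1, a2, a3, a4 = (_as_array(s, demean) for s in (x1, x2, x3, x4))
    n = a1.size
    if not (a2.size == a3.size == a4.size == n):
        raise ValueError("length mismatch between arguments")
    m1234 = np.mean(a1 * a2 * a3 * a4)
    m12 = np.mean(a1 * a2)
    m34 = np.mean(a3 * a4)
    m13 = np.mean(a1 * a3)
    m24 = np.mean(a2 * a4)
    m14 = np.mean(a1 * a4)
    m23 = np.mean(a2 * a3)
    return complex(m1234 - m12 * m34 - m13 * m24 - m14 * m23)


def normalized_cumulant(x1, x2, x3, x4, demean: bool = True) -> complex:
    """Dimensionless cumulant: ``kappa / sqrt(prod_i <|x_i|^2>)``."""
    arrs = [_as_array(s, demean) for s in (x1, x2, x3, x4)]
    norm = np.sqrt(np.prod([_power(a) for a in arrs]))
    return joint_cumulant(*arrs, demean=False) / norm


def coherence(x, y, demean: bool = True) -> complex:
    """Complex coherence ``rho = <x ybar> / sqrt(<|x|^2><|y|^2>)``; |rho| <= 1."""
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    if a.size != b.size:
        raise ValueError("length mismatch")
    return complex(np.mean(a * np.conj(b)) / np.sqrt(_power(a) * _power(b)))


def conjugate_coherence(x, y, demean: bool = True) -> complex:
    """Coherence between ``x`` and ``conj(y)``: ``<xy>/sqrt(<|x|^2><|y|^2>)``.

    Vanishes for jointly proper (circular) pairs; quantifies impropriety.
    """
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    if a.size != b.size:
        raise ValueError("length mismatch")
    return complex(np.mean(a * b) / np.sqrt(_power(a) * _power(b)))


def circularity_coefficient(x, demean: bool = True) -> complex:
    """Conjugate coherence of a signal with itself, ``<x^2>/<|x|^2>``.

    Zero iff real and imaginary parts have equal variance and are
    uncorrelated; 1 for a real-valued signal viewed as complex.
    """
    return conjugate_coherence(x, x, demean=demean)


def power_correlation(x, y, demean: bool = True) -> float:
    """Pearson correlation of the power envelopes |x|^2 and |y|^2."""
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    if a.size != b.size:
        raise ValueError("length mismatch")
    px = np.abs(a) ** 2
    py = np.abs(b) ** 2
    dx = px - px.mean()
    dy = py - py.mean()
    vx = np.mean(dx**2)
    vy = np.mean(dy**2)
    # constant-envelope degeneracy, allowing for float roundoff in |x|^2
    tol_x = (1e-12 * px.mean()) ** 2
    tol_y = (1e-12 * py.mean()) ** 2
    if vx <= tol_x or vy <= tol_y:
        raise ValueError("constant power envelope: power correlation undefined")
    return float(np.mean(dx * dy) / np.sqrt(vx * vy))


def _real_part(value: complex, what: str) -> float:
    if abs(value.imag) > _IMAG_RTOL * abs(value) + _IMAG_ATOL:
        raise AssertionError(
            f"{what} should be real; imaginary residue {value.imag:.3e}"
        )
    return value.real


def kurtosis(x, demean: bool = True) -> float:
    """Excess kurtosis ``K_x = kappa~(x, x, xbar, xbar)`` (real).

    Zero for complex Gaussian signals; -1 exactly for constant-modulus
    signals; positive for bursty (heavy-tailed envelope) signals.
    """
    a = _as_array(x, demean)
    k = normalized_cumulant(a, a, np.conj(a), np.conj(a), demean=False)
    return _real_part(k, "kurtosis")


def cokurtosis(x, y, demean: bool = True) -> float:
    """Excess cokurtosis ``K_{x,y} = kappa~(x, y, xbar, ybar)`` (real).

    Equals the covariance of the unit-normalized powers in excess of the value
    a proper Gaussian pair with the same coherence would have; measures
    co-occurrence of large envelope excursions.
    """
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    k = normalized_cumulant(a, b, np.conj(a), np.conj(b), demean=False)
    return _real_part(k, "cokurtosis")


@dataclass
class Decomposition:
    """Additive decomposition of the power correlation.

    ``reconstructed_r = term_coherence + term_cokurtosis + term_conj_coherence``
    reproduces the direct envelope Pearson correlation exactly (finite-sample
    identity).
    """

    term_coherence: float
    term_cokurtosis: float
    term_conj_coherence: float
    denominator: float
    reconstructed_r: float


def decompose(x, y, demean: bool = True) -> Decomposition:
    """Split r_{x,y} into coherence, cokurtosis and conjugate-coherence terms.

    Each returned term is the corresponding numerator entry
    (|rho|^2, K_{x,y}, |rho_{x,ybar}|^2) divided by the common denominator
    sqrt((1+K_x+|rho_{x,xbar}|^2)(1+K_y+|rho_{y,ybar}|^2)).
    """
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    if a.size != b.size:
        raise ValueError("length mismatch")
    rho = coherence(a, b, demean=False)
    rho_conj = conjugate_coherence(a, b, demean=False)
    kx = kurtosis(a, demean=False)
    ky = kurtosis(b, demean=False)
    kxy = cokurtosis(a, b, demean=False)
    cx = circularity_coefficient(a, demean=False)
    cy = circularity_coefficient(b, demean=False)
    dx = 1.0 + kx + abs(cx) ** 2
    dy = 1.0 + ky + abs(cy) ** 2
    if dx <= 0.0 or dy <= 0.0:
        raise ValueError("zero envelope variance: decomposition undefined")
    denom = float(np.sqrt(dx * dy))
    t_coh = abs(rho) ** 2 / denom
    t_kur = kxy / denom
    t_cc = abs(rho_conj) ** 2 / denom
    return Decomposition(
        term_coherence=t_coh,
        term_cokurtosis=t_kur,
        term_conj_coherence=t_cc,
        denominator=denom,
        reconstructed_r=t_coh + t_kur + t_cc,
    )


def nongauss_power_correlation(x, y, demean: bool = True) -> float:
    """Non-Gaussian power correlation ``r^e = K_{x,y}/sqrt((1+K_x)(1+K_y))``.

    The cokurtosis normalized by the envelope-power standard deviations of
    proper signals; the part of the power correlation that a Gaussian pair
    with the same coherence cannot produce.
    """
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    kx = kurtosis(a, demean=False)
    ky = kurtosis(b, demean=False)
    if 1.0 + kx <= 0.0 or 1.0 + ky <= 0.0:
        raise ValueError("degenerate denominator: 1+K must be positive")
    return cokurtosis(a, b, demean=False) / float(np.sqrt((1 + kx) * (1 + ky)))


def relative_contribution(x, y, demean: bool = True) -> float:
    """Relative contribution of squared-magnitude coherence to r_{x,y}.

    ``c = |rho|^2 / (|rho|^2 + K_{x,y})`` — the proper-signal form in which
    the conjugate-coherence terms are dropped.  The cokurtosis contribution is
    ``1 - c``.  Raises if the denominator vanishes.
    """
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    rho2 = abs(coherence(a, b, demean=False)) ** 2
    kxy = cokurtosis(a, b, demean=False)
    denom = rho2 + kxy
    if denom == 0.0:
        raise ValueError("zero denominator: relative contribution undefined")
    return float(rho2 / denom)


@dataclass
class HOSummary:
    """Per-pair bundle of all second- and fourth-order statistics."""

    coherence: complex
    conj_coherence: complex
    circ_x: complex
    circ_y: complex
    kurtosis_x: float
    kurtosis_y: float
    cokurtosis: float
    power_corr: float
    nongauss_power_corr: float
    contribution_coh: float
    n_samples: int

    _COLUMNS = (
        "coherence_re", "coherence_im", "conj_coherence_re", "conj_coherence_im",
        "circ_x_re", "circ_x_im", "circ_y_re", "circ_y_im",
        "kurtosis_x", "kurtosis_y", "cokurtosis",
        "power_corr", "nongauss_power_corr", "contribution_coh", "n_samples",
    )

    def as_row(self) -> dict:
        """Flatten to a dict of real-valued CSV columns."""
        return {
            "coherence_re": self.coherence.real,
            "coherence_im": self.coherence.imag,
            "conj_coherence_re": self.conj_coherence.real,
            "conj_coherence_im": self.conj_coherence.imag,
            "circ_x_re": self.circ_x.real,
            "circ_x_im": self.circ_x.imag,
            "circ_y_re": self.circ_y.real,
            "circ_y_im": self.circ_y.imag,
            "kurtosis_x": self.kurtosis_x,
            "kurtosis_y": self.kurtosis_y,
            "cokurtosis": self.cokurtosis,
            "power_corr": self.power_corr,
            "nongauss_power_corr": self.nongauss_power_corr,
            "contribution_coh": self.contribution_coh,
            "n_samples": self.n_samples,
        }


def summarize(x, y, demean: bool = True) -> HOSummary:
    """Compute the full higher-order summary for one signal pair."""
    a = _as_array(x, demean)
    b = _as_array(y, demean)
    if a.size != b.size:
        raise ValueError("length mismatch")
    rho = coherence(a, b, demean=False)
    kxy = cokurtosis(a, b, demean=False)
    rho2 = abs(rho) ** 2
    try:
        contrib = rho2 / (rho2 + kxy) if (rho2 + kxy) != 0.0 else float("nan")
    except ZeroDivisionError:  # pragma: no cover
        contrib = float("nan")
    return HOSummary(
        coherence=rho,
        conj_coherence=conjugate_coherence(a, b, demean=False),
        circ_x=circularity_coefficient(a, demean=False),
        circ_y=circularity_coefficient(b, demean=False),
        kurtosis_x=kurtosis(a, demean=False),
        kurtosis_y=kurtosis(b, demean=False),
        cokurtosis=kxy,
        power_corr=power_correlation(a, b, demean=False),
        nongauss_power_corr=nongauss_power_correlation(a, b, demean=False),
        contribution_coh=contrib,
        n_samples=a.size,
    )
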