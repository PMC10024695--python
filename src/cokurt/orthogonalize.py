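"""Instantaneous leakage-removal orthogonalization.

Reconstructed source signals in electrophysiology share zero-lag components
through volume conduction / incomplete unmixing ("signal leakage").  The
standard remedy subtracts from ``y`` the instantaneous linear contribution of
``x``:

    y_perp = y - alpha * x,   alpha = sqrt(<|y|^2>/<|x|^2>) * Re(rho_{x,y}),

which leaves the cross-spectrum between ``x`` and ``y_perp`` purely imaginary.
This module implements the operation together with the closed-form
post-orthogonalization coherence, cokurtosis and coherence-contribution
formulas, which are finite-sample identities and are asserted against direct
re-estimation on ``y_perp`` in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hos

__all__ = [
    "OrthoResult",
    "orthogonalize",
    "predicted_coherence_sq",
    "predicted_cokurtosis",
    "orthogonalized_contribution",
]

_COLLINEAR_TOL = 1e-12


@dataclass
class OrthoResult:
    """Orthogonalized signal plus the closed-form predicted statistics."""

    alpha: float
    y_perp: np.ndarray
    predicted_coh_sq: float
    predicted_cokurtosis: float
    predicted_contribution: float
    eta: float


def _prep(x, y):
    a = hos.demean(x)
    b = hos.demean(y)
    if a.size != b.size:
        raise ValueError("length mismatch")
    return a, b


def orthogonalize(y, x, demean: bool = True) -> OrthoResult:
    """Orthogonalize ``y`` with respect to ``x`` (note the argument order).

    Not symmetric: removing x's leakage from y differs from the reverse.
    Raises for collinear inputs (|Re rho| = 1), where y_perp carries no
    independent signal.
    """
    a, b = _prep(x, y) if demean else (np.asarray(x, complex), np.asarray(y, complex))
    rho = hos.coherence(a, b, demean=False)
    re2 = rho.real**2
    if re2 >= 1.0 - _COLLINEAR_TOL:
        raise ValueError("collinear signals: |Re(rho)| = 1, orthogonalization degenerate")
    px = float(np.mean(np.abs(a) ** 2))
    py = float(np.mean(np.abs(b) ** 2))
    alpha = np.sqrt(py / px) * rho.real
    y_perp = b - alpha * a
    # cross-spectrum of (x, y_perp) is purely imaginary by construction
    cross = np.mean(a * np.conj(y_perp))
    scale = np.sqrt(px * float(np.mean(np.abs(y_perp) ** 2)))
    if abs(cross.real) > 1e-10 * scale:
        raise AssertionError("post-orthogonalization cross-spectrum not imaginary")
    coh_sq = predicted_coherence_sq(a, b, demean=False)
    kxyp = predicted_cokurtosis(a, b, demean=False)
    contrib, eta = orthogonalized_contribution(a, b, demean=False)
    return OrthoResult(
        alpha=float(alpha),
        y_perp=y_perp,
        predicted_coh_sq=coh_sq,
        predicted_cokurtosis=kxyp,
        predicted_contribution=contrib,
        eta=eta,
    )


def predicted_coherence_sq(x, y, demean: bool = True) -> float:
    """Closed-form |rho_{x,y_perp}|^2 = Im(rho)^2 / (1 - Re(rho)^2)."""
    a, b = _prep(x, y) if demean else (np.asarray(x, complex), np.asarray(y, complex))
    rho = hos.coherence(a, b, demean=False)
    re2 = rho.real**2
    if re2 >= 1.0 - _COLLINEAR_TOL:
        raise ValueError("degenerate denominator: Re(rho)^2 = 1")
    return float(rho.imag**2 / (1.0 - re2))


def predicted_cokurtosis(x, y, demean: bool = True, neglect_mixed: bool = False) -> float:
    """Closed-form cokurtosis between ``x`` and ``y_perp``.

    K_{x,y_perp} = (K_{x,y} - 2 Re(kappa~(x,y,xbar,xbar)) Re(rho)
                    + K_x Re(rho)^2) / (1 - Re(rho)^2).

    With ``neglect_mixed=True`` the mixed-cumulant cross term
    ``2 Re(kappa~(x,y,xbar,xbar)) Re(rho)`` is dropped — the small-term
    approximation used when only the marginal and pair cumulants are
    available.  The full formula is a finite-sample identity.
    """
    a, b = _prep(x, y) if demean else (np.asarray(x, complex), np.asarray(y, complex))
    rho = hos.coherence(a, b, demean=False)
    re = rho.real
    if re**2 >= 1.0 - _COLLINEAR_TOL:
        raise ValueError("degenerate denominator: Re(rho)^2 = 1")
    kxy = hos.cokurtosis(a, b, demean=False)
    kx = hos.kurtosis(a, demean=False)
    num = kxy + kx * re**2
    if not neglect_mixed:
        mixed = hos.normalized_cumulant(a, b, np.conj(a), np.conj(a), demean=False)
        num -= 2.0 * mixed.real * re
    return float(num / (1.0 - re**2))


def orthogonalized_contribution(x, y, demean: bool = True) -> tuple[float, float]:
    """Predicted coherence contribution after orthogonalization, and eta.

    Returns ``(c_{x,y_perp}, eta_{x,y})`` where

        c = Im(rho)^2 / (Im(rho)^2 + K_{x,y} + K_x Re(rho)^2)

    (mixed-cumulant term neglected) and

        eta = K_x Re(rho)^2 + cot^2(phi) (K_{x,y} + K_x Re(rho)^2),

    phi = arg(rho).  eta quantifies how much orthogonalization depresses the
    coherence contribution: with K_x, K_{x,y} >= 0 it is non-negative, so the
    contribution can only decrease.  For phi = 0 (zero-lag coherence) the
    contribution collapses to 0 and the orthogonalized power correlation
    reduces to the non-Gaussian power correlation.
    """
    a, b = _prep(x, y) if demean else (np.asarray(x, complex), np.asarray(y, complex))
    rho = hos.coherence(a, b, demean=False)
    kx = hos.kurtosis(a, demean=False)
    kxy = hos.cokurtosis(a, b, demean=False)
    im2 = rho.imag**2
    re2 = rho.real**2
    extra = kxy + kx * re2
    if im2 == 0.0:
        # zero expected phase difference: coherence contribution vanishes
        c = 0.0
        eta = float("inf") if extra > 0 else kx * re2
        return c, eta
    c = float(im2 / (im2 + extra))
    phi = np.angle(rho)
    cot2 = (np.cos(phi) / np.sin(phi)) ** 2
    eta = float(kx * re2 + cot2 * extra)
    return c, eta
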