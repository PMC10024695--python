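"""Point-process burst extraction and co-occurrence matrices.

A burst is a sample where the standardized real part of a band-limited
analytic signal exceeds a threshold (default 3 SD).  Burst co-occurrence
between two channels is the mean of the product of their binary burst
indicators — the empirical probability of simultaneous bursts.  For a
standardized Gaussian real part the expected burst rate is 2(1 - Phi(3))
~= 0.0027, and independent channels co-occur at the product of their rates.

Complex signals are z-scored so that the REAL PART has zero mean and unit
standard deviation, which makes the threshold directly interpretable in SD
units of the thresholded quantity.  By propriety the imaginary part then has
(asymptotically) unit SD as well, so thresholding it instead gives the same
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orthogonalize import orthogonalize

__all__ = [
    "BurstRaster",
    "standardize",
    "binarize_bursts",
    "burst_cooccurrence",
    "cooccurrence_matrix",
]


@dataclass
class BurstRaster:
    """Binary burst indicators (channels x samples) with per-channel rates."""

    indicator: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.indicator = np.atleast_2d(np.asarray(self.indicator))
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")
        self.indicator = self.indicator.astype(np.uint8)

    @property
    def rate(self) -> np.ndarray:
        return self.indicator.mean(axis=1)


def standardize(x) -> np.ndarray:
    """Z-score a complex signal to zero mean and unit real-part SD."""
    v = np.asarray(x, dtype=complex).ravel()
    v = v - v.mean()
    sd = v.real.std()
    if sd == 0.0:
        raise ValueError("zero-variance real part: cannot standardize")
    return v / sd


def binarize_bursts(x, threshold: float = 3.0, standardized: bool = False) -> np.ndarray:
    """Binary burst indicator: 1 where |Re(x')| exceeds ``threshold``.

    ``x`` is z-scored first unless ``standardized`` says it already is.
    An all-zero raster (no threshold crossings) is a valid outcome.
    """
    v = np.asarray(x, dtype=complex).ravel()
    if not standardized:
        v = standardize(v)
    return (np.abs(v.real) > threshold).astype(np.uint8)


def burst_cooccurrence(bx: np.ndarray, by: np.ndarray) -> float:
    """Fraction of samples where both channels burst: (1/n) sum(bx * by)."""
    bx = np.asarray(bx).ravel()
    by = np.asarray(by).ravel()
    if bx.size != by.size:
        raise ValueError("length mismatch")
    if bx.size == 0:
        raise ValueError("empty raster")
    return float(np.mean(bx.astype(float) * by.astype(float)))


def _pair_cooccurrence(x, y, threshold: float) -> float:
    """Co-occurrence for one ordered pair: z-score, orthogonalize y to x, binarize."""
    xp = standardize(x)
    yp = standardize(y)
    y_perp = orthogonalize(yp, xp, demean=False).y_perp
    bx = binarize_bursts(xp, threshold, standardized=True)
    byp = binarize_bursts(y_perp, threshold)
    return burst_cooccurrence(bx, byp)


def cooccurrence_matrix(
    signals,
    threshold: float = 3.0,
    symmetrize: bool = True,
) -> np.ndarray:
    """Burst co-occurrence matrix for one subject or a cohort.

    ``signals`` is a (channels x samples) complex array (one subject) or a
    sequence of such arrays (a cohort; subject matrices are averaged).  For an
    ordered pair (i, j), channel j is orthogonalized to channel i before
    binarization; with ``symmetrize`` the two directed values are averaged.
    The diagonal holds plain burst rates.
    """
    if isinstance(signals, np.ndarray) and signals.ndim == 2:
        subjects = [signals]
    else:
        subjects = [np.atleast_2d(np.asarray(s, dtype=complex)) for s in signals]
    p = subjects[0].shape[0]
    out = np.zeros((p, p))
    for subj in subjects:
        if subj.shape[0] != p:
            raise ValueError("subjects have differing channel counts")
        m = np.zeros((p, p))
        rasters = [binarize_bursts(subj[i], threshold) for i in range(p)]
        for i in range(p):
            m[i, i] = rasters[i].mean()
            for j in range(i + 1, p):
                cij = _pair_cooccurrence(subj[i], subj[j], threshold)
                if symmetrize:
                    cji = _pair_cooccurrence(subj[j], subj[i], threshold)
                    m[i, j] = m[j, i] = 0.5 * (cij + cji)
                else:
                    m[i, j] = cij
                    m[j, i] = _pair_cooccurrence(subj[j], subj[i], threshold)
        out += m
    return out / len(subjects)
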