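"""Phasor transform of decay histograms and phasor algebra.

The phasor maps every decay histogram to a point (g, s): the real and
imaginary components of the Fourier transform of the raw, photon-normalized
histogram evaluated at (a harmonic of) the laser repetition frequency,

    g = sum_i k_i cos(w t_i) / sum_i k_i,
    s = sum_i k_i sin(w t_i) / sum_i k_i,

with t_i the bin centers.  No fitting is involved, which makes the phasor
fast and model-free; mono-exponential decays lie on the universal
semicircle g^2 + s^2 = g, and photon-weighted mixtures combine linearly.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .flim_core import PhasorPoint, TimingCalibration

__all__ = [
    "phasor_from_histogram",
    "phasor_of_monoexponential",
    "phasor_mixture",
    "phasor_summary",
]


def phasor_from_histogram(
    hist: np.ndarray,
    calib: TimingCalibration,
    harmonic: int = 1,
) -> PhasorPoint:
    """First-harmonic (or higher) phasor of a raw decay histogram.

    Computed directly on the raw counts — no decay fitting and no IRF
    correction — matching the convention of evaluating the Fourier
    transform at the repetition frequency of the laser.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size != calib.n_bins:
        raise ValueError("histogram length must match calibration n_bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("cannot compute the phasor of an empty histogram")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = harmonic * calib.angular_frequency
    t = calib.bin_centers_s()
    g = float(np.dot(hist, np.cos(omega * t)) / total)
    s = float(np.dot(hist, np.sin(omega * t)) / total)
    return PhasorPoint(g=g, s=s, harmonic=harmonic, n_photons=int(round(total)))


def phasor_of_monoexponential(tau_s: float, omega: float) -> PhasorPoint:
    """Closed-form phasor of a mono-exponential decay with lifetime tau.

    g = 1 / (1 + (w tau)^2), s = w tau / (1 + (w tau)^2); the point lies
    exactly on the universal semicircle g^2 + s^2 = g.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    wt = omega * tau_s
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom)


def phasor_mixture(
    points: Sequence[PhasorPoint],
    photon_weights: Sequence[float],
) -> PhasorPoint:
    """Photon-weighted average of phasor points.

    By linearity of the Fourier transform this equals the phasor of the
    summed histograms when the weights are the photon totals.
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    if len(points) != len(photon_weights):
        raise ValueError("points and photon_weights must have equal length")
    w = np.asarray(photon_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("photon_weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("photon_weights must not all be zero")
    g = float(np.dot(w, [p.g for p in points]) / wsum)
    s = float(np.dot(w, [p.s for p in points]) / wsum)
    harmonic = points[0].harmonic
    return PhasorPoint(g=g, s=s, harmonic=harmonic, n_photons=int(round(wsum)))


def phasor_summary(points: Iterable[PhasorPoint]) -> Tuple[float, float, float, float]:
    """Per-image phasor summary: (mean g, mean s, SD g, SD s).

    Sample standard deviations (ddof=1); at least two points are required.
    This is the summary used to compare the spread of cell-encircled versus
    pixel-wise phasor clouds and to drive the power analysis.
    """
    pts: List[PhasorPoint] = list(points)
    if len(pts) < 2:
        raise ValueError("phasor_summary needs at least two points")
    g = np.array([p.g for p in pts])
    s = np.array([p.s for p in pts])
    return (
        float(g.mean()),
        float(s.mean()),
        float(g.std(ddof=1)),
        float(s.std(ddof=1)),
    )
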