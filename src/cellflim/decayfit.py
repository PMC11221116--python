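"""Bi-exponential decay model and Poisson maximum-likelihood fitting.

A TCSPC histogram records Poisson-distributed photon counts whose
expectation follows the fluorescence impulse response, periodically wrapped
at the laser repetition period and blurred by the instrument response
function (IRF).  The underlying decay is a1*exp(-t/tau1) + a2*exp(-t/tau2)
with *amplitude* weights a1 + a2 = 1 (the convention of the printed
tau_m = a1*tau1 + a2*tau2); component i then contributes the photon
fraction phi_i = a_i*tau_i / (a1*tau1 + a2*tau2), and the expected counts
are

    m_i = N * [ phi1 * w(t_i; tau1) + phi2 * w(t_i; tau2) ] + b

where w(t; tau) is the normalized, periodically wrapped, IRF-convolved
mono-exponential profile (sum_i w = 1), N the total model photons, and b a
constant background per bin — so sum_i m_i = N + n_bins*b exactly.
Parameters are estimated by minimizing the Poisson negative log-likelihood
sum_i [m_i - k_i ln m_i] with a bounded quasi-Newton optimizer in the
photon-fraction parameterization (better conditioned) and deterministic
multi-start over a log-spaced (tau1, tau2) grid; no randomness is
involved, so fits are reproducible.  Reported amplitude weights are exact
conversions of the fitted photon fraction.

Histograms below the photon-count threshold (default 300) are rejected with
:class:`BelowThresholdError` rather than fitted, because low-count
bi-exponential fits are unreliable.  Results are canonicalized so
``tau1 <= tau2`` and ``a1`` is the short component's normalized amplitude;
the amplitude-weighted mean lifetime ``tau_m = a1*tau1 + a2*tau2`` and the
Pearson reduced chi-square accompany every fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize

from .flim_core import DecayFitResult, FitConfig, FlimError, TimingCalibration

__all__ = [
    "BelowThresholdError",
    "DecayModelParams",
    "amplitude_to_photon_fraction",
    "photon_to_amplitude_fraction",
    "gaussian_irf_kernel",
    "model_decay",
    "fit_biexponential",
    "mean_lifetime",
    "reduced_chi_square",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class BelowThresholdError(FlimError):
    """Histogram has fewer photons than the fitting threshold."""


def amplitude_to_photon_fraction(a1: float, tau1_ps: float, tau2_ps: float) -> float:
    """Photon fraction of component 1 from its amplitude fraction."""
    num = a1 * tau1_ps
    return num / (num + (1.0 - a1) * tau2_ps)


def photon_to_amplitude_fraction(phi1: float, tau1_ps: float, tau2_ps: float) -> float:
    """Amplitude fraction of component 1 from its photon fraction."""
    num = phi1 / tau1_ps
    return num / (num + (1.0 - phi1) / tau2_ps)


@dataclass
class DecayModelParams:
    """Forward-model parameters of a bi-exponential decay.

    ``f1`` is the *amplitude* fraction of component 1 (the a1 of
    tau_m = a1*tau1 + a2*tau2), not its share of detected photons.
    """

    tau1_ps: float
    tau2_ps: float
    f1: float
    total_counts: float
    background_per_bin: float = 0.0
    shift_bins: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1_ps <= 0 or self.tau2_ps <= 0:
            raise ValueError("lifetimes must be positive")
        if not (0.0 <= self.f1 <= 1.0):
            raise ValueError("f1 must lie in [0, 1]")
        if self.total_counts < 0:
            raise ValueError("total_counts must be non-negative")
        if self.background_per_bin < 0:
            raise ValueError("background_per_bin must be non-negative")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def gaussian_irf_kernel(
    calib: TimingCalibration,
    fwhm_ps: float,
    center_bins: float = 0.0,
) -> np.ndarray:
    """Discrete Gaussian IRF kernel (sums to 1) for circular convolution.

    ``center_bins`` places the IRF peak at that (possibly fractional) bin
    offset, which doubles as the timing-shift parameter of the model.
    """
    if fwhm_ps <= 0:
        raise ValueError("fwhm_ps must be positive")
    sigma_bins = (fwhm_ps * _FWHM_TO_SIGMA) / calib.bin_width_ps
    half = max(1, int(math.ceil(4.0 * sigma_bins + abs(center_bins))))
    half = min(half, calib.n_bins // 2)
    offsets = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * ((offsets - center_bins) / sigma_bins) ** 2)
    return k / k.sum()


def _wrapped_basis(tau_ps: float, t_ps: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized wrapped mono-exponential profile and its d/d(ln tau).

    Periodic wrapping multiplies the raw exponential by a constant
    (1 / (1 - exp(-T/tau))) that cancels under normalization, so the
    normalized profile on one period is simply exp(-t/tau)/sum.
    """
    u = np.exp(-t_ps / tau_ps)
    su = u.sum()
    w = u / su
    # d w / d ln(tau): u' = u * t / tau  (per ln-tau), then quotient rule
    v = u * (t_ps / tau_ps)
    dw = (v - u * (v.sum() / su)) / su
    return w, dw


def _convolve(x: np.ndarray, kernel: Optional[np.ndarray]) -> np.ndarray:
    if kernel is None:
        return x
    return ndimage.convolve1d(x, kernel, mode="wrap")


def model_decay(
    params: DecayModelParams,
    calib: TimingCalibration,
    irf_fwhm_ps: Optional[float] = None,
) -> np.ndarray:
    """Expected counts per bin for a bi-exponential decay.

    The profile is normalized so that the model photons sum to
    ``total_counts`` plus ``n_bins * background_per_bin`` exactly (circular
    IRF convolution preserves the normalization).
    """
    t = calib.bin_centers_ps()
    kernel = None
    if irf_fwhm_ps is not None:
        kernel = gaussian_irf_kernel(calib, irf_fwhm_ps, center_bins=params.shift_bins)
    elif params.shift_bins:
        shift = int(round(params.shift_bins))
        if shift != params.shift_bins:
            raise ValueError("fractional shift_bins requires an IRF kernel")
    w1, _ = _wrapped_basis(params.tau1_ps, t)
    w2, _ = _wrapped_basis(params.tau2_ps, t)
    phi1 = amplitude_to_photon_fraction(params.f1, params.tau1_ps, params.tau2_ps)
    w = phi1 * w1 + (1.0 - phi1) * w2
    if kernel is not None:
        w = _convolve(w, kernel)
    elif params.shift_bins:
        w = np.roll(w, int(round(params.shift_bins)))
    return params.total_counts * w + params.background_per_bin


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

def _nll_and_grad(
    x: np.ndarray,
    k: np.ndarray,
    t: np.ndarray,
    kernel: Optional[np.ndarray],
    fit_background: bool,
    include: Optional[np.ndarray],
) -> Tuple[float, np.ndarray]:
    """Poisson negative log-likelihood and analytic gradient.

    Parameter vector: [ln tau1, ln tau2, phi1, ln N, (b)] with phi1 the
    photon fraction of component 1 (converted to an amplitude fraction
    only when reporting).
    """
    lt1, lt2, f1, lN = x[:4]
    b = x[4] if fit_background else 0.0
    tau1, tau2, N = math.exp(lt1), math.exp(lt2), math.exp(lN)
    w1, dw1 = _wrapped_basis(tau1, t)
    w2, dw2 = _wrapped_basis(tau2, t)
    if kernel is not None:
        w1, dw1 = _convolve(w1, kernel), _convolve(dw1, kernel)
        w2, dw2 = _convolve(w2, kernel), _convolve(dw2, kernel)
    shape = f1 * w1 + (1.0 - f1) * w2
    m = N * shape + b
    if include is not None:
        m = m[include]
        k = k[include]
        w1v, w2v = w1[include], w2[include]
        dw1v, dw2v = dw1[include], dw2[include]
        shape_v = shape[include]
    else:
        w1v, w2v, dw1v, dw2v, shape_v = w1, w2, dw1, dw2, shape
    m = np.maximum(m, 1e-12)
    nll = float(m.sum() - np.dot(k, np.log(m)))
    r = 1.0 - k / m  # d nll / d m_i
    g = np.empty_like(x)
    g[0] = N * f1 * np.dot(r, dw1v)
    g[1] = N * (1.0 - f1) * np.dot(r, dw2v)
    g[2] = N * np.dot(r, w1v - w2v)
    g[3] = N * np.dot(r, shape_v)
    if fit_background:
        g[4] = float(r.sum())
    return nll, g


def _tail_include(hist: np.ndarray) -> np.ndarray:
    """Bins strictly after the histogram peak + 1 (classic tail fit)."""
    peak = int(np.argmax(hist))
    include = np.zeros(hist.size, dtype=bool)
    include[min(peak + 1, hist.size - 1):] = True
    return include


def fit_biexponential(
    hist: np.ndarray,
    calib: TimingCalibration,
    config: Optional[FitConfig] = None,
) -> DecayFitResult:
    """Fit a bi-exponential decay to a histogram by Poisson MLE.

    Raises :class:`BelowThresholdError` when the histogram holds fewer than
    ``config.min_photons`` photons, and ``ValueError`` for an all-zero
    histogram.  Non-convergence after all starts still returns the best
    parameters with ``converged=False``.
    """
    if config is None:
        config = FitConfig()
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size != calib.n_bins:
        raise ValueError(
            f"histogram length {hist.size} does not match calibration n_bins "
            f"{calib.n_bins}"
        )
    total = float(hist.sum())
    if total <= 0:
        raise ValueError("cannot fit an all-zero histogram")
    if total < config.min_photons:
        raise BelowThresholdError(
            f"histogram has {total:.0f} photons, below the {config.min_photons}"
            " photon threshold"
        )

    t = calib.bin_centers_ps()
    kernel = None
    if config.irf_fwhm_ps is not None:
        kernel = gaussian_irf_kernel(
            calib, config.irf_fwhm_ps, center_bins=config.shift_bins
        )
    include = None
    if config.fit_from_peak and kernel is None:
        include = _tail_include(hist)

    lo, hi = config.tau_bounds_ps
    n_bins = calib.n_bins
    b0 = 0.1 * total / n_bins if config.fit_background else 0.0
    lN0 = math.log(max(total - n_bins * b0, 1.0))

    # deterministic multi-start: coarse NLL screen on a 4x4 log-spaced tau
    # grid, then quasi-Newton refinement of the best n_starts candidates
    grid = np.geomspace(max(lo, 3.0 * calib.bin_width_ps), min(hi, 8000.0), 4)
    starts = []
    for ta, tb in product(grid, grid):
        x0 = np.array(
            [math.log(min(ta, tb)), math.log(max(ta, tb)), 0.5, lN0]
            + ([b0] if config.fit_background else [])
        )
        nll0, _ = _nll_and_grad(x0, hist, t, kernel, config.fit_background, include)
        starts.append((nll0, x0))
    starts.sort(key=lambda p: p[0])

    bounds = [
        (math.log(lo), math.log(hi)),
        (math.log(lo), math.log(hi)),
        (1e-6, 1.0 - 1e-6),
        (lN0 - 4.0, lN0 + 4.0),
    ]
    if config.fit_background:
        bounds.append((0.0, total / n_bins))

    best = None
    seen = set()
    for nll0, x0 in starts[: max(config.n_starts, 1)]:
        key = (round(x0[0], 6), round(x0[1], 6))
        if key in seen:
            continue
        seen.add(key)
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(hist, t, kernel, config.fit_background, include),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tolerance},
        )
        if best is None or res.fun < best.fun:
            best = res

    x = best.x
    tau_a, tau_b = math.exp(x[0]), math.exp(x[1])
    phi_a = float(x[2])  # photon fraction of component a
    N = math.exp(x[3])
    b = float(x[4]) if config.fit_background else 0.0
    amp_a = photon_to_amplitude_fraction(phi_a, tau_a, tau_b)
    # canonical order: component 1 is the short lifetime
    if tau_a <= tau_b:
        tau1, tau2, a1 = tau_a, tau_b, amp_a
    else:
        tau1, tau2, a1 = tau_b, tau_a, 1.0 - amp_a
    a2 = 1.0 - a1

    params = DecayModelParams(
        tau1_ps=tau1, tau2_ps=tau2, f1=a1, total_counts=N,
        background_per_bin=b, shift_bins=config.shift_bins,
    )
    model = model_decay(params, calib, irf_fwhm_ps=config.irf_fwhm_ps)
    n_free = 4 + (1 if config.fit_background else 0)
    if include is not None:
        chi2 = reduced_chi_square(hist[include], model[include], n_free)
    else:
        chi2 = reduced_chi_square(hist, model, n_free)

    return DecayFitResult(
        tau1_ps=tau1,
        tau2_ps=tau2,
        a1=a1,
        a2=a2,
        tau_m_ps=a1 * tau1 + a2 * tau2,
        amplitude=N,
        background=b,
        shift_bins=config.shift_bins,
        chi2_reduced=chi2,
        n_photons=int(round(total)),
        converged=bool(best.success),
    )


def mean_lifetime(fit: DecayFitResult) -> float:
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + a2*tau2 (ps)."""
    return fit.a1 * fit.tau1_ps + fit.a2 * fit.tau2_ps


def reduced_chi_square(
    hist: np.ndarray,
    model_counts: np.ndarray,
    n_free_params: int,
) -> float:
    """Pearson reduced chi-square over bins with model expectation >= 1.

    Bins with expectation below one photon are excluded because the Pearson
    statistic is unstable at near-zero expectation.
    """
    hist = np.asarray(hist, dtype=float)
    model_counts = np.asarray(model_counts, dtype=float)
    if hist.shape != model_counts.shape:
        raise ValueError("hist and model_counts must have the same shape")
    inc = model_counts >= 1.0
    dof = int(inc.sum()) - n_free_params
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    resid = hist[inc] - model_counts[inc]
    return float(np.sum(resid**2 / model_counts[inc]) / dof)
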