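"""Multi-tensor diffusion (MTD) forward model.

A voxel's fODF peaks define a mixture of axisymmetric Gaussian tensors that
all share one eigenvalue pair (lambda_par, lambda_perp).  The pair is not
fitted: it is pinned uniquely by (a) the deconvolution ratio
R = lambda_par / lambda_perp of the kernel candidate and (b) the spherical
mean of the measured diffusion signal, which for axisymmetric tensors has the
closed form

    Sbar = exp(-b lambda_perp) * sqrt(pi) * erf(sqrt(b Delta)) / (2 sqrt(b Delta)),
    Delta = lambda_par - lambda_perp.

The spherical mean is orientation- and dispersion-invariant and is closed
under mixtures with shared eigenvalues, so the constraint transfers from the
single-tensor formula to the whole MTD mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .sphere import GradientScheme, PeakSet

__all__ = [
    "MTDFit",
    "spherical_mean_signal",
    "eigenvalues_from_constraint",
    "lambda_perp_from_constraint",
    "mtd_predict",
]

LAMBDA_BOUNDS = (1e-6, 4e-3)  # diffusivity search bounds, mm^2/s


@dataclass
class MTDFit:
    """One voxel's multi-tensor reconstruction for one kernel-ratio candidate."""

    peaks: PeakSet
    fractions: np.ndarray
    eigenvalues: tuple[float, float]  # (lambda_par, lambda_perp), mm^2/s
    predicted: np.ndarray             # Shat(g) per direction, b0-normalized
    loglik: float
    ratio: float

    @property
    def k(self) -> int:
        """Parameter count: three MTD parameters per orientation."""
        return 3 * self.peaks.nufo

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


def _erf_ratio(x2: np.ndarray) -> np.ndarray:
    """sqrt(pi) * erf(sqrt(x2)) / (2 sqrt(x2)), series-expanded near 0.

    x2 = b * Delta; the series keeps the isotropic limit (value 1) exact and
    numerically stable for b*Delta below ~1e-9.
    """
    x2 = np.asarray(x2, dtype=float)
    small = x2 < 1e-9
    safe = np.where(small, 1.0, x2)
    x = np.sqrt(safe)
    full = np.sqrt(np.pi) * erf(x) / (2.0 * x)
    series = 1.0 - x2 / 3.0 + x2 * x2 / 10.0
    return np.where(small, series, full)


def spherical_mean_signal(lambda_par, lambda_perp, bvalue) -> np.ndarray:
    """Analytic direction-averaged signal of an axisymmetric tensor at b."""
    lambda_par = np.asarray(lambda_par, dtype=float)
    lambda_perp = np.asarray(lambda_perp, dtype=float)
    delta = lambda_par - lambda_perp
    return np.exp(-bvalue * lambda_perp) * _erf_ratio(bvalue * delta)


def lambda_perp_from_constraint(
    ratio,
    spherical_mean,
    bvalue: float,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
    tol: float = 1e-12,
    clamp: bool = False,
) -> np.ndarray:
    """Vectorized inversion of the spherical-mean constraint for lambda_perp.

    Solves Sbar(lambda_perp; R, b) = spherical_mean by bisection (the mean is
    strictly decreasing in lambda_perp at fixed R).  With ``clamp=True``,
    out-of-range means (possible under noise) are clamped to the attainable
    interval instead of raising.
    """
    ratio = np.asarray(ratio, dtype=float)
    sbar = np.asarray(spherical_mean, dtype=float)
    if np.any(ratio < 1.0):
        raise ValueError("ratio must be >= 1")

    lo, hi = bounds

    def f(lperp):
        return spherical_mean_signal(ratio * lperp, lperp, bvalue)

    s_hi, s_lo = f(np.full_like(sbar + ratio, lo)), f(np.full_like(sbar + ratio, hi))
    if clamp:
        sbar = np.clip(sbar, s_lo, s_hi)
    else:
        if np.any(sbar >= 1.0) or np.any(sbar <= 0.0):
            raise ValueError("spherical_mean must lie strictly in (0, 1)")
        if np.any(sbar > s_hi) or np.any(sbar < s_lo):
            raise ValueError(
                f"no root for spherical mean within diffusivity bounds {bounds} mm^2/s"
            )

    a = np.full_like(sbar, lo)
    b = np.full_like(sbar, hi)
    # ~50 bisection halvings bring the bracket below 1e-12 mm^2/s
    for _ in range(60):
        m = 0.5 * (a + b)
        too_high = f(m) > sbar  # mean too large -> lambda_perp too small
        a = np.where(too_high, m, a)
        b = np.where(too_high, b, m)
        if np.max(b - a) < tol:
            break
    return 0.5 * (a + b)


def eigenvalues_from_constraint(
    ratio: float,
    spherical_mean: float,
    bvalue: float,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> tuple[float, float]:
    """(lambda_par, lambda_perp) pinned by ratio and the spherical mean."""
    lperp = float(lambda_perp_from_constraint(ratio, spherical_mean, bvalue, bounds))
    return ratio * lperp, lperp


def mtd_predict(
    peaks: PeakSet,
    eigenvalues: tuple[float, float],
    scheme: GradientScheme,
) -> np.ndarray:
    """b0-normalized MTD signal prediction Shat(g).

    Shat(g) = sum_i f_i exp(-b g^T D_i g) with D_i the shared-eigenvalue
    axisymmetric tensor along peak i and volume fractions f_i taken from the
    peak amplitudes, normalized to sum to 1.
    """
    if peaks.nufo < 1:
        raise ValueError("empty PeakSet: no orientations to predict from")
    lpar, lperp = eigenvalues
    if not (lpar >= lperp > 0):
        raise ValueError("require lambda_par >= lambda_perp > 0")
    frac = peaks.amplitudes / peaks.amplitudes.sum()
    cos2 = (scheme.directions @ peaks.orientations.T) ** 2  # (ndir, npk)
    b = scheme.bvalues[:, None]
    sig = np.exp(-b * (lperp + (lpar - lperp) * cos2))
    return sig @ frac


def mtd_predict_batch(
    orientations: np.ndarray,
    fractions: np.ndarray,
    lambda_par: np.ndarray,
    lambda_perp: np.ndarray,
    scheme: GradientScheme,
) -> np.ndarray:
    """Vectorized MTD prediction across voxels.

    orientations: (nvox, kmax, 3) zero-padded; fractions: (nvox, kmax) with
    padding weight 0; eigenvalues: (nvox,).  Returns (nvox, ndir).
    """
    cos2 = np.einsum("vkc,dc->vkd", orientations, scheme.directions) ** 2
    b = scheme.bvalues[None, None, :]
    expo = -b * (lambda_perp[:, None, None]
                 + (lambda_par - lambda_perp)[:, None, None] * cos2)
    return np.einsum("vk,vkd->vd", fractions, np.exp(expo))
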