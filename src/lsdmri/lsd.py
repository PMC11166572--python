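"""The LSD model-selection engine.

Per voxel, every kernel-ratio candidate in the bank is scored: the CSA dODF
is sharpened into an fODF candidate (SDT), its peaks become a multi-tensor
signal prediction whose eigenvalues are pinned by the spherical-mean
constraint, and the candidate's Gaussian log-likelihood against the measured
signal yields an AIC (2k - 2 ln L with k = 3 NuFO).  AIC maps are spatially
smoothed (or pooled over a 3x3x3 patch), the argmin candidate is selected,
and its fODF / NuFO / ratio are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from . import mtd
from .recon import (
    DWIVolume,
    KernelBank,
    csa_transform,
    kernel_rh_batch,
    sdt_constrained_batch,
)
from .sphere import extract_peaks_batch, n_coefficients, sphere_grid

log = logging.getLogger(__name__)

__all__ = [
    "LSDConfig",
    "LSDResult",
    "gaussian_loglik",
    "aic_score",
    "smooth_aic_stack",
    "lsd_fit_signals",
    "run_lsd",
    "default_simulation_bank",
    "default_realdata_bank",
]

MAX_PEAKS = 5  # cap on orientations per voxel (bounds the AIC parameter count)


def default_simulation_bank(n: int = 16) -> KernelBank:
    """Candidate ratios for simulation studies: log-spaced over [1.1, 10]."""
    return KernelBank.log_spaced(1.1, 10.0, n)


def default_realdata_bank(n: int = 20) -> KernelBank:
    """Candidate ratios for measured data: 20 log-spaced over [1.1, 6.0]."""
    return KernelBank.log_spaced(1.1, 6.0, n)


@dataclass
class LSDConfig:
    """Tunable parameters of an LSD run."""

    ratios: KernelBank = field(default_factory=default_realdata_bank)
    lmax: int = 8
    rel_threshold: float = 0.25
    min_sep_angle: float = 25.0
    smooth_sigma: float = 0.5          # AIC smoothing s.d., voxels
    selection_mode: str = "voxelwise-smoothed"

    def __post_init__(self):
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.selection_mode not in ("voxelwise-smoothed", "patch3x3x3"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


@dataclass
class LSDResult:
    """Per-voxel outputs of an LSD run over a volume."""

    fodf_field: np.ndarray   # spatial + (ncoef,)
    nufo_map: np.ndarray     # spatial, int
    ratio_map: np.ndarray    # spatial, selected kernel ratio
    aic_stack: np.ndarray    # spatial + (n_ratios,), post-smoothing
    peak_field: np.ndarray   # spatial + (MAX_PEAKS, 3), zero-padded
    config: LSDConfig = None
    mask: np.ndarray = None


def gaussian_loglik(predicted: np.ndarray, observed: np.ndarray, sigma) -> float:
    """ln L of independent Gaussian directional residuals, in the log domain.

    ln L = sum_g [ -ln(sigma sqrt(2 pi)) - 0.5 ((Shat - S) / sigma)^2 ].
    Batched over leading axes; ``sigma`` may be scalar or per-voxel.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("prediction/observation shape mismatch")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    s = sigma[..., None] if sigma.ndim == predicted.ndim - 1 else sigma
    s = np.broadcast_to(s, predicted.shape)
    z = (predicted - observed) / s
    out = -np.sum(np.log(s * np.sqrt(2.0 * np.pi)), axis=-1) \
        - 0.5 * np.sum(z * z, axis=-1)
    return out if out.ndim else float(out)


def aic_score(nufo: int, loglik: float) -> float:
    """AIC = 2 k - 2 ln L with k = 3 NuFO (three MTD parameters per peak)."""
    if np.any(np.asarray(nufo) < 1):
        raise ValueError("nufo must be >= 1 for a scored candidate")
    return 2.0 * (3.0 * np.asarray(nufo)) - 2.0 * np.asarray(loglik)


def lsd_fit_signals(
    signals: np.ndarray,
    b0: np.ndarray,
    sigma: np.ndarray,
    scheme,
    config: LSDConfig,
) -> dict:
    """Score every kernel-ratio candidate for a flat batch of voxels.

    Returns per-candidate AIC/NuFO stacks plus per-candidate fODF SH, peak
    orientations and fractions, all vectorized over voxels.  Spatial
    smoothing and selection live in :func:`run_lsd`.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    nvox = signals.shape[0]
    b0 = np.broadcast_to(np.asarray(b0, dtype=float), (nvox,))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (nvox,))
    bvalue = scheme.bvalue
    lmax = config.lmax
    ncoef = n_coefficients(lmax)
    nr = len(config.ratios)
    grid = sphere_grid(724)

    rel = signals / np.clip(b0[:, None], 1e-12, None)
    dodf = csa_transform(rel, scheme.directions, lmax)
    sbar = rel.mean(axis=1)

    aic = np.full((nvox, nr), np.inf)
    nufo = np.zeros((nvox, nr), dtype=int)
    fodfs = np.zeros((nvox, nr, ncoef))
    peak_dirs = np.zeros((nvox, nr, MAX_PEAKS, 3))
    peak_fracs = np.zeros((nvox, nr, MAX_PEAKS))

    for ci, ratio in enumerate(config.ratios.ratios):
        lperp = mtd.lambda_perp_from_constraint(
            np.full(nvox, ratio), sbar, bvalue, clamp=True
        )
        lpar = ratio * lperp
        rh = kernel_rh_batch(lpar, lperp, bvalue, lmax)
        fodf_c = sdt_constrained_batch(dodf, rh, lmax)
        fodfs[:, ci] = fodf_c
        peaks = extract_peaks_batch(
            fodf_c, lmax,
            rel_threshold=config.rel_threshold,
            min_sep_angle=config.min_sep_angle,
            grid=grid, max_peaks=MAX_PEAKS,
        )
        for v, p in enumerate(peaks):
            if p.nufo:
                nufo[v, ci] = p.nufo
                peak_dirs[v, ci, : p.nufo] = p.orientations
                peak_fracs[v, ci, : p.nufo] = p.amplitudes / p.amplitudes.sum()
        ok = nufo[:, ci] > 0
        if not np.any(ok):
            continue
        pred = mtd.mtd_predict_batch(
            peak_dirs[ok, ci], peak_fracs[ok, ci], lpar[ok], lperp[ok], scheme
        )
        ll = gaussian_loglik(pred * b0[ok, None], signals[ok], sigma[ok])
        aic[ok, ci] = aic_score(nufo[ok, ci], ll)

    return {
        "aic": aic, "nufo": nufo, "fodf": fodfs,
        "peak_dirs": peak_dirs, "peak_fracs": peak_fracs,
    }


def smooth_aic_stack(
    aic_stack: np.ndarray,
    smooth_sigma: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-aware 3D Gaussian smoothing of each candidate's AIC map.

    Normalized convolution: the masked map and the mask are filtered
    separately and divided, so out-of-mask (and unscored) voxels do not bleed
    into the result.  ``smooth_sigma = 0`` is the identity.
    """
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    stack = np.asarray(aic_stack, dtype=float)
    if smooth_sigma == 0:
        return stack.copy()
    out = np.full_like(stack, np.inf)
    for ci in range(stack.shape[-1]):
        m = stack[..., ci]
        valid = np.isfinite(m)
        if mask is not None:
            valid &= mask.astype(bool)
        filled = np.where(valid, m, 0.0)
        num = gaussian_filter(filled, smooth_sigma, mode="constant")
        den = gaussian_filter(valid.astype(float), smooth_sigma, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        out[..., ci] = np.where(valid, sm, np.inf)
    return out


def patch_aic_stack(aic_stack: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pool each candidate's AIC over the 3x3x3 neighborhood (mask-aware mean)."""
    stack = np.asarray(aic_stack, dtype=float)
    out = np.full_like(stack, np.inf)
    for ci in range(stack.shape[-1]):
        m = stack[..., ci]
        valid = np.isfinite(m)
        if mask is not None:
            valid &= mask.astype(bool)
        filled = np.where(valid, m, 0.0)
        num = uniform_filter(filled, size=3, mode="constant")
        den = uniform_filter(valid.astype(float), size=3, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        out[..., ci] = np.where(valid, sm, np.inf)
    return out


def run_lsd(dwi: DWIVolume, config: LSDConfig | None = None) -> LSDResult:
    """Full LSD reconstruction of a volume.

    Voxels inside the mask where every candidate yields an empty peak set get
    NuFO 0, an isotropic fODF and the lowest bank ratio.
    """
    if config is None:
        config = LSDConfig()
    signals, b0, sigma = dwi.masked_signals()
    fit = lsd_fit_signals(signals, b0, sigma, dwi.scheme, config)

    shape = dwi.spatial_shape
    nr = len(config.ratios)
    ncoef = n_coefficients(config.lmax)
    aic_vol = np.full(shape + (nr,), np.inf)
    aic_vol[dwi.mask] = fit["aic"]

    if config.selection_mode == "patch3x3x3":
        aic_sm = patch_aic_stack(aic_vol, dwi.mask)
    else:
        aic_sm = smooth_aic_stack(aic_vol, config.smooth_sigma, dwi.mask)

    sel = np.argmin(aic_sm, axis=-1)           # ties: lowest ratio wins
    sel_flat = sel[dwi.mask]
    nvox = sel_flat.size
    rows = np.arange(nvox)

    fodf = np.zeros(shape + (ncoef,))
    nufo = np.zeros(shape, dtype=int)
    ratio = np.zeros(shape)
    pkf = np.zeros(shape + (MAX_PEAKS, 3))

    fodf_sel = fit["fodf"][rows, sel_flat]
    nufo_sel = fit["nufo"][rows, sel_flat]
    ratio_sel = config.ratios.ratios[sel_flat]
    peaks_sel = fit["peak_dirs"][rows, sel_flat]

    # voxels with no valid candidate anywhere: isotropic fODF, NuFO 0
    dead = ~np.isfinite(fit["aic"]).any(axis=1)
    if np.any(dead):
        log.warning("%d voxel(s) had no valid candidate; set isotropic", dead.sum())
        iso = np.zeros(ncoef)
        iso[0] = 0.5 / np.sqrt(np.pi)
        fodf_sel[dead] = iso
        nufo_sel[dead] = 0
        ratio_sel[dead] = config.ratios.ratios[0]
        peaks_sel[dead] = 0.0

    fodf[dwi.mask] = fodf_sel
    nufo[dwi.mask] = nufo_sel
    ratio[dwi.mask] = ratio_sel
    pkf[dwi.mask] = peaks_sel
    return LSDResult(
        fodf_field=fodf, nufo_map=nufo, ratio_map=ratio,
        aic_stack=aic_sm, peak_field=pkf, config=config, mask=dwi.mask,
    )
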