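"""Ground-truth signal generator for validating fODF reconstruction.

Voxels are modeled as symmetrized von Mises-Fisher fODFs (concentration
kappa, mean orientations mu) convolved with an axisymmetric diffusion-tensor
kernel.  The convolution is approximated discretely by rotating the kernel
over a near-uniform 724-point spherical grid and averaging the per-vertex
tensor signals with the fODF values as weights; signals are normalized to 1
at b = 0 and corrupted with Gaussian noise of s.d. sigma (SNR = 1/sigma).

Three published experiment designs are reproduced:

* a direction sweep (n = 28..200 gradient directions, 60 and 90 degree
  crossings, noise scaled so sqrt(n)/sigma is constant with SNR 100 at n=55);
* ``2peaks-manyK`` — 65 two-peak fODF shapes x 30 diffusion kernels
  (1,950 voxel geometries) at SNR 10..100;
* ``2peaks-oneK`` — 195 two-peak fODF shapes with the single median kernel
  (MD 0.9e-3 mm^2/s, R 4.107) at SNR 10..100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recon import DiffusionKernel
from .sphere import (
    GradientScheme,
    SphereGrid,
    SphericalFunctionSH,
    cached_scheme,
    fibonacci_sphere,
    fit_matrix,
    sphere_grid,
)

__all__ = [
    "VoxelGeometry",
    "NoiseModel",
    "ExperimentConfig",
    "SyntheticDataset",
    "vmf_fodf",
    "convolve_on_grid",
    "add_noise",
    "build_direction_sweep",
    "build_2peaks_manyK",
    "build_2peaks_oneK",
    "companion_single_peak",
    "generate_dataset",
    "random_rotation",
]

DENSE_FIT_N = 2000  # sampling density for SH-fitting vMF fODFs


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGeometry:
    """Ground truth for one voxel: fiber orientations, dispersion, kernel."""

    true_orientations: np.ndarray   # (npeaks, 3) unit mean orientations
    kappa: float                    # vMF concentration, > 0
    kernel: DiffusionKernel
    crossing_angle: float | None = None  # degrees, two-peak bookkeeping

    def __post_init__(self):
        mu = np.atleast_2d(np.asarray(self.true_orientations, dtype=float))
        norms = np.linalg.norm(mu, axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ValueError("orientations must be unit vectors")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        object.__setattr__(self, "true_orientations", mu / norms[:, None])

    @property
    def nufo(self) -> int:
        return self.true_orientations.shape[0]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on b0-normalized signal; SNR = 1/sigma."""

    sigma: float
    seed: int = 0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def snr(self) -> float:
        return 1.0 / self.sigma

    @classmethod
    def from_snr(cls, snr: float, seed: int = 0) -> "NoiseModel":
        return cls(sigma=1.0 / snr, seed=seed)


@dataclass
class ExperimentConfig:
    """A published simulation design: geometries, sampling and noise levels."""

    name: str
    geometries: list[VoxelGeometry]
    n_directions: list[int]
    bvalue: float
    snr_levels: list[float]
    replicates: int
    lmax: int = 8
    scheme_seed: int = 0
    sigma_scaling: str = "fixed"   # "fixed" | "sqrt_n" (direction sweep)
    snr_ref: float = 100.0
    n_ref: int = 55

    def scheme(self, n: int | None = None) -> GradientScheme:
        """Electrostatic-repulsion scheme for n directions (memoized)."""
        if n is None:
            if len(self.n_directions) != 1:
                raise ValueError("ambiguous: specify n")
            n = self.n_directions[0]
        return cached_scheme(n, self.bvalue, seed=self.scheme_seed)

    def sigma_for(self, n: int, snr: float | None = None) -> float:
        """Noise s.d.; under sqrt_n scaling, sqrt(n)/sigma is held constant."""
        if self.sigma_scaling == "sqrt_n":
            return np.sqrt(n) / (np.sqrt(self.n_ref) * self.snr_ref)
        if snr is None:
            raise ValueError("snr required for fixed sigma scaling")
        return 1.0 / snr


@dataclass
class SyntheticDataset:
    """Flat voxel batch of synthetic signals with ground truth."""

    signals: np.ndarray      # (nvox, ndir), noisy, b0-normalized
    clean: np.ndarray        # (nvox, ndir), noiseless
    sigma: np.ndarray        # (nvox,)
    scheme: GradientScheme
    truth: pd.DataFrame      # one row per voxel
    orientations: np.ndarray  # (nvox, max_peaks, 3) rotated ground truth, 0-padded
    nufo: np.ndarray         # (nvox,)


# ---------------------------------------------------------------------------
# fODF generation and convolution
# ---------------------------------------------------------------------------

def _sym_vmf_values(dirs: np.ndarray, orientations: np.ndarray, kappa: float) -> np.ndarray:
    """Mean of symmetrized vMF densities over the given mean orientations.

    Closed form kappa / (4 pi sinh kappa) * cosh(kappa mu.v), written with
    shifted exponentials so large kappa cannot overflow; supports batched
    orientations of shape (..., npeaks, 3) against dirs (ndirs, 3) and then
    returns (..., ndirs).
    """
    mu = np.asarray(orientations, dtype=float)
    d = np.einsum("...kc,dc->...kd", np.atleast_2d(mu), dirs)
    # cosh(kappa d) / sinh(kappa) = (e^{k(d-1)} + e^{-k(d+1)}) / (1 - e^{-2k})
    num = np.exp(kappa * (d - 1.0)) + np.exp(-kappa * (d + 1.0))
    dens = kappa / (4.0 * np.pi * (1.0 - np.exp(-2.0 * kappa))) * num
    return dens.mean(axis=-2)


def vmf_fodf(orientations: np.ndarray, kappa: float, lmax: int = 8) -> SphericalFunctionSH:
    """Band-limited fODF of symmetrized vMF lobes, averaged over peaks.

    f(v) = mean_i 0.5 [vMF(v; mu_i, kappa) + vMF(v; -mu_i, kappa)], SH-fit on
    a dense grid; integrates to 1 up to band-limit error.
    """
    dirs = fibonacci_sphere(DENSE_FIT_N)
    vals = _sym_vmf_values(dirs, orientations, kappa)
    coeffs = vals @ fit_matrix(dirs, lmax).T
    return SphericalFunctionSH(coeffs, lmax)


def convolve_on_grid(
    fodf: SphericalFunctionSH | np.ndarray,
    kernel: DiffusionKernel,
    grid: SphereGrid | None = None,
    scheme: GradientScheme | None = None,
) -> np.ndarray:
    """Discrete fODF (x) kernel convolution: weighted sum of rotated tensors.

    S(g) = sum_v w(v) exp(-b g^T D(v) g) / sum_v w(v), with D(v) the kernel
    tensor rotated to vertex v and w(v) the fODF value there (tiny negative
    band-limit ripples clipped to zero).  Normalized so S = 1 at b = 0.

    ``fodf`` may be a band-limited SH function (evaluated at the vertices) or
    raw per-vertex weights, e.g. an exactly sampled density whose sharpness
    exceeds the SH band limit.
    """
    if grid is None:
        grid = sphere_grid(724)
    if isinstance(fodf, SphericalFunctionSH):
        w = fodf.evaluate(grid.vertices)
    else:
        w = np.asarray(fodf, dtype=float)
        if w.shape != (grid.n,):
            raise ValueError("weight vector length must match grid size")
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        raise ValueError("fODF is nonpositive everywhere on the grid")
    cos2 = (scheme.directions @ grid.vertices.T) ** 2       # (ndir, nvert)
    lp, lt = kernel.lambda_par, kernel.lambda_perp
    sig = np.exp(-scheme.bvalues[:, None] * (lt + (lp - lt) * cos2))
    return (sig @ w) / w.sum()


def add_noise(signal: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Add i.i.d. Gaussian deviates of s.d. sigma; reproducible per seed."""
    rng = np.random.default_rng(noise.seed)
    return np.asarray(signal, dtype=float) + rng.normal(0.0, noise.sigma, np.shape(signal))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternion sampling."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# published experiment designs
# ---------------------------------------------------------------------------

def _two_peak_orientations(angle_deg: float) -> np.ndarray:
    """Two unit orientations crossing at the given angle, symmetric about z."""
    a = np.radians(angle_deg) / 2.0
    return np.array([
        [np.sin(a), 0.0, np.cos(a)],
        [-np.sin(a), 0.0, np.cos(a)],
    ])


def manyk_grids() -> dict[str, np.ndarray]:
    """Parameter grids of the 2peaks-manyK design.

    13 crossing angles x 5 concentrations = 65 fODF shapes; 6 MD x 5 R = 30
    kernels.  R is sqrt-linear (squares of a linear grid on [sqrt(1.5),
    sqrt(8)]), kappa is log-linear.
    """
    return {
        "angles": np.linspace(30.0, 90.0, 13),
        "kappas": np.geomspace(8.0, 24.0, 5),
        "mds": np.linspace(0.6e-3, 1.2e-3, 6),
        "ratios": np.linspace(np.sqrt(1.5), np.sqrt(8.0), 5) ** 2,
    }


def build_2peaks_manyK(replicates: int = 100) -> ExperimentConfig:
    """Two-peak fODF shapes crossed with a grid of diffusion kernels.

    65 fODF shapes x 30 kernels = 1,950 voxel geometries; n = 60 directions
    at b = 1,500 s/mm^2; SNR 10..100 in steps of 10.
    """
    g = manyk_grids()
    geometries = []
    for angle in g["angles"]:
        for kappa in g["kappas"]:
            mu = _two_peak_orientations(angle)
            for md in g["mds"]:
                for ratio in g["ratios"]:
                    geometries.append(VoxelGeometry(
                        true_orientations=mu, kappa=float(kappa),
                        kernel=DiffusionKernel(md=float(md), ratio=float(ratio)),
                        crossing_angle=float(angle),
                    ))
    return ExperimentConfig(
        name="2peaks-manyK", geometries=geometries, n_directions=[60],
        bvalue=1500.0, snr_levels=list(range(10, 101, 10)),
        replicates=replicates, lmax=8,
    )


def build_2peaks_oneK(replicates: int = 1000) -> ExperimentConfig:
    """Two-peak fODF shapes with the single median kernel of 2peaks-manyK.

    195 fODF shapes (39 crossing angles x 5 concentrations); kernel MD and R
    are the medians of the manyK kernel grids (0.9e-3 mm^2/s, R = 4.107).
    """
    g = manyk_grids()
    md = float(np.median(g["mds"]))
    ratio = float(np.median(g["ratios"]))
    kernel = DiffusionKernel(md=md, ratio=ratio)
    geometries = []
    for angle in np.linspace(30.0, 90.0, 39):
        for kappa in g["kappas"]:
            geometries.append(VoxelGeometry(
                true_orientations=_two_peak_orientations(angle),
                kappa=float(kappa), kernel=kernel, crossing_angle=float(angle),
            ))
    return ExperimentConfig(
        name="2peaks-oneK", geometries=geometries, n_directions=[60],
        bvalue=1500.0, snr_levels=list(range(10, 101, 10)),
        replicates=replicates, lmax=8,
    )


def build_direction_sweep(
    n_values: list[int] | None = None,
    replicates: int = 1000,
) -> ExperimentConfig:
    """Angular accuracy vs number of diffusion directions.

    60 and 90 degree crossings (kappa 24), kernel MD 1e-3 mm^2/s R 3,
    b = 1,000 s/mm^2, n = 28, 30, ..., 200; sigma chosen per n so that
    sqrt(n)/sigma is constant with SNR 100 at n = 55.  Reconstruction uses
    SH order 6.
    """
    if n_values is None:
        n_values = list(range(28, 201, 2))
    kernel = DiffusionKernel(md=1.0e-3, ratio=3.0)
    geometries = [
        VoxelGeometry(_two_peak_orientations(a), kappa=24.0, kernel=kernel,
                      crossing_angle=float(a))
        for a in (60.0, 90.0)
    ]
    return ExperimentConfig(
        name="direction-sweep", geometries=geometries,
        n_directions=list(n_values), bvalue=1000.0,
        snr_levels=[100.0], replicates=replicates, lmax=6,
        sigma_scaling="sqrt_n", snr_ref=100.0, n_ref=55,
    )


def companion_single_peak(config: ExperimentConfig) -> list[VoxelGeometry]:
    """Single-peak companion geometries for CSD response estimation.

    Same kernel and concentration grids as ``config`` but one fiber per
    voxel (used by the iterative single-fiber response estimator).
    """
    seen = {}
    for g in config.geometries:
        key = (g.kappa, g.kernel.md, g.kernel.ratio)
        if key not in seen:
            seen[key] = VoxelGeometry(
                np.array([[0.0, 0.0, 1.0]]), kappa=g.kappa, kernel=g.kernel,
            )
    return list(seen.values())


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    geometries: list[VoxelGeometry],
    scheme: GradientScheme,
    snr: float | None,
    replicates: int,
    master_seed: int = 0,
    sigma: float | None = None,
    rotate: bool = True,
    lmax: int = 8,
    grid: SphereGrid | None = None,
    geometry_ids: list[int] | None = None,
) -> SyntheticDataset:
    """Noisy signals for every (geometry, replicate) pair, fully seeded.

    Each pair gets an independent RNG derived from
    ``SeedSequence([master_seed, geometry_id, replicate])``; the random 3D
    rotation (if enabled) and the noise draw both come from it, so any voxel
    is reproducible in isolation.
    """
    if grid is None:
        grid = sphere_grid(724)
    if sigma is None:
        if snr is None:
            raise ValueError("provide snr or sigma")
        sigma = 1.0 / snr
    if geometry_ids is None:
        geometry_ids = list(range(len(geometries)))
    verts = grid.vertices
    dirs = scheme.directions
    cos2_gv = (dirs @ verts.T) ** 2  # (ndir, nvert)

    max_pk = max(g.nufo for g in geometries)
    nvox = len(geometries) * replicates
    signals = np.empty((nvox, scheme.n))
    clean = np.empty((nvox, scheme.n))
    orientations = np.zeros((nvox, max_pk, 3))
    nufo = np.empty(nvox, dtype=int)
    rows = []

    i = 0
    for gid, geom in zip(geometry_ids, geometries):
        lp, lt = geom.kernel.lambda_par, geom.kernel.lambda_perp
        E_T = np.exp(-scheme.bvalues[None, :] * (lt + (lp - lt) * cos2_gv.T))  # (nvert, ndir)
        rngs = [
            np.random.default_rng(np.random.SeedSequence([master_seed, gid, rep]))
            for rep in range(replicates)
        ]
        if rotate:
            mus = np.stack([
                geom.true_orientations @ random_rotation(r).T for r in rngs
            ])
        else:
            mus = np.broadcast_to(
                geom.true_orientations, (replicates,) + geom.true_orientations.shape
            )
        # fODF weights: the symmetrized vMF pdf sampled at the grid vertices
        w = _sym_vmf_values(verts, mus, geom.kappa)              # (nrep, nvert)
        s = (w @ E_T) / w.sum(axis=1)[:, None]                   # (nrep, ndir)
        for rep in range(replicates):
            signals[i] = s[rep] + rngs[rep].normal(0.0, sigma, scheme.n)
            clean[i] = s[rep]
            orientations[i, : geom.nufo] = mus[rep]
            nufo[i] = geom.nufo
            rows.append({
                "geometry": gid, "replicate": rep, "snr": 1.0 / sigma,
                "sigma": sigma, "kappa": geom.kappa,
                "md": geom.kernel.md, "ratio": geom.kernel.ratio,
                "crossing_angle": geom.crossing_angle, "nufo_true": geom.nufo,
            })
            i += 1
    return SyntheticDataset(
        signals=signals, clean=clean, sigma=np.full(nvox, float(sigma)),
        scheme=scheme, truth=pd.DataFrame(rows),
        orientations=orientations, nufo=nufo,
    )
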