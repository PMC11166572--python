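"""Spherical sampling, even-order spherical harmonics and peak extraction.

Antipodally symmetric functions on the sphere (dODFs, fODFs) are represented
in a real, orthonormal, even-order spherical-harmonic (SH) basis.  Coefficient
ordering follows ascending even order ``l`` with ``m`` running from ``-l`` to
``l`` inside each order; negative ``m`` maps to the sine terms.  The basis is
orthonormal on the unit sphere, so the order-0 coefficient of a function
integrating to 1 is ``1 / (2 sqrt(pi))``.

A converter to the MRtrix SH dialect is provided: MRtrix uses the same
ordering but omits the extra Condon–Shortley factor on the real/imaginary
combinations, so coefficients differ by ``(-1)^m``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

__all__ = [
    "GradientScheme",
    "SphereGrid",
    "SphericalFunctionSH",
    "PeakSet",
    "sh_degrees",
    "n_coefficients",
    "sh_basis",
    "sh_fit",
    "sh_eval",
    "to_mrtrix",
    "from_mrtrix",
    "fibonacci_sphere",
    "sphere_grid",
    "make_electrostatic_scheme",
    "extract_peaks",
    "extract_peaks_batch",
    "hemisphere_fold",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """Diffusion sampling scheme: unit gradient directions and b-values.

    Parameters
    ----------
    directions : (n, 3) array
        Unit gradient directions (dimensionless, image coordinates).
    bvalues : (n,) array
        Diffusion weightings in s/mm^2; nonnegative.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if b.size == 1 and d.shape[0] > 1:
            b = np.full(d.shape[0], float(b[0]))
        if d.shape[0] != b.shape[0]:
            raise ValueError(
                f"direction count {d.shape[0]} != b-value count {b.shape[0]}"
            )
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("gradient directions must be unit vectors")
        # renormalize tiny drift so downstream dot products stay exact
        d = d / norms[:, None]
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    @property
    def n(self) -> int:
        return self.directions.shape[0]

    @property
    def bvalue(self) -> float:
        """The single shell b-value; errors if the scheme is multi-shell."""
        b = np.unique(self.bvalues)
        if b.size != 1:
            raise ValueError(f"scheme is not single-shell: b-values {b}")
        return float(b[0])


@dataclass(frozen=True)
class SphereGrid:
    """Near-uniform point set on the sphere with neighbor adjacency.

    ``neighbors`` is a padded integer array of shape (n, max_degree); entries
    equal to ``n`` are padding (no neighbor).
    """

    vertices: np.ndarray
    neighbors: np.ndarray

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    def mean_spacing_deg(self) -> float:
        """Mean angular distance (degrees) to the nearest neighbor."""
        v = self.vertices
        pad = np.vstack([v, np.full((1, 3), np.inf)])
        nb = pad[self.neighbors]  # (n, deg, 3)
        cos = np.clip(np.einsum("ij,ikj->ik", v, nb), -1.0, 1.0)
        cos = np.where(np.isfinite(cos), cos, -1.0)
        return float(np.degrees(np.arccos(cos.max(axis=1))).mean())


@dataclass
class SphericalFunctionSH:
    """Antipodally symmetric spherical function in the even-order real SH basis."""

    coefficients: np.ndarray
    lmax: int = 8

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float).ravel()
        expect = n_coefficients(self.lmax)
        if c.size != expect:
            raise ValueError(
                f"lmax={self.lmax} requires {expect} coefficients, got {c.size}"
            )
        self.coefficients = c

    def evaluate(self, dirs: np.ndarray) -> np.ndarray:
        return sh_eval(self.coefficients, dirs, self.lmax)

    def sphere_integral(self) -> float:
        """Integral over the full sphere (orthonormal basis identity)."""
        return float(self.coefficients[0] * 2.0 * np.sqrt(np.pi))


@dataclass
class PeakSet:
    """Extracted fODF/dODF maxima: sign-ambiguous unit orientations.

    Orientations are reported on the upper hemisphere (nonnegative z; ties
    broken toward nonnegative y, then x), amplitudes sorted descending.
    """

    orientations: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        if self.orientations.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("orientations/amplitudes length mismatch")

    @property
    def nufo(self) -> int:
        return self.orientations.shape[0]


# ---------------------------------------------------------------------------
# SH basis
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def sh_degrees(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index arrays of the even-order basis, m from -l to l."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def n_coefficients(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def _to_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    r = np.linalg.norm(d, axis=1)
    d = d / r[:, None]
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def _legendre_normalized(x: np.ndarray, sin_t: np.ndarray, lmax: int) -> dict:
    """Fully normalized associated Legendre P̄_lm(x) with Condon–Shortley
    phase, by the standard stable three-term recurrence (vectorized in x)."""
    P = {}
    P[(0, 0)] = np.full_like(x, 0.5 / np.sqrt(np.pi))
    for m in range(1, lmax + 1):
        P[(m, m)] = -np.sqrt((2 * m + 1.0) / (2.0 * m)) * sin_t * P[(m - 1, m - 1)]
    for m in range(0, lmax):
        P[(m + 1, m)] = np.sqrt(2 * m + 3.0) * x * P[(m, m)]
    for m in range(0, lmax + 1):
        for l in range(m + 2, lmax + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            P[(l, m)] = a * (x * P[(l - 1, m)] - b * P[(l - 2, m)])
    return P


def sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of the real even-order orthonormal SH basis.

    Row i holds the basis functions evaluated at direction i.  Evaluated via
    a vectorized normalized-Legendre recurrence (much faster than repeated
    complex spherical-harmonic calls).
    """
    theta, phi = _to_angles(dirs)
    x, sin_t = np.cos(theta), np.sin(theta)
    P = _legendre_normalized(x, sin_t, lmax)
    ls, ms = sh_degrees(lmax)
    out = np.empty((theta.size, ls.size))
    sqrt2 = np.sqrt(2.0)
    # cos(m phi), sin(m phi) via complex powers (cheaper than 2 lmax trig calls)
    z = np.exp(1j * phi)
    cos_m, sin_m = {}, {}
    zm = np.ones_like(z)
    for m in range(1, lmax + 1):
        zm = zm * z
        cos_m[m], sin_m[m] = zm.real, zm.imag
    for j, (l, m) in enumerate(zip(ls, ms)):
        am = abs(m)
        if m == 0:
            out[:, j] = P[(l, 0)]
        elif m > 0:
            # sqrt(2) (-1)^m Re(Y_l^m); the CS phase in P̄ supplies (-1)^m
            out[:, j] = sqrt2 * (-1.0) ** m * P[(l, am)] * cos_m[am]
        else:
            out[:, j] = sqrt2 * (-1.0) ** am * P[(l, am)] * sin_m[am]
    return out


def sh_fit(
    values: np.ndarray,
    dirs: np.ndarray,
    lmax: int,
    reg: float = 0.0,
) -> np.ndarray:
    """Least-squares SH coefficients of samples ``values`` at ``dirs``.

    ``reg`` adds Laplace–Beltrami regularization ``reg * (l(l+1))^2`` on the
    normal equations (Descoteaux-style smoothing).  Supports batched values of
    shape (..., ndirs); returns (..., ncoef).
    """
    values = np.asarray(values, dtype=float)
    B = sh_basis(dirs, lmax)
    ncoef = B.shape[1]
    if B.shape[0] < ncoef:
        raise ValueError(
            f"underdetermined SH fit: lmax={lmax} needs >= {ncoef} samples, "
            f"got {B.shape[0]}"
        )
    inv = fit_matrix(dirs, lmax, reg)
    return values @ inv.T


def fit_matrix(dirs: np.ndarray, lmax: int, reg: float = 0.0) -> np.ndarray:
    """(ncoef, ndirs) matrix mapping samples to regularized LS coefficients."""
    B = sh_basis(dirs, lmax)
    ls, _ = sh_degrees(lmax)
    L2 = (ls * (ls + 1.0)) ** 2
    M = B.T @ B + reg * np.diag(L2)
    return np.linalg.solve(M, B.T)


def sh_eval(coefficients: np.ndarray, dirs: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Evaluate SH coefficients at directions; batched over leading axes."""
    c = np.asarray(coefficients, dtype=float)
    if lmax is None:
        lmax = lmax_from_ncoef(c.shape[-1])
    B = sh_basis(dirs, lmax)
    return c @ B.T


def lmax_from_ncoef(ncoef: int) -> int:
    lmax = int(round((-3 + np.sqrt(1 + 8 * ncoef)) / 2))
    if n_coefficients(lmax) != ncoef:
        raise ValueError(f"{ncoef} is not a valid even-order SH length")
    return lmax


def _mrtrix_signs(lmax: int) -> np.ndarray:
    _, ms = sh_degrees(lmax)
    return (-1.0) ** ms


def to_mrtrix(coefficients: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Convert coefficients from this package's basis to the MRtrix dialect."""
    c = np.asarray(coefficients, dtype=float)
    if lmax is None:
        lmax = lmax_from_ncoef(c.shape[-1])
    return c * _mrtrix_signs(lmax)


def from_mrtrix(coefficients: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Inverse of :func:`to_mrtrix` (the conversion is an involution)."""
    return to_mrtrix(coefficients, lmax)


# ---------------------------------------------------------------------------
# sphere grids
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Spherical Fibonacci point set: n near-uniform unit vectors."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@functools.lru_cache(maxsize=8)
def sphere_grid(n: int = 724) -> SphereGrid:
    """Near-uniform grid with adjacency from the convex-hull triangulation.

    The 724-point default is the working resolution for discrete fODF/kernel
    convolution and for seeding peak search (~7.6 degrees mean spacing).
    """
    v = fibonacci_sphere(n)
    hull = ConvexHull(v)
    nbrs = [set() for _ in range(n)]
    for a, b, c in hull.simplices:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    deg = max(len(s) for s in nbrs)
    padded = np.full((n, deg), n, dtype=np.int64)
    for i, s in enumerate(nbrs):
        idx = sorted(s)
        padded[i, : len(idx)] = idx
    return SphereGrid(vertices=v, neighbors=padded)


def hemisphere_fold(dirs: np.ndarray) -> np.ndarray:
    """Map sign-ambiguous orientations to z >= 0 (ties: y >= 0, then x >= 0)."""
    d = np.atleast_2d(np.asarray(dirs, dtype=float)).copy()
    flip = (d[:, 2] < 0) | ((d[:, 2] == 0) & (d[:, 1] < 0)) | (
        (d[:, 2] == 0) & (d[:, 1] == 0) & (d[:, 0] < 0)
    )
    d[flip] *= -1.0
    return d


# ---------------------------------------------------------------------------
# electrostatic gradient schemes
# ---------------------------------------------------------------------------

def _electrostatic_energy_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    # antipodally symmetrized Coulomb energy on unit vectors x (n, 3)
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=2)
    ds = np.linalg.norm(summ, axis=2)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    energy = 0.5 * (np.sum(1.0 / dd) + np.sum(1.0 / ds))
    gd = -diff / dd[:, :, None] ** 3
    gs = -summ / ds[:, :, None] ** 3
    grad = gd.sum(axis=1) + gs.sum(axis=1)
    return energy, grad


def electrostatic_energy(directions: np.ndarray) -> float:
    """Antipodally symmetrized 1/r pairwise energy of a direction set."""
    return _electrostatic_energy_grad(np.asarray(directions, dtype=float))[0]


def make_electrostatic_scheme(
    n: int,
    bvalue: float,
    seed: int = 0,
    restarts: int = 10,
    maxiter: int = 500,
) -> GradientScheme:
    """Single-shell scheme of n directions by electrostatic repulsion.

    Minimizes the antipodally symmetrized Coulomb energy with L-BFGS from
    ``restarts`` seeded random starts and keeps the lowest-energy solution;
    deterministic for a given ``seed``.
    """
    if n < 6:
        raise ValueError("need n >= 6 directions (order-2 SH fitting minimum)")

    def objective(flat):
        y = flat.reshape(n, 3)
        r = np.linalg.norm(y, axis=1)
        x = y / r[:, None]
        e, gx = _electrostatic_energy_grad(x)
        # chain rule through normalization: project out radial component
        gy = (gx - (gx * x).sum(axis=1)[:, None] * x) / r[:, None]
        return e, gy.ravel()

    rng = np.random.default_rng(seed)
    best = None
    best_e = np.inf
    for _ in range(restarts):
        y0 = rng.standard_normal((n, 3))
        y0 /= np.linalg.norm(y0, axis=1)[:, None]
        res = minimize(objective, y0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
        x = res.x.reshape(n, 3)
        x /= np.linalg.norm(x, axis=1)[:, None]
        e = electrostatic_energy(x)
        if e < best_e:
            best_e, best = e, x
    return GradientScheme(directions=hemisphere_fold(best), bvalues=np.full(n, float(bvalue)))


_scheme_cache: dict[tuple, GradientScheme] = {}


def cached_scheme(n: int, bvalue: float, seed: int = 0) -> GradientScheme:
    """Memoized :func:`make_electrostatic_scheme` (schemes are expensive)."""
    key = (n, float(bvalue), seed)
    if key not in _scheme_cache:
        _scheme_cache[key] = make_electrostatic_scheme(n, bvalue, seed=seed)
    return _scheme_cache[key]


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def _tangent_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orthonormal tangent frame at each unit vector d (npk, 3)
    ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    u = np.cross(ref, d)
    u /= np.linalg.norm(u, axis=1)[:, None]
    v = np.cross(d, u)
    return u, v


def _refine_on_sphere(
    coeffs: np.ndarray,
    vox_idx: np.ndarray,
    dirs: np.ndarray,
    lmax: int,
    iters: int = 4,
    h: float = 0.01,
    max_step: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-refine candidate maxima of SH surfaces; batched over peaks.

    coeffs: (nvox, ncoef); vox_idx maps each peak to its voxel.  Returns
    refined unit directions and their amplitudes.
    """
    d = dirs.copy()
    npk = d.shape[0]
    if npk == 0:
        return d, np.empty(0)
    # coarse Newton steps first, then fine steps to polish the maximum
    steps = [h] * iters + [h / 10.0] * 2
    for h in steps:
        u, v = _tangent_frame(d)
        pts = np.stack([
            d,
            d + h * u, d - h * u,
            d + h * v, d - h * v,
            d + h * u + h * v,
        ])  # (6, npk, 3)
        pts /= np.linalg.norm(pts, axis=2)[:, :, None]
        B = sh_basis(pts.reshape(-1, 3), lmax)
        f = np.einsum("pk,pk->p", B, coeffs[np.tile(vox_idx, 6)]).reshape(6, npk)
        gu = (f[1] - f[2]) / (2 * h)
        gv = (f[3] - f[4]) / (2 * h)
        huu = (f[1] + f[2] - 2 * f[0]) / h**2
        hvv = (f[3] + f[4] - 2 * f[0]) / h**2
        huv = (f[5] - f[1] - f[3] + f[0]) / h**2
        det = huu * hvv - huv**2
        negdef = (det > 0) & (huu < 0)
        # Newton step where the Hessian is negative definite, else gradient
        su = np.where(negdef, -(hvv * gu - huv * gv) / np.where(det == 0, 1, det),
                      0.05 * gu)
        sv = np.where(negdef, -(huu * gv - huv * gu) / np.where(det == 0, 1, det),
                      0.05 * gv)
        norm = np.sqrt(su**2 + sv**2)
        scale = np.where(norm > max_step, max_step / np.where(norm == 0, 1, norm), 1.0)
        d = d + (su * scale)[:, None] * u + (sv * scale)[:, None] * v
        d /= np.linalg.norm(d, axis=1)[:, None]
    amp = np.einsum("pk,pk->p", sh_basis(d, lmax), coeffs[vox_idx])
    return d, amp


def extract_peaks_batch(
    coeffs: np.ndarray,
    lmax: int | None = None,
    rel_threshold: float = 0.25,
    min_sep_angle: float = 25.0,
    grid: SphereGrid | None = None,
    refine: bool = True,
    max_peaks: int | None = None,
) -> list[PeakSet]:
    """Extract peaks from many SH functions at once (vectorized grid search).

    Discrete local maxima on ``grid`` are refined by Newton steps on the
    analytic SH surface, then filtered by relative amplitude and greedy
    angular-separation suppression in descending-amplitude order.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    nvox = coeffs.shape[0]
    if lmax is None:
        lmax = lmax_from_ncoef(coeffs.shape[1])
    if not (0.0 < rel_threshold <= 1.0):
        raise ValueError("rel_threshold must be in (0, 1]")
    if grid is None:
        grid = sphere_grid(724)

    vals = sh_eval(coeffs, grid.vertices, lmax)  # (nvox, ngrid)
    ext = np.concatenate([vals, np.full((nvox, 1), -np.inf)], axis=1)
    nbr_max = ext[:, grid.neighbors].max(axis=2)  # (nvox, ngrid)
    is_max = (vals > nbr_max) & (vals > 0)
    # cheap pre-filter: maxima far below the relative threshold cannot
    # survive selection, so skip their refinement (0.5 safety margin)
    is_max &= vals >= 0.5 * rel_threshold * vals.max(axis=1, keepdims=True)

    vox_idx, vert_idx = np.nonzero(is_max)
    dirs = grid.vertices[vert_idx]
    if refine and dirs.shape[0]:
        dirs, amps = _refine_on_sphere(coeffs, vox_idx, dirs, lmax)
    else:
        amps = vals[vox_idx, vert_idx]
    dirs = hemisphere_fold(dirs)

    cos_min = np.cos(np.radians(min_sep_angle))
    out: list[PeakSet] = []
    start = np.searchsorted(vox_idx, np.arange(nvox + 1))
    for v in range(nvox):
        sl = slice(start[v], start[v + 1])
        d, a = dirs[sl], amps[sl]
        keep = a > 0
        d, a = d[keep], a[keep]
        if a.size == 0:
            out.append(PeakSet(np.empty((0, 3)), np.empty(0)))
            continue
        order = np.argsort(-a)
        d, a = d[order], a[order]
        a_thr = rel_threshold * a[0]
        sel_d, sel_a = [], []
        for i in range(a.size):
            if a[i] < a_thr:
                continue
            if any(abs(np.dot(d[i], sd)) > cos_min + 1e-12 for sd in sel_d):
                continue
            sel_d.append(d[i])
            sel_a.append(a[i])
            if max_peaks is not None and len(sel_d) >= max_peaks:
                break
        out.append(PeakSet(np.array(sel_d), np.array(sel_a)))
    return out


def extract_peaks(
    f: SphericalFunctionSH,
    rel_threshold: float = 0.25,
    min_sep_angle: float = 25.0,
    grid: SphereGrid | None = None,
    refine: bool = True,
    max_peaks: int | None = None,
) -> PeakSet:
    """Peaks of a single spherical function; see :func:`extract_peaks_batch`."""
    return extract_peaks_batch(
        f.coefficients[None, :], f.lmax, rel_threshold, min_sep_angle,
        grid, refine, max_peaks,
    )[0]
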