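"""Shared fixtures: schemes and small synthetic datasets are expensive to
build, so they are session-scoped and reused across test modules."""

import numpy as np
import pytest

from lsdmri import sphere as sp
from lsdmri.recon import DiffusionKernel


@pytest.fixture(scope="session")
def scheme60():
    """60-direction electrostatic scheme at b = 1500 s/mm^2."""
    return sp.cached_scheme(60, 1500.0, seed=0)


@pytest.fixture(scope="session")
def grid724():
    return sp.sphere_grid(724)


@pytest.fixture(scope="session")
def dense_dirs():
    return sp.fibonacci_sphere(2000)


@pytest.fixture(scope="session")
def kernel_r3():
    return DiffusionKernel(md=1.0e-3, ratio=3.0)


def sym_vmf_sh(orientations, kappa, lmax=8, weights=None):
    """SH fit of a symmetrized vMF mixture (test helper, scipy oracle)."""
    from scipy.stats import vonmises_fisher

    dirs = sp.fibonacci_sphere(2000)
    mu = np.atleast_2d(orientations)
    if weights is None:
        weights = np.full(mu.shape[0], 1.0 / mu.shape[0])
    vals = np.zeros(dirs.shape[0])
    for w, m in zip(weights, mu):
        p = vonmises_fisher(m / np.linalg.norm(m), kappa)
        vals += w * 0.5 * (p.pdf(dirs) + p.pdf(-dirs))
    return sp.SphericalFunctionSH(sp.sh_fit(vals, dirs, lmax), lmax)
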