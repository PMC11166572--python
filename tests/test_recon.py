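"""CSA dODF estimation, sharpening deconvolution and the CSD baseline."""

import numpy as np
import pytest

from lsdmri import mtd
from lsdmri import recon as rc
from lsdmri import simulate as sim
from lsdmri import sphere as sp
from lsdmri.sphere import GradientScheme


def tensor_solid_angle_odf(dirs, lpar, lperp):
    """Exact constant-solid-angle ODF of a z-aligned axisymmetric tensor.

    Radial marginalization of the Gaussian propagator gives
    ODF(u) = 1 / (4 pi |D|^{1/2} (u^T D^{-1} u)^{3/2}); peak along z.
    """
    det = lpar * lperp * lperp
    quad = dirs[:, 0] ** 2 / lperp + dirs[:, 1] ** 2 / lperp + dirs[:, 2] ** 2 / lpar
    return 1.0 / (4.0 * np.pi * np.sqrt(det) * quad ** 1.5)


class TestDiffusionKernel:
    def test_eigenvalue_md_identity(self):
        k = rc.DiffusionKernel(md=0.9e-3, ratio=4.107)
        assert (k.lambda_par + 2 * k.lambda_perp) / 3.0 == pytest.approx(0.9e-3, rel=1e-14)
        assert k.lambda_par / k.lambda_perp == pytest.approx(4.107, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rc.DiffusionKernel(md=-1e-3, ratio=2.0)
        with pytest.raises(ValueError):
            rc.DiffusionKernel(md=1e-3, ratio=0.5)

    def test_kernel_bank_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            rc.KernelBank(np.array([2.0, 1.5]))
        with pytest.raises(ValueError, match="> 1"):
            rc.KernelBank(np.array([0.9, 2.0]))
        bank = rc.KernelBank.log_spaced(1.1, 10.0, 16)
        assert len(bank) == 16
        assert bank.ratios[0] == pytest.approx(1.1)
        assert bank.ratios[-1] == pytest.approx(10.0)


class TestCSA:
    def test_isotropic_signal_gives_constant_odf(self, scheme60, dense_dirs):
        odf = rc.csa_odf(np.full(60, np.exp(-1.0)), 1.0, scheme60)
        vals = odf.evaluate(dense_dirs)
        np.testing.assert_allclose(vals, 1.0 / (4 * np.pi), atol=1e-6)
        assert odf.sphere_integral() == pytest.approx(1.0, abs=1e-12)

    def test_tensor_odf_peak_matches_propagator_marginalization(self):
        # oracle: dense evaluation of the exact solid-angle tensor ODF
        k = rc.DiffusionKernel(md=1e-3, ratio=5.0)
        scheme = GradientScheme(sp.cached_scheme(60, 1500.0).directions,
                                np.full(60, 5000.0))
        sig = k.signal(scheme.directions, 5000.0)
        odf = rc.csa_odf(sig, 1.0, scheme)
        pk = sp.extract_peaks(odf)
        oracle = tensor_solid_angle_odf(
            sp.fibonacci_sphere(50_000), k.lambda_par, k.lambda_perp
        )
        oracle_dir = sp.fibonacci_sphere(50_000)[np.argmax(oracle)]
        ang = np.degrees(np.arccos(abs(pk.orientations[0] @ oracle_dir)))
        assert pk.nufo == 1
        assert ang < 3.0

    def test_rotation_equivariance(self, scheme60):
        from tests.test_sphere import rotation_about

        k = rc.DiffusionKernel(md=1e-3, ratio=5.0)
        R = rotation_about([0.2, 1.0, 0.4], 0.9)
        sig = k.signal(scheme60.directions, 1500.0)
        # rotating the scheme is equivalent to measuring a rotated tensor
        odf0 = rc.csa_odf(sig, 1.0, scheme60)
        # sampling at directions G R is equivalent to measuring a tensor
        # whose principal axis is R z with the original scheme
        sig_rot = k.signal(scheme60.directions @ R, 1500.0)
        odf1 = rc.csa_odf(sig_rot, 1.0, scheme60)
        p0 = sp.extract_peaks(odf0).orientations[0]
        p1 = sp.extract_peaks(odf1).orientations[0]
        ang = np.degrees(np.arccos(np.clip(abs(p1 @ (R @ p0)), 0, 1)))
        assert ang < 2.0

    def test_intensity_scaling_invariance(self, scheme60):
        sig = rc.DiffusionKernel(1e-3, 3.0).signal(scheme60.directions, 1500.0)
        a = rc.csa_odf(sig * 480.0, 480.0, scheme60)
        b = rc.csa_odf(sig, 1.0, scheme60)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-12)

    def test_all_zero_signal_rejected(self, scheme60):
        with pytest.raises(ValueError, match="zero"):
            rc.csa_odf(np.zeros(60), 1.0, scheme60)


class TestSDT:
    def test_matched_kernel_recovers_single_fiber(self, scheme60, kernel_r3):
        # forward-simulate a near-delta fiber, reconstruct with matching R
        geom = sim.VoxelGeometry(np.array([[0.0, 0.0, 1.0]]), 256.0, kernel_r3)
        ds = sim.generate_dataset([geom], scheme60, snr=None, sigma=1e-12,
                                  replicates=1, master_seed=0, rotate=False)
        dodf = rc.csa_odf(ds.clean[0], 1.0, scheme60)
        fodf = rc.sdt_deconvolve(dodf, kernel_r3, 1500.0)
        pk = sp.extract_peaks(fodf)
        assert pk.nufo == 1
        ang = np.degrees(np.arccos(abs(pk.orientations[0] @ [0, 0, 1.0])))
        assert ang < 1.0

    def test_oversharp_kernel_splits_peaks(self, scheme60):
        # deconvolving a blunt fiber with a much sharper kernel fragments
        # the fODF: the failure mode motivating voxel-wise kernel selection
        true_k = rc.DiffusionKernel(md=1e-3, ratio=2.0)
        sharp_k = rc.DiffusionKernel(md=1e-3, ratio=10.0)
        geom = sim.VoxelGeometry(np.array([[0.0, 0.0, 1.0]]), 256.0, true_k)
        ds = sim.generate_dataset([geom], scheme60, snr=200.0,
                                  replicates=1, master_seed=5, rotate=False)
        dodf = rc.csa_odf(ds.signals[0], 1.0, scheme60)
        fodf = rc.sdt_deconvolve(dodf, sharp_k, 1500.0)
        pk = sp.extract_peaks(fodf)
        assert pk.nufo >= 2

    def test_constant_dodf_stays_constant(self, scheme60):
        c = np.zeros(sp.n_coefficients(8))
        c[0] = 0.5 / np.sqrt(np.pi)
        fodf = rc.sdt_deconvolve(sp.SphericalFunctionSH(c, 8),
                                 rc.DiffusionKernel(1e-3, 4.0), 1500.0)
        assert fodf.coefficients[0] == pytest.approx(c[0])
        assert np.abs(fodf.coefficients[1:]).max() < 1e-12

    def test_forward_inverse_identity_in_band_limit(self):
        # convolution expressed as rotational-harmonic multiplication, then
        # SDT division with the same kernel: exact identity
        from tests.conftest import sym_vmf_sh

        f = sym_vmf_sh([[0, 0, 1.0], [np.sin(1.0), 0, np.cos(1.0)]], 20.0)
        kern = rc.DiffusionKernel(md=1e-3, ratio=5.0)
        rh = rc.kernel_rh(kern, 3000.0, 8, domain="odf")
        assert np.all(np.abs(rh) >= rc.SDT_FLOOR * abs(rh[0]))
        ls, _ = sp.sh_degrees(8)
        conv = f.coefficients * rh[ls // 2]
        back = rc.sdt_apply(conv, rh, 8)
        np.testing.assert_allclose(back, f.coefficients, atol=1e-6)

    def test_low_ratio_kernel_orders_zeroed(self):
        # blunt kernels have vanishing high-order harmonics: division must
        # zero those orders rather than amplify them
        rh = rc.kernel_rh(rc.DiffusionKernel(1e-3, 1.2), 1000.0, 8, domain="odf")
        coeffs = np.ones(sp.n_coefficients(8))
        out = rc.sdt_apply(coeffs[None], rh[None], 8)[0]
        ls, _ = sp.sh_degrees(8)
        dead_orders = np.abs(rh) < rc.SDT_FLOOR * abs(rh[0])
        assert dead_orders.any()
        assert np.all(out[dead_orders[ls // 2]] == 0.0)

    def test_ratio_one_rejected(self, scheme60):
        c = np.zeros(sp.n_coefficients(8))
        c[0] = 0.5 / np.sqrt(np.pi)
        with pytest.raises(ValueError, match="ratio > 1"):
            rc.sdt_deconvolve(sp.SphericalFunctionSH(c, 8),
                              rc.DiffusionKernel(1e-3, 1.0), 1500.0)


class TestCSD:
    def test_response_recovery_from_homogeneous_volume(self, scheme60):
        # exact single-fiber voxels (pure tensor signals at random axes);
        # closed-form oracle: signal rotational harmonics of the kernel
        k = rc.DiffusionKernel(md=0.9e-3, ratio=4.107)
        rng = np.random.default_rng(21)
        axes = rng.standard_normal((400, 3))
        axes /= np.linalg.norm(axes, axis=1)[:, None]
        cos2 = (axes @ scheme60.directions.T) ** 2
        lp, lt = k.lambda_par, k.lambda_perp
        signals = np.exp(-1500.0 * (lt + (lp - lt) * cos2))
        signals += rng.normal(0.0, 0.01, signals.shape)
        est = rc.estimate_response_tournier(signals, scheme60, 8)
        oracle = rc.kernel_rh(k, 1500.0, 8, domain="signal")
        # compare the orders that matter for deconvolution (l <= 4 carry
        # >97% of the response energy)
        np.testing.assert_allclose(est[:3], oracle[:3], rtol=0.05)

    def test_single_fiber_recovery(self, scheme60, kernel_r3):
        geoms = [sim.VoxelGeometry(np.array([[0.0, 0.0, 1.0]]), 128.0, kernel_r3)]
        ds = sim.generate_dataset(geoms, scheme60, snr=100.0, replicates=60,
                                  master_seed=22)
        resp = rc.kernel_rh(kernel_r3, 1500.0, 8, domain="signal")
        fodf = rc.csd_deconvolve(ds.signals, scheme60, resp, 8)
        pks = sp.extract_peaks_batch(fodf, 8, rel_threshold=0.25, max_peaks=5)
        nufo = np.array([p.nufo for p in pks])
        assert (nufo == 1).mean() >= 0.95
        errs = [
            np.degrees(np.arccos(np.clip(abs(p.orientations[0] @ ds.orientations[i, 0]), 0, 1)))
            for i, p in enumerate(pks) if p.nufo >= 1
        ]
        assert np.mean(errs) < 5.0

    def test_too_small_volume_rejected(self, scheme60):
        with pytest.raises(ValueError, match=">= 50"):
            rc.estimate_response_tournier(np.ones((10, 60)), scheme60, 8)

    def test_global_sharp_kernel_inflates_nufo_in_blunt_voxels(self, scheme60):
        # heterogeneous kernels + one global high-anisotropy response:
        # reconstructed peak counts exceed the true two in low-R voxels
        mu = sim._two_peak_orientations(60.0)
        geoms = [sim.VoxelGeometry(mu, 24.0, rc.DiffusionKernel(0.9e-3, 1.5))]
        ds = sim.generate_dataset(geoms, scheme60, snr=100.0, replicates=40,
                                  master_seed=23)
        sharp = rc.kernel_rh(rc.DiffusionKernel(0.9e-3, 8.0), 1500.0, 8,
                             domain="signal")
        fodf = rc.csd_deconvolve(ds.signals, scheme60, sharp, 8)
        pks = sp.extract_peaks_batch(fodf, 8, rel_threshold=0.25, max_peaks=5)
        nufo_err = np.array([p.nufo for p in pks]) - 2
        assert nufo_err.mean() > 0
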