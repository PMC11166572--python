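"""Reusable experiment workflows: reconstruct synthetic datasets with LSD and
the CSD baseline, score them, and run the published comparison designs at a
configurable problem size.

Voxels in these datasets are independent draws, so LSD runs without spatial
AIC pooling (each voxel's candidate scores stand alone).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import simulate as sim
from .lsd import LSDConfig, default_simulation_bank, lsd_fit_signals
from .recon import csd_deconvolve, estimate_response_tournier
from .sphere import GradientScheme, PeakSet, cached_scheme, extract_peaks_batch

log = logging.getLogger(__name__)

__all__ = [
    "lsd_peaks_on_dataset",
    "csd_peaks_on_dataset",
    "direction_sweep_experiment",
    "manyk_comparison",
    "retest_experiment",
]


def lsd_peaks_on_dataset(
    ds: sim.SyntheticDataset,
    config: LSDConfig | None = None,
) -> tuple[list[PeakSet], np.ndarray]:
    """LSD reconstruction of a flat voxel batch: peaks and selected ratios."""
    if config is None:
        config = LSDConfig(ratios=default_simulation_bank(), smooth_sigma=0.0)
    nvox = ds.signals.shape[0]
    fit = lsd_fit_signals(ds.signals, np.ones(nvox), ds.sigma, ds.scheme, config)
    sel = np.argmin(fit["aic"], axis=1)
    rows = np.arange(nvox)
    nufo = fit["nufo"][rows, sel]
    peaks = [
        PeakSet(fit["peak_dirs"][v, sel[v], : nufo[v]],
                fit["peak_fracs"][v, sel[v], : nufo[v]])
        for v in range(nvox)
    ]
    return peaks, config.ratios.ratios[sel]


def csd_peaks_on_dataset(
    ds: sim.SyntheticDataset,
    response_rh: np.ndarray,
    lmax: int = 8,
    rel_threshold: float = 0.25,
    min_sep_angle: float = 25.0,
) -> list[PeakSet]:
    """CSD reconstruction of a flat voxel batch with a global response."""
    fodf = csd_deconvolve(ds.signals, ds.scheme, response_rh, lmax)
    return extract_peaks_batch(fodf, lmax, rel_threshold=rel_threshold,
                               min_sep_angle=min_sep_angle, max_peaks=5)


def direction_sweep_experiment(
    n_values: list[int],
    replicates: int,
    master_seed: int = 0,
    bank_size: int = 16,
) -> pd.DataFrame:
    """Angular error of LSD vs number of diffusion directions.

    Follows the published design (60/90 degree crossings, kappa 24, R = 3,
    b = 1000 s/mm^2, noise scaled so sqrt(n)/sigma is constant with SNR 100
    at n = 55; reconstruction at SH order 6) on the requested subset of n
    values and replicate count.  Returns per-(n, geometry) records.
    """
    cfg = sim.build_direction_sweep(n_values=n_values, replicates=replicates)
    lsd_cfg = LSDConfig(
        ratios=default_simulation_bank(bank_size), lmax=cfg.lmax,
        smooth_sigma=0.0,
    )
    all_records = []
    for n in cfg.n_directions:
        scheme = cfg.scheme(n)
        sigma = cfg.sigma_for(n)
        ds = sim.generate_dataset(
            cfg.geometries, scheme, snr=None, sigma=sigma,
            replicates=cfg.replicates, master_seed=master_seed, lmax=cfg.lmax,
        )
        peaks, _ = lsd_peaks_on_dataset(ds, lsd_cfg)
        rec = ev.make_records(peaks, ds.truth, ds.orientations, ds.nufo, "LSD")
        rec["n_directions"] = n
        all_records.append(rec)
    return pd.concat(all_records, ignore_index=True)


def _companion_response(
    geometries,
    scheme: GradientScheme,
    snr: float,
    replicates: int,
    master_seed: int,
    lmax: int = 8,
) -> np.ndarray:
    """CSD response from a single-peak companion dataset (Tournier method)."""
    comp = sim.generate_dataset(
        geometries, scheme, snr=snr, replicates=replicates,
        master_seed=master_seed + 1_000_003, lmax=lmax,
    )
    return estimate_response_tournier(comp.signals, scheme, lmax)


def manyk_comparison(
    geometry_stride: int = 4,
    snr_levels: tuple = (20.0, 50.0, 100.0),
    replicates: int = 25,
    master_seed: int = 0,
    companion_replicates: int = 10,
) -> pd.DataFrame:
    """LSD vs CSD on a strided subset of the two-peak many-kernel design.

    Every ``geometry_stride``-th voxel geometry of the 1,950 is simulated at
    the requested SNR levels; the CSD response comes from the matching
    single-peak companion dataset at each SNR.  Returns the combined
    per-voxel evaluation records for both methods.
    """
    cfg = sim.build_2peaks_manyK(replicates=replicates)
    geometries = cfg.geometries[::geometry_stride]
    geometry_ids = list(range(0, len(cfg.geometries), geometry_stride))
    scheme = cached_scheme(60, cfg.bvalue, seed=cfg.scheme_seed)
    sub_cfg = sim.ExperimentConfig(
        name="subset", geometries=geometries, n_directions=[60],
        bvalue=cfg.bvalue, snr_levels=list(snr_levels), replicates=replicates,
    )
    companions = sim.companion_single_peak(sub_cfg)
    lsd_cfg = LSDConfig(ratios=default_simulation_bank(), smooth_sigma=0.0)

    records = []
    for snr in snr_levels:
        ds = sim.generate_dataset(
            geometries, scheme, snr=snr, replicates=replicates,
            master_seed=master_seed, geometry_ids=geometry_ids,
        )
        lsd_peaks, _ = lsd_peaks_on_dataset(ds, lsd_cfg)
        records.append(ev.make_records(lsd_peaks, ds.truth, ds.orientations,
                                       ds.nufo, "LSD"))
        response = _companion_response(companions, scheme, snr,
                                       companion_replicates, master_seed)
        csd_peaks = csd_peaks_on_dataset(ds, response)
        records.append(ev.make_records(csd_peaks, ds.truth, ds.orientations,
                                       ds.nufo, "CSD"))
        log.info("manyK comparison: SNR %g done (%d voxels/method)",
                 snr, len(ds.truth))
    return pd.concat(records, ignore_index=True)


def retest_experiment(
    n_geometries: int = 50,
    snr: float = 100.0,
    master_seed: int = 0,
) -> dict:
    """Synthetic test-retest: one set of voxel geometries, two noise draws.

    The same clean signals (fixed per-geometry rotations) are corrupted by
    two independent noise realizations and reconstructed independently;
    reports the voxel-wise coefficient of variation of the selected kernel
    ratio and the angles between matched fiber orientations.
    """
    cfg = sim.build_2peaks_oneK(replicates=1)
    step = max(1, len(cfg.geometries) // n_geometries)
    geometries = cfg.geometries[::step][:n_geometries]
    scheme = cached_scheme(60, cfg.bvalue, seed=cfg.scheme_seed)

    base = sim.generate_dataset(
        geometries, scheme, snr=snr, replicates=1, master_seed=master_seed,
    )
    rng1 = np.random.default_rng(np.random.SeedSequence([master_seed, 77, 1]))
    rng2 = np.random.default_rng(np.random.SeedSequence([master_seed, 77, 2]))
    sigma = 1.0 / snr
    runs = []
    for rng in (rng1, rng2):
        noisy = base.clean + rng.normal(0.0, sigma, base.clean.shape)
        ds = sim.SyntheticDataset(
            signals=noisy, clean=base.clean, sigma=base.sigma,
            scheme=scheme, truth=base.truth,
            orientations=base.orientations, nufo=base.nufo,
        )
        peaks, ratios = lsd_peaks_on_dataset(ds)
        runs.append((peaks, ratios))

    (pk1, r1), (pk2, r2) = runs
    nvox = len(pk1)
    p1 = np.zeros((nvox, 2, 3))
    p2 = np.zeros((nvox, 2, 3))
    n1 = np.array([p.nufo for p in pk1])
    n2 = np.array([p.nufo for p in pk2])
    for i in range(nvox):
        # match run-2 peaks to run-1 ordering before pairing angles
        if n1[i]:
            p1[i, : min(2, n1[i])] = pk1[i].orientations[:2]
        if n2[i] and n1[i]:
            ref = p1[i, 0]
            order = np.argsort(
                -np.abs(pk2[i].orientations @ ref)
            ) if n2[i] > 1 else np.array([0])
            ordered = pk2[i].orientations[order]
            p2[i, : min(2, n2[i])] = ordered[:2]
    metrics = ev.test_retest_metrics(
        {"ratio": r1}, {"ratio": r2}, p1, p2, n1, n2
    )
    valid = (n1 >= 1) & (n2 >= 1)
    return {
        "ratio_cov": metrics["cov"]["ratio"],
        "primary_angle": np.where(valid, metrics["angles"]["primary"], np.nan),
        "secondary_angle": metrics["angles"]["secondary"],
        "nufo_run1": n1,
        "nufo_run2": n2,
    }
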