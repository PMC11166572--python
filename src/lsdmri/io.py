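"""NIfTI / FSL-gradient-table readers and writers, fixtures, run manifests.

Orientation convention: gradient directions and all reported fiber
orientations live in image (voxel) coordinates, matching the FSL bvec
dialect.  No reorientation by the NIfTI affine is performed — the classic
dMRI pitfall to keep in mind when mixing tools.
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .lsd import LSDConfig, LSDResult
from .recon import DiffusionKernel, DWIVolume
from .sphere import GradientScheme, cached_scheme

log = logging.getLogger(__name__)

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_results",
    "make_fixture",
    "write_manifest",
]

B0_THRESHOLD = 50.0  # s/mm^2; volumes below count as non-diffusion-weighted


def _atomic_save(img: nib.Nifti1Image, path: Path) -> None:
    # write-temp-then-rename so readers never see partial files
    tmp = tempfile.NamedTemporaryFile(
        dir=path.parent, suffix=".nii.gz", delete=False
    )
    tmp.close()
    nib.save(img, tmp.name)
    os.replace(tmp.name, path)


def _atomic_write_text(text: str, path: Path) -> None:
    tmp = tempfile.NamedTemporaryFile(
        "w", dir=path.parent, suffix=".tmp", delete=False
    )
    tmp.write(text)
    tmp.close()
    os.replace(tmp.name, path)


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    """Read FSL-style bval/bvec text files into a GradientScheme.

    Accepts both 3xN and Nx3 bvec layouts (auto-detected by shape); bvecs
    deviating from unit norm by more than 1e-3 are renormalized with a
    warning.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ValueError("bvec file must be a 2D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"cannot interpret bvec shape {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise ValueError("bval/bvec length mismatch")
    norms = np.linalg.norm(bvecs, axis=1)
    # b=0 rows conventionally hold zero vectors; substitute +z placeholders
    zero = norms < 1e-6
    bvecs[zero] = [0.0, 0.0, 1.0]
    norms[zero] = 1.0
    if np.any(np.abs(norms - 1.0) > 1e-3):
        log.warning("renormalizing %d non-unit bvec(s)", int((np.abs(norms - 1) > 1e-3).sum()))
    return GradientScheme(directions=bvecs / norms[:, None], bvalues=bvals)


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path, layout: str = "3xn") -> None:
    """Write a scheme in the FSL text dialect (3xN by default)."""
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    _atomic_write_text(" ".join(f"{b:.6g}" for b in scheme.bvalues) + "\n", bval_path)
    d = scheme.directions if layout == "nx3" else scheme.directions.T
    _atomic_write_text(
        "\n".join(" ".join(f"{x:.12g}" for x in row) for row in d) + "\n", bvec_path
    )


def read_dwi(nifti_path, bval_path, bvec_path, sigma_path, mask_path) -> DWIVolume:
    """Load a 4D DWI dataset with noise map and mask into a DWIVolume.

    The b0 image is the mean of all volumes with b < 50 s/mm^2; the stored
    scheme retains only the diffusion-weighted directions.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("DWI must be a 4D NIfTI volume")
    scheme_all = read_bvals_bvecs(bval_path, bvec_path)
    if scheme_all.n != data.shape[-1]:
        raise ValueError(
            f"gradient table length {scheme_all.n} != volume count {data.shape[-1]}"
        )
    is_b0 = scheme_all.bvalues < B0_THRESHOLD
    if not np.any(is_b0):
        raise ValueError(
            "no b=0 volumes found (b < 50 s/mm^2 required for normalization)"
        )
    b0 = data[..., is_b0].mean(axis=-1)
    sigma = np.asarray(nib.load(str(sigma_path)).dataobj, dtype=float)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    dwi = DWIVolume(
        signal=data[..., ~is_b0],
        b0=b0,
        sigma_map=sigma,
        mask=mask,
        scheme=GradientScheme(
            scheme_all.directions[~is_b0], scheme_all.bvalues[~is_b0]
        ),
    )
    setattr(dwi, "affine", img.affine)
    return dwi


def write_results(
    result: LSDResult,
    out_dir,
    affine: np.ndarray | None = None,
    overwrite: bool = False,
    extra_manifest: dict | None = None,
) -> dict[str, Path]:
    """Write an LSDResult as NIfTI maps plus a YAML manifest.

    Outputs fodf.nii.gz (4D SH field; basis recorded in the sidecar), plus
    nufo, ratio and aic stacks; maps stored as float32 (NuFO as int16).
    Refuses to clobber existing outputs unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    files = {
        "fodf": result.fodf_field.astype(np.float32),
        "nufo": result.nufo_map.astype(np.int16),
        "ratio": result.ratio_map.astype(np.float32),
        "aic": np.where(np.isfinite(result.aic_stack), result.aic_stack, 0.0).astype(np.float32),
    }
    written = {}
    for name, arr in files.items():
        path = out_dir / f"{name}.nii.gz"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
        _atomic_save(nib.Nifti1Image(arr, affine), path)
        written[name] = path
    manifest = {
        "software": {"name": "lsdmri", "version": __version__},
        "sh_basis": "real, even-order, orthonormal; m from -l to l "
                    "(negative m = sine terms); convert to MRtrix via (-1)^m",
        "lmax": int(result.config.lmax) if result.config else None,
        "storage_dtype": "float32 (nufo: int16)",
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if result.config is not None:
        manifest["config"] = {
            "ratios": [float(r) for r in result.config.ratios.ratios],
            "lmax": result.config.lmax,
            "rel_threshold": result.config.rel_threshold,
            "min_sep_angle": result.config.min_sep_angle,
            "smooth_sigma": result.config.smooth_sigma,
            "selection_mode": result.config.selection_mode,
        }
    if extra_manifest:
        manifest.update(extra_manifest)
    mpath = out_dir / "manifest.yaml"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True to replace")
    _atomic_write_text(yaml.safe_dump(manifest, sort_keys=False), mpath)
    written["manifest"] = mpath
    return written


def write_manifest(path, config: dict, master_seed: int, inputs: dict | None = None) -> None:
    """Standalone run manifest: config echo, seed, input checksums, version."""
    checksums = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        checksums[name] = h
    doc = {
        "software": {"name": "lsdmri", "version": __version__},
        "master_seed": int(master_seed),
        "config": config,
        "input_checksums": checksums,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    _atomic_write_text(yaml.safe_dump(doc, sort_keys=False), Path(path))


def make_fixture(
    kind: str,
    out_dir,
    size: int = 8,
    seed: int = 0,
    snr: float = 100.0,
    n_directions: int = 60,
    bvalue: float = 1500.0,
    n_b0: int = 4,
) -> dict[str, Path]:
    """Generate a small on-disk phantom dataset (dwi/bval/bvec/sigma/mask).

    Kinds: ``single-fiber`` (one tight fiber population per voxel, R = 3),
    ``crossing`` (90 degree crossing, kappa 24) and ``heterogeneous-volume``
    (per-voxel random kernel ratio in [1.5, 8]).  Deterministic per seed;
    byte-identical across repeated calls.
    """
    from .simulate import VoxelGeometry, generate_dataset, _two_peak_orientations

    if size > 32:
        raise ValueError("test-tier fixtures are capped at 32^3 voxels")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nvox = size ** 3
    rng = np.random.default_rng(seed)
    if kind == "single-fiber":
        geoms = [VoxelGeometry(np.array([[0.0, 0.0, 1.0]]), 128.0,
                               DiffusionKernel(1.0e-3, 3.0))] * nvox
    elif kind == "crossing":
        geoms = [VoxelGeometry(_two_peak_orientations(90.0), 24.0,
                               DiffusionKernel(1.0e-3, 3.0))] * nvox
    elif kind == "heterogeneous-volume":
        ratios = rng.uniform(1.5, 8.0, nvox)
        geoms = [VoxelGeometry(np.array([[0.0, 0.0, 1.0]]), 128.0,
                               DiffusionKernel(1.0e-3, float(r))) for r in ratios]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    scheme = cached_scheme(n_directions, bvalue, seed=0)
    ds = generate_dataset(
        geoms, scheme, snr=snr, replicates=1, master_seed=seed,
        rotate=False, geometry_ids=list(range(nvox)),
    )
    shape = (size, size, size)
    sigma = 1.0 / snr
    dwi4d = np.concatenate([
        np.ones((nvox, n_b0)) + rng.normal(0.0, sigma, (nvox, n_b0)),
        ds.signals,
    ], axis=1).reshape(shape + (n_b0 + scheme.n,))

    affine = np.eye(4)
    paths = {}
    # deterministic timestamps come from gzip mtime=0 via nibabel defaults
    for name, arr in [
        ("dwi", dwi4d.astype(np.float32)),
        ("sigma", np.full(shape, sigma, dtype=np.float32)),
        ("mask", np.ones(shape, dtype=np.uint8)),
    ]:
        p = out_dir / f"{name}.nii.gz"
        img = nib.Nifti1Image(arr, affine)
        _atomic_save(img, p)
        paths[name] = p
    full_scheme = GradientScheme(
        np.vstack([np.tile([0.0, 0.0, 1.0], (n_b0, 1)), scheme.directions]),
        np.r_[np.zeros(n_b0), scheme.bvalues],
    )
    write_bvals_bvecs(full_scheme, out_dir / "dwi.bval", out_dir / "dwi.bvec")
    paths["bval"], paths["bvec"] = out_dir / "dwi.bval", out_dir / "dwi.bvec"
    truth_path = out_dir / "truth.tsv"
    _atomic_write_text(ds.truth.to_csv(sep="\t", index=False), truth_path)
    paths["truth"] = truth_path
    return paths
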