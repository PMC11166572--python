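"""Reconstruction scoring: NuFO error, matched angular error, STAR tables,
and test-retest stability metrics.

Angular error matches estimated and ground-truth peaks by exhaustive
enumeration of injective assignments (both sets are small) and reports the
assignment minimizing the mean of the per-pair angles, folded to [0, 90]
degrees for sign ambiguity.  A reconstruction counts as a *success* when its
peak count is exact and the angular error (mean over matched pairs) stays
below 5 degrees; the summed variant is also recorded per voxel.  The
success-to-attempt ratio (STAR) aggregates the success flags per
(SNR, crossing angle, method) cell as a percentage.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .sphere import PeakSet

__all__ = [
    "angular_error",
    "make_records",
    "star",
    "star_difference",
    "test_retest_metrics",
    "pairwise_peak_angles",
    "sweep_summary",
    "SUCCESS_ANGLE",
]

SUCCESS_ANGLE = 5.0   # degrees, mean over matched pairs
EMPTY_ANGLE = 90.0    # worst-case error assigned to empty estimates


def _fold_angle_deg(cosval: np.ndarray) -> np.ndarray:
    return np.degrees(np.arccos(np.clip(np.abs(cosval), 0.0, 1.0)))


def angular_error(
    estimated: PeakSet | np.ndarray,
    truth: np.ndarray,
    reduce: str = "mean",
) -> float:
    """Optimal-assignment angular error between peak sets, in degrees.

    Loops over all injective pair matches between the smaller set and the
    larger one and returns the minimum of the chosen reduction ("mean" or
    "total") of per-pair angles.  An empty estimate scores 90 degrees
    (worst case); the count mismatch itself is reported separately as the
    NuFO error.
    """
    est = estimated.orientations if isinstance(estimated, PeakSet) else np.asarray(estimated)
    est = est.reshape(-1, 3)
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    if truth.shape[0] == 0:
        raise ValueError("ground truth must contain at least one orientation")
    if est.shape[0] == 0:
        return EMPTY_ANGLE
    ang = _fold_angle_deg(est @ truth.T)       # (nest, ntrue)
    k = min(est.shape[0], truth.shape[0])
    nest, ntrue = ang.shape
    best = np.inf
    # enumerate injective assignments of the smaller side into the larger
    if nest <= ntrue:
        for perm in permutations(range(ntrue), k):
            best = min(best, ang[np.arange(k), perm].sum())
    else:
        for perm in permutations(range(nest), k):
            best = min(best, ang[perm, np.arange(k)].sum())
    return float(best / k) if reduce == "mean" else float(best)


def make_records(
    peaksets: list[PeakSet] | np.ndarray,
    truth: pd.DataFrame,
    true_orientations: np.ndarray,
    true_nufo: np.ndarray,
    method: str,
) -> pd.DataFrame:
    """Per-voxel evaluation records for one method.

    ``peaksets`` aligns with the rows of ``truth`` (the generator's table);
    ``true_orientations`` is the zero-padded (nvox, kmax, 3) ground truth.
    """
    rows = []
    for i, p in enumerate(peaksets):
        tr = true_orientations[i, : true_nufo[i]]
        mean_err = angular_error(p, tr, reduce="mean")
        total_err = mean_err * min(max(p.nufo, 1), true_nufo[i]) \
            if p.nufo else EMPTY_ANGLE * true_nufo[i]
        nufo_err = int(p.nufo - true_nufo[i])
        rows.append({
            "nufo_error": nufo_err,
            "angular_error": mean_err,
            "total_angular_error": total_err,
            "success": bool(nufo_err == 0 and mean_err < SUCCESS_ANGLE),
        })
    rec = pd.concat([truth.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    rec["method"] = method
    return rec


def star(
    records: pd.DataFrame,
    group_keys: list[str] = ("method", "snr", "crossing_angle"),
    min_attempts: int = 20,
) -> pd.DataFrame:
    """Success-to-attempt ratio per group, in percent.

    Cells with fewer than ``min_attempts`` records are omitted to bound
    binomial noise.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    g = records.groupby(list(group_keys), dropna=False)
    out = g.agg(attempts=("success", "size"), successes=("success", "sum"))
    out["star"] = 100.0 * out["successes"] / out["attempts"]
    out = out[out["attempts"] >= min_attempts]
    return out.reset_index()


def star_difference(
    table: pd.DataFrame,
    method_a: str = "LSD",
    method_b: str = "CSD",
    keys: list[str] = ("snr", "crossing_angle"),
) -> pd.DataFrame:
    """Percentage-point STAR difference (method_a - method_b) per cell."""
    keys = list(keys)
    a = table[table["method"] == method_a].set_index(keys)["star"]
    b = table[table["method"] == method_b].set_index(keys)["star"]
    diff = (a - b).dropna().rename("star_diff_pp")
    return diff.reset_index()


def pairwise_peak_angles(dirs1: np.ndarray, dirs2: np.ndarray) -> np.ndarray:
    """Elementwise folded angles (degrees) between two orientation arrays."""
    d1 = np.asarray(dirs1, dtype=float)
    d2 = np.asarray(dirs2, dtype=float)
    return _fold_angle_deg(np.sum(d1 * d2, axis=-1))


def test_retest_metrics(
    scalars1: dict[str, np.ndarray],
    scalars2: dict[str, np.ndarray],
    peaks1: np.ndarray | None = None,
    peaks2: np.ndarray | None = None,
    nufo1: np.ndarray | None = None,
    nufo2: np.ndarray | None = None,
) -> dict:
    """Voxel-wise stability of two aligned runs.

    For each scalar map, the two-sample coefficient of variation
    (sample s.d. / mean, undefined means masked out as NaN); for the peak
    fields, the folded angle between primary orientations, and between
    secondary orientations where both runs report NuFO >= 2.
    """
    out = {"cov": {}, "angles": {}}
    for name in scalars1:
        a = np.asarray(scalars1[name], dtype=float)
        b = np.asarray(scalars2[name], dtype=float)
        pair = np.stack([a, b])
        mean = pair.mean(axis=0)
        sd = pair.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = np.where(mean != 0, sd / mean, np.nan)
        out["cov"][name] = cov
    if peaks1 is not None and peaks2 is not None:
        out["angles"]["primary"] = pairwise_peak_angles(
            peaks1[..., 0, :], peaks2[..., 0, :]
        )
        if nufo1 is not None and nufo2 is not None:
            both2 = (np.asarray(nufo1) >= 2) & (np.asarray(nufo2) >= 2)
            sec = pairwise_peak_angles(peaks1[..., 1, :], peaks2[..., 1, :])
            out["angles"]["secondary"] = np.where(both2, sec, np.nan)
    return out


def sweep_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample s.d. of angular error per direction count and geometry."""
    g = records.groupby(["n_directions", "crossing_angle"])
    out = g["angular_error"].agg(
        mean_angular_error="mean",
        sd_angular_error=lambda x: x.std(ddof=1),
        replicates="size",
    )
    return out.reset_index()
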