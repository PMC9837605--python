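"""Group-level paired inference with Monte Carlo cluster-extent control.

The group map is a voxel-wise paired t-test of aware minus unaware
percent-area activation. Voxels passing an uncorrected height threshold
are retained only when they belong to a connected component whose extent
exceeds a size calibrated on null simulations: smooth Gaussian noise
fields matching the estimated residual smoothness are thresholded at the
same voxel-wise level, the maximum cluster size is recorded per
iteration, and the smallest extent whose exceedance frequency is at most
the corrected alpha becomes the cluster threshold (family-wise error
control over the whole map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .deconvolve import FWHM_TO_SIGMA

__all__ = [
    "TMap",
    "NullClusterDistribution",
    "paired_t_map",
    "simulate_null_clusters",
    "count_suprathreshold_clusters",
    "extract_clusters",
    "cluster_label_map",
]

CLUSTER_TABLE_COLUMNS = [
    "structure",
    "vol_uL",
    "hemisphere",
    "x",
    "y",
    "z",
    "n_voxels",
    "peak_t",
]


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


@dataclass
class TMap:
    """Voxel-wise paired t statistics with grid geometry."""

    t: np.ndarray
    df: int
    n_subjects: int
    voxel_mm: float
    affine: np.ndarray

    def threshold_for_p(self, voxel_p: float, two_tailed: bool = True) -> float:
        q = voxel_p / 2.0 if two_tailed else voxel_p
        return float(stats.t.isf(q, self.df))


def paired_t_map(
    aware_maps: np.ndarray,
    unaware_maps: np.ndarray,
    voxel_mm: float = 3.0,
    affine: np.ndarray | None = None,
) -> TMap:
    """Paired t-test of aware vs unaware maps, stacked (n, x, y, z).

    Per voxel, the one-sample t of the subject-wise differences with
    df = n - 1. Voxels with zero difference variance (or any non-finite
    subject value) are masked as NaN.
    """
    a = np.asarray(aware_maps, dtype=float)
    u = np.asarray(unaware_maps, dtype=float)
    if a.shape != u.shape:
        raise ValueError("aware and unaware stacks must share one shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - u
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # exactly identical inputs give 0/0 -> define t = 0 (no difference);
    # nonzero mean with zero variance stays masked (t undefined)
    t[(sd == 0) & (mean == 0)] = 0.0
    t[~np.isfinite(t)] = np.nan
    if affine is None:
        from .io import default_affine

        affine = default_affine(t.shape, voxel_mm)
    return TMap(t=t, df=n - 1, n_subjects=n, voxel_mm=voxel_mm, affine=affine)


@dataclass
class NullClusterDistribution:
    """Null distribution of suprathreshold cluster extent.

    ``max_sizes`` holds the per-iteration maximum cluster size (voxels).
    ``threshold_vox`` is the smallest extent whose null exceedance
    frequency is at most ``alpha``.
    """

    max_sizes: np.ndarray
    threshold_vox: int
    alpha: float
    voxel_p: float
    fwhm_mm: float
    voxel_mm: float
    n_iterations: int
    statistic: str

    @property
    def threshold_uL(self) -> float:
        return self.threshold_vox * self.voxel_mm**3

    def exceedance(self, size_vox: int) -> float:
        return float(np.mean(self.max_sizes >= size_vox))


def _null_field(
    grid_shape: tuple[int, int, int],
    sigma_vox: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One unit-variance smooth Gaussian null map (periodic boundary)."""
    field = rng.standard_normal(grid_shape)
    if sigma_vox > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="wrap")
        field /= field.std()
    return field


def count_suprathreshold_clusters(
    field: np.ndarray,
    z_thresh: float,
    connectivity: int = 6,
    two_tailed: bool = True,
) -> np.ndarray:
    """Sizes (voxels) of connected suprathreshold components of a map."""
    mask = np.abs(field) >= z_thresh if two_tailed else field >= z_thresh
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return np.zeros(0, dtype=int)
    return np.asarray(ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)), dtype=int)


def simulate_null_clusters(
    grid_shape: tuple[int, int, int],
    voxel_mm: float,
    fwhm_mm: float,
    voxel_p: float = 0.001,
    n_iter: int = 10_000,
    alpha: float = 0.010,
    seed: int = 0,
    connectivity: int = 6,
    two_tailed: bool = True,
    statistic: str = "max",
) -> NullClusterDistribution:
    """Monte Carlo selection of the cluster-extent threshold.

    Each iteration generates Gaussian white noise on the grid, smooths it
    to ``fwhm_mm``, standardises, thresholds at the two-tailed voxel-wise
    ``voxel_p``, and records cluster sizes. With ``statistic="max"`` the
    extent threshold is the smallest size s with P(max cluster >= s) <=
    alpha (family-wise control); with ``statistic="count"`` it is the
    smallest s with E[#clusters >= s] <= alpha per map.
    """
    if not 0.0 < voxel_p < 1.0:
        raise ValueError("voxel_p must be in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if alpha < 1.0 / n_iter:
        raise ValueError(
            f"alpha={alpha} finer than Monte Carlo resolution 1/{n_iter}"
        )
    if statistic not in ("max", "count"):
        raise ValueError("statistic must be 'max' or 'count'")
    rng = np.random.default_rng(seed)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    z = float(stats.norm.isf(voxel_p / 2.0 if two_tailed else voxel_p))

    max_sizes = np.zeros(n_iter, dtype=int)
    all_sizes: list[np.ndarray] = []
    for it in range(n_iter):
        sizes = count_suprathreshold_clusters(
            _null_field(grid_shape, sigma_vox, rng), z, connectivity, two_tailed
        )
        max_sizes[it] = sizes.max() if len(sizes) else 0
        if statistic == "count":
            all_sizes.append(sizes)

    if statistic == "max":
        # smallest s with P(max >= s) <= alpha
        sorted_max = np.sort(max_sizes)
        threshold = 1
        for s in range(1, int(max_sizes.max()) + 2):
            if np.mean(max_sizes >= s) <= alpha:
                threshold = s
                break
    else:
        sizes_flat = np.concatenate(all_sizes) if all_sizes else np.zeros(0, dtype=int)
        threshold = 1
        top = int(sizes_flat.max()) + 2 if len(sizes_flat) else 2
        for s in range(1, top):
            if np.sum(sizes_flat >= s) / n_iter <= alpha:
                threshold = s
                break
    return NullClusterDistribution(
        max_sizes=max_sizes,
        threshold_vox=int(threshold),
        alpha=alpha,
        voxel_p=voxel_p,
        fwhm_mm=fwhm_mm,
        voxel_mm=voxel_mm,
        n_iterations=n_iter,
        statistic=statistic,
    )


def cluster_label_map(
    tmap: TMap,
    t_threshold: float,
    min_volume_uL: float,
    connectivity: int = 6,
) -> np.ndarray:
    """Labelled component map of surviving clusters (0 = background)."""
    finite_t = np.nan_to_num(tmap.t, nan=0.0)
    mask = np.abs(finite_t) >= t_threshold
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    vox_uL = tmap.voxel_mm**3
    out = np.zeros_like(labels)
    next_id = 0
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if comp.sum() * vox_uL >= min_volume_uL:
            next_id += 1
            out[comp] = next_id
    return out


def extract_clusters(
    tmap: TMap,
    t_threshold: float,
    min_volume_uL: float,
    connectivity: int = 6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster table of suprathreshold components above the extent cutoff.

    Components of |t| >= threshold under the chosen connectivity are kept
    when their volume (voxel count x voxel volume; 1 mm^3 = 1 uL) reaches
    ``min_volume_uL``. The centre of mass is the |t|-weighted mean of the
    voxel world coordinates (RAS+ mm); the hemisphere is L/R by the sign
    of world x (M when |x| < half a voxel). Returns (table, label map);
    the table is sorted by decreasing volume and may be empty.
    """
    if t_threshold <= 0 or min_volume_uL < 0:
        raise ValueError("thresholds must be positive")
    labels = cluster_label_map(tmap, t_threshold, min_volume_uL, connectivity)
    n = int(labels.max())
    vox_uL = tmap.voxel_mm**3
    rows = []
    abst = np.abs(np.nan_to_num(tmap.t, nan=0.0))
    for lbl in range(1, n + 1):
        comp = labels == lbl
        idx = np.argwhere(comp)
        w = abst[comp]
        world = (tmap.affine @ np.c_[idx, np.ones(len(idx))].T)[:3].T
        com = (w[:, None] * world).sum(axis=0) / w.sum()
        peak = float(tmap.t[comp][np.argmax(w)])
        nvox = int(comp.sum())
        hemi = "M" if abs(com[0]) < tmap.voxel_mm / 2 else ("L" if com[0] < 0 else "R")
        rows.append(
            {
                "structure": "",
                "vol_uL": nvox * vox_uL,
                "hemisphere": hemi,
                "x": com[0],
                "y": com[1],
                "z": com[2],
                "n_voxels": nvox,
                "peak_t": peak,
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    if len(table):
        order = table["vol_uL"].to_numpy().argsort()[::-1]
        table = table.iloc[order].reset_index(drop=True)
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[np.asarray(order) + 1] = np.arange(1, n + 1)
        labels = relabel[labels]
        table.insert(0, "cluster_id", np.arange(1, n + 1))
    else:
        table.insert(0, "cluster_id", np.array([], dtype=int))
    return table, labels
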