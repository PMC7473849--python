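"""Between-subject searchlight decoding and group-level thresholding.

A sphere of fixed voxel radius (3 voxels, up to 123 voxels per sphere)
is scrolled across the in-mask grid; at every center the sphere's in-mask
voxels feed the shared decoding pipeline under leave-one-subject-out
cross-validation, and each left-out subject's test accuracy is written at
the center. The stack of per-subject accuracy maps is tested voxelwise
against chance (50%), thresholded with Benjamini–Hochberg FDR and a
cluster-extent criterion, and surviving clusters become ROIs for the
regional and temporal analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decode_core import (
    CvScheme,
    LabeledPatterns,
    balanced_subsample,
    cross_validate,
    detrend_zscore_trials,
    spatial_zscore,
)
from .synthetic_bold import VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "sphere_offsets",
    "AccuracyMap",
    "run_searchlight",
    "prepare_patterns",
    "group_test_vs_chance",
    "fdr_mask",
    "Roi",
    "RoiSet",
    "cluster_rois",
]


def sphere_offsets(radius: int) -> np.ndarray:
    """All integer voxel offsets with Euclidean norm <= radius.

    Radius 3 yields the canonical 123-voxel searchlight sphere.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius)
    grid = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = ii**2 + jj**2 + kk**2 <= radius**2
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


@dataclass
class AccuracyMap:
    """Per-voxel decoding accuracy, one map per left-out subject."""

    values: np.ndarray  # subjects x n_mask_voxels; NaN where skipped
    subject_ids: list
    grid: VolumeGrid
    label_set: str = ""

    @property
    def mean_map(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def prepare_patterns(
    beta_data: list[np.ndarray],
    labels: list[np.ndarray],
    subject_ids: list,
    meta: list[pd.DataFrame] | None = None,
) -> LabeledPatterns:
    """Normalize per-subject beta series and stack them for decoding.

    Per subject: spatial z-score of every trial map, then detrend +
    z-score of every voxel across trials, as in the searchlight pipeline.
    """
    Xs, ys, sids, metas = [], [], [], []
    for i, (X, y) in enumerate(zip(beta_data, labels)):
        Xn = detrend_zscore_trials(spatial_zscore(X))
        Xs.append(Xn)
        ys.append(np.asarray(y))
        sids.append(np.full(len(y), subject_ids[i], dtype=object))
        if meta is not None:
            metas.append(meta[i])
    return LabeledPatterns(
        np.vstack(Xs),
        np.concatenate(ys),
        np.concatenate(sids),
        pd.concat(metas, ignore_index=True) if meta is not None else None,
    )


def run_searchlight(
    patterns: LabeledPatterns,
    grid: VolumeGrid,
    radius: int = 3,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    C: float = 1.0,
    centers: np.ndarray | None = None,
) -> AccuracyMap:
    """Leave-one-subject-out searchlight over all in-mask centers.

    ``patterns`` should already be normalized (see ``prepare_patterns``)
    with features spanning the full in-mask voxel axis. Per subject, 50%
    of trials (class-balanced) are retained by default to bound the cost
    of the leave-one-subject-out fits. Spheres are clipped at mask edges;
    no per-sphere feature selection is applied. Centers with fewer than
    two in-sphere voxels are skipped (NaN) with a log entry.
    """
    if patterns.X.shape[1] != grid.n_voxels:
        raise ValueError("patterns features must span the grid's in-mask voxels")
    patterns = balanced_subsample(patterns, subsample_fraction, seed=seed)
    offs = sphere_offsets(radius)
    coords = grid.coords
    vol = grid.voxel_id_volume
    dims = np.array(grid.dims)
    subject_ids = list(np.unique(patterns.subject_ids))
    if centers is None:
        centers = np.arange(grid.n_voxels)
    values = np.full((len(subject_ids), grid.n_voxels), np.nan)
    scheme = CvScheme("leave_one_subject_out", seed=seed)
    for center in centers:
        pts = coords[center] + offs
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        ids = vol[tuple(pts[ok].T)]
        ids = ids[ids >= 0]
        if len(ids) < 2:
            logger.info("skipping searchlight center %d: sphere has %d voxels", center, len(ids))
            continue
        sub = LabeledPatterns(patterns.X[:, ids], patterns.y, patterns.subject_ids, None)
        res = cross_validate(sub, scheme, k_select=None, C=C)
        for fid, acc in zip(res.fold_ids, res.fold_accuracies):
            values[subject_ids.index(fid), center] = acc
    return AccuracyMap(values, subject_ids, grid)


def group_test_vs_chance(acc: AccuracyMap, chance: float = 0.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise one-sample t test of subject accuracies against chance.

    Returns (t, p, zero_variance_flag); voxels where all subjects score
    identically have t = 0 and p = 1 and are flagged.
    """
    vals = acc.values if isinstance(acc, AccuracyMap) else np.asarray(acc)
    if vals.shape[0] < 3:
        raise ValueError("need at least three subjects for the group test")
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    n = np.sum(~np.isnan(vals), axis=0)
    flat = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - chance) / (sd / np.sqrt(n))
    t = np.where(flat, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(flat, 1.0, p)
    return t, p, flat


def fdr_mask(p: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Benjamini–Hochberg step-up mask at level ``alpha``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


@dataclass
class Roi:
    label: int
    voxel_ids: np.ndarray  # in-mask voxel indices
    size: int
    peak_voxel: int | None = None  # in-mask index of max map value
    peak_value: float | None = None


@dataclass
class RoiSet:
    rois: list[Roi]
    grid: VolumeGrid

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def table(self) -> pd.DataFrame:
        rows = []
        for roi in self.rois:
            coord = self.grid.coords[roi.peak_voxel] if roi.peak_voxel is not None else None
            rows.append(
                dict(
                    label=roi.label,
                    size=roi.size,
                    peak_index=roi.peak_voxel,
                    peak_coord=None if coord is None else tuple(int(c) for c in coord),
                    peak_value=roi.peak_value,
                )
            )
        return pd.DataFrame(rows, columns=["label", "size", "peak_index", "peak_coord", "peak_value"])


def cluster_rois(
    mask: np.ndarray,
    grid: VolumeGrid,
    min_size: int = 50,
    connectivity: int = 6,
    value_map: np.ndarray | None = None,
) -> RoiSet:
    """Connected components of a significance mask, size-thresholded.

    ``mask`` is boolean over in-mask voxels; components use face
    connectivity by default (6-neighborhood; 18 and 26 also supported).
    ROIs come back sorted by size, largest first, relabeled 1..n; if a
    ``value_map`` (e.g. mean accuracy) is given, each ROI records its peak.
    """
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    vol = grid.unmask(np.asarray(mask, dtype=float)) > 0.5
    labeled, n = ndimage.label(vol, structure=structure)
    id_vol = grid.voxel_id_volume
    rois = []
    for lab in range(1, n + 1):
        where = labeled == lab
        size = int(where.sum())
        if size < min_size:
            continue
        ids = np.sort(id_vol[where])
        peak_voxel = peak_value = None
        if value_map is not None:
            vals = np.asarray(value_map)[ids]
            peak_voxel = int(ids[np.argmax(vals)])
            peak_value = float(np.max(vals))
        rois.append(Roi(lab, ids, size, peak_voxel, peak_value))
    rois.sort(key=lambda r: -r.size)
    for i, roi in enumerate(rois):
        roi.label = i + 1
    return RoiSet(rois, grid)
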