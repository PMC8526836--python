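"""Resting-state functional connectivity statistics.

Voxelwise and regionwise rsfMRI measures: Pearson correlation matrices,
Fisher r-to-z, weighted global (degree-centrality) connectivity with an
optional long-range distance exclusion, seed-based correlation maps,
group contrasts (Cohen's d, pooled-variance t), cross-site occurrence
maps, permutation cluster-extent correction, Dice overlap, motion
censoring, and covariate residualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

__all__ = [
    "FCMatrix", "VoxelDataset", "ConnectivityMap", "Cluster",
    "SubjectExcluded", "fc_matrix", "fisher_z", "global_connectivity",
    "seed_map", "cohen_d_map", "occurrence_map", "group_tmap",
    "permutation_cluster_correct", "grid_adjacency", "dice",
    "censor_frames", "residualize",
]

_R_CLIP = 1.0 - 1e-7


class SubjectExcluded(RuntimeError):
    """Raised when motion censoring leaves too few usable frames."""


@dataclass
class FCMatrix:
    """Pearson functional-connectivity matrix with optional Fisher-z copy."""

    labels: list[str]
    R: np.ndarray
    Z: np.ndarray | None = None


@dataclass
class VoxelDataset:
    """Voxel x time BOLD data with physical voxel-center coordinates."""

    data: np.ndarray          # voxel x time
    coords: np.ndarray        # voxel x 3, physical units (um or mm)
    mask: np.ndarray | None = None  # boolean inclusion flags per voxel
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != self.data.shape[0]:
            raise ValueError("coords and data must be row-aligned")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.data.shape[0],):
                raise ValueError("mask must flag each voxel row")


@dataclass
class ConnectivityMap:
    """Per-voxel (or per-region) scalar map: Fisher z, d, t, or counts."""

    values: np.ndarray
    units: str = "z"


@dataclass
class Cluster:
    voxels: np.ndarray        # indices into the map
    extent: int
    p_value: float
    significant: bool


def fc_matrix(ts: np.ndarray, labels: list[str] | None = None) -> FCMatrix:
    """Pairwise temporal Pearson correlation of a region x time matrix.

    Constant rows are flagged with a warning and their correlations set to
    NaN (diagonal kept at 1).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a region x time matrix with >= 3 timepoints")
    constant = ts.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(ts)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant region(s); "
                      "correlations undefined (NaN)")
        R[constant, :] = np.nan
        R[:, constant] = np.nan
    np.fill_diagonal(R, 1.0)
    if labels is None:
        labels = [f"r{i}" for i in range(ts.shape[0])]
    return FCMatrix(labels=list(labels), R=R, Z=fisher_z(R))


def fisher_z(r):
    """Variance-stabilizing Fisher r-to-z transform, z = atanh(r).

    Correlations with |r| >= 1 - 1e-7 are clipped to that bound first so
    the result stays finite (degenerate perfectly correlated pairs).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return z if z.ndim else float(z)


def _masked(ds: VoxelDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.flatnonzero(ds.mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    return idx, ds.data[idx], ds.coords[idx]


def global_connectivity(ds: VoxelDataset,
                        exclusion_radius_um: float = 0.0) -> ConnectivityMap:
    """Weighted global connectivity (unthresholded weighted degree centrality).

    Per masked voxel: the mean Fisher-z correlation with every other masked
    voxel whose center lies strictly farther than ``exclusion_radius_um``
    (the long-range variant; radius 0 keeps all other voxels).  Voxels with
    no admissible partner get NaN with a warning.  Unmasked voxels are NaN.
    """
    idx, data, coords = _masked(ds)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(data)
    Z = fisher_z(np.nan_to_num(R, nan=0.0))
    admissible = ~np.eye(idx.size, dtype=bool)
    if exclusion_radius_um > 0:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        admissible &= d2 > exclusion_radius_um ** 2
    counts = admissible.sum(axis=1)
    if np.all(counts == 0):
        raise ValueError("no voxel has an admissible partner at this radius")
    values = np.full(ds.data.shape[0], np.nan)
    with np.errstate(invalid="ignore"):
        gc = np.where(admissible, Z, 0.0).sum(axis=1) / counts
    if np.any(counts == 0):
        warnings.warn(f"{int((counts == 0).sum())} voxel(s) have no "
                      "admissible partner; set to NaN")
        gc[counts == 0] = np.nan
    values[idx] = gc
    return ConnectivityMap(values=values, units="z")


def seed_map(ds: VoxelDataset, seed_voxels) -> ConnectivityMap:
    """Fisher-z correlation of each voxel with the seed's mean timeseries."""
    seed_voxels = np.asarray(seed_voxels, dtype=int)
    if seed_voxels.size == 0:
        raise ValueError("seed is empty")
    if not ds.mask[seed_voxels].all():
        raise ValueError("seed voxels must lie inside the mask")
    idx, data, _ = _masked(ds)
    seed_ts = ds.data[seed_voxels].mean(axis=0)
    if seed_ts.std() == 0:
        raise ValueError("seed timeseries is constant")
    sc = (seed_ts - seed_ts.mean()) / seed_ts.std()
    dc = data - data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc @ sc) / (sd * len(sc))
    values = np.full(ds.data.shape[0], np.nan)
    values[idx] = fisher_z(np.nan_to_num(r, nan=0.0))
    return ConnectivityMap(values=values, units="z")


def _stack(maps) -> np.ndarray:
    rows = [m.values if isinstance(m, ConnectivityMap) else np.asarray(m, float)
            for m in maps]
    return np.vstack(rows)


def cohen_d_map(mapsA, mapsB) -> ConnectivityMap:
    """Voxelwise Cohen's d between two groups of subject maps.

    d = (mean_A - mean_B) / s_pooled with the two (n-1)-denominator sample
    variances pooled by degrees of freedom.  Zero pooled SD gives NaN with
    a warning.
    """
    A, B = _stack(mapsA), _stack(mapsB)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    zero = sp == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} feature(s) with zero pooled SD; NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (A.mean(axis=0) - B.mean(axis=0)) / np.where(zero, np.nan, sp)
    return ConnectivityMap(values=d, units="d")


def occurrence_map(site_d_maps, d_threshold: float = 0.2) -> ConnectivityMap:
    """Count, per voxel, how many site-level d maps exceed the threshold."""
    D = _stack(site_d_maps)
    counts = (D > d_threshold).sum(axis=0)
    return ConnectivityMap(values=counts.astype(float), units="count")


def group_tmap(mapsA, mapsB) -> ConnectivityMap:
    """Unpaired two-sample Student's t map (pooled variance) per voxel."""
    A, B = _stack(mapsA), _stack(mapsB)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(A, B, axis=0, equal_var=True).statistic
    return ConnectivityMap(values=t, units="t")


def suprathreshold_mask(tmap: ConnectivityMap, t_threshold: float = 2.0) -> np.ndarray:
    """Boolean |t| > threshold companion mask."""
    return np.abs(tmap.values) > t_threshold


def grid_adjacency(shape: tuple[int, ...]) -> sparse.csr_matrix:
    """6-connectivity adjacency of a regular 3-D voxel grid (flat indexing)."""
    shape = tuple(shape)
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for axis in range(len(shape)):
        a = np.take(idx, range(shape[axis] - 1), axis=axis).ravel()
        b = np.take(idx, range(1, shape[axis]), axis=axis).ravel()
        rows.extend([a, b])
        cols.extend([b, a])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    return sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))


def _clusters_from_tvalues(t: np.ndarray, threshold: float,
                           adjacency: sparse.spmatrix) -> list[np.ndarray]:
    """Connected components of same-sign suprathreshold voxels."""
    out = []
    for sign in (1.0, -1.0):
        supra = np.flatnonzero(sign * t > threshold)
        if supra.size == 0:
            continue
        sub = adjacency[supra][:, supra]
        n_comp, lab = csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            out.append(supra[lab == c])
    return out


def permutation_cluster_correct(tmap: ConnectivityMap, mapsA, mapsB,
                                adjacency: sparse.spmatrix,
                                cluster_forming_t: float = 2.0,
                                alpha: float = 0.01, n_perm: int = 1000,
                                seed: int = 0) -> list[Cluster]:
    """Cluster-extent family-wise-error correction by label permutation.

    Clusters of contiguous same-sign suprathreshold voxels are significant
    when their extent exceeds the (1 - alpha) quantile of the maximum
    cluster extent obtained under random relabeling of group membership.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    A, B = _stack(mapsA), _stack(mapsB)
    n_vox = A.shape[1]
    if (adjacency.shape != (n_vox, n_vox)
            or (adjacency != adjacency.T).nnz != 0):
        raise ValueError("adjacency must be a symmetric voxel x voxel graph")
    adjacency = sparse.csr_matrix(adjacency)
    pooled = np.vstack([A, B])
    na = A.shape[0]
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        tp = group_tmap(pooled[perm[:na]], pooled[perm[na:]]).values
        cl = _clusters_from_tvalues(np.nan_to_num(tp), cluster_forming_t,
                                    adjacency)
        null_max[p] = max((c.size for c in cl), default=0)
    extent_threshold = np.quantile(null_max, 1.0 - alpha)
    clusters = []
    for vox in _clusters_from_tvalues(np.nan_to_num(tmap.values),
                                      cluster_forming_t, adjacency):
        pval = (1 + np.sum(null_max >= vox.size)) / (n_perm + 1)
        clusters.append(Cluster(voxels=vox, extent=vox.size, p_value=pval,
                                significant=vox.size > extent_threshold))
    return clusters


def dice(maskA, maskB) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two voxel sets."""
    A = np.asarray(maskA, dtype=bool)
    B = np.asarray(maskB, dtype=bool)
    total = A.sum() + B.sum()
    if total == 0:
        warnings.warn("both masks empty; Dice undefined")
        return float("nan")
    return 2.0 * np.logical_and(A, B).sum() / total


def censor_frames(ts: np.ndarray, fd: np.ndarray,
                  fd_threshold_mm: float = 0.2,
                  min_fraction: float = 0.5) -> np.ndarray:
    """Drop frames whose framewise displacement exceeds the threshold.

    Raises :class:`SubjectExcluded` when fewer than ``min_fraction`` of the
    frames survive (the subject should be dropped from the analysis).
    """
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.shape[1]:
        raise ValueError("fd must have one value per frame (column)")
    keep = fd <= fd_threshold_mm
    if keep.mean() < min_fraction:
        raise SubjectExcluded(
            f"only {keep.sum()}/{keep.size} frames below "
            f"{fd_threshold_mm} mm")
    return ts[:, keep]


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
                names.append(dname)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def residualize(maps: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of each feature on intercept + covariates.

    Categorical columns (e.g. acquisition site) are expanded to indicator
    codes.  This is the fixed-effect harmonization: per-site mean offsets
    and linear covariate contributions are removed from every feature.
    """
    M = np.asarray(maps, dtype=float)
    if M.shape[0] != len(covariates):
        raise ValueError("maps and covariates must have one row per subject")
    X, names = _design_matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta
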