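"""Voxelwise statistics on aligned metabolism volumes.

SUVR proportional scaling, Gaussian smoothing, mass-univariate OLS
contrasts (group difference, loss-aversion regression, sex-by-LA
interaction), cluster-forming thresholds, cluster-level FDR via
permutation (Freedman-Lane when nuisance covariates are present),
minimum-statistic conjunction, peak tables, and ROI extraction.

Cluster-level inference: voxels exceeding the one-sided forming
threshold (default p < 0.001) are grouped into connected components
(default 18-connectivity), each component's extent is referred to a
permutation null distribution of the maximum cluster extent, and
Benjamini-Hochberg FDR is applied across the observed clusters'
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.ndimage import gaussian_filter, generate_binary_structure, label

from .behavior import fdr_adjust
from .volume import VolumeImage

__all__ = [
    "DesignSpec",
    "StatMap",
    "ClusterResult",
    "proportional_scale",
    "smooth_gaussian",
    "fit_voxelwise_glm",
    "cluster_inference",
    "conjunction",
    "peak_table",
    "cluster_to_mask",
    "extract_roi_means",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_STRUCTURES = {6: generate_binary_structure(3, 1),
               18: generate_binary_structure(3, 2),
               26: generate_binary_structure(3, 3)}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def proportional_scale(volume: VolumeImage) -> VolumeImage:
    """Scale a volume to its global mean (SUVR).

    The global value uses the two-pass rule: first the whole-volume
    mean m0, then the mean of voxels exceeding m0/8 (this excludes
    air/background so the global tracks in-brain uptake).  The output
    is input / global, making all downstream statistics invariant to
    per-subject multiplicative uptake factors.
    """
    m0 = volume.data.mean()
    sel = volume.data > m0 / 8.0
    if not sel.any():
        raise ValueError("no voxels exceed one-eighth of the volume mean")
    global_value = volume.data[sel].mean()
    if global_value <= 0:
        raise ValueError(f"non-positive global value {global_value}")
    return volume.with_data(volume.data / global_value, is_scaled=True)


def smooth_gaussian(volume: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Separable Gaussian smoothing with an isotropic FWHM in mm.

    sigma_mm = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel
    units from the affine (anisotropic voxels are handled per axis).
    Zero-flux ("reflect") boundaries, so an interior impulse conserves
    mass.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return volume.with_data(volume.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / volume.voxel_sizes
    return volume.with_data(gaussian_filter(volume.data, sigma_vox,
                                            mode="reflect"))


# ---------------------------------------------------------------------------
# design and GLM
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Named design matrix with a contrast.

    Build with :meth:`build`, which mean-centers the requested columns
    and forms product (interaction) columns from the centered factors.
    """

    matrix: pd.DataFrame
    contrast: np.ndarray
    contrast_name: str = ""
    direction: int = 1            # +1: test c'beta > 0; -1: c'beta < 0

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        X = self.matrix.to_numpy(dtype=float)
        if len(self.contrast) != X.shape[1]:
            raise ValueError("contrast length must equal design column count")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @classmethod
    def build(cls, columns: dict[str, np.ndarray],
              contrast: dict[str, float],
              contrast_name: str = "", direction: int = 1,
              center: tuple[str, ...] = (),
              products: dict[str, tuple[str, str]] | None = None,
              add_intercept: bool = True) -> "DesignSpec":
        cols = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
        for c in center:
            cols[c] = cols[c] - cols[c].mean()
        for name, (a, b) in (products or {}).items():
            cols[name] = cols[a] * cols[b]
        if add_intercept and "intercept" not in cols:
            n = len(next(iter(cols.values())))
            cols = {"intercept": np.ones(n), **cols}
        mat = pd.DataFrame(cols)
        cvec = np.array([contrast.get(c, 0.0) for c in mat.columns])
        return cls(mat, cvec, contrast_name, direction)

    def with_contrast(self, contrast: dict[str, float], name: str = "",
                      direction: int = 1) -> "DesignSpec":
        cvec = np.array([contrast.get(c, 0.0) for c in self.matrix.columns])
        return DesignSpec(self.matrix, cvec, name, direction)


@dataclass
class StatMap:
    """Voxelwise t-statistic grid with its inferential context.

    ``data`` holds t values in-mask and NaN outside (out-of-mask voxels
    are absent, never zero).  Carries the per-voxel data and design so
    permutation inference can re-fit under resampling.
    """

    data: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray
    contrast_name: str = ""
    direction: int = 1
    _Y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _contrast: np.ndarray | None = field(default=None, repr=False)

    def forming_t(self, forming_p: float) -> float:
        """One-sided t threshold equivalent to the forming p."""
        return float(st.t.ppf(1.0 - forming_p, self.df))

    def suprathreshold(self, forming_p: float) -> np.ndarray:
        """Boolean grid of in-mask voxels exceeding the forming threshold
        in the map's direction."""
        t = self.forming_t(forming_p)
        out = np.zeros(self.mask.shape, dtype=bool)
        out[self.mask] = np.nan_to_num(self.data[self.mask],
                                       nan=-np.inf) > t
        return out


def _t_from_Y(Y: np.ndarray, X: np.ndarray, c: np.ndarray,
              pinvX: np.ndarray, cc: float, df: int) -> np.ndarray:
    """t = c'beta / sqrt(sigma^2 c'(X'X)^-1 c) for stacked voxel data."""
    B = pinvX @ Y
    resid = Y - X @ B
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    denom = np.sqrt(np.maximum(sigma2 * cc, 1e-300))
    return (c @ B) / denom


def fit_voxelwise_glm(volumes, design: DesignSpec,
                      mask: np.ndarray | None = None) -> StatMap:
    """Per-voxel ordinary least squares with a t contrast.

    ``volumes`` is an ordered sequence of :class:`VolumeImage`, one per
    design row, sharing grid and affine.  The contrast is evaluated in
    the design's stated direction (the sign of ``c'beta`` is flipped
    for direction -1, so larger t always means "more in the predicted
    direction").
    """
    vols = list(volumes.values()) if isinstance(volumes, dict) else list(volumes)
    X = design.matrix.to_numpy(dtype=float)
    n, k = X.shape
    if len(vols) != n:
        raise ValueError(f"{len(vols)} volumes for {n} design rows")
    shape, affine = vols[0].shape, vols[0].affine
    for v in vols[1:]:
        if v.shape != shape or not np.allclose(v.affine, affine):
            raise ValueError("all volumes must share shape and affine")
    if mask is None:
        mask = vols[0].mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
    Y = np.stack([v.data[mask] for v in vols])        # (n, v)
    c = design.contrast * design.direction
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    pinvX = np.linalg.pinv(X)
    cc = float(c @ np.linalg.inv(X.T @ X) @ c)
    t = _t_from_Y(Y, X, c, pinvX, cc, df)
    grid = np.full(shape, np.nan)
    grid[mask] = t
    return StatMap(grid, df, mask, affine, design.contrast_name,
                   design.direction, _Y=Y, _X=X, _contrast=c)


# ---------------------------------------------------------------------------
# cluster inference
# ---------------------------------------------------------------------------

def _label_clusters(binary: np.ndarray, connectivity: int):
    struct = _STRUCTURES[connectivity]
    labels, n = label(binary, structure=struct)
    return labels, n


def _max_extent(binary: np.ndarray, connectivity: int) -> int:
    labels, n = _label_clusters(binary, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


@dataclass
class ClusterResult:
    """Suprathreshold clusters of a statistic map with corrected p-values."""

    table: pd.DataFrame
    label_map: np.ndarray
    stat_map: StatMap
    forming_p: float
    q_fdr: float
    connectivity: int
    n_permutations: int
    null_max_extent: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_significant(self) -> int:
        if len(self.table) == 0:
            return 0
        return int(self.table["significant"].sum())

    def significant_ids(self) -> list[int]:
        if len(self.table) == 0:
            return []
        return [int(i) for i in
                self.table.loc[self.table["significant"], "cluster_id"]]


def cluster_inference(stat_map: StatMap, forming_p: float = 0.001,
                      q_fdr: float = 0.05, n_permutations: int = 1000,
                      connectivity: int = 18,
                      seed: int | np.random.Generator = 0) -> ClusterResult:
    """Cluster-extent inference with a permutation null and cluster FDR.

    The null distribution of the maximum suprathreshold cluster extent
    is built by Freedman-Lane permutation: the reduced (nuisance-only)
    model is fit, its residuals are permuted and added back to the
    reduced fit, and the full model is re-estimated.  Columns with
    nonzero contrast weight are "of interest"; the rest (intercept and
    covariates) are nuisance.  With no nuisance beyond the intercept
    this reduces to the usual group-label/data permutation.

    Each observed cluster gets p_uncorr = Pr(max null extent >= K), and
    BH-FDR is applied across the observed clusters.  No suprathreshold
    voxels yields an empty table.
    """
    if stat_map._Y is None:
        raise ValueError("stat map lacks the data needed for permutation")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    rng = np.random.default_rng(seed)
    Y, X, c = stat_map._Y, stat_map._X, stat_map._contrast
    n, k = X.shape
    df = stat_map.df
    t_thresh = stat_map.forming_t(forming_p)
    mask = stat_map.mask
    shape = mask.shape

    pinvX = np.linalg.pinv(X)
    cc = float(c @ np.linalg.inv(X.T @ X) @ c)

    # observed clusters
    supra = stat_map.suprathreshold(forming_p)
    labels, n_clus = _label_clusters(supra, connectivity)
    if n_clus == 0:
        empty = pd.DataFrame(columns=["cluster_id", "extent", "peak_t",
                                      "peak_i", "peak_j", "peak_k",
                                      "peak_x", "peak_y", "peak_z",
                                      "p_uncorrected", "p_fdr", "significant"])
        return ClusterResult(empty, labels, stat_map, forming_p, q_fdr,
                             connectivity, n_permutations, None)

    # Freedman-Lane null of the max cluster extent
    interest = c != 0
    Z = X[:, ~interest]
    if Z.shape[1] == 0:
        fitted_r = np.zeros_like(Y)
        resid_r = Y
    else:
        pinvZ = np.linalg.pinv(Z)
        fitted_r = Z @ (pinvZ @ Y)
        resid_r = Y - fitted_r
    null_max = np.empty(n_permutations, dtype=int)
    grid = np.zeros(shape)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        t_null = _t_from_Y(fitted_r + resid_r[perm], X, c, pinvX, cc, df)
        grid[mask] = t_null
        null_max[b] = _max_extent((grid > t_thresh) & mask, connectivity)

    rows = []
    for cid in range(1, n_clus + 1):
        in_c = labels == cid
        extent = int(in_c.sum())
        tvals = np.where(in_c, stat_map.data, -np.inf)
        peak_idx = np.unravel_index(np.nanargmax(np.nan_to_num(tvals, nan=-np.inf)),
                                    shape)
        world = stat_map.affine @ np.array([*peak_idx, 1.0])
        p_unc = (1 + int((null_max >= extent).sum())) / (n_permutations + 1)
        rows.append({"cluster_id": cid, "extent": extent,
                     "peak_t": float(stat_map.data[peak_idx]),
                     "peak_i": peak_idx[0], "peak_j": peak_idx[1],
                     "peak_k": peak_idx[2],
                     "peak_x": float(world[0]), "peak_y": float(world[1]),
                     "peak_z": float(world[2]),
                     "p_uncorrected": p_unc})
    table = pd.DataFrame(rows).sort_values("extent", ascending=False,
                                           ignore_index=True)
    table["p_fdr"] = fdr_adjust(table["p_uncorrected"].to_numpy())
    table["significant"] = table["p_fdr"] < q_fdr
    return ClusterResult(table, labels, stat_map, forming_p, q_fdr,
                         connectivity, n_permutations, null_max)


def conjunction(map_a: StatMap, map_b: StatMap,
                forming_p: float = 0.001,
                clusters_a: ClusterResult | None = None,
                clusters_b: ClusterResult | None = None,
                connectivity: int = 18) -> tuple[np.ndarray, pd.DataFrame]:
    """Minimum-statistic conjunction of two maps.

    A voxel survives iff it exceeds its own one-sided forming threshold
    in both maps (each in its stated direction); the surviving set is
    exactly the intersection of the two suprathreshold sets.  Surviving
    voxels are clustered and tabulated with the peak minimum statistic.
    When the parent cluster results are supplied, each conjunction
    cluster inherits as corrected p the larger of the corrected p's of
    the parent clusters it falls inside (a conjunction can be no more
    significant than its weaker parent); otherwise p is NaN.
    """
    if map_a.mask.shape != map_b.mask.shape:
        raise ValueError("maps must share the grid")
    if not np.allclose(map_a.affine, map_b.affine):
        raise ValueError("maps must share the affine")
    joint = map_a.suprathreshold(forming_p) & map_b.suprathreshold(forming_p)
    labels, n_clus = _label_clusters(joint, connectivity)
    rows = []
    min_stat = np.fmin(np.nan_to_num(map_a.data, nan=-np.inf),
                       np.nan_to_num(map_b.data, nan=-np.inf))
    for cid in range(1, n_clus + 1):
        in_c = labels == cid
        tvals = np.where(in_c, min_stat, -np.inf)
        peak_idx = np.unravel_index(np.argmax(tvals), joint.shape)
        world = map_a.affine @ np.array([*peak_idx, 1.0])
        p_corr = np.nan
        if clusters_a is not None and clusters_b is not None:
            p_parent = []
            for res in (clusters_a, clusters_b):
                ids = np.unique(res.label_map[in_c])
                ids = ids[ids > 0]
                if len(ids) and len(res.table):
                    sub = res.table.set_index("cluster_id").loc[ids, "p_fdr"]
                    p_parent.append(float(sub.min()))
                else:
                    p_parent.append(np.nan)
            p_corr = float(np.max(p_parent))
        rows.append({"cluster_id": cid, "extent": int(in_c.sum()),
                     "peak_min_t": float(min_stat[peak_idx]),
                     "peak_i": peak_idx[0], "peak_j": peak_idx[1],
                     "peak_k": peak_idx[2],
                     "peak_x": float(world[0]), "peak_y": float(world[1]),
                     "peak_z": float(world[2]), "p_fdr": p_corr})
    table = pd.DataFrame(rows, columns=["cluster_id", "extent", "peak_min_t",
                                        "peak_i", "peak_j", "peak_k",
                                        "peak_x", "peak_y", "peak_z", "p_fdr"])
    return joint, table


def peak_table(clusters: ClusterResult, max_peaks: int = 3) -> pd.DataFrame:
    """Local maxima within each cluster, in world coordinates.

    A voxel is a local maximum if its t is >= every 26-neighbor within
    the same cluster.  Up to ``max_peaks`` per cluster, sorted by t
    descending with lexicographic voxel-index tie-break.
    """
    sm_ = clusters.stat_map
    labels = clusters.label_map
    t = np.nan_to_num(sm_.data, nan=-np.inf)
    rows = []
    for cid in (clusters.table["cluster_id"] if len(clusters.table) else []):
        idxs = np.argwhere(labels == cid)
        peaks = []
        for ijk in idxs:
            i, j, k = ijk
            val = t[i, j, k]
            is_peak = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        ni, nj, nk = i + di, j + dj, k + dk
                        if (0 <= ni < t.shape[0] and 0 <= nj < t.shape[1]
                                and 0 <= nk < t.shape[2]
                                and labels[ni, nj, nk] == cid
                                and t[ni, nj, nk] > val):
                            is_peak = False
                            break
                    if not is_peak:
                        break
                if not is_peak:
                    break
            if is_peak:
                peaks.append((val, tuple(int(v) for v in ijk)))
        peaks.sort(key=lambda p: (-p[0], p[1]))
        for val, ijk in peaks[:max_peaks]:
            world = sm_.affine @ np.array([*ijk, 1.0])
            rows.append({"cluster_id": int(cid), "t": float(val),
                         "i": ijk[0], "j": ijk[1], "k": ijk[2],
                         "x": float(world[0]), "y": float(world[1]),
                         "z": float(world[2])})
    return pd.DataFrame(rows, columns=["cluster_id", "t", "i", "j", "k",
                                       "x", "y", "z"])


def cluster_to_mask(clusters: ClusterResult, cluster_id: int) -> VolumeImage:
    """Binary mask of one cluster on the statistic map's grid."""
    binary = clusters.label_map == cluster_id
    if not binary.any():
        raise ValueError(f"cluster {cluster_id} is empty or absent")
    return VolumeImage(binary.astype(float), clusters.stat_map.affine,
                       mask=clusters.stat_map.mask)


def extract_roi_means(volumes, mask: VolumeImage | np.ndarray) -> pd.Series:
    """Unweighted mean of in-mask voxel values, per subject."""
    binary = mask.data.astype(bool) if isinstance(mask, VolumeImage) \
        else np.asarray(mask, dtype=bool)
    if not binary.any():
        raise ValueError("ROI mask is empty")
    items = volumes.items() if isinstance(volumes, dict) \
        else enumerate(volumes)
    out = {}
    for key, vol in items:
        if vol.shape != binary.shape:
            raise ValueError("mask grid differs from volume grid")
        out[key] = float(vol.data[binary].mean())
    return pd.Series(out, name="roi_mean")
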