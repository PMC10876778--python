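"""Group-level inference on voxel maps.

The case–control contrast is a voxel-wise pooled-variance two-sample
t-test.  Cluster-level family-wise-error control uses permutation of group
labels with the maximum-cluster-size statistic: voxels two-sided
supra-threshold at the cluster-defining p (default 0.001) are grouped with
26-connectivity, separately for each sign, and each observed cluster's FWE
p-value is the proportion of permutation maxima at least as large as its
size.  When the number of distinct label assignments is small the
permutation distribution is enumerated exhaustively.

``GroupContrast`` is the model object (built from two lists of maps and a
mask); ``fit`` returns a :class:`GroupContrastResults` carrying the t-map,
the cluster set, per-cluster effect sizes and a ``summary`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import ActivityMap, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "voxelwise_ttest",
    "cluster_fwe",
    "cohens_d",
    "extract_roi_mean",
    "Cluster",
    "ClusterSet",
    "GroupContrast",
    "GroupContrastResults",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


def _stack(maps: list[ActivityMap]) -> np.ndarray:
    return np.stack([m.data for m in maps], axis=0)


def _tstat(data_a: np.ndarray, data_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (b minus a) along axis 0, vectorized."""
    n1, n2 = data_a.shape[0], data_b.shape[0]
    m1, m2 = data_a.mean(axis=0), data_b.mean(axis=0)
    v1 = data_a.var(axis=0, ddof=1)
    v2 = data_b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m2 - m1) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def voxelwise_ttest(
    maps_a: list[ActivityMap],
    maps_b: list[ActivityMap],
    mask: np.ndarray,
) -> tuple[StatMap, StatMap]:
    """Voxel-wise two-sample t-test (group B minus group A).

    Returns the t-map and the two-sided p-map, df = n1 + n2 - 2.  Voxels
    with zero pooled variance get t = 0 (p = 1).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    mask = np.asarray(mask, bool)
    affine = maps_a[0].affine
    data_a, data_b = _stack(maps_a), _stack(maps_b)
    if data_a.shape[1:] != mask.shape or data_b.shape[1:] != mask.shape:
        raise ValueError("all maps must share the mask's grid")
    df = data_a.shape[0] + data_b.shape[0] - 2
    t = _tstat(data_a, data_b)
    t[~mask] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~mask] = 1.0
    return StatMap(t, affine, df, "t"), StatMap(p, affine, df, "p")


@dataclass
class Cluster:
    """One supra-threshold cluster."""

    voxels: np.ndarray          # (m, 3) int voxel indices
    size: int
    sign: int                   # +1 (B > A) or -1
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    p_fwe: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_fwe < self._alpha)

    _alpha: float = 0.05

    def member_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class ClusterSet:
    """Disjoint supra-threshold clusters with FWE-corrected p-values."""

    clusters: list[Cluster]
    cdt_p: float
    fwe_alpha: float
    t_threshold: float
    n_perm_used: int
    exhaustive: bool

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < self.fwe_alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size_voxels": c.size,
                "sign": c.sign,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_t": c.peak_t,
                "p_fwe": c.p_fwe,
                "significant": c.p_fwe < self.fwe_alpha,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows)

    def label_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Integer label volume: cluster i+1 over its member voxels."""
        lab = np.zeros(shape, int)
        for i, c in enumerate(self.clusters):
            lab[tuple(c.voxels.T)] = i + 1
        return lab


def _clusters_from_t(t: np.ndarray, mask: np.ndarray, t_thr: float) -> list[tuple[np.ndarray, int]]:
    """26-connected supra-threshold components, each sign separately."""
    found = []
    for sign in (1, -1):
        supra = mask & (sign * t > t_thr)
        if not supra.any():
            continue
        lab, n = ndimage.label(supra, structure=_CONN26)
        for i in range(1, n + 1):
            vox = np.argwhere(lab == i)
            found.append((vox, sign))
    return found


def _max_cluster_size(t: np.ndarray, mask: np.ndarray, t_thr: float) -> int:
    best = 0
    for sign in (1, -1):
        supra = mask & (sign * t > t_thr)
        if not supra.any():
            continue
        lab, n = ndimage.label(supra, structure=_CONN26)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def _label_assignments(n_total: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """Yield boolean group-A membership vectors for the null distribution.

    Enumerates all C(n_total, n_a) assignments when fewer than ``n_perm``,
    otherwise draws ``n_perm`` random assignments (observed labelling is
    included in both cases).
    """
    n_comb = math.comb(n_total, n_a)
    if n_comb <= n_perm:
        for idx in combinations(range(n_total), n_a):
            sel = np.zeros(n_total, bool)
            sel[list(idx)] = True
            yield sel
        return True
    # first assignment = observed labelling
    obs = np.zeros(n_total, bool)
    obs[:n_a] = True
    yield obs
    for _ in range(n_perm - 1):
        sel = np.zeros(n_total, bool)
        sel[rng.choice(n_total, n_a, replace=False)] = True
        yield sel
    return False


def cluster_fwe(
    tmap: StatMap,
    mask: np.ndarray,
    maps_a: list[ActivityMap],
    maps_b: list[ActivityMap],
    cdt_p: float = 0.001,
    fwe_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterSet:
    """Cluster-level FWE inference by group-label permutation.

    The cluster-defining threshold is two-sided at ``cdt_p``; positive and
    negative excursions are clustered separately with 26-connectivity.  The
    null distribution of the maximum cluster size (over both signs) is
    built by recomputing the t-map under permuted group labels; each
    observed cluster's FWE p-value is the fraction of null maxima >= its
    size (the observed labelling counts as one permutation).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; FWE p-values will be coarse", n_perm)
    mask = np.asarray(mask, bool)
    t_thr = float(stats.t.ppf(1.0 - cdt_p / 2.0, tmap.df))

    observed = _clusters_from_t(tmap.data, mask, t_thr)
    affine = tmap.affine

    data = np.concatenate([_stack(maps_a), _stack(maps_b)], axis=0)
    n_a = len(maps_a)
    n_total = data.shape[0]
    flat = data.reshape(n_total, -1)[:, mask.ravel()]

    rng = np.random.default_rng(seed)
    null_max = []
    gen = _label_assignments(n_total, n_a, n_perm, rng)
    exhaustive = math.comb(n_total, n_a) <= n_perm
    tmask = np.zeros(mask.shape)
    for sel in gen:
        t_per = _tstat(flat[sel], flat[~sel])
        tmask[mask] = t_per
        null_max.append(_max_cluster_size(tmask, mask, t_thr))
    null_max = np.asarray(null_max)
    n_used = null_max.size

    clusters = []
    for vox, sign in observed:
        size = vox.shape[0]
        tv = tmap.data[tuple(vox.T)]
        k = int(np.argmax(np.abs(tv)))
        peak_ijk = tuple(int(v) for v in vox[k])
        peak_mm = tuple(float(v) for v in (affine @ np.append(vox[k], 1.0))[:3])
        p = float((null_max >= size).sum()) / n_used
        clusters.append(
            Cluster(vox, size, sign, peak_ijk, peak_mm, float(tv[k]), p, fwe_alpha)
        )
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters, cdt_p, fwe_alpha, t_thr, n_used, exhaustive)


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Cohen's d (mean_b - mean_a over the pooled SD, df-weighted)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((b.mean() - a.mean()) / np.sqrt(sp2))


def extract_roi_mean(amap: ActivityMap, cluster_voxels: np.ndarray) -> float:
    """Mean map value over an explicit voxel list ((m, 3) indices)."""
    vox = np.asarray(cluster_voxels, int)
    if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] == 0:
        raise ValueError("cluster voxel list must be a nonempty (m, 3) array")
    if (vox < 0).any() or (vox >= np.array(amap.data.shape)).any():
        raise ValueError("cluster voxels outside the map grid")
    return float(amap.data[tuple(vox.T)].mean())


class GroupContrast:
    """Two-sample voxel-wise contrast with cluster-level permutation FWE.

    Parameters
    ----------
    maps_a, maps_b : lists of ActivityMap
        Standardized (and usually smoothed) per-subject metric maps; the
        contrast is B minus A.
    mask : ndarray of bool
        Analysis mask shared by all maps.
    """

    def __init__(self, maps_a: list[ActivityMap], maps_b: list[ActivityMap], mask: np.ndarray):
        if len(maps_a) < 2 or len(maps_b) < 2:
            raise ValueError("need at least 2 maps per group")
        self.maps_a = maps_a
        self.maps_b = maps_b
        self.mask = np.asarray(mask, bool)
        self.affine = maps_a[0].affine

    def fit(
        self,
        cdt_p: float = 0.001,
        fwe_alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int | None = None,
    ) -> "GroupContrastResults":
        tmap, pmap = voxelwise_ttest(self.maps_a, self.maps_b, self.mask)
        clusters = cluster_fwe(
            tmap, self.mask, self.maps_a, self.maps_b, cdt_p, fwe_alpha, n_perm, seed
        )
        return GroupContrastResults(self, tmap, pmap, clusters)


@dataclass
class GroupContrastResults:
    """Fitted group contrast: t/p maps, clusters, ROI extraction helpers."""

    model: GroupContrast
    tmap: StatMap
    pmap: StatMap
    clusters: ClusterSet

    def roi_means(self, cluster: Cluster) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject mean within a cluster, for each group."""
        a = np.array([extract_roi_mean(m, cluster.voxels) for m in self.model.maps_a])
        b = np.array([extract_roi_mean(m, cluster.voxels) for m in self.model.maps_b])
        return a, b

    def cluster_effect_size(self, cluster: Cluster) -> float:
        a, b = self.roi_means(cluster)
        return cohens_d(a, b)

    def summary(self) -> pd.DataFrame:
        frame = self.clusters.to_frame()
        if len(frame):
            frame["cohens_d"] = [self.cluster_effect_size(c) for c in self.clusters]
        return frame

    def __str__(self) -> str:
        head = (
            f"GroupContrast: n_a={len(self.model.maps_a)}, n_b={len(self.model.maps_b)}, "
            f"df={self.tmap.df}, cdt |t|>{self.clusters.t_threshold:.3f} "
            f"(p={self.clusters.cdt_p}), {self.clusters.n_perm_used} permutations"
            f"{' (exhaustive)' if self.clusters.exhaustive else ''}\n"
        )
        frame = self.summary()
        return head + (frame.to_string(index=False) if len(frame) else "no supra-threshold clusters")
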