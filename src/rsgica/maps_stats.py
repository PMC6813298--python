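"""Group inference on back-projected component maps.

Per component: a one-sample t-test over subject maps, Benjamini-Hochberg
FDR across voxels, 26-connectivity clustering of positive and negative
survivors separately, and a cluster-extent FDR built from a
nonparametric sign-flip null (random per-subject sign, t-map and voxel
threshold recomputed, maximum cluster extent recorded).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidVolumeError

#: 26-connectivity structuring element for 3D clustering
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TMapResult:
    """Voxel-wise one-sample t statistics for one component."""

    t_values: np.ndarray          # (V,)
    p_values: np.ndarray          # (V,) two-sided
    df: int
    q_voxel: float | None = None
    voxel_mask: np.ndarray | None = None   # FDR survivors, (V,) bool
    p_star: float | None = None
    infinite_t_voxels: np.ndarray = field(default_factory=lambda: np.array([], int))


def _tstats(subject_maps: np.ndarray):
    """t, two-sided p and degenerate-voxel indices for an (n, V) stack."""
    n = subject_maps.shape[0]
    mean = subject_maps.mean(axis=0)
    sd = subject_maps.std(axis=0, ddof=1)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    p = np.empty_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df=n - 1)
    p[~finite] = 0.0
    p[zero_sd & (mean == 0)] = 1.0
    return t, p, np.flatnonzero(zero_sd & (mean != 0))


def one_sample_tmap(subject_maps: np.ndarray) -> TMapResult:
    """One-sample t-test of each voxel against 0 across subjects.

    Zero-variance voxels with nonzero mean get signed-infinite t (p = 0)
    and are listed in ``infinite_t_voxels``.
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    n = subject_maps.shape[0]
    if n < 3:
        raise InvalidVolumeError(f"need at least 3 subjects, got {n}")
    t, p, inf_idx = _tstats(subject_maps)
    return TMapResult(t_values=t, p_values=p, df=n - 1,
                      infinite_t_voxels=inf_idx)


def fdr_bh(p_values, q: float):
    """Benjamini-Hochberg FDR at level ``q``.

    Returns ``(reject, p_star)``: the boolean rejection mask and the
    largest sorted p-value satisfying p(i) <= (i/m) q, or None when
    nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q={q} must lie in (0,1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    p_star = float(p[reject].max()) if reject.any() else None
    return reject, p_star


@dataclass
class Cluster:
    """A connected set of suprathreshold voxels of one polarity."""

    voxels: np.ndarray            # (m, 3) voxel coordinates
    size: int
    center_of_mass: tuple         # voxel coordinates (float)
    polarity: str                 # "positive" | "negative"
    cluster_p: float | None = None
    cluster_q: float | None = None
    survives: bool = True


def connected_clusters(mask3d: np.ndarray, polarity: str = "positive") -> list[Cluster]:
    """26-connectivity connected components of a binary 3D mask."""
    mask3d = np.asarray(mask3d).astype(bool)
    labeled, n = ndimage.label(mask3d, structure=_STRUCT26)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labeled == lab)
        clusters.append(Cluster(
            voxels=vox, size=vox.shape[0],
            center_of_mass=tuple(vox.mean(axis=0)),
            polarity=polarity,
        ))
    return clusters


def _max_extent(reject_flat, t_flat, mask3d):
    """Largest 26-connected cluster size over both polarities."""
    best = 0
    for sign in (1, -1):
        m3 = np.zeros(mask3d.shape, dtype=bool)
        m3[mask3d] = reject_flat & (sign * t_flat > 0)
        if m3.any():
            labeled, n = ndimage.label(m3, structure=_STRUCT26)
            if n:
                best = max(best, int(np.bincount(labeled.ravel())[1:].max()))
    return best


@dataclass
class ThresholdedComponent:
    """A component's dual-FDR-thresholded map.

    ``clusters`` holds every voxel-FDR cluster with its extent p/q;
    ``pos_mask``/``neg_mask`` keep only voxels in clusters that survive
    the cluster-level FDR.
    """

    component_id: int
    tmap: TMapResult
    mask3d: np.ndarray            # analysis (brain) mask
    pos_mask: np.ndarray          # 3D bool, surviving positive voxels
    neg_mask: np.ndarray
    clusters: list[Cluster]
    q_voxel: float
    q_cluster: float

    @property
    def voxel_mask(self) -> np.ndarray:
        return self.pos_mask | self.neg_mask

    @property
    def surviving_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.survives]


def null_max_extents(subject_maps: np.ndarray, mask3d: np.ndarray,
                     q_voxel: float, n_permutations: int, seed: int) -> np.ndarray:
    """Sign-flip null distribution of the maximum cluster extent.

    For each permutation every subject's map is multiplied by a random
    ±1, the t-map and BH voxel threshold recomputed, and the largest
    cluster extent (either polarity) recorded.
    """
    n = subject_maps.shape[0]
    if n < 5:
        raise InvalidVolumeError(
            f"sign-flip null needs at least 5 subjects, got {n}"
        )
    if n_permutations < 100:
        raise ValueError(
            f"need at least 100 permutations, got {n_permutations}"
        )
    rng = np.random.default_rng(seed)
    maps = np.asarray(subject_maps, dtype=float)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    # per-voxel sum of squares is sign-invariant, so all permutation
    # t-maps come from a single matrix product
    ssq = (maps**2).sum(axis=0)
    means = signs @ maps / n
    var = np.maximum(ssq / n - means**2, 0.0) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = means / np.sqrt(var / n)
    t_all[~np.isfinite(t_all)] = 0.0
    p_all = 2.0 * stats.t.sf(np.abs(t_all), df=n - 1)
    # vectorised BH across voxels for every permutation at once
    m = p_all.shape[1]
    order = np.argsort(p_all, axis=1)
    p_sorted = np.take_along_axis(p_all, order, axis=1)
    crit = q_voxel * np.arange(1, m + 1) / m
    below = p_sorted <= crit
    kmax = np.where(below.any(axis=1), m - 1 - np.argmax(below[:, ::-1], axis=1), -1)
    out = np.zeros(n_permutations, dtype=int)
    for i in range(n_permutations):
        if kmax[i] < 0:
            continue
        reject = p_all[i] <= p_sorted[i, kmax[i]]
        out[i] = _max_extent(reject, t_all[i], mask3d)
    return out


def threshold_component(
    subject_maps: np.ndarray,
    mask3d: np.ndarray,
    q_voxel: float = 0.001,
    q_cluster: float = 0.005,
    n_permutations: int = 1000,
    seed: int = 0,
    component_id: int = 0,
    null_extents: np.ndarray | None = None,
) -> ThresholdedComponent:
    """Dual FDR thresholding of one component.

    ``subject_maps`` is the (n_subjects, V) stack of back-projected maps
    restricted to ``mask3d``.  A precomputed ``null_extents`` array may be
    supplied to share a null distribution across calls with identical
    inputs; by default it is computed here by sign flipping.
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    mask3d = np.asarray(mask3d).astype(bool)
    tres = one_sample_tmap(subject_maps)
    reject, p_star = fdr_bh(tres.p_values, q_voxel)
    tres.q_voxel, tres.voxel_mask, tres.p_star = q_voxel, reject, p_star

    pos3 = np.zeros(mask3d.shape, bool)
    neg3 = np.zeros(mask3d.shape, bool)
    pos3[mask3d] = reject & (tres.t_values > 0)
    neg3[mask3d] = reject & (tres.t_values < 0)
    clusters = (connected_clusters(pos3, "positive")
                + connected_clusters(neg3, "negative"))

    if clusters:
        if null_extents is None:
            null_extents = null_max_extents(
                subject_maps, mask3d, q_voxel, n_permutations, seed
            )
        m = null_extents.size
        for c in clusters:
            c.cluster_p = (1 + int((null_extents >= c.size).sum())) / (m + 1)
        rej, _ = fdr_bh([c.cluster_p for c in clusters], q_cluster)
        for c, r in zip(clusters, rej):
            c.survives = bool(r)
            c.cluster_q = q_cluster
        pos3[:] = False
        neg3[:] = False
        for c in clusters:
            if c.survives:
                target = pos3 if c.polarity == "positive" else neg3
                target[tuple(c.voxels.T)] = True

    return ThresholdedComponent(
        component_id=component_id, tmap=tres, mask3d=mask3d,
        pos_mask=pos3, neg_mask=neg3, clusters=clusters,
        q_voxel=q_voxel, q_cluster=q_cluster,
    )


def threshold_components(subject_maps_by_component, mask3d,
                         q_voxel=0.001, q_cluster=0.005,
                         n_permutations=1000, seed=0) -> list[ThresholdedComponent]:
    """Threshold every component of a decomposition.

    ``subject_maps_by_component`` is (k, n_subjects, V); permutation seeds
    are derived per component for determinism.
    """
    out = []
    for ci, maps in enumerate(subject_maps_by_component):
        out.append(threshold_component(
            maps, mask3d, q_voxel=q_voxel, q_cluster=q_cluster,
            n_permutations=n_permutations, seed=seed + 1000 * ci,
            component_id=ci,
        ))
    return out


def cluster_table(components: list[ThresholdedComponent],
                  affine: np.ndarray | None = None) -> pd.DataFrame:
    """TSV-ready table of clusters (component, polarity, size, centre,
    cluster p and q, survival)."""
    rows = []
    for comp in components:
        for c in comp.clusters:
            com = np.asarray(c.center_of_mass)
            if affine is not None:
                com = (affine @ np.append(com, 1.0))[:3]
            rows.append({
                "component": comp.component_id,
                "polarity": c.polarity,
                "size": c.size,
                "center_x": com[0], "center_y": com[1], "center_z": com[2],
                "cluster_p": c.cluster_p,
                "cluster_q": c.cluster_q,
                "survives": c.survives,
            })
    return pd.DataFrame(rows)
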