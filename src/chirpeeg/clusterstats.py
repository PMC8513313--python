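"""Cluster-based nonparametric Monte-Carlo permutation test.

Two groups of time-frequency matrices (subjects x 100 x 625) are compared
with a pointwise Welch t statistic; pixels beyond a two-sided cluster-forming
threshold are grouped into 4-connected clusters separately per sign, and
each observed cluster's size (or mass) is referred to the distribution of
the per-permutation maximum cluster statistic under random relabelings of
subjects, controlling the family-wise error at alpha per tail (default
0.025, i.e. two-tailed 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, stats

from .synthgen import ValidationError

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class GroupedMaps:
    """Stacked subject maps with a two-level group factor."""

    maps: np.ndarray                # subjects x H x W
    group_labels: np.ndarray        # 0/1 (or two distinct values)
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        labels = np.asarray(self.group_labels)
        levels = np.unique(labels)
        if len(levels) != 2:
            raise ValidationError("group_labels must have exactly two levels")
        self.group_labels = (labels == levels[1]).astype(np.int8)
        if self.maps.shape[0] != len(self.group_labels):
            raise ValidationError("labels do not match subject count")
        for lev in (0, 1):
            if np.sum(self.group_labels == lev) < 2:
                raise ValidationError("each group needs at least 2 subjects")

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class Cluster:
    pixels: np.ndarray              # (k, 2) array of (row, col) indices
    sign: int                       # +1 or -1
    size: int
    mass: float
    p_value: float | None = None


@dataclass
class ClusterTestResult:
    stat_map: np.ndarray
    clusters: list[Cluster]
    null_max_stats: dict[int, np.ndarray]   # sign -> per-permutation maxima
    significance_mask: np.ndarray
    n_permutations: int
    alpha_per_tail: float
    seed: int | None


def _welch(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and df maps for subject-stacked arrays (n, ...)."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = sa + sb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(denom)
        df = denom**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero = denom == 0
    t = np.where(zero, 0.0, t)
    df = np.where(zero, na + nb - 2, df)
    return t, df


def pointwise_stat(g: GroupedMaps) -> np.ndarray:
    """Welch t per pixel (group 0 minus group 1); masked pixels set to 0."""
    t, _ = _welch(g.maps[g.group_labels == 0], g.maps[g.group_labels == 1])
    if g.validity_mask is not None:
        t = np.where(g.validity_mask, t, 0.0)
    return t


def _suprathreshold(t: np.ndarray, df: np.ndarray, alpha_cluster: float,
                    validity: np.ndarray | None) -> np.ndarray:
    """Two-sided pointwise test at alpha_cluster with Welch df per pixel."""
    p = 2.0 * stats.t.sf(np.abs(t), df)
    supra = p < alpha_cluster
    if validity is not None:
        supra &= validity
    return supra


def form_clusters(stat_map: np.ndarray, supra: np.ndarray,
                  connectivity: int = 4) -> list[Cluster]:
    """Group suprathreshold pixels into contiguous clusters per sign."""
    structure = _STRUCTURES[connectivity]
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = supra & ((stat_map > 0) if sign > 0 else (stat_map < 0))
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            sel = labels == lab
            clusters.append(Cluster(
                pixels=np.argwhere(sel),
                sign=sign,
                size=int(sel.sum()),
                mass=float(np.abs(stat_map[sel]).sum()),
            ))
    return clusters


def _max_cluster_stats(t: np.ndarray, supra: np.ndarray, connectivity: int,
                       statistic: str) -> dict[int, float]:
    structure = _STRUCTURES[connectivity]
    out = {}
    for sign in (1, -1):
        mask = supra & ((t > 0) if sign > 0 else (t < 0))
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            out[sign] = 0.0
        elif statistic == "size":
            out[sign] = float(np.max(ndimage.sum_labels(
                np.ones_like(t), labels, np.arange(1, n + 1))))
        else:
            out[sign] = float(np.max(ndimage.sum_labels(
                np.abs(t), labels, np.arange(1, n + 1))))
    return out


def permutation_null(g: GroupedMaps, n_perm: int = 1000,
                     alpha_cluster: float = 0.05, connectivity: int = 4,
                     statistic: str = "size", seed: int | None = None,
                     exact: bool = False) -> dict[int, np.ndarray]:
    """Per-permutation maximum cluster statistic, per sign.

    Permutations relabel subjects uniformly over assignments that preserve
    the two group sizes (identity allowed).  With ``exact=True`` every
    distinct assignment is enumerated instead (feasible for small samples)
    and n_perm is ignored.
    """
    n = g.maps.shape[0]
    na = int(np.sum(g.group_labels == 0))
    flat = g.maps.reshape(n, -1)
    validity = None if g.validity_mask is None else g.validity_mask
    shape = g.shape

    if exact:
        assignments = list(combinations(range(n), na))
    else:
        rng = np.random.default_rng(seed)
        assignments = [tuple(rng.permutation(n)[:na]) for _ in range(n_perm)]

    null = {1: np.empty(len(assignments)), -1: np.empty(len(assignments))}
    idx_all = np.arange(n)
    for i, ia in enumerate(assignments):
        in_a = np.zeros(n, dtype=bool)
        in_a[list(ia)] = True
        t, df = _welch(flat[in_a], flat[~in_a])
        t = t.reshape(shape)
        df = df.reshape(shape)
        if validity is not None:
            t = np.where(validity, t, 0.0)
        supra = _suprathreshold(t, df, alpha_cluster, validity)
        mx = _max_cluster_stats(t, supra, connectivity, statistic)
        null[1][i] = mx[1]
        null[-1][i] = mx[-1]
    return null


def significant_clusters(stat_map: np.ndarray, clusters: list[Cluster],
                         null_max_stats: dict[int, np.ndarray],
                         alpha_per_tail: float = 0.025,
                         statistic: str = "size",
                         seed: int | None = None,
                         exact: bool = False) -> ClusterTestResult:
    """Attach permutation p-values and build the significance mask.

    Monte-Carlo p uses the permutation-inclusive convention
    p = (1 + #{null >= obs}) / (1 + n_perm), so p is never exactly 0; under
    exact enumeration p = #{null >= obs} / n_assignments (the identity
    assignment guarantees p > 0).
    """
    n_perm = len(next(iter(null_max_stats.values())))
    mask = np.zeros(stat_map.shape, dtype=bool)
    for cl in clusters:
        obs = cl.size if statistic == "size" else cl.mass
        exceed = int(np.sum(null_max_stats[cl.sign] >= obs))
        cl.p_value = exceed / n_perm if exact else (1 + exceed) / (1 + n_perm)
        if cl.p_value <= alpha_per_tail:
            mask[tuple(cl.pixels.T)] = True
    return ClusterTestResult(
        stat_map=stat_map,
        clusters=clusters,
        null_max_stats=null_max_stats,
        significance_mask=mask,
        n_permutations=n_perm,
        alpha_per_tail=alpha_per_tail,
        seed=seed,
    )


def cluster_permutation_test(g: GroupedMaps, n_perm: int = 1000,
                             alpha_cluster: float = 0.05,
                             alpha_per_tail: float = 0.025,
                             connectivity: int = 4,
                             statistic: str = "size",
                             seed: int | None = None,
                             exact: bool = False) -> ClusterTestResult:
    """Full pipeline: t map, clusters, permutation null, significance."""
    xa = g.maps[g.group_labels == 0]
    xb = g.maps[g.group_labels == 1]
    t, df = _welch(xa, xb)
    if g.validity_mask is not None:
        t = np.where(g.validity_mask, t, 0.0)
    supra = _suprathreshold(t, df, alpha_cluster, g.validity_mask)
    clusters = form_clusters(t, supra, connectivity)
    null = permutation_null(g, n_perm=n_perm, alpha_cluster=alpha_cluster,
                            connectivity=connectivity, statistic=statistic,
                            seed=seed, exact=exact)
    return significant_clusters(t, clusters, null,
                                alpha_per_tail=alpha_per_tail,
                                statistic=statistic, seed=seed, exact=exact)
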