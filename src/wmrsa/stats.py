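"""Cluster-based permutation inference and Bonferroni adjustment.

Family-wise error over time, time-frequency or temporal-generalization maps
is controlled by cluster-based permutation: cells significant at the
two-sided cluster-forming alpha are grouped into connected clusters
(adjacency in 1-D, 4-neighborhood in 2-D), each cluster's summed t is
compared against the null distribution of the maximal summed |t| obtained by
re-computing the map under label shuffles. Positive and negative clusters
are formed separately; the null pools the maximum absolute mass. Corrected
p-values use the (r + 1) / (n + 1) estimator and are never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

__all__ = [
    "Cluster",
    "ClusterResult",
    "find_clusters",
    "max_cluster_mass",
    "cluster_permutation",
    "cluster_1samp",
    "cluster_indep",
    "bonferroni",
    "one_sample_t",
    "welch_t",
]


def one_sample_t(data: np.ndarray, axis: int = 0) -> tuple[np.ndarray, int]:
    """t statistic of mean vs 0 along ``axis``; returns (t map, df)."""
    data = np.asarray(data, dtype=float)
    n = data.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = data.mean(axis=axis)
    sd = data.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t, n - 1


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch's unequal-variance t along axis 0; returns (t, df) maps."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, df


@dataclass
class Cluster:
    cells: tuple[np.ndarray, ...]  # index arrays into the map
    mass: float  # summed t (signed)
    p: float = np.nan  # corrected p

    @property
    def sign(self) -> int:
        return 1 if self.mass >= 0 else -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max: np.ndarray  # (n_perm,) max |summed t| per permutation
    n_perm: int
    alpha_form: float
    strategy: str
    t_map: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _structure(ndim: int) -> np.ndarray:
    # 4-neighborhood in 2-D, plain adjacency in 1-D (no diagonals)
    return ndimage.generate_binary_structure(ndim, 1)


def find_clusters(t_map: np.ndarray, t_crit: float) -> list[Cluster]:
    """Maximal connected components of supra-threshold cells, by sign."""
    t_map = np.asarray(t_map, dtype=float)
    struct = _structure(t_map.ndim)
    clusters: list[Cluster] = []
    finite = np.isfinite(t_map)
    for sign in (1, -1):
        mask = finite & (sign * t_map > t_crit)
        labels, n = ndimage.label(mask, structure=struct)
        for k in range(1, n + 1):
            cells = np.nonzero(labels == k)
            clusters.append(Cluster(cells=cells, mass=float(t_map[cells].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def max_cluster_mass(t_map: np.ndarray, t_crit: float) -> float:
    """Maximum absolute summed t over clusters of a map (0 if none)."""
    cl = find_clusters(t_map, t_crit)
    return abs(cl[0].mass) if cl else 0.0


def _attach_p(clusters: list[Cluster], null_max: np.ndarray) -> None:
    n = null_max.size
    for c in clusters:
        c.p = (np.sum(null_max >= abs(c.mass)) + 1.0) / (n + 1.0)


def cluster_permutation(
    t_map: np.ndarray,
    df: float | np.ndarray,
    perm_t_maps,
    alpha_form: float = 0.05,
    strategy: str = "custom",
) -> ClusterResult:
    """Generic cluster correction from an observed t map and permuted maps.

    ``perm_t_maps`` is an iterable of t maps computed under label shuffles;
    ``df`` converts the cluster-forming alpha into a t threshold (a scalar df
    or a map, in which case the median df is used for the shared threshold).
    """
    df_scalar = float(np.nanmedian(df))
    t_crit = float(t_dist.ppf(1.0 - alpha_form / 2.0, df_scalar))
    clusters = find_clusters(t_map, t_crit)
    null = np.asarray(
        [max_cluster_mass(p, t_crit) for p in perm_t_maps], dtype=float
    )
    if null.size < 100:
        warnings.warn(f"only {null.size} permutations; corrected p is coarse")
    _attach_p(clusters, null)
    return ClusterResult(
        clusters=clusters,
        null_max=null,
        n_perm=int(null.size),
        alpha_form=alpha_form,
        strategy=strategy,
        t_map=np.asarray(t_map, dtype=float),
    )


def _signflip_t_maps(
    data: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """t maps of sign-flipped one-sample tests, vectorized over permutations.

    Sign flips leave per-cell sums of squares unchanged, so the permuted
    variance follows from the permuted mean alone.
    """
    n = data.shape[0]
    flat = data.reshape(n, -1)
    sumsq = np.einsum("ij,ij->j", flat, flat)
    mean = signs @ flat / n  # (n_perm, cells)
    var = (sumsq / n - mean**2) * (n / (n - 1.0))
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return t.reshape((signs.shape[0],) + data.shape[1:])


def cluster_1samp(
    data: np.ndarray,
    n_perm: int = 1000,
    alpha_form: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster permutation test of a subject x map array against zero.

    The exchangeability move is a per-subject sign flip — the permutation
    equivalent of shuffling condition labels in a paired design.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    data = np.asarray(data, dtype=float)
    t_map, df = one_sample_t(data)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, data.shape[0]))
    perm_t = _signflip_t_maps(data, signs)
    return cluster_permutation(
        t_map, df, perm_t, alpha_form=alpha_form, strategy="condition_label"
    )


def cluster_indep(
    data_a: np.ndarray,
    data_b: np.ndarray,
    n_perm: int = 1000,
    alpha_form: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster permutation test of two independent groups (Welch t).

    Group (e.g. region) labels are shuffled across subjects; used when the
    two regions' subject sets differ.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    t_map, df = welch_t(a, b)
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    n_tot = pooled.shape[0]

    def perm_iter():
        for _ in range(n_perm):
            idx = rng.permutation(n_tot)
            pa, pb = pooled[idx[:na]], pooled[idx[na:]]
            yield welch_t(pa, pb)[0]

    return cluster_permutation(
        t_map, df, perm_iter(), alpha_form=alpha_form, strategy="region_label"
    )


def bonferroni(
    p_values, m: int, alpha: float = 0.05
) -> dict:
    """Bonferroni decisions: significant iff p < alpha / m.

    ``m`` is the number of comparisons the caller corrects over (layers or
    bands); a warning is raised when fewer tests than m are supplied only if
    m < the number of tests (an under-correction).
    """
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be at least 1")
    if m < p.size:
        warnings.warn(f"m={m} is smaller than the number of tests ({p.size})")
    threshold = alpha / m
    return {
        "threshold": threshold,
        "significant": p < threshold,
        "p_adjusted": np.minimum(p * m, 1.0),
    }
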