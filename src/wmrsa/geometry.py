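"""Representational-geometry statistics on RSM stacks.

The Category Cluster Index (CCI) is the mean within-category correlation
minus the mean between-category correlation of an RSM (diagonal and
lower-triangle duplicates excluded): 1 for perfectly clustered categories,
0 for no categorical organization. Significance is assessed by shuffling the
item category labels and comparing the observed CCI to the 95th percentile
of the null. Consistency correlates whole RSMs (second-level Spearman);
slope analysis regresses each item pair's correlation on layer depth; MDS
stress-1 quantifies how well a low-dimensional embedding of 1 - rho
distances reproduces the representational geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, spearmanr, ttest_1samp, ttest_rel

from .models import LayeredModelRSMs
from .rsm import pair_masks

__all__ = [
    "CCIResult",
    "SlopeFit",
    "StressCurve",
    "cci",
    "cci_permutation_test",
    "consistency",
    "slope_analysis",
    "compare_slopes",
    "mds_stress",
    "stress1",
]


def _pair_values(rsm: np.ndarray, categories: np.ndarray):
    rsm = np.asarray(rsm, dtype=float)
    categories = np.asarray(categories)
    if rsm.shape[0] != categories.size:
        raise ValueError("category labels must match RSM size")
    labels, counts = np.unique(categories, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(counts < 2):
        raise ValueError("every category needs at least 2 items")
    iu, within, between = pair_masks(categories)
    return rsm[iu], within, between


def cci(rsm: np.ndarray, categories: np.ndarray) -> float:
    """Category Cluster Index: mean(within pairs) - mean(between pairs)."""
    vals, within, between = _pair_values(rsm, categories)
    return float(vals[within].mean() - vals[between].mean())


@dataclass
class CCIResult:
    cci: float
    mean_within: float
    mean_between: float
    var_within: float
    var_between: float
    p: float
    null_q95: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return self.cci > self.null_q95


def cci_permutation_test(
    rsm: np.ndarray,
    categories: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CCIResult:
    """One-sided category-label permutation test of the CCI.

    Shuffling the category labels of items (equivalently permuting RSM rows
    and columns jointly) builds the null; the observed CCI is significant
    when it exceeds the null's 95th percentile. The reported p uses the
    (r + 1) / (n + 1) estimator and can never be 0.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    vals, within, between = _pair_values(rsm, categories)
    observed = float(vals[within].mean() - vals[between].mean())
    categories = np.asarray(categories)
    iu = np.triu_indices(categories.size, k=1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(categories)
        w = perm[iu[0]] == perm[iu[1]]
        null[k] = vals[w].mean() - vals[~w].mean()
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    return CCIResult(
        cci=observed,
        mean_within=float(vals[within].mean()),
        mean_between=float(vals[between].mean()),
        var_within=float(vals[within].var(ddof=1)),
        var_between=float(vals[between].var(ddof=1)),
        p=float(p),
        null_q95=float(np.quantile(null, 0.95)),
        n_perm=n_perm,
    )


def consistency(stack: LayeredModelRSMs, mode: str = "across_layers") -> np.ndarray:
    """Second-level Spearman correlations between RSMs of a stack.

    ``across_layers`` correlates the last-timepoint RSM of every layer pair
    (layer x layer matrix). ``across_time`` correlates consecutive timepoints
    within each layer, returning a ragged list of per-layer arrays.
    """
    def vec(m: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]

    if mode == "across_layers":
        mats = stack.last_timepoints()
        if mats.shape[0] < 2:
            raise ValueError("need at least 2 layers")
        vecs = np.stack([vec(m) for m in mats])
        ranks = rankdata(vecs, axis=1)
        c = np.corrcoef(ranks)
        np.fill_diagonal(c, 1.0)
        return c
    if mode == "across_time":
        out = []
        for layer in stack.rsms:
            if len(layer) < 2:
                raise ValueError("need at least 2 timepoints per layer")
            rhos = [
                spearmanr(vec(a), vec(b)).statistic
                for a, b in zip(layer[:-1], layer[1:])
            ]
            out.append(np.asarray(rhos))
        return out
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SlopeFit:
    """Per-pair least-squares slopes of correlation against layer index."""

    slopes_within: np.ndarray
    slopes_between: np.ndarray
    mean_within: float
    mean_between: float
    t_within: float
    p_within: float
    t_between: float
    p_between: float


def _pair_slopes(values: np.ndarray) -> np.ndarray:
    """Least-squares slope of each column of (n_layers, n_pairs) vs depth."""
    x = np.arange(values.shape[0], dtype=float)
    xc = x - x.mean()
    return xc @ (values - values.mean(axis=0)) / (xc @ xc)


def slope_analysis(stack: LayeredModelRSMs, categories: np.ndarray) -> SlopeFit:
    """Regress every item pair's correlation on layer index (last timepoints).

    Within- and between-category slope distributions are each tested against
    zero with a two-sided one-sample t-test; the analytic p is reported
    exactly (never printed as 0).
    """
    mats = stack.last_timepoints()
    if mats.shape[0] < 3:
        raise ValueError("need at least 3 layers for a slope fit")
    iu, within, between = pair_masks(categories)
    values = mats[:, iu[0], iu[1]]  # (L, P)
    slopes = _pair_slopes(values)
    sw, sb = slopes[within], slopes[between]
    tw = ttest_1samp(sw, 0.0)
    tb = ttest_1samp(sb, 0.0)
    # the analytic p can underflow for extreme t; report the smallest
    # positive float rather than an exact zero
    tiny = float(np.finfo(float).tiny)
    return SlopeFit(
        slopes_within=sw,
        slopes_between=sb,
        mean_within=float(sw.mean()),
        mean_between=float(sb.mean()),
        t_within=float(tw.statistic),
        p_within=max(float(tw.pvalue), tiny),
        t_between=float(tb.statistic),
        p_between=max(float(tb.pvalue), tiny),
    )


def compare_slopes(
    fit_a: SlopeFit, fit_b: SlopeFit, which: str = "between"
) -> tuple[float, float, float]:
    """Paired t-test of matched pair slopes between two stacks.

    Returns (mean difference a - b, t, p)."""
    a = fit_a.slopes_within if which == "within" else fit_a.slopes_between
    b = fit_b.slopes_within if which == "within" else fit_b.slopes_between
    if a.size != b.size:
        raise ValueError("stacks must share the item-pair set")
    res = ttest_rel(a, b)
    return float((a - b).mean()), float(res.statistic), float(res.pvalue)


def stress1(distances: np.ndarray, embedding: np.ndarray) -> float:
    """Stress-1 of an embedding against target distances (condensed form)."""
    d_hat = pdist(embedding)
    denom = np.sum(distances**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((distances - d_hat) ** 2) / denom))


@dataclass
class StressCurve:
    dims: np.ndarray
    stress: np.ndarray  # mean across subsample repeats
    stress_repeats: np.ndarray  # (n_repeats, n_dims)
    coords_2d: np.ndarray | None
    match_n: int | None


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering solution, used to initialize SMACOF."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    comp = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return comp


def _embed(
    d: np.ndarray, k: int, rng: np.random.Generator, n_init: int
) -> tuple[np.ndarray, float]:
    """Best-of-inits metric SMACOF embedding: classical + random starts."""
    import warnings as _warnings

    from sklearn.manifold import smacof

    n = d.shape[0]
    inits = [_classical_mds(d, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(max(0, n_init - 1))]
    best = None
    cond = d[np.triu_indices(n, k=1)]
    for x0 in inits:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            emb, _ = smacof(
                d,
                metric=True,
                n_components=k,
                init=x0,
                n_init=1,
                max_iter=1000,
                eps=1e-12,
                random_state=0,
            )
        s = stress1(cond, emb)
        if best is None or s < best[1]:
            best = (emb, s)
    return best


def mds_stress(
    rsm: np.ndarray,
    dims: int | np.ndarray = 2,
    n_repeats: int = 100,
    match_n: int | None = None,
    seed: int | np.random.Generator = 0,
    n_init: int = 4,
) -> StressCurve:
    """Metric MDS (SMACOF) stress-1 per embedding dimension.

    Dissimilarity is 1 - rho, clipped at 0. When ``match_n`` is set, items
    are randomly subsampled to that count and the embedding repeated
    ``n_repeats`` times; otherwise a single pass over the full item set is
    run. Dimensions above item count - 1 are rejected. Each embedding is the
    best of a classical-MDS initialization plus ``n_init - 1`` random
    restarts of the SMACOF majorization.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rsm = np.asarray(rsm, dtype=float)
    n = rsm.shape[0]
    dims = np.atleast_1d(np.asarray(dims, dtype=int))
    sub_n = n if match_n is None else int(match_n)
    if np.any(dims < 1) or np.any(dims > sub_n - 1):
        raise ValueError("dims must lie in 1..(item count - 1)")
    full_d = np.clip(1.0 - rsm, 0.0, None)
    np.fill_diagonal(full_d, 0.0)
    reps = 1 if match_n is None else n_repeats
    stress = np.empty((reps, dims.size))
    for r in range(reps):
        if match_n is None:
            d = full_d
        else:
            keep = np.sort(rng.choice(n, size=sub_n, replace=False))
            d = full_d[np.ix_(keep, keep)]
        for j, k in enumerate(dims):
            _, stress[r, j] = _embed(d, int(k), rng, n_init)
    coords = None
    if 2 in dims:
        coords, _ = _embed(full_d, 2, rng, n_init)
    return StressCurve(
        dims=dims,
        stress=stress.mean(axis=0),
        stress_repeats=stress,
        coords_2d=coords,
        match_n=match_n,
    )
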