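"""Model-to-neural RSA fits, category contrasts and group-level inference.

Two complementary routes quantify category-specific structure:

* **Model-based fits** correlate a hypothesis RSM (binary category/item model
  or a layer of a hierarchical feature model) with the neural RSM at every
  (window, frequency) cell using Spearman's rho on the vectorized upper
  triangles. Rho is Fisher z-transformed per subject and tested against zero
  at the group level; multiple comparisons are corrected by cluster-based
  permutation where the *model's* item labels are shuffled.

* **Contrast-based similarity** (EES / EMS) compares correlations between
  different items of the same category against items of different categories
  across all pairs of time windows (temporal generalization). Repetition
  averaging precedes the contrast; different-category pairs whose
  contributing trials overlap are excluded to avoid autocorrelation bias.
  Group inference is a one-sample t on the subject-level same-minus-different
  Fisher-z maps, cluster-corrected under category-label shuffles.

All group statistics are invariant to subject ordering, and correlations of
exactly ±1 are clipped to 1 - 1e-6 before the Fisher transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from scipy.stats import ttest_rel

from .models import ModelRSM
from .rsm import FeatureSeries, ItemPower, WindowScheme
from .stats import (
    ClusterResult,
    cluster_1samp,
    cluster_indep,
    cluster_permutation,
    one_sample_t,
)

__all__ = [
    "FitMap",
    "GeneralizationMap",
    "LatencyResult",
    "TrialFitResult",
    "fisher_z",
    "frequency_rsm_stack",
    "model_fit_map",
    "category_contrast",
    "category_timecourse",
    "latency_comparison",
    "trial_level_fit",
    "behavioral_summary",
]

RHO_CAP = 1.0 - 1e-6


def fisher_z(rho: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh transform with |rho| clipped below 1."""
    return np.arctanh(np.clip(rho, -RHO_CAP, RHO_CAP))


def _rank_center_norm(x: np.ndarray) -> np.ndarray:
    """Rank along the last axis, center and L2-normalize (Spearman core).

    After this transform, a plain dot product between two vectors is their
    Spearman correlation.
    """
    r = rankdata(x, axis=-1)
    r -= r.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(r, axis=-1, keepdims=True)
    norm[norm == 0] = np.nan  # constant vectors: correlation undefined
    return r / norm


def frequency_rsm_stack(
    item_power: ItemPower, scheme: WindowScheme | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Neural RSMs per (window, frequency): returns (stack, window times).

    ``stack`` has shape (n_windows, n_freqs, n_items, n_items); features at
    each cell are channels x window time points of a single frequency.
    """
    from .rsm import _window_starts

    if scheme is None:
        scheme = WindowScheme()
    starts, w = _window_starts(item_power.times, item_power.valid, scheme)
    if starts.size == 0:
        raise ValueError("no valid window fits the epoch")
    n_items, n_ch, n_f, _ = item_power.data.shape
    centers = np.array(
        [item_power.times[i] + 0.5 * scheme.width for i in starts]
    )
    stack = np.empty((starts.size, n_f, n_items, n_items))
    for k, i in enumerate(starts):
        block = item_power.data[..., i : i + w]  # (n, ch, F, w)
        feats = block.transpose(2, 0, 1, 3).reshape(n_f, n_items, n_ch * w)
        r = _rank_center_norm(feats)
        r = np.nan_to_num(r)  # constant rows -> zero vector -> rho 0
        stack[k] = np.einsum("fnd,fmd->fnm", r, r)
    return stack, centers


@dataclass
class FitMap:
    """Subject Fisher-z fits and the group t map over (window, frequency)."""

    z: np.ndarray  # (n_subjects, n_windows, n_freqs)
    t: np.ndarray  # (n_windows, n_freqs)
    p: np.ndarray
    df: int
    window_times: np.ndarray
    frequencies: np.ndarray
    model_tag: str
    mask: str
    clusters: ClusterResult | None = None


def _pair_selection(categories: np.ndarray, mask: str):
    n = categories.size
    iu = np.triu_indices(n, k=1)
    within = categories[iu[0]] == categories[iu[1]]
    if mask == "all":
        sel = np.ones(iu[0].size, dtype=bool)
    elif mask in ("within", "within_category"):
        sel = within
    elif mask in ("between", "between_category"):
        sel = ~within
    else:
        raise ValueError(f"unknown mask {mask!r}")
    return iu, sel


def _model_matrix(model) -> tuple[np.ndarray, str]:
    if isinstance(model, ModelRSM):
        return model.matrix, model.tag
    return np.asarray(model, dtype=float), "model"


def model_fit_map(
    subject_stacks: list[np.ndarray],
    model,
    categories,
    window_times: np.ndarray,
    frequencies: np.ndarray,
    mask: str = "all",
    n_perm: int = 0,
    alpha_form: float = 0.05,
    seed: int | np.random.Generator = 0,
    model_tag: str | None = None,
) -> FitMap:
    """Fit a model RSM to every subject's (window, frequency) neural RSMs.

    ``subject_stacks`` holds one (W, F, n_s, n_s) array per subject. The item
    set is normally shared across subjects with a single ``model`` matrix and
    one ``categories`` array; per-subject models and category arrays (lists of
    the same length as ``subject_stacks``) are supported for analyses over
    per-subject item subsets. With ``n_perm > 0`` a cluster-based permutation
    test is run in which the model's item labels are shuffled and the whole
    map recomputed — jointly across subjects when the item set is shared,
    independently per subject otherwise.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_subj = len(subject_stacks)
    if isinstance(model, (list, tuple)):
        mats_tags = [_model_matrix(m) for m in model]
        m_mats = [mt[0] for mt in mats_tags]
        tag = model_tag or mats_tags[0][1]
        shared = False
    else:
        m_mat, tag0 = _model_matrix(model)
        m_mats = [m_mat] * n_subj
        tag = model_tag or tag0
        shared = True
    if isinstance(categories, (list, tuple)):
        cat_list = [np.asarray(c) for c in categories]
        shared = shared and all(
            np.array_equal(c, cat_list[0]) for c in cat_list
        )
    else:
        cat_list = [np.asarray(categories)] * n_subj

    W, F = subject_stacks[0].shape[:2]
    n_cells = W * F
    z = np.empty((n_subj, n_cells))
    per_subject = []  # (neural_hat, m_vals, iu, sel, pair_index)
    for s, stack in enumerate(subject_stacks):
        n = stack.shape[-1]
        if m_mats[s].shape[0] != n or cat_list[s].size != n:
            raise ValueError("model and neural RSMs must share the item set")
        iu, sel = _pair_selection(cat_list[s], mask)
        m_vals = m_mats[s][iu]
        m_obs = m_vals[sel]
        if np.all(m_obs == m_obs[0]):
            raise ValueError("model pair vector is constant; fit undefined")
        m_hat = _rank_center_norm(m_obs[None, :])[0]
        vec = stack[:, :, iu[0], iu[1]][..., sel].reshape(n_cells, -1)
        neural = np.nan_to_num(_rank_center_norm(vec))
        z[s] = fisher_z(neural @ m_hat)
        per_subject.append((neural, m_vals, iu, sel, n))
    z = z.reshape(n_subj, W, F)
    t_map, df = one_sample_t(z)
    p_map = 2.0 * t_dist.sf(np.abs(t_map), df)

    clusters = None
    if n_perm > 0:

        def permuted_model_ranks(m_vals, iu, sel, n):
            pair_index = np.zeros((n, n), dtype=int)
            pair_index[iu] = np.arange(iu[0].size)
            pair_index = pair_index + pair_index.T
            perm_vals = np.empty((n_perm, int(sel.sum())))
            for k in range(n_perm):
                perm = rng.permutation(n)
                kprime = pair_index[perm[iu[0]], perm[iu[1]]]
                perm_vals[k] = m_vals[kprime][sel]
            return np.nan_to_num(_rank_center_norm(perm_vals))

        if shared:
            neural0, m_vals0, iu0, sel0, n0 = per_subject[0]
            perm_hat_shared = permuted_model_ranks(m_vals0, iu0, sel0, n0)
        a1 = np.zeros((n_perm, n_cells))
        a2 = np.zeros((n_perm, n_cells))
        for neural, m_vals, iu, sel, n in per_subject:
            perm_hat = (
                perm_hat_shared
                if shared
                else permuted_model_ranks(m_vals, iu, sel, n)
            )
            z_perm = fisher_z(perm_hat @ neural.T)  # (n_perm, cells)
            a1 += z_perm
            a2 += z_perm**2
        mean = a1 / n_subj
        var = np.maximum((a2 / n_subj - mean**2) * n_subj / (n_subj - 1), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = mean / np.sqrt(var / n_subj)
        clusters = cluster_permutation(
            t_map,
            df,
            t_perm.reshape(n_perm, W, F),
            alpha_form=alpha_form,
            strategy="stimulus_label",
        )
    return FitMap(
        z=z,
        t=t_map,
        p=p_map,
        df=df,
        window_times=np.asarray(window_times),
        frequencies=np.asarray(frequencies),
        model_tag=tag,
        mask=mask,
        clusters=clusters,
    )


@dataclass
class GeneralizationMap:
    """Phase-A x phase-B same-minus-different category similarity maps."""

    subject_maps: np.ndarray  # (S, Wa, Wb)
    t: np.ndarray
    p: np.ndarray
    df: int
    times_a: np.ndarray
    times_b: np.ndarray
    n_same_pairs: int
    n_diff_pairs: int
    n_excluded_pairs: int
    clusters: ClusterResult | None = None


def _overlap_exclusion(
    feats_a: FeatureSeries, feats_b: FeatureSeries
) -> np.ndarray:
    """Pairs (upper triangle) whose contributing trial sets intersect."""
    n = feats_a.items.size
    union = [
        set(feats_a.contributing_trials[i]) | set(feats_b.contributing_trials[i])
        for i in range(n)
    ]
    iu = np.triu_indices(n, k=1)
    return np.array(
        [bool(union[i] & union[j]) for i, j in zip(iu[0], iu[1])], dtype=bool
    )


def _pairwise_z(
    feats_a: FeatureSeries, feats_b: FeatureSeries
) -> np.ndarray:
    """Fisher-z Spearman correlations for all item pairs and window pairs.

    Returns an array of shape (Wa, Wb, n, n)."""
    ra = np.nan_to_num(_rank_center_norm(feats_a.data))  # (n, Wa, D)
    rb = np.nan_to_num(_rank_center_norm(feats_b.data))
    n, wa, d = ra.shape
    wb = rb.shape[1]
    corr = ra.reshape(n * wa, d) @ rb.reshape(n * wb, d).T
    corr = corr.reshape(n, wa, n, wb).transpose(1, 3, 0, 2)
    return fisher_z(corr)


def _contrast_weights(
    cats: np.ndarray, iu, excluded: np.ndarray
) -> np.ndarray | None:
    """Pair weights realizing mean(same) - mean(kept different) for labels."""
    same = cats[iu[0]] == cats[iu[1]]
    diff_kept = (~same) & (~excluded)
    if not same.any() or not diff_kept.any():
        return None
    w = np.zeros(iu[0].size)
    w[same] = 1.0 / same.sum()
    w[diff_kept] -= 1.0 / diff_kept.sum()
    return w


def category_contrast(
    subject_feats_a: list[FeatureSeries],
    subject_feats_b: list[FeatureSeries] | None = None,
    n_perm: int = 0,
    alpha_form: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> GeneralizationMap:
    """Temporal-generalization category contrast between two task phases.

    For every (window a, window b) cell and every subject, the mean Fisher-z
    correlation of same-category (different-item) pairs minus that of
    different-category pairs is computed; different-category pairs whose
    contributing trial sets intersect are excluded (after repetition
    averaging). EES is the symmetric case ``subject_feats_b=None`` (A = B);
    the cross-phase (EMS) variant averages the two roles of each unordered
    item pair.

    Item sets may differ across subjects (e.g. only cued items appear in the
    maintenance phase). The cluster-permutation null shuffles item category
    labels — jointly across subjects when they share the item set, otherwise
    independently per subject.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    same_phase = subject_feats_b is None
    if same_phase:
        subject_feats_b = subject_feats_a
    n_subj = len(subject_feats_a)
    wa = subject_feats_a[0].data.shape[1]
    wb = subject_feats_b[0].data.shape[1]
    n_cells = wa * wb

    cats0 = np.asarray(subject_feats_a[0].categories)
    shared_items = all(
        np.array_equal(np.asarray(f.categories), cats0) for f in subject_feats_a
    )

    subj_pair_z: list[np.ndarray] = []
    subj_cats: list[np.ndarray] = []
    subj_excluded: list[np.ndarray] = []
    subj_iu: list[tuple] = []
    maps = np.empty((n_subj, n_cells))
    n_same = n_diff = n_excl = 0
    for s in range(n_subj):
        fa, fb = subject_feats_a[s], subject_feats_b[s]
        if not np.array_equal(np.asarray(fa.items), np.asarray(fb.items)):
            raise ValueError("phase A and B must cover the same items per subject")
        cats = np.asarray(fa.categories)
        iu = np.triu_indices(cats.size, k=1)
        z = _pairwise_z(fa, fb)
        if same_phase:
            zp = z[:, :, iu[0], iu[1]]
        else:
            # cross-phase similarity of the unordered pair: average both roles
            zp = 0.5 * (z[:, :, iu[0], iu[1]] + z[:, :, iu[1], iu[0]])
        zp = zp.reshape(n_cells, iu[0].size)
        excluded = _overlap_exclusion(fa, fb)
        w = _contrast_weights(cats, iu, excluded)
        if w is None:
            raise ValueError("a contrast condition has zero surviving pairs")
        maps[s] = zp @ w
        same = cats[iu[0]] == cats[iu[1]]
        n_same += int(same.sum())
        n_diff += int(((~same) & ~excluded).sum())
        n_excl += int(((~same) & excluded).sum())
        subj_pair_z.append(zp)
        subj_cats.append(cats)
        subj_excluded.append(excluded)
        subj_iu.append(iu)
    maps = maps.reshape(n_subj, wa, wb)
    t_map, df = one_sample_t(maps)
    p_map = 2.0 * t_dist.sf(np.abs(t_map), df)

    clusters = None
    if n_perm > 0:
        if shared_items:
            label_perms = [rng.permutation(cats0.size) for _ in range(n_perm)]
        # accumulate mean / variance across subjects without materializing
        # the (S, cells, n_perm) array
        a1 = np.zeros((n_cells, n_perm))
        a2 = np.zeros((n_cells, n_perm))
        for s in range(n_subj):
            cats, iu, excl = subj_cats[s], subj_iu[s], subj_excluded[s]
            weights = np.zeros((n_perm, iu[0].size))
            for k in range(n_perm):
                pc = (
                    cats[label_perms[k]]
                    if shared_items
                    else rng.permutation(cats)
                )
                w = _contrast_weights(pc, iu, excl)
                if w is not None:
                    weights[k] = w
            m_s = subj_pair_z[s] @ weights.T
            a1 += m_s
            a2 += m_s**2
        mean = a1 / n_subj
        var = np.maximum((a2 / n_subj - mean**2) * n_subj / (n_subj - 1), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = mean / np.sqrt(var / n_subj)
        t_perm = t_perm.T.reshape(n_perm, wa, wb)
        clusters = cluster_permutation(
            t_map, df, t_perm, alpha_form=alpha_form, strategy="stimulus_label"
        )
    return GeneralizationMap(
        subject_maps=maps,
        t=t_map,
        p=p_map,
        df=df,
        times_a=subject_feats_a[0].window_times,
        times_b=subject_feats_b[0].window_times,
        n_same_pairs=n_same,
        n_diff_pairs=n_diff,
        n_excluded_pairs=n_excl,
        clusters=clusters,
    )


def category_timecourse(feats: FeatureSeries) -> np.ndarray:
    """Within-minus-between category contrast at matching windows only.

    Returns a (n_windows,) series of mean Fisher-z differences — the
    high-temporal-resolution (diagonal) variant of the category contrast.
    """
    cats = np.asarray(feats.categories)
    iu = np.triu_indices(cats.size, k=1)
    same = cats[iu[0]] == cats[iu[1]]
    excluded = _overlap_exclusion(feats, feats)
    diff_kept = (~same) & (~excluded)
    if not same.any() or not diff_kept.any():
        raise ValueError("a contrast condition has zero surviving pairs")
    r = np.nan_to_num(_rank_center_norm(feats.data))  # (n, W, D)
    corr = np.einsum("nwd,mwd->wnm", r, r)
    z = fisher_z(corr)[:, iu[0], iu[1]]  # (W, P)
    return z[:, same].mean(axis=1) - z[:, diff_kept].mean(axis=1)


@dataclass
class LatencyResult:
    """Onsets of category information per region and their comparison."""

    times: np.ndarray
    timecourse_a: np.ndarray  # (Sa, W) subject contrast series, region A
    timecourse_b: np.ndarray
    clusters_a: ClusterResult
    clusters_b: ClusterResult
    onset_a: float | None
    onset_b: float | None
    difference: ClusterResult

    @property
    def onset_difference(self) -> float | None:
        if self.onset_a is None or self.onset_b is None:
            return None
        return self.onset_b - self.onset_a


def _onset(clusters: ClusterResult, times: np.ndarray, alpha: float) -> float | None:
    """First time point of the earliest corrected-significant positive cluster."""
    sig = [c for c in clusters.significant(alpha) if c.mass > 0]
    if not sig:
        return None
    return float(times[min(int(c.cells[0].min()) for c in sig)])


def latency_comparison(
    timecourse_a: np.ndarray,
    timecourse_b: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    alpha_form: float = 0.05,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> LatencyResult:
    """Compare category-information onsets between two regions.

    Inputs are subject x window contrast series (from
    :func:`category_timecourse`) for each region. Onsets come from
    cluster-corrected within-region tests; the between-region difference uses
    Welch t-tests per time point with region-label shuffles (the subject sets
    of the two regions may differ).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = np.atleast_2d(np.asarray(timecourse_a, dtype=float))
    b = np.atleast_2d(np.asarray(timecourse_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each region needs at least 2 subjects")
    res_a = cluster_1samp(a, n_perm=n_perm, alpha_form=alpha_form, seed=rng)
    res_b = cluster_1samp(b, n_perm=n_perm, alpha_form=alpha_form, seed=rng)
    diff = cluster_indep(a, b, n_perm=n_perm, alpha_form=alpha_form, seed=rng)
    times = np.asarray(times)
    return LatencyResult(
        times=times,
        timecourse_a=a,
        timecourse_b=b,
        clusters_a=res_a,
        clusters_b=res_b,
        onset_a=_onset(res_a, times, alpha),
        onset_b=_onset(res_b, times, alpha),
        difference=diff,
    )


@dataclass
class TrialFitResult:
    """Single-trial model fits split by response correctness."""

    subject_diff_maps: np.ndarray  # (S_kept, W, F) correct - incorrect
    t: np.ndarray
    p: np.ndarray
    df: int
    kept_subjects: np.ndarray
    clusters: ClusterResult | None = None


def trial_level_fit(
    subject_stacks: list[np.ndarray],
    subject_item_of: list[np.ndarray],
    subject_correct: list[np.ndarray],
    model: ModelRSM | np.ndarray,
    min_trials: int = 5,
    n_perm: int = 0,
    alpha_form: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> TrialFitResult:
    """Row-wise single-trial model fits contrasted by correctness.

    For each presentation r, its row of the presentation-level neural RSM
    (stack (W, F, n_pres, n_pres)) is Spearman-correlated with the model row
    of the presented item against the items of all other presentations.
    Fits are averaged within correct and incorrect trials; subjects with
    fewer than ``min_trials`` in either condition are excluded; the
    correct-minus-incorrect maps are tested at the group level with a
    condition-label shuffle cluster permutation.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m_mat = model.matrix if isinstance(model, ModelRSM) else np.asarray(model)

    kept = []
    fits_by_subject = []
    correct_by_subject = []
    for s, stack in enumerate(subject_stacks):
        item_of = np.asarray(subject_item_of[s])
        correct = np.asarray(subject_correct[s], dtype=float)
        n_pres = item_of.size
        ok = np.isfinite(correct)
        n_corr = int((correct[ok] == 1).sum())
        n_inc = int((correct[ok] == 0).sum())
        if n_corr < min_trials or n_inc < min_trials:
            continue
        w, f = stack.shape[:2]
        fits = np.empty((n_pres, w, f))
        others_all = np.arange(n_pres)
        for r in range(n_pres):
            others = others_all[others_all != r]
            neural_rows = stack[:, :, r, :][:, :, others]  # (W, F, n-1)
            model_row = m_mat[item_of[r], item_of[others]]
            if np.all(model_row == model_row[0]):
                fits[r] = np.nan
                continue
            mr = _rank_center_norm(model_row[None, :])[0]
            nr = np.nan_to_num(
                _rank_center_norm(neural_rows.reshape(w * f, -1))
            )
            fits[r] = fisher_z(nr @ mr).reshape(w, f)
        kept.append(s)
        fits_by_subject.append(fits)
        correct_by_subject.append(correct)

    if len(kept) < 2:
        raise ValueError("fewer than 2 subjects meet the trial-count inclusion rule")

    def cond_diff(fits, correct):
        ok = np.isfinite(correct)
        c = np.nanmean(fits[ok & (correct == 1)], axis=0)
        i = np.nanmean(fits[ok & (correct == 0)], axis=0)
        return c - i

    diffs = np.stack(
        [cond_diff(f, c) for f, c in zip(fits_by_subject, correct_by_subject)]
    )
    t_map, df = one_sample_t(diffs)
    p_map = 2.0 * t_dist.sf(np.abs(t_map), df)

    clusters = None
    if n_perm > 0:

        def perm_iter():
            for _ in range(n_perm):
                perm_diffs = np.stack(
                    [
                        cond_diff(f, rng.permutation(c))
                        for f, c in zip(fits_by_subject, correct_by_subject)
                    ]
                )
                yield one_sample_t(perm_diffs)[0]

        clusters = cluster_permutation(
            t_map,
            df,
            perm_iter(),
            alpha_form=alpha_form,
            strategy="condition_label",
        )
    return TrialFitResult(
        subject_diff_maps=diffs,
        t=t_map,
        p=p_map,
        df=df,
        kept_subjects=np.asarray(kept),
        clusters=clusters,
    )


def behavioral_summary(subject_tables: list[pd.DataFrame]) -> dict:
    """Proportion correct per cue condition, compared across subjects.

    Per subject and condition, the proportion of correct responses is
    computed independently for encoding positions 1-3 and averaged over the
    positions that were probed; condition means are compared with a
    two-sided paired t-test (refused with fewer than 2 subjects, or when the
    condition difference has zero variance).
    """
    rows = []
    for s, table in enumerate(subject_tables):
        enc = table[(table.phase == "encoding")]
        for cond in ("single", "multi"):
            sub = enc[enc.condition == cond]
            if len(sub) == 0:
                raise ValueError(f"condition {cond!r} missing for subject {s}")
            per_pos = sub.dropna(subset=["correct"]).groupby("position")["correct"].mean()
            rows.append(
                dict(subject=s, condition=cond, proportion_correct=per_pos.mean())
            )
    df = pd.DataFrame(rows)
    means = df.pivot(index="subject", columns="condition", values="proportion_correct")
    out = {
        "per_subject": df,
        "mean_single": float(means["single"].mean()),
        "mean_multi": float(means["multi"].mean()),
        "t": None,
        "p": None,
        "note": None,
    }
    if len(means) < 2:
        out["note"] = "group test refused: fewer than 2 subjects"
        return out
    d = means["single"] - means["multi"]
    if np.allclose(d.std(ddof=1), 0.0):
        out["note"] = "group test undefined: zero variance of condition difference"
        return out
    res = ttest_rel(means["single"], means["multi"])
    out["t"], out["p"] = float(res.statistic), float(res.pvalue)
    return out
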