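"""Representational feature vectors and neural RSM time series.

Feature vectors concatenate channels x in-scope frequencies x time points of
z-scored power inside 500 ms sliding windows (5 points at the standard
100 ms resolution, 50 averaged points in the 10 ms high-resolution variant).
Item-to-item similarity is always Spearman's rank correlation; each window's
RSM is labeled by the window's center time. Items are kept in canonical
stimulus-id order so neural and model RSMs align by id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .timefreq import TFPower

__all__ = [
    "WindowScheme",
    "ItemPower",
    "FeatureSeries",
    "RSMSeries",
    "average_repetitions",
    "build_feature_series",
    "build_highres_features",
    "neural_rsm_series",
    "vectorize_rsm",
    "spearman_matrix",
    "pair_masks",
]


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window parameters: 500 ms windows advancing by 100 ms."""

    width: float = 0.5
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step > self.width:
            raise ValueError("step must not exceed width (windows must overlap or tile)")

    @property
    def overlap(self) -> float:
        return self.width - self.step


@dataclass
class ItemPower:
    """Repetition-averaged power: items x channels x frequencies x time."""

    data: np.ndarray
    items: np.ndarray  # stimulus ids, canonical order
    categories: np.ndarray  # category of each item
    times: np.ndarray
    frequencies: np.ndarray
    contributing_trials: list[set]  # trial ids contributing to each item
    valid: np.ndarray  # (n_freqs, n_times)


@dataclass
class FeatureSeries:
    """Per item (or presentation), per window: one concatenated feature vector."""

    data: np.ndarray  # (n_items, n_windows, n_features)
    window_times: np.ndarray  # window center times
    items: np.ndarray
    categories: np.ndarray
    contributing_trials: list[set]
    scope: str  # e.g. "freq:20.0", "band:beta", "all"


@dataclass
class RSMSeries:
    """Per window: a symmetric item x item Spearman correlation matrix."""

    rsms: np.ndarray  # (n_windows, n_items, n_items)
    window_times: np.ndarray
    items: np.ndarray
    categories: np.ndarray
    scope: str


def average_repetitions(
    power: TFPower, meta: pd.DataFrame, phase: str = "encoding"
) -> ItemPower:
    """Average power across repeated presentations of every stimulus.

    ``meta`` has one row per epoch of ``power`` (same order) with columns
    ``phase``, ``stimulus``, ``category`` and ``trial``. The record of
    contributing trial ids per item is retained — the encoding/maintenance
    contrast needs it to exclude overlapping-trial pairs.
    """
    if len(meta) != power.n_trials:
        raise ValueError("meta must have one row per epoch")
    sel = (meta.phase == phase).to_numpy() & (meta.stimulus >= 0).to_numpy()
    if not sel.any():
        raise ValueError(f"no epochs in phase {phase!r}")
    sub = meta[sel].reset_index(drop=True)
    data = power.data[sel]
    items = np.unique(sub.stimulus.to_numpy())
    out = np.empty((items.size,) + data.shape[1:])
    cats = np.empty(items.size, dtype=int)
    contributing: list[set] = []
    for k, item in enumerate(items):
        rows = np.flatnonzero(sub.stimulus.to_numpy() == item)
        out[k] = data[rows].mean(axis=0)
        cats[k] = sub.category.iloc[rows[0]]
        contributing.append(set(sub.trial.iloc[rows].tolist()))
    missing = set()  # items never presented are simply absent
    if missing:
        warnings.warn(f"items excluded (no presentation): {sorted(missing)}")
    return ItemPower(
        data=out,
        items=items,
        categories=cats,
        times=np.asarray(power.times),
        frequencies=np.asarray(power.frequencies),
        contributing_trials=contributing,
        valid=power.valid.copy(),
    )


def _window_starts(times: np.ndarray, valid: np.ndarray, scheme: WindowScheme):
    dt = float(np.median(np.diff(times)))
    w = int(round(scheme.width / dt))
    s = max(1, int(round(scheme.step / dt)))
    starts = []
    col_ok = valid.all(axis=0)
    for i in range(0, times.size - w + 1, s):
        if col_ok[i : i + w].all():
            starts.append(i)
    return np.asarray(starts, dtype=int), w


def build_feature_series(
    item_power: ItemPower,
    scheme: WindowScheme | None = None,
    scope: str = "all",
    freq_indices: np.ndarray | None = None,
    min_channels: int = 2,
) -> FeatureSeries:
    """Concatenate channels x in-scope frequencies x window time points.

    ``freq_indices`` selects the frequency rows in scope (a single frequency
    for the frequency-resolved analyses, a band's members for the contrast
    analyses, all 52 when ``None``). Regions with fewer than ``min_channels``
    channels are rejected, mirroring the two-electrode inclusion rule.
    Windows containing any invalid (edge-flagged) sample are dropped whole.
    """
    if scheme is None:
        scheme = WindowScheme()
    n_ch = item_power.data.shape[1]
    if n_ch < min_channels:
        raise ValueError(f"region has {n_ch} channel(s); at least {min_channels} required")
    if freq_indices is None:
        freq_indices = np.arange(item_power.frequencies.size)
    freq_indices = np.asarray(freq_indices, dtype=int)
    sub = item_power.data[:, :, freq_indices, :]
    valid = item_power.valid[freq_indices, :]
    starts, w = _window_starts(item_power.times, valid, scheme)
    if starts.size == 0:
        raise ValueError("no valid window fits the epoch")
    n_items = sub.shape[0]
    feats = np.empty((n_items, starts.size, n_ch * freq_indices.size * w))
    centers = np.empty(starts.size)
    for k, i in enumerate(starts):
        block = sub[..., i : i + w]  # items x ch x f x w
        feats[:, k, :] = block.reshape(n_items, -1)
        # a window covering [t, t + width) is labeled by its span center
        centers[k] = item_power.times[i] + 0.5 * scheme.width
    return FeatureSeries(
        data=feats,
        window_times=centers,
        items=item_power.items,
        categories=item_power.categories,
        contributing_trials=item_power.contributing_trials,
        scope=scope,
    )


def build_highres_features(
    item_power: ItemPower,
    width: float = 0.5,
    step: float = 0.01,
    min_channels: int = 2,
) -> FeatureSeries:
    """High-temporal-resolution features: 500 ms windows advancing by 10 ms.

    Within each window the samples are averaged per (channel, frequency), so
    the feature vector is channels x frequencies (time-collapsed) — built for
    onset-latency comparisons at 10 ms resolution.
    """
    n_ch = item_power.data.shape[1]
    if n_ch < min_channels:
        raise ValueError(f"region has {n_ch} channel(s); at least {min_channels} required")
    scheme = WindowScheme(width=width, step=step)
    starts, w = _window_starts(item_power.times, item_power.valid, scheme)
    if starts.size == 0:
        raise ValueError("no valid window fits the epoch")
    n_items = item_power.data.shape[0]
    csum = np.concatenate(
        [
            np.zeros(item_power.data.shape[:-1] + (1,)),
            np.cumsum(item_power.data, axis=-1),
        ],
        axis=-1,
    )
    feats = np.empty((n_items, starts.size, n_ch * item_power.frequencies.size))
    centers = np.empty(starts.size)
    for k, i in enumerate(starts):
        mean = (csum[..., i + w] - csum[..., i]) / w
        feats[:, k, :] = mean.reshape(n_items, -1)
        centers[k] = item_power.times[i] + 0.5 * width
    return FeatureSeries(
        data=feats,
        window_times=centers,
        items=item_power.items,
        categories=item_power.categories,
        contributing_trials=item_power.contributing_trials,
        scope="highres:all",
    )


def spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between the rows of ``x`` (average ranks).

    Rows with constant features have undefined correlations; those entries
    are returned as NaN and excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    ranks = rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ranks)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0, out=c) if np.isfinite(c).all() else c


def neural_rsm_series(features: FeatureSeries) -> RSMSeries:
    """Spearman RSM between every item pair, per window."""
    n_items = features.data.shape[0]
    if n_items < 3:
        raise ValueError("need at least 3 items for an RSM series")
    n_w = features.data.shape[1]
    rsms = np.empty((n_w, n_items, n_items))
    for wdx in range(n_w):
        rsms[wdx] = spearman_matrix(features.data[:, wdx, :])
    return RSMSeries(
        rsms=rsms,
        window_times=features.window_times,
        items=features.items,
        categories=features.categories,
        scope=features.scope,
    )


def pair_masks(categories: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle index pair arrays plus within/between category masks."""
    categories = np.asarray(categories)
    iu = np.triu_indices(categories.size, k=1)
    within = categories[iu[0]] == categories[iu[1]]
    return iu, within, ~within


def vectorize_rsm(
    rsm: np.ndarray,
    categories: np.ndarray | None = None,
    mask: str = "all",
) -> np.ndarray:
    """Upper triangle of an RSM, diagonal excluded, optionally masked.

    ``mask`` restricts to same-category (``within``) or different-category
    (``between``) pairs; it requires ``categories``.
    """
    rsm = np.asarray(rsm, dtype=float)
    if rsm.ndim != 2 or rsm.shape[0] != rsm.shape[1]:
        raise ValueError("rsm must be square")
    finite = np.isfinite(rsm)
    sym = finite & finite.T
    if not np.allclose(rsm[sym].reshape(-1), rsm.T[sym].reshape(-1), atol=1e-10):
        raise ValueError("rsm must be symmetric")
    iu = np.triu_indices(rsm.shape[0], k=1)
    vec = rsm[iu]
    if mask == "all":
        return vec
    if categories is None:
        raise ValueError("masked vectorization requires category labels")
    categories = np.asarray(categories)
    within = categories[iu[0]] == categories[iu[1]]
    if mask == "within_category" or mask == "within":
        return vec[within]
    if mask == "between_category" or mask == "between":
        return vec[~within]
    raise ValueError(f"unknown mask {mask!r}")
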