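"""Hypothesis model RSMs: binary category/item models and layered stacks.

Binary models code the hypothesized similarity structure directly: the
category model marks pairs of same-category items with 1 and different
categories with 0; the item model marks repeated presentations of the same
stimulus across different trials with 1. Layered stacks hold one RSM per
(layer, timepoint) of a hierarchical feature model — either simulated with a
known geometry schedule or ingested from externally computed activations
(e.g. unit activations of a feedforward or recurrent convolutional network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rsm import spearman_matrix
from .synth import StimulusSet

__all__ = [
    "ModelRSM",
    "LayeredModelRSMs",
    "category_model",
    "item_model",
    "rsms_from_activations",
    "load_activations_hdf5",
]


@dataclass
class ModelRSM:
    """An item x item model similarity matrix with its hypothesis tag."""

    matrix: np.ndarray
    items: np.ndarray
    categories: np.ndarray | None
    tag: str  # {"category", "item", "layered:<layer>"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("model RSM must be square")
        if not np.allclose(m, m.T):
            raise ValueError("model RSM must be symmetric")
        self.matrix = m


@dataclass
class LayeredModelRSMs:
    """A layer x timepoint grid of RSMs over a shared item set.

    Timepoint counts may differ per layer (ragged), as in recurrent
    architectures whose layers run different numbers of recurrent passes
    (e.g. 5/4/3/2). By convention, model fits use the last timepoint of each
    layer — the stabilized representation — while consistency analyses use
    all timepoints.
    """

    rsms: list[list[np.ndarray]]  # [layer][timepoint] -> (n, n)
    layers: list[str]
    source: str  # {"simulated", "ingested"}
    categories: np.ndarray | None = None

    def __post_init__(self) -> None:
        sizes = {m.shape for layer in self.rsms for m in layer}
        if len(sizes) > 1:
            raise ValueError("all RSMs must share the item set")
        if any(len(layer) < 1 for layer in self.rsms):
            raise ValueError("each layer needs at least one timepoint")

    @property
    def n_layers(self) -> int:
        return len(self.rsms)

    @property
    def n_rsms(self) -> int:
        return sum(len(layer) for layer in self.rsms)

    def timepoint_counts(self) -> list[int]:
        return [len(layer) for layer in self.rsms]

    def last_timepoints(self) -> np.ndarray:
        """Stack of each layer's final-timepoint RSM, shape (L, n, n)."""
        return np.stack([layer[-1] for layer in self.rsms])


def category_model(stimuli: StimulusSet) -> ModelRSM:
    """Binary same-category model: M[i, j] = 1 iff category(i) == category(j)."""
    cats = stimuli.category_of
    m = (cats[:, None] == cats[None, :]).astype(float)
    model = ModelRSM(
        matrix=m, items=stimuli.ids, categories=cats.copy(), tag="category"
    )
    if stimuli.n_categories == 1:
        model.tag = "category:non-informative"
    return model


def item_model(presentations: pd.DataFrame) -> ModelRSM:
    """Presentation-level same-item model across different trials.

    Rows of ``presentations`` (encoding rows of a trial table) are the units;
    a pair is coded 1 when it is the same stimulus shown in two different
    trials, 0 otherwise. Undefined (error) when no stimulus repeats.
    """
    enc = presentations[presentations.phase == "encoding"].reset_index(drop=True)
    stim = enc.stimulus.to_numpy()
    trial = enc.trial.to_numpy()
    same_item = stim[:, None] == stim[None, :]
    diff_trial = trial[:, None] != trial[None, :]
    m = (same_item & diff_trial).astype(float)
    np.fill_diagonal(m, 1.0)
    iu = np.triu_indices(len(enc), k=1)
    if m[iu].sum() == 0:
        raise ValueError("item model undefined: no repeated presentations")
    return ModelRSM(
        matrix=m,
        items=stim,
        categories=enc.category.to_numpy(),
        tag="item",
    )


def rsms_from_activations(
    activations: list[list[np.ndarray]],
    layers: list[str] | None = None,
    categories: np.ndarray | None = None,
) -> LayeredModelRSMs:
    """Spearman RSM per (layer, timepoint) from item x unit activation matrices."""
    n_items = None
    rsms: list[list[np.ndarray]] = []
    for layer in activations:
        layer_rsms = []
        for a in layer:
            a = np.asarray(a, dtype=float)
            if a.ndim != 2 or a.shape[1] < 2:
                raise ValueError("activations must be items x units with >= 2 units")
            if n_items is None:
                n_items = a.shape[0]
            elif a.shape[0] != n_items:
                raise ValueError("item count differs across layers/timepoints")
            layer_rsms.append(spearman_matrix(a))
        rsms.append(layer_rsms)
    if layers is None:
        layers = [f"layer{i + 1}" for i in range(len(rsms))]
    return LayeredModelRSMs(
        rsms=rsms, layers=layers, source="ingested", categories=categories
    )


def load_activations_hdf5(
    h5_path: str | Path, manifest_path: str | Path
) -> LayeredModelRSMs:
    """Ingest externally computed activations from HDF5 plus a JSON manifest.

    The manifest lists layer names and per-layer timepoint counts; the HDF5
    file holds one ``<layer>/t<k>`` dataset (items x units) per timepoint.
    Supports 8x1 (feedforward), 7x8 and 5/4/3/2-style recurrent layouts
    without re-running any network.
    """
    import h5py

    with open(manifest_path) as fh:
        manifest = json.load(fh)
    layers = manifest["layers"]
    counts = manifest["timepoints"]
    categories = manifest.get("categories")
    acts: list[list[np.ndarray]] = []
    with h5py.File(h5_path, "r") as fh:
        for layer, n_tp in zip(layers, counts):
            acts.append([fh[f"{layer}/t{k}"][()] for k in range(n_tp)])
    return rsms_from_activations(
        acts,
        layers=list(layers),
        categories=None if categories is None else np.asarray(categories),
    )
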