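"""Synthetic working-memory data with known representational ground truth.

The generator emulates a retro-cue multi-item working-memory experiment:
stimuli come from 6 categories with 10 exemplars each (60 images), every
trial encodes a sequence of 3 items from 3 different categories, and a
retro-cue then instructs the participant to maintain either a single item
(50% of trials) or all items. Epochs carry band- and window-limited
category-specific power patterns over channels at a controllable
signal-to-noise ratio on top of 1/f-like background noise, so every
downstream analysis stage can be validated against a known effect.

Maintenance-phase patterns are injected with a ``maintenance_mix`` parameter:
1 reuses the encoding category templates (a reinstated, sensory-like regime),
0 uses independent templates (a fully transformed, control-like regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timefreq import EpochedRecording, TFPower, build_frequency_grid

__all__ = [
    "StimulusSet",
    "SyntheticSpec",
    "GeometrySchedule",
    "SimulatedSubject",
    "make_stimulus_set",
    "simulate_trial_table",
    "simulate_epochs",
    "simulate_layered_rsms",
    "pink_noise",
]


@dataclass(frozen=True)
class StimulusSet:
    """A balanced category x exemplar stimulus design.

    Stimulus ids are 0..n-1 in canonical order: id ``i`` belongs to category
    ``i // n_exemplars`` and is exemplar ``i % n_exemplars`` within it.
    """

    n_categories: int = 6
    n_exemplars: int = 10

    @property
    def n_stimuli(self) -> int:
        return self.n_categories * self.n_exemplars

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_stimuli)

    @property
    def category_of(self) -> np.ndarray:
        return self.ids // self.n_exemplars

    @property
    def exemplar_of(self) -> np.ndarray:
        return self.ids % self.n_exemplars


def make_stimulus_set(n_categories: int = 6, n_exemplars: int = 10) -> StimulusSet:
    """Create a stimulus set; both counts must be at least 1."""
    if n_categories < 1 or n_exemplars < 1:
        raise ValueError("n_categories and n_exemplars must be >= 1")
    return StimulusSet(int(n_categories), int(n_exemplars))


@dataclass
class SyntheticSpec:
    """Parameters of a simulated subject.

    SNRs are expressed in z-units per unit template amplitude in ``tf`` mode
    and as oscillatory burst amplitudes relative to the 1/f background in
    ``raw`` mode. ``effect_snr = item_effect_snr = 0`` yields pure noise.
    """

    n_subjects: int = 12
    n_channels: int = 8
    n_sessions: int = 1
    n_trials_per_session: int = 60
    effect_band: tuple[float, float] = (13.0, 29.0)
    effect_window: tuple[float, float] = (0.1, 0.7)
    effect_snr: float = 1.2
    item_effect_snr: float = 0.0
    maintenance_mix: float = 1.0
    maintenance_window: tuple[float, float] = (0.1, 0.7)
    maintenance_snr: float | None = None  # defaults to effect_snr
    noise_exponent: float = 1.0
    epoch_span: tuple[float, float] = (-2.0, 7.0)
    sampling_rate: float = 1000.0
    tf_step: float = 0.1  # time step of tf-mode power arrays (s)
    p_correct_single: float = 0.8
    p_correct_multi: float = 0.75
    effect_only_correct: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.effect_band
        if not (3.0 <= lo < hi <= 150.0):
            raise ValueError("effect_band must lie within 3-150 Hz")
        if not (
            self.epoch_span[0] <= self.effect_window[0]
            < self.effect_window[1] <= self.epoch_span[1]
        ):
            raise ValueError("effect_window must lie within epoch_span")
        if self.effect_snr < 0 or self.item_effect_snr < 0:
            raise ValueError("SNRs must be non-negative")
        if not 0.0 <= self.maintenance_mix <= 1.0:
            raise ValueError("maintenance_mix must be in [0, 1]")


@dataclass
class GeometrySchedule:
    """Target within/between-category correlations per layer of an RSM stack."""

    n_layers: int
    n_timepoints: int | list[int]
    within_by_layer: list[float]
    between_by_layer: list[float]
    noise_sd: float = 0.0
    seed: int = 0

    def timepoints(self) -> list[int]:
        if isinstance(self.n_timepoints, int):
            return [self.n_timepoints] * self.n_layers
        return list(self.n_timepoints)

    def validate(self) -> None:
        if len(self.within_by_layer) != self.n_layers:
            raise ValueError("within_by_layer must have n_layers entries")
        if len(self.between_by_layer) != self.n_layers:
            raise ValueError("between_by_layer must have n_layers entries")
        if len(self.timepoints()) != self.n_layers:
            raise ValueError("per-layer timepoint list must have n_layers entries")
        vals = list(self.within_by_layer) + list(self.between_by_layer)
        if any(abs(v) > 1 for v in vals):
            raise ValueError("correlation targets must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_trial_table(
    stimulus_set: StimulusSet,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one subject's presentation table.

    Each trial contributes three encoding rows (items from three distinct
    categories) and one maintenance row time-locked to the retro-cue. Within
    a session, per-stimulus presentation counts are balanced up to a
    difference of one. Cue condition is single-item in half the trials; the
    cued item of single trials is the maintained content. Correctness is
    simulated per probed position (only the cued position is probed in
    single-item trials).
    """
    if stimulus_set.n_categories < 3:
        raise ValueError("need at least 3 categories to build 3-item sequences")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_stim = stimulus_set.n_stimuli
    cat_of = stimulus_set.category_of
    rows: list[dict] = []
    trial_id = 0
    for session in range(spec.n_sessions):
        n_trials = spec.n_trials_per_session
        slots = 3 * n_trials
        # Balanced presentation counts: base repetitions plus a random
        # category-balanced remainder.
        counts = np.full(n_stim, slots // n_stim, dtype=int)
        remainder = slots - counts.sum()
        if remainder:
            extra = rng.permutation(n_stim)[:remainder]
            counts[extra] += 1
        remaining = counts.astype(float)
        conditions = np.array(
            ["single", "multi"] * (n_trials // 2) + ["single"] * (n_trials % 2)
        )
        rng.shuffle(conditions)
        for t in range(n_trials):
            per_cat = np.array(
                [remaining[cat_of == c].sum() for c in range(stimulus_set.n_categories)]
            )
            # pick the 3 categories with most remaining presentations,
            # random tie-break, so category use stays balanced and feasible
            noise = rng.random(per_cat.size) * 1e-6
            cats = np.argsort(-(per_cat + noise))[:3]
            if np.any(per_cat[cats] <= 0):
                raise RuntimeError("presentation pool exhausted; design infeasible")
            items = []
            for c in cats:
                pool = np.flatnonzero((cat_of == c) & (remaining > 0))
                w = remaining[pool] / remaining[pool].sum()
                item = rng.choice(pool, p=w)
                remaining[item] -= 1
                items.append(int(item))
            order = rng.permutation(3)
            items = [items[k] for k in order]
            condition = conditions[t]
            cued_position = int(rng.integers(1, 4)) if condition == "single" else 0
            p_ok = (
                spec.p_correct_single
                if condition == "single"
                else spec.p_correct_multi
            )
            for pos, item in enumerate(items, start=1):
                probed = condition == "multi" or pos == cued_position
                correct = float(rng.random() < p_ok) if probed else np.nan
                rows.append(
                    dict(
                        trial=trial_id,
                        session=session,
                        phase="encoding",
                        position=pos,
                        stimulus=item,
                        category=int(cat_of[item]),
                        exemplar=int(stimulus_set.exemplar_of[item]),
                        condition=condition,
                        cued_position=cued_position,
                        correct=correct,
                    )
                )
            if condition == "single":
                cued_item = items[cued_position - 1]
                cue_stim, cue_cat = cued_item, int(cat_of[cued_item])
            else:
                cue_stim, cue_cat = -1, -1
            rows.append(
                dict(
                    trial=trial_id,
                    session=session,
                    phase="maintenance",
                    position=0,
                    stimulus=cue_stim,
                    category=cue_cat,
                    exemplar=-1 if cue_stim < 0 else int(stimulus_set.exemplar_of[cue_stim]),
                    condition=condition,
                    cued_position=cued_position,
                    correct=np.nan,
                )
            )
            trial_id += 1
    table = pd.DataFrame(rows)
    # carry per-trial correctness of the cued item onto maintenance rows
    enc = table[table.phase == "encoding"]
    cued = enc[
        (enc.condition == "single") & (enc.position == enc.cued_position)
    ].set_index("trial")["correct"]
    maint = table.phase == "maintenance"
    table.loc[maint, "correct"] = table.loc[maint, "trial"].map(cued).to_numpy()
    return table


def pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sfreq: float,
    exponent: float = 1.0,
) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (
        rng.standard_normal(shape[:-1] + (freqs.size,))
        + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@dataclass
class SimulatedSubject:
    """One subject's simulated data plus the ground-truth templates."""

    trial_table: pd.DataFrame
    encoding: TFPower | EpochedRecording
    maintenance: TFPower | EpochedRecording
    encoding_meta: pd.DataFrame  # one row per encoding epoch
    maintenance_meta: pd.DataFrame  # one row per maintenance epoch
    category_templates: np.ndarray  # (n_categories, n_channels)
    maintenance_templates: np.ndarray
    item_templates: np.ndarray  # (n_stimuli, n_channels)


def _template_bank(
    rng: np.random.Generator, stimulus_set: StimulusSet, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cat = rng.standard_normal((stimulus_set.n_categories, spec.n_channels))
    indep = rng.standard_normal((stimulus_set.n_categories, spec.n_channels))
    m = spec.maintenance_mix
    maint = m * cat + np.sqrt(max(0.0, 1.0 - m * m)) * indep
    item = rng.standard_normal((stimulus_set.n_stimuli, spec.n_channels))
    return cat, maint, item


def simulate_epochs(
    trial_table: pd.DataFrame,
    spec: SyntheticSpec,
    stimulus_set: StimulusSet,
    mode: str = "tf",
    rng: np.random.Generator | None = None,
) -> SimulatedSubject:
    """Simulate epochs around every encoding presentation and retro-cue.

    ``tf`` mode injects the category/item channel templates directly into
    z-scale power on the canonical 52-frequency grid inside the effect band
    and window; ``raw`` mode returns 1/f-filtered time series with
    band-limited oscillatory bursts whose channel-amplitude pattern encodes
    the same templates. Maintenance epochs of single-item trials carry the
    maintenance template of the cued item's category.
    """
    spec.validate()
    if mode not in ("tf", "raw"):
        raise ValueError("mode must be 'tf' or 'raw'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cat_tpl, maint_tpl, item_tpl = _template_bank(rng, stimulus_set, spec)
    maint_snr = spec.effect_snr if spec.maintenance_snr is None else spec.maintenance_snr

    enc_meta = trial_table[trial_table.phase == "encoding"].reset_index(drop=True)
    mnt_meta = trial_table[trial_table.phase == "maintenance"].reset_index(drop=True)
    channels = [f"C{i + 1}" for i in range(spec.n_channels)]

    def gain(meta_row) -> float:
        if not spec.effect_only_correct:
            return 1.0
        return 1.0 if meta_row.correct == 1.0 else 0.0

    if mode == "tf":
        grid = build_frequency_grid()
        t0, t1 = spec.epoch_span
        times = np.arange(t0, t1 + 1e-9, spec.tf_step)
        fmask = (grid.frequencies >= spec.effect_band[0]) & (
            grid.frequencies <= spec.effect_band[1]
        )
        if not fmask.any():
            raise ValueError("effect_band contains no grid frequency")

        def build(meta, window, templates, snr, use_item):
            n = len(meta)
            data = rng.standard_normal(
                (n, spec.n_channels, grid.n_frequencies, times.size)
            )
            tmask = (times >= window[0]) & (times <= window[1])
            ix = np.ix_(
                np.arange(spec.n_channels),
                np.flatnonzero(fmask),
                np.flatnonzero(tmask),
            )
            for e, row in enumerate(meta.itertuples()):
                if row.stimulus < 0:
                    continue
                g = gain(row)
                tpl = snr * g * templates[row.category]
                if use_item and spec.item_effect_snr > 0:
                    tpl = tpl + spec.item_effect_snr * g * item_tpl[row.stimulus]
                data[e][ix] += tpl[:, None, None]
            return TFPower(
                data=data,
                times=times,
                frequencies=grid.frequencies,
                channels=channels,
                sessions=meta.session.to_numpy(),
                zscored=True,
            )

        enc = build(enc_meta, spec.effect_window, cat_tpl, spec.effect_snr, True)
        mnt = build(mnt_meta, spec.maintenance_window, maint_tpl, maint_snr, True)
    else:
        sf = spec.sampling_rate
        t0, t1 = spec.epoch_span
        times = np.arange(round(t0 * sf), round(t1 * sf)) / sf
        f_c = 0.5 * (spec.effect_band[0] + spec.effect_band[1])

        def burst(window) -> np.ndarray:
            # trapezoid with 25 ms linear ramps to limit spectral splatter
            up = np.clip((times - window[0]) / 0.025, 0.0, 1.0)
            down = np.clip((window[1] - times) / 0.025, 0.0, 1.0)
            return up * down

        def build(meta, window, templates, snr, use_item):
            n = len(meta)
            data = pink_noise(
                rng, (n, spec.n_channels, times.size), sf, spec.noise_exponent
            )
            env = burst(window)
            for e, row in enumerate(meta.itertuples()):
                if row.stimulus < 0:
                    continue
                g = gain(row)
                phase = rng.uniform(0, 2 * np.pi)
                carrier = np.cos(2 * np.pi * f_c * times + phase) * env
                amp = snr * g * _positive_amplitude(templates[row.category])
                if use_item and spec.item_effect_snr > 0:
                    amp = amp + spec.item_effect_snr * g * _positive_amplitude(
                        item_tpl[row.stimulus]
                    )
                data[e] += amp[:, None] * carrier[None, :]
            return EpochedRecording(
                data=data,
                sfreq=sf,
                times=times,
                channels=channels,
                sessions=meta.session.to_numpy(),
            )

        enc = build(enc_meta, spec.effect_window, cat_tpl, spec.effect_snr, True)
        mnt = build(mnt_meta, spec.maintenance_window, maint_tpl, maint_snr, True)

    return SimulatedSubject(
        trial_table=trial_table,
        encoding=enc,
        maintenance=mnt,
        encoding_meta=enc_meta,
        maintenance_meta=mnt_meta,
        category_templates=cat_tpl,
        maintenance_templates=maint_tpl,
        item_templates=item_tpl,
    )


def _positive_amplitude(template: np.ndarray) -> np.ndarray:
    """Map a zero-mean template to non-negative oscillation amplitudes."""
    return np.log1p(np.exp(template))  # softplus keeps channel contrast


def simulate_layered_rsms(
    schedule: GeometrySchedule,
    stimulus_set: StimulusSet,
    rng: np.random.Generator | None = None,
):
    """Simulate a layer x timepoint stack of model RSMs with known geometry.

    Each RSM has within-category entries centered on the layer's
    ``within_by_layer`` target and between-category entries on
    ``between_by_layer``, with symmetric Gaussian jitter of SD ``noise_sd``,
    unit diagonal, clipped to [-1, 1].
    """
    from .models import LayeredModelRSMs

    schedule.validate()
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    n = stimulus_set.n_stimuli
    same = stimulus_set.category_of[:, None] == stimulus_set.category_of[None, :]
    rsms: list[list[np.ndarray]] = []
    for layer, n_tp in enumerate(schedule.timepoints()):
        w = schedule.within_by_layer[layer]
        b = schedule.between_by_layer[layer]
        layer_rsms = []
        for _ in range(n_tp):
            m = np.where(same, w, b).astype(float)
            if schedule.noise_sd > 0:
                noise = rng.standard_normal((n, n)) * schedule.noise_sd
                noise = (noise + noise.T) / np.sqrt(2.0)
                m = m + noise
            np.fill_diagonal(m, 1.0)
            layer_rsms.append(np.clip(m, -1.0, 1.0))
        rsms.append(layer_rsms)
    return LayeredModelRSMs(
        rsms=rsms,
        layers=[f"layer{i + 1}" for i in range(schedule.n_layers)],
        source="simulated",
        categories=stimulus_set.category_of.copy(),
    )
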