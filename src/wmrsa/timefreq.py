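"""Spectral decomposition and normalization for epoched intracranial recordings.

The canonical feature space for all similarity analyses in this package is
oscillatory power on a 52-frequency grid spanning 3-150 Hz: 1-Hz spacing from
3 to 29 Hz (27 frequencies, wavelet cycles increasing linearly from 3 to 6)
and 5-Hz spacing from 30 to 150 Hz (25 frequencies, cycles from 6 to 12).
Power is estimated with complex Morlet wavelets and z-scored across trials
within each recording session so that only stimulus-related structure
survives into the representational analyses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "FrequencyGrid",
    "BandPartition",
    "EpochedRecording",
    "TFPower",
    "build_frequency_grid",
    "bipolar_rereference",
    "morlet_power",
    "zscore_by_session",
    "assign_bands",
    "BAND_BOUNDS",
]

#: Band bounds in Hz. Low gamma is the half-open interval [30, 75) so that
#: 75 Hz itself belongs to high gamma, giving 9 low-gamma and 16 high-gamma
#: frequencies on the canonical grid (with 6 theta, 4 alpha, 17 beta).
BAND_BOUNDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 29.0),
    "low_gamma": (30.0, 75.0),
    "high_gamma": (75.0, 150.0),
}


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered wavelet frequencies (Hz) and per-frequency cycle counts."""

    frequencies: np.ndarray
    cycles: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        c = np.asarray(self.cycles, dtype=float)
        if f.shape != c.shape:
            raise ValueError("frequencies and cycles must have the same length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "cycles", c)

    @property
    def n_frequencies(self) -> int:
        return self.frequencies.size

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies.tolist(),
            "cycles": self.cycles.tolist(),
        }


@dataclass(frozen=True)
class BandPartition:
    """Disjoint assignment of grid frequencies to canonical bands."""

    bounds: dict[str, tuple[float, float]]
    members: dict[str, np.ndarray]  # band -> indices into the grid

    def counts(self) -> dict[str, int]:
        return {b: int(v.size) for b, v in self.members.items()}

    def to_dict(self) -> dict:
        return {
            "bounds": {b: list(v) for b, v in self.bounds.items()},
            "members": {b: v.tolist() for b, v in self.members.items()},
        }


@dataclass
class EpochedRecording:
    """Trials x channels x samples voltage epochs at a fixed sampling rate.

    Channel labels follow the depth-electrode convention ``<electrode><contact>``
    (e.g. ``A1 ... A8``); contacts are numbered from deep to superficial.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    sfreq: float
    times: np.ndarray  # (n_samples,), seconds relative to event onset
    channels: list[str]
    sessions: np.ndarray | None = None  # (n_trials,) session labels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match the sample axis")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels must match the channel axis")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")


@dataclass
class TFPower:
    """Trials x channels x frequencies x time oscillatory power.

    ``valid`` flags (frequency, time) cells with full wavelet support; edge
    samples within half a wavelet of the epoch boundary are marked invalid
    rather than zero-padded, so they can never contribute spurious
    low-frequency similarity.
    """

    data: np.ndarray  # (n_trials, n_channels, n_freqs, n_times)
    times: np.ndarray
    frequencies: np.ndarray
    channels: list[str]
    sessions: np.ndarray | None = None
    zscored: bool = False
    valid: np.ndarray | None = None  # (n_freqs, n_times) bool
    zero_variance_cells: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be trials x channels x freqs x times")
        if self.data.shape[3] != np.asarray(self.times).size:
            raise ValueError("times length must match the time axis")
        if self.data.shape[2] != np.asarray(self.frequencies).size:
            raise ValueError("frequencies length must match the frequency axis")
        if self.valid is None:
            self.valid = np.ones((self.data.shape[2], self.data.shape[3]), bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def build_frequency_grid(
    low: tuple[float, float, float] = (3.0, 29.0, 1.0),
    high: tuple[float, float, float] = (30.0, 150.0, 5.0),
    low_cycles: tuple[float, float] = (3.0, 6.0),
    high_cycles: tuple[float, float] = (6.0, 12.0),
) -> FrequencyGrid:
    """Build the canonical 52-frequency wavelet grid.

    The defaults give 27 frequencies at 1-Hz spacing (3..29 Hz, cycles
    rising linearly 3 to 6) and 25 at 5-Hz spacing (30..150 Hz, cycles 6 to
    12).
    """
    lo = np.arange(low[0], low[1] + 0.5 * low[2], low[2])
    hi = np.arange(high[0], high[1] + 0.5 * high[2], high[2])
    cyc = np.concatenate(
        [
            np.linspace(low_cycles[0], low_cycles[1], lo.size),
            np.linspace(high_cycles[0], high_cycles[1], hi.size),
        ]
    )
    return FrequencyGrid(np.concatenate([lo, hi]), cyc)


_LABEL_RE = re.compile(r"^(?P<electrode>.*?)(?P<contact>\d+)$")


def bipolar_rereference(recording: EpochedRecording) -> EpochedRecording:
    """Re-reference depth-electrode contacts to adjacent-contact differences.

    An electrode with N contacts yields N-1 virtual channels. The sign
    convention is deeper minus shallower: virtual channel ``A1-A2`` carries
    ``A1 - A2``. Single-contact electrodes contribute no virtual channels and
    raise a warning.
    """
    groups: dict[str, list[tuple[int, int]]] = {}
    for idx, label in enumerate(recording.channels):
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"channel label {label!r} lacks a contact number")
        groups.setdefault(m["electrode"], []).append((int(m["contact"]), idx))

    out_idx_a: list[int] = []
    out_idx_b: list[int] = []
    out_labels: list[str] = []
    for electrode, contacts in groups.items():
        contacts = sorted(contacts)
        if len(contacts) < 2:
            warnings.warn(
                f"electrode {electrode!r} has a single contact; no virtual "
                "channel produced",
                stacklevel=2,
            )
            continue
        for (_, ia), (_, ib) in zip(contacts[:-1], contacts[1:]):
            out_idx_a.append(ia)
            out_idx_b.append(ib)
            out_labels.append(
                f"{recording.channels[ia]}-{recording.channels[ib]}"
            )
    if not out_labels:
        raise ValueError("no electrode with at least 2 contacts")
    data = recording.data[:, out_idx_a, :] - recording.data[:, out_idx_b, :]
    return EpochedRecording(
        data=data,
        sfreq=recording.sfreq,
        times=recording.times,
        channels=out_labels,
        sessions=recording.sessions,
    )


def _morlet(freq: float, n_cycles: float, sfreq: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at ±3.5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    w -= w.mean()  # zero-mean correction, negligible beyond ~3 cycles
    return w / np.linalg.norm(w)


def morlet_power(
    recording: EpochedRecording,
    grid: FrequencyGrid | None = None,
    out_step: float = 0.01,
) -> TFPower:
    """Morlet-wavelet power of every epoch on the frequency grid.

    Power is the squared magnitude of the complex wavelet transform,
    resampled on a regular ``out_step`` grid (default 10 ms). Samples whose
    wavelet support exceeds the epoch are flagged invalid per frequency.
    """
    if grid is None:
        grid = build_frequency_grid()
    fmax = grid.frequencies.max()
    if recording.sfreq < 2 * fmax:
        raise ValueError(
            f"sampling rate {recording.sfreq} Hz cannot resolve {fmax} Hz"
        )
    n_trials, n_ch, n_samp = recording.data.shape
    dec = max(1, int(round(out_step * recording.sfreq)))
    out_idx = np.arange(0, n_samp, dec)
    out_times = recording.times[out_idx]

    power = np.empty(
        (n_trials, n_ch, grid.n_frequencies, out_idx.size), dtype=float
    )
    valid = np.ones((grid.n_frequencies, out_idx.size), dtype=bool)
    flat = recording.data.reshape(n_trials * n_ch, n_samp)
    for fi, (f, nc) in enumerate(zip(grid.frequencies, grid.cycles)):
        w = _morlet(f, nc, recording.sfreq)
        half = (w.size - 1) // 2
        if w.size > n_samp:
            raise ValueError(
                f"epoch too short for a {nc:g}-cycle wavelet at {f:g} Hz"
            )
        conv = fftconvolve(flat, w[None, :], mode="same", axes=1)
        p = np.abs(conv) ** 2
        power[:, :, fi, :] = p[:, out_idx].reshape(n_trials, n_ch, -1)
        valid[fi] = (out_idx >= half) & (out_idx < n_samp - half)
    return TFPower(
        data=power,
        times=out_times,
        frequencies=grid.frequencies,
        channels=list(recording.channels),
        sessions=recording.sessions,
        valid=valid,
    )


def downsample_power(power: TFPower, out_step: float = 0.1) -> TFPower:
    """Subsample an existing power array to a coarser time step."""
    dt = float(np.median(np.diff(power.times)))
    dec = max(1, int(round(out_step / dt)))
    return replace(
        power,
        data=power.data[..., ::dec],
        times=power.times[::dec],
        valid=power.valid[:, ::dec],
    )


def zscore_by_session(power: TFPower) -> TFPower:
    """Z-score power across trials within each session, pointwise.

    For every (channel, frequency, time sample), the mean and SD across all
    trials of a session are removed, so session-wide features of the signal
    unrelated to the specific stimulus cancel out. Cells with zero variance
    are set to 0 and counted in ``zero_variance_cells``.
    """
    sessions = power.sessions
    if sessions is None:
        sessions = np.zeros(power.n_trials, dtype=int)
    out = np.empty_like(power.data)
    n_zero = 0
    for s in np.unique(sessions):
        sel = sessions == s
        if sel.sum() < 2:
            raise ValueError(f"session {s!r} has fewer than 2 trials")
        block = power.data[sel]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        zero = sd == 0
        n_zero += int(zero.sum())
        sd = np.where(zero, 1.0, sd)
        z = (block - mu) / sd
        z[:, zero] = 0.0
        out[sel] = z
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance cells set to 0 during z-scoring",
            stacklevel=2,
        )
    return replace(power, data=out, zscored=True, zero_variance_cells=n_zero)


def assign_bands(
    grid: FrequencyGrid, bounds: dict[str, tuple[float, float]] | None = None
) -> BandPartition:
    """Partition the grid frequencies into the five canonical bands."""
    if bounds is None:
        bounds = BAND_BOUNDS
    members: dict[str, np.ndarray] = {}
    assigned = np.zeros(grid.n_frequencies, dtype=bool)
    names = list(bounds)
    for i, band in enumerate(names):
        lo, hi = bounds[band]
        if i + 1 < len(names) and bounds[names[i + 1]][0] == hi:
            sel = (grid.frequencies >= lo) & (grid.frequencies < hi)
        else:
            sel = (grid.frequencies >= lo) & (grid.frequencies <= hi)
        members[band] = np.flatnonzero(sel & ~assigned)
        assigned |= sel
    if not assigned.all():
        bad = grid.frequencies[~assigned]
        raise ValueError(f"grid frequencies outside all bands: {bad}")
    return BandPartition(bounds=dict(bounds), members=members)
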