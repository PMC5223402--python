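"""Mu-band spectral estimation and ERD/ERS arithmetic.

Per 500-ms tick the engine estimates mu-rhythm (7.5-14.5 Hz) power at the
four sensorimotor sensors with a bare rectangular-window periodogram: a
500-point FFT at 1000 Hz gives 2-Hz bins, and the in-band bin centers are
8, 10, 12 and 14 Hz.  Event-related desynchronization / synchronization is
expressed as the log2 ratio of tick power to a fixed baseline power taken
from the 15-s rest block recorded before the first feedback block; negative
values are ERD (power decrease), positive values ERS.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .recording import (
    EEG_CHANNELS,
    EMG_CHANNELS,
    SFREQ,
    TICK_SAMPLES,
    Recording,
    validate_segment,
)

ERD_LOG2_FLOOR = -20.0
"""log2-ratio returned for a zero-power tick instead of -inf."""


@dataclass(frozen=True)
class MuBand:
    """Closed frequency interval defining the mu rhythm, in Hz."""

    lower: float = 7.5
    upper: float = 14.5

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper < SFREQ / 2:
            raise ValueError(f"invalid band [{self.lower}, {self.upper}] Hz")

    def bin_indices(self, n_samples: int = TICK_SAMPLES) -> np.ndarray:
        """Periodogram bin indices whose center frequency falls in the band."""
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / SFREQ)
        return np.nonzero((freqs >= self.lower) & (freqs <= self.upper))[0]


@dataclass(frozen=True)
class ChannelPowerSet:
    """Mu-band power (µV²) of one tick at the four EEG sensors."""

    c3: float
    cp3: float
    c4: float
    cp4: float

    def __post_init__(self) -> None:
        if min(self.c3, self.cp3, self.c4, self.cp4) < 0:
            raise ValueError("band powers must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.c3, self.cp3, self.c4, self.cp4])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ChannelPowerSet":
        return cls(*(float(v) for v in values))


@dataclass(frozen=True)
class BaselineProfile:
    """Per-channel baseline statistics from the 15-s rest block.

    ``mu_power`` holds the mean mu-band tick power per EEG channel (µV²,
    the denominators of the feedback score); ``emg_mean``/``emg_sd`` hold
    mean and sample SD of the per-tick rectified EMG means (µV), used by
    the 2-SD movement gate.
    """

    mu_power: ChannelPowerSet
    emg_mean: dict[str, float] = field(default_factory=dict)
    emg_sd: dict[str, float] = field(default_factory=dict)
    duration: float = 15.0

    def __post_init__(self) -> None:
        if min(self.mu_power.as_array()) <= 0:
            raise ValueError("baseline mu powers must be strictly positive")
        if any(sd < 0 for sd in self.emg_sd.values()):
            raise ValueError("EMG SDs must be non-negative")


def periodogram_power(trace: np.ndarray) -> np.ndarray:
    """Rectangular-window periodogram of one or more 500-sample traces.

    Returns per-bin power such that the bins of a pure sinusoid with an
    integer number of cycles sum to A²/2, and the total over all bins
    equals the time-domain mean square (Parseval).
    """
    x = np.atleast_2d(np.asarray(trace, dtype=np.float64))
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    power = np.abs(spec) ** 2 / n**2
    # one-sided correction: interior bins carry the conjugate half too
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    return power if trace.ndim > 1 else power[0]


def band_power(trace: np.ndarray, band: MuBand) -> np.ndarray:
    """Mu-band power (µV²) of 500-sample trace(s): sum of in-band bins."""
    x = np.asarray(trace, dtype=np.float64)
    if x.shape[-1] != TICK_SAMPLES:
        raise ValueError(f"expected {TICK_SAMPLES}-sample ticks, got {x.shape[-1]}")
    power = periodogram_power(x)
    return power[..., band.bin_indices()].sum(axis=-1)


def segment_band_power(segment: np.ndarray, band: MuBand = MuBand()) -> ChannelPowerSet:
    """Mu-band power of one tick at C3, CP3, C4, CP4.

    ``segment`` is either a full 10-channel tick (channel order as in
    :data:`~iinfb.recording.ALL_CHANNELS`) or a 4-row array already
    restricted to the EEG sensors.
    """
    seg = validate_segment(segment)
    if seg.shape[0] not in (4, 10):
        raise ValueError("segment must carry 4 EEG or all 10 channels")
    eeg = seg[: len(EEG_CHANNELS)]
    return ChannelPowerSet.from_array(band_power(eeg, band))


def log2_power_ratio(
    power: float, baseline_power: float, floor: float = ERD_LOG2_FLOOR
) -> float:
    """log2(power / baseline): negative for ERD, positive for ERS.

    A zero-power tick returns ``floor`` rather than -inf; a non-positive
    baseline is a contract violation.
    """
    if baseline_power <= 0:
        raise ValueError("baseline power must be strictly positive")
    if power < 0:
        raise ValueError("power must be non-negative")
    if power == 0:
        return floor
    return float(np.log2(power / baseline_power))


def smoothed_metric(history, window: int = 6) -> float:
    """Running mean of the most recent ``window`` ticks (3 s at 500 ms).

    At stream start, fewer than ``window`` values are averaged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = list(history)
    if not values:
        raise ValueError("empty history")
    tail = values[-window:]
    return float(np.mean(tail, axis=0)) if np.ndim(tail[0]) == 0 else np.mean(
        tail, axis=0
    )


class RunningMean:
    """Streaming form of :func:`smoothed_metric` for scalars or vectors."""

    def __init__(self, window: int = 6):
        if window < 1:
            raise ValueError("window must be >= 1")
        self._buf: deque = deque(maxlen=window)

    def push(self, value):
        self._buf.append(np.asarray(value, dtype=np.float64))
        return self.value

    @property
    def value(self):
        if not self._buf:
            raise ValueError("no values pushed yet")
        out = np.mean(np.stack(list(self._buf)), axis=0)
        return float(out) if out.ndim == 0 else out

    def reset(self) -> None:
        self._buf.clear()


def rectified_emg_means(segment: np.ndarray, recording_channels=None) -> dict[str, float]:
    """Mean full-wave-rectified amplitude (µV) of each EMG channel of a tick."""
    seg = validate_segment(segment)
    if recording_channels is None:
        if seg.shape[0] == 10:
            idx = {"EMG_flex": 8, "EMG_ext": 9}
        elif seg.shape[0] == 2:
            idx = {"EMG_flex": 0, "EMG_ext": 1}
        else:
            raise ValueError("cannot locate EMG channels in segment")
    else:
        idx = {c: list(recording_channels).index(c) for c in EMG_CHANNELS}
    return {c: float(np.mean(np.abs(seg[i]))) for c, i in idx.items()}


def compute_baseline_profile(
    recording: Recording, band: MuBand = MuBand()
) -> BaselineProfile:
    """Baseline statistics from the rest block preceding the first NFB block.

    Mu baseline per channel is the mean over the block's 500-ms tick powers;
    EMG statistics are mean and sample SD (ddof=1) over per-tick rectified
    means.  Requires at least one full tick and the full channel montage.
    """
    for ch in EEG_CHANNELS + EMG_CHANNELS:
        if ch not in recording.channels:
            raise KeyError(f"baseline recording missing channel {ch!r}")
    if recording.n_ticks < 1:
        raise ValueError("baseline recording shorter than one 500-ms tick")
    ticks = recording.ticks()  # (n_ticks, n_ch, 500)
    eeg_idx = [recording.index(c) for c in EEG_CHANNELS]
    powers = band_power(ticks[:, eeg_idx, :], band)  # (n_ticks, 4)
    mu = ChannelPowerSet.from_array(powers.mean(axis=0))
    emg_mean, emg_sd = {}, {}
    for ch in EMG_CHANNELS:
        per_tick = np.mean(np.abs(ticks[:, recording.index(ch), :]), axis=-1)
        emg_mean[ch] = float(per_tick.mean())
        emg_sd[ch] = float(per_tick.std(ddof=1)) if len(per_tick) > 1 else 0.0
    return BaselineProfile(
        mu_power=mu,
        emg_mean=emg_mean,
        emg_sd=emg_sd,
        duration=recording.n_ticks * 0.5,
    )
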