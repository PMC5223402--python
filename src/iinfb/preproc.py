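"""Online (streaming) and offline preprocessing of continuous data.

The online path mirrors a real-time acquisition chain: mastoid
re-referencing, a causal 1-100 Hz band-pass with a 60-Hz notch whose IIR
state is carried across 500-ms chunk boundaries (so streamed output equals
filtering the concatenated signal), DC baseline correction from the first
3 s, and PCA-based ocular-artifact attenuation triggered by a ±360 µV EOG
threshold.  The offline path uses a 0.5-Hz zero-phase high-pass, the same
notch, and a more sensitive ±200 µV EOG threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    SFREQ,
    Recording,
)

NOTCH_FREQ = 60.0
NOTCH_Q = 30.0
BANDPASS_ORDER = 4


@dataclass(frozen=True)
class PreprocConfig:
    """Mode-dependent preprocessing parameters.

    ``online`` and ``offline`` defaults differ exactly in the high-pass
    cutoff (1.0 vs 0.5 Hz), the EOG artifact threshold (360 vs 200 µV) and
    phase behavior (causal streaming vs zero-phase).
    """

    mode: str
    hp_cutoff: float
    lp_cutoff: float | None
    notch: float = NOTCH_FREQ
    eog_threshold: float = 360.0
    artifact_window: tuple[float, float] = (-200.0, 500.0)  # ms around peak
    dc_window: float = 3.0  # s

    def __post_init__(self) -> None:
        if self.mode not in ("online", "offline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.hp_cutoff <= 0 or (self.lp_cutoff is not None and self.lp_cutoff <= 0):
            raise ValueError("cutoffs must be positive")
        if self.eog_threshold <= 0:
            raise ValueError("EOG threshold must be positive")
        lo, hi = self.artifact_window
        if not lo <= 0 <= hi:
            raise ValueError("artifact window must span the peak")

    @classmethod
    def online(cls) -> "PreprocConfig":
        return cls(mode="online", hp_cutoff=1.0, lp_cutoff=100.0, eog_threshold=360.0)

    @classmethod
    def offline(cls) -> "PreprocConfig":
        return cls(mode="offline", hp_cutoff=0.5, lp_cutoff=None, eog_threshold=200.0)


# ---------------------------------------------------------------------------
# re-referencing and DC correction
# ---------------------------------------------------------------------------

def rereference_to_mastoids(
    recording: Recording, left_ref: np.ndarray, right_ref: np.ndarray
) -> Recording:
    """Subtract the mastoid average (L+R)/2 from every EEG channel.

    EOG and EMG channels are left untouched (bipolar derivations do not
    share the EEG reference).
    """
    left = np.asarray(left_ref, dtype=np.float64)
    right = np.asarray(right_ref, dtype=np.float64)
    if left.shape != (recording.n_samples,) or right.shape != (recording.n_samples,):
        raise ValueError("reference traces must match the recording length")
    out = recording.copy()
    ref = (left + right) / 2.0
    for ch in EEG_CHANNELS:
        out.data[out.index(ch)] -= ref
    return out


def baseline_correct_dc(recording: Recording, dc_window: float = 3.0) -> Recording:
    """Subtract each channel's mean over the first ``dc_window`` seconds."""
    n = int(round(dc_window * recording.sfreq))
    if recording.n_samples < n:
        raise ValueError("recording shorter than the DC window")
    out = recording.copy()
    out.data -= out.data[:, :n].mean(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_filters(config: PreprocConfig, sfreq: int = SFREQ):
    """Second-order sections for the band-pass/high-pass and the notch."""
    if config.lp_cutoff is not None:
        sos_band = signal.butter(
            BANDPASS_ORDER,
            [config.hp_cutoff, config.lp_cutoff],
            btype="bandpass",
            fs=sfreq,
            output="sos",
        )
    else:
        sos_band = signal.butter(
            BANDPASS_ORDER, config.hp_cutoff, btype="highpass", fs=sfreq, output="sos"
        )
    b_notch, a_notch = signal.iirnotch(config.notch, NOTCH_Q, fs=sfreq)
    sos_notch = signal.tf2sos(b_notch, a_notch)
    return np.vstack([sos_band, sos_notch])


@dataclass
class FilterState:
    """Carries IIR state across streamed chunks, one state set per channel."""

    sos: np.ndarray
    zi: np.ndarray  # (n_sections, n_channels, 2)

    @classmethod
    def initial(cls, config: PreprocConfig, n_channels: int) -> "FilterState":
        """Zero initial conditions: the filter is strictly linear."""
        sos = design_filters(config)
        zi = np.zeros((sos.shape[0], n_channels, 2))
        return cls(sos=sos, zi=zi)

    def prime(self, first_samples: np.ndarray) -> None:
        """Set the state to the steady-state step response scaled by each
        channel's first sample, softening the start-up transient."""
        zi0 = signal.sosfilt_zi(self.sos)  # (n_sections, 2)
        self.zi = (
            zi0[:, np.newaxis, :]
            * np.asarray(first_samples)[np.newaxis, :, np.newaxis]
        )


def filter_stream(
    config: PreprocConfig, segment: np.ndarray, state: FilterState
) -> tuple[np.ndarray, FilterState]:
    """Causal filtering of one chunk, continuous across chunk boundaries.

    ``segment`` is ``(n_channels, n_samples)``; ``state`` must have been
    created by :meth:`FilterState.initial` for the same channel count.
    Returns the filtered chunk and the updated state.
    """
    if state is None or not isinstance(state, FilterState):
        raise ValueError("filter state not initialized")
    seg = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    if seg.shape[0] != state.zi.shape[1]:
        raise ValueError(
            f"state initialized for {state.zi.shape[1]} channels, got {seg.shape[0]}"
        )
    out, zi = signal.sosfilt(state.sos, seg, axis=-1, zi=state.zi)
    state.zi = zi
    return out, state


def filter_offline(config: PreprocConfig, recording: Recording) -> Recording:
    """Zero-phase (forward-backward) filtering of a whole recording."""
    sos = design_filters(config)
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


# ---------------------------------------------------------------------------
# ocular artifacts
# ---------------------------------------------------------------------------

MIN_EVENT_SEPARATION_S = 0.5


def detect_eog_events(
    eog_traces: np.ndarray, threshold: float, sfreq: int = SFREQ
) -> list[int]:
    """Find blink/eye-movement peaks on the EOG montage.

    Any sample where the largest absolute EOG amplitude crosses
    ``threshold`` µV starts (or extends) an excursion; excursions closer
    than 500 ms are merged into one event whose index is the absolute
    maximum (earliest sample on ties).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    traces = np.atleast_2d(np.asarray(eog_traces, dtype=np.float64))
    if traces.size == 0:
        return []
    envelope = np.max(np.abs(traces), axis=0)
    above = np.nonzero(envelope > threshold)[0]
    if above.size == 0:
        return []
    gap = int(MIN_EVENT_SEPARATION_S * sfreq)
    events: list[int] = []
    run_start = above[0]
    prev = above[0]
    for idx in above[1:]:
        if idx - prev >= gap:
            seg = envelope[run_start : prev + 1]
            events.append(run_start + int(np.argmax(seg)))
            run_start = idx
        prev = idx
    seg = envelope[run_start : prev + 1]
    events.append(run_start + int(np.argmax(seg)))
    return events


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, stop in sorted(windows):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def attenuate_artifact_pca(
    recording: Recording,
    events: list[int],
    window: tuple[float, float] = (-200.0, 500.0),
) -> Recording:
    """Project out the first principal component around each artifact peak.

    Within each (merged) window of ``window`` ms relative to the event
    peak, the dominant spatial component across the EEG+EOG channels --
    the first left singular vector of the windowed data, computed from the
    window alone (local covariance, no mean removal) -- is removed.
    Samples outside every window are untouched.
    """
    if not events:
        return recording.copy()
    lo_ms, hi_ms = window
    n = recording.n_samples
    for ev in events:
        if not 0 <= ev < n:
            raise ValueError(f"event index {ev} outside recording")
    windows = [
        (max(0, ev + int(lo_ms * recording.sfreq / 1000)),
         min(n, ev + int(hi_ms * recording.sfreq / 1000) + 1))
        for ev in events
    ]
    out = recording.copy()
    rows = [out.index(c) for c in EEG_CHANNELS + EOG_CHANNELS]
    for start, stop in _merge_windows(windows):
        block = out.data[np.ix_(rows, range(start, stop))]
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        if s[0] == 0:
            continue
        pattern = u[:, :1]  # dominant spatial pattern in this window
        out.data[np.ix_(rows, range(start, stop))] = block - pattern @ (
            pattern.T @ block
        )
    return out


def preprocess_offline(recording: Recording, config: PreprocConfig | None = None) -> Recording:
    """Full offline chain: zero-phase filter, DC correction, EOG PCA."""
    cfg = config or PreprocConfig.offline()
    out = filter_offline(cfg, recording)
    out = baseline_correct_dc(out, cfg.dc_window)
    eog = out.pick(EOG_CHANNELS)
    events = detect_eog_events(eog, cfg.eog_threshold, out.sfreq)
    return attenuate_artifact_pca(out, events, cfg.artifact_window)
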