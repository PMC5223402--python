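"""Multichannel recording container for the closed-loop engine.

A :class:`Recording` holds the ten-channel montage used throughout the
package -- four sensorimotor EEG sensors (C3, CP3, C4, CP4), four EOG
sensors and two bipolar forearm EMG channels -- sampled at 1000 Hz in
microvolts, plus a sorted list of ``(label, sample_index)`` event markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SFREQ = 1000
"""Sampling rate in Hz. The whole pipeline assumes this value."""

TICK_S = 0.5
TICK_SAMPLES = int(TICK_S * SFREQ)  # 500 samples per processing quantum

EEG_CHANNELS = ("C3", "CP3", "C4", "CP4")
EOG_CHANNELS = ("EOG_up", "EOG_down", "EOG_left", "EOG_right")
EMG_CHANNELS = ("EMG_flex", "EMG_ext")
ALL_CHANNELS = EEG_CHANNELS + EOG_CHANNELS + EMG_CHANNELS

LEFT_HEMI = ("C3", "CP3")   # contralateral to the imagined right hand
RIGHT_HEMI = ("C4", "CP4")  # ipsilateral

MARKER_LABELS = frozenset(
    {
        "baseline_start",
        "trial_start",
        "trial_end",
        "rest_start",
        "block_start",
        "block_end",
        "mi_start",
        "mi_end",
    }
)


@dataclass
class Recording:
    """Continuous multichannel time series in µV with event markers.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in µV.
    channels
        Channel labels, one per row of ``data``.
    markers
        ``(label, sample_index)`` pairs, strictly sorted by sample index.
        Labels must come from :data:`MARKER_LABELS`.
    sfreq
        Sampling rate in Hz (always 1000 in this system).
    """

    data: np.ndarray
    channels: tuple[str, ...] = ALL_CHANNELS
    markers: list[tuple[str, int]] = field(default_factory=list)
    sfreq: int = SFREQ

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows for {len(self.channels)} channel labels"
            )
        self.validate_markers()

    def validate_markers(self) -> None:
        last = -1
        for label, idx in self.markers:
            if label not in MARKER_LABELS:
                raise ValueError(f"unknown marker label {label!r}")
            if not 0 <= idx < max(self.n_samples, 1):
                raise ValueError(f"marker {label!r} at {idx} outside recording")
            if idx < last:
                raise ValueError("markers must be sorted by sample index")
            last = idx

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def n_ticks(self) -> int:
        """Number of complete 500-ms ticks."""
        return self.n_samples // TICK_SAMPLES

    # -- access ---------------------------------------------------------
    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in recording") from None

    def get(self, channel: str) -> np.ndarray:
        """Return one channel's trace (a view, in µV)."""
        return self.data[self.index(channel)]

    def pick(self, channels: tuple[str, ...]) -> np.ndarray:
        """Stack the requested channels into an ``(n, n_samples)`` array."""
        return self.data[[self.index(c) for c in channels]]

    def slice(self, start: int, stop: int) -> "Recording":
        """Sub-recording on ``[start, stop)`` samples; markers re-based."""
        markers = [
            (lbl, idx - start) for lbl, idx in self.markers if start <= idx < stop
        ]
        return Recording(self.data[:, start:stop].copy(), self.channels, markers)

    def ticks(self) -> np.ndarray:
        """Reshape into complete ticks: ``(n_ticks, n_channels, 500)``."""
        n = self.n_ticks * TICK_SAMPLES
        return (
            self.data[:, :n]
            .reshape(len(self.channels), self.n_ticks, TICK_SAMPLES)
            .transpose(1, 0, 2)
        )

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.channels, list(self.markers))

    def marker_samples(self, label: str) -> list[int]:
        return [idx for lbl, idx in self.markers if lbl == label]


Segment = np.ndarray
"""One 500-ms chunk: array of shape ``(n_channels, 500)`` in µV."""


def validate_segment(segment: np.ndarray, n_channels: int | None = None) -> np.ndarray:
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim == 1:
        seg = seg[np.newaxis, :]
    if seg.shape[-1] != TICK_SAMPLES:
        raise ValueError(
            f"segment must have exactly {TICK_SAMPLES} samples, got {seg.shape[-1]}"
        )
    if n_channels is not None and seg.shape[0] != n_channels:
        raise ValueError(f"expected {n_channels} channels, got {seg.shape[0]}")
    return seg
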