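"""Virtual-subject EEG/EOG/EMG generator.

Emulates the signals the closed-loop engine was built for, with exactly
controllable effect sizes: a sinusoidal mu rhythm (default 10 Hz) whose
amplitude is multiplied by sqrt(ratio) during task states so band power
scales by the ratio, 1/f background noise, stereotyped blinks on the
vertical EOG with partial bleed into the EEG sensors, and band-limited
EMG bursts at five times the baseline EMG RMS.  A
:class:`VirtualSubject` also closes the loop: trials whose mean video
score exceeds 4 multiplicatively deepen the contralateral ERD
(``responsiveness``), emulating learning.

Everything is driven by a single seed; identical seeds give bit-identical
recordings and session logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .controller import EngineConfig, SessionLog, run_session
from .recording import (
    ALL_CHANNELS,
    EEG_CHANNELS,
    LEFT_HEMI,
    SFREQ,
    TICK_SAMPLES,
    Recording,
)

TASK_STATES = ("rest", "ii", "mi")

BLINK_AMPLITUDE_UV = 300.0
BLINK_DURATION_S = 0.4
BLINK_EEG_BLEED = 0.2
EMG_BURST_RMS_FACTOR = 5.0
EMG_BURST_BAND_HZ = (30.0, 300.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one virtual participant.

    ``contra_ratio_task`` / ``ipsi_ratio_task`` are the target task/baseline
    mu-power ratios at the left (contralateral) and right (ipsilateral)
    sensors during imagined imitation or motor imagery; 1 means no
    modulation, 0.5 means 50% ERD.  ``responsiveness`` is the per-trial
    multiplicative drift of the contralateral ratio toward a floor of 0.05
    after successful trials (mean video score > 4).
    """

    contra_ratio_task: float = 0.5
    ipsi_ratio_task: float = 1.0
    responsiveness: float = 0.05
    mu_freq: float = 10.0
    mu_amp: float = 10.0      # µV, baseline mu amplitude
    noise_amp: float = 5.0    # µV RMS, 1/f background
    blink_rate: float = 12.0  # per minute
    emg_burst_rate: float = 2.0  # per minute
    emg_amp: float = 2.0      # µV RMS, resting EMG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contra_ratio_task <= 0 or self.ipsi_ratio_task <= 0:
            raise ValueError("task power ratios must be > 0")
        for name in ("responsiveness", "blink_rate", "emg_burst_rate",
                     "mu_amp", "noise_amp", "emg_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.mu_freq < SFREQ / 2:
            raise ValueError("mu frequency outside (0, Nyquist)")


def pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f-power background noise, normalized to the requested RMS."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SFREQ)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rms: float, band: tuple[float, float]
) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SFREQ)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _blink_waveform(n: int) -> np.ndarray:
    """Raised-cosine deflection of unit peak amplitude, ``n`` samples."""
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


class VirtualSubject:
    """Streaming signal source for :func:`~iinfb.controller.run_session`.

    Tracks mu phase and a global sample counter so consecutive chunks are
    continuous, logs every blink peak and EMG-burst tick it emits (in
    absolute samples / tick indices), and adapts its contralateral ERD
    depth when notified of successful trials.
    """

    def __init__(self, profile: SubjectProfile):
        self.profile = profile
        self.rng = np.random.default_rng(profile.seed)
        self.contra_ratio = profile.contra_ratio_task
        self.ipsi_ratio = profile.ipsi_ratio_task
        self._phases = self.rng.uniform(0, 2 * np.pi, size=len(EEG_CHANNELS))
        # resting EMG is a frozen tick-periodic noise template: every tick's
        # rectified mean is bit-identical, so the 2-SD gate has exact
        # specificity and only scheduled bursts can trip it
        self._emg_template = np.stack(
            [
                _bandlimited_noise(
                    self.rng, TICK_SAMPLES, profile.emg_amp, EMG_BURST_BAND_HZ
                )
                for _ in range(2)
            ]
        )
        self._n = 0  # global sample counter
        self.blink_samples: list[int] = []
        self.burst_ticks: list[int] = []

    # -- generation ------------------------------------------------------
    def chunk(
        self, state: str, n_ticks: int, burst_ticks: list[int] | None = None
    ) -> np.ndarray:
        """Raw 10-channel data for ``n_ticks`` consecutive ticks.

        ``burst_ticks`` optionally forces EMG bursts at the given
        chunk-relative tick indices instead of the Poisson schedule.
        """
        if state not in TASK_STATES:
            raise ValueError(f"unknown task state {state!r}")
        if n_ticks < 1:
            raise ValueError("n_ticks must be >= 1")
        p = self.profile
        n = n_ticks * TICK_SAMPLES
        t = (self._n + np.arange(n)) / SFREQ
        data = np.zeros((len(ALL_CHANNELS), n))

        # mu rhythm: amplitude sqrt(ratio) so band power scales by ratio
        for i, ch in enumerate(EEG_CHANNELS):
            amp = p.mu_amp
            if state in ("ii", "mi"):
                ratio = self.contra_ratio if ch in LEFT_HEMI else self.ipsi_ratio
                amp = amp * np.sqrt(ratio)
            data[i] = amp * np.sin(2 * np.pi * p.mu_freq * t + self._phases[i])
            data[i] += pink_noise(self.rng, n, p.noise_amp)

        # EOG background
        for ch in ("EOG_up", "EOG_down", "EOG_left", "EOG_right"):
            data[ALL_CHANNELS.index(ch)] = pink_noise(self.rng, n, p.noise_amp)

        self._add_blinks(data, n)
        self._add_emg(data, n_ticks, burst_ticks)
        self._n += n
        return data

    def tick(self, state: str) -> np.ndarray:
        """One 500-ms segment (shape ``(10, 500)``)."""
        return self.chunk(state, 1)

    def _add_blinks(self, data: np.ndarray, n: int) -> None:
        p = self.profile
        if p.blink_rate == 0:
            return
        blink_len = int(BLINK_DURATION_S * SFREQ)
        expected = p.blink_rate / 60.0 * n / SFREQ
        count = self.rng.poisson(expected)
        wave = BLINK_AMPLITUDE_UV * _blink_waveform(blink_len)
        up = ALL_CHANNELS.index("EOG_up")
        down = ALL_CHANNELS.index("EOG_down")
        eeg_rows = [ALL_CHANNELS.index(c) for c in EEG_CHANNELS]
        for _ in range(count):
            start = int(self.rng.integers(0, max(1, n - blink_len)))
            sl = slice(start, start + blink_len)
            data[up, sl] += wave
            data[down, sl] -= wave
            for r in eeg_rows:
                data[r, sl] += BLINK_EEG_BLEED * wave
            self.blink_samples.append(self._n + start + blink_len // 2)

    def _add_emg(
        self, data: np.ndarray, n_ticks: int, burst_ticks: list[int] | None
    ) -> None:
        p = self.profile
        emg_rows = [ALL_CHANNELS.index(c) for c in ("EMG_flex", "EMG_ext")]
        for j, r in enumerate(emg_rows):
            data[r] = np.tile(self._emg_template[j], n_ticks)
        if burst_ticks is None:
            if p.emg_burst_rate == 0:
                return
            prob = p.emg_burst_rate / 60.0 * (TICK_SAMPLES / SFREQ)
            burst_ticks = list(np.nonzero(self.rng.random(n_ticks) < prob)[0])
        # burst RMS target: 5x resting RMS for the whole tick
        extra = p.emg_amp * np.sqrt(EMG_BURST_RMS_FACTOR**2 - 1.0)
        for bt in burst_ticks:
            if not 0 <= bt < n_ticks:
                raise ValueError(f"burst tick {bt} outside chunk")
            sl = slice(bt * TICK_SAMPLES, (bt + 1) * TICK_SAMPLES)
            for r in emg_rows:
                data[r, sl] += _bandlimited_noise(
                    self.rng, TICK_SAMPLES, extra, EMG_BURST_BAND_HZ
                )
            self.burst_ticks.append(self._n // TICK_SAMPLES + int(bt))

    # -- closed loop -----------------------------------------------------
    def notify_trial(self, mean_video_score: float) -> None:
        """Adapt to feedback: successful trials deepen contralateral ERD."""
        if mean_video_score > 4 and self.profile.responsiveness > 0:
            self.contra_ratio = max(
                0.05, self.contra_ratio * (1.0 - self.profile.responsiveness)
            )


def generate_baseline_recording(
    profile: SubjectProfile, duration: float = 15.0
) -> Recording:
    """Rest-state recording of ``duration`` seconds (no task modulation)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_samples = int(round(duration * SFREQ))
    n_ticks = -(-n_samples // TICK_SAMPLES)  # ceil
    subject = VirtualSubject(profile)
    data = subject.chunk("rest", n_ticks)[:, :n_samples]
    return Recording(data, ALL_CHANNELS, markers=[("baseline_start", 0)])


def generate_tick(
    subject: VirtualSubject | SubjectProfile, state: str
) -> np.ndarray:
    """One 500-ms segment from a subject (profiles are wrapped on the fly)."""
    if isinstance(subject, SubjectProfile):
        subject = VirtualSubject(subject)
    return subject.tick(state)


def simulate_closed_loop_session(
    profile: SubjectProfile, config: EngineConfig = EngineConfig()
) -> tuple[Recording, SessionLog]:
    """Run a full session of a virtual subject through the real controller.

    Returns the raw marker-annotated recording and the tick-level session
    log.  Reproducible: the subject stream and the MI rest-jitter schedule
    are both derived from ``profile.seed``.
    """
    subject = VirtualSubject(profile)
    schedule_rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 1]))
    recording, log, _baseline = run_session(
        subject, config, mode="real", schedule_rng=schedule_rng
    )
    return recording, log
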