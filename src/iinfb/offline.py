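"""Post-hoc ERD/S analysis of recorded sessions.

Marker-based epoching, EMG-based segment rejection (same 2-SD gate as the
online engine), per-tick log2 ERD/S against task-specific 4-s baselines
-- the final 4 s of the pre-session baseline block for the feedback task,
the final 4 s of the first rest period of the motor-imagery block for the
MI task -- and tidy long-format export with descriptive group x session
summaries.  Inferential modeling is deliberately left to external tools;
the exported table carries the group and session variables needed for it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controller import EngineConfig, emg_gate_from_means
from .mu import BaselineProfile, MuBand, band_power, compute_baseline_profile
from .preproc import PreprocConfig, preprocess_offline
from .recording import (
    EEG_CHANNELS,
    EMG_CHANNELS,
    LEFT_HEMI,
    RIGHT_HEMI,
    TICK_SAMPLES,
    Recording,
)

ERDS_COLUMNS = ["group", "session", "task", "hemisphere", "tick", "log2_erds"]
BASELINE_WINDOW_S = 4.0


@dataclass(frozen=True)
class Epoch:
    """A contiguous marker-delimited span of one task context."""

    task: str   # "nfb" or "mi"
    kind: str   # "task" or "rest"
    start: int  # sample index, inclusive
    stop: int   # sample index, exclusive

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def n_ticks(self) -> int:
        return self.n_samples // TICK_SAMPLES


def epoch_by_markers(recording: Recording) -> list[Epoch]:
    """Cut task and rest epochs out of the marker stream.

    ``trial_start``/``trial_end`` pairs become feedback-task epochs,
    ``mi_start``/``mi_end`` pairs become MI epochs, and each
    ``rest_start`` runs to the next marker.  Rests are attributed to the
    MI task when they immediately precede an ``mi_start``.  A recording
    without markers yields no epochs (with a warning); unmatched
    start/end pairs raise.
    """
    markers = recording.markers
    if not markers:
        warnings.warn("recording has no markers; no epochs produced")
        return []
    epochs: list[Epoch] = []
    open_trial: int | None = None
    open_mi: int | None = None
    for i, (label, idx) in enumerate(markers):
        if label == "trial_start":
            if open_trial is not None:
                raise ValueError("nested trial_start markers")
            open_trial = idx
        elif label == "trial_end":
            if open_trial is None:
                raise ValueError("trial_end without trial_start")
            epochs.append(Epoch("nfb", "task", open_trial, idx + 1))
            open_trial = None
        elif label == "mi_start":
            if open_mi is not None:
                raise ValueError("nested mi_start markers")
            open_mi = idx
        elif label == "mi_end":
            if open_mi is None:
                raise ValueError("mi_end without mi_start")
            epochs.append(Epoch("mi", "task", open_mi, idx + 1))
            open_mi = None
        elif label == "rest_start":
            nxt_label, nxt_idx = next(
                ((l, j) for l, j in markers[i + 1:]), (None, recording.n_samples)
            )
            stop = nxt_idx + 1 if nxt_label == "block_end" else nxt_idx
            task = "mi" if nxt_label == "mi_start" else "nfb"
            epochs.append(Epoch(task, "rest", idx, stop))
    if open_trial is not None or open_mi is not None:
        raise ValueError("unmatched epoch start marker at end of recording")
    return sorted(epochs, key=lambda e: e.start)


def validate_schedule(
    epochs: list[Epoch],
    config: EngineConfig,
    sfreq: float = 1000.0,
) -> list[str]:
    """Compare epoch counts and durations with the configured schedule.

    Epochs are cut marker-to-marker, so their length follows whatever
    schedule produced the recording; any mismatch with ``config`` (e.g.
    conventions that expect a different MI epoch length) is surfaced as a
    warning rather than silently resolved.  Returns the warning messages.
    """
    msgs: list[str] = []
    nfb = [e for e in epochs if e.task == "nfb" and e.kind == "task"]
    mi = [e for e in epochs if e.task == "mi" and e.kind == "task"]
    if len(nfb) != config.nfb_trial_count:
        msgs.append(
            f"{len(nfb)} feedback epochs, schedule expects {config.nfb_trial_count}"
        )
    if len(mi) != config.mi_trials:
        msgs.append(f"{len(mi)} MI epochs, schedule expects {config.mi_trials}")
    for e in mi:
        if abs(e.n_samples / sfreq - config.mi_duration_s) > config.tick_s:
            msgs.append(
                f"MI epoch of {e.n_samples / sfreq:.1f} s differs from configured "
                f"{config.mi_duration_s:.1f} s"
            )
            break
    for m in msgs:
        warnings.warn(m)
    return msgs


def epoch_tick_table(epochs: list[Epoch], kind: str = "task") -> pd.DataFrame:
    """Enumerate complete 500-ms ticks of the selected epochs."""
    rows = []
    tick_counter: dict[str, int] = {}
    for ei, e in enumerate(epochs):
        if e.kind != kind:
            continue
        for t in range(e.n_ticks):
            k = tick_counter.get(e.task, 0)
            rows.append(
                (e.task, ei, k, e.start + t * TICK_SAMPLES)
            )
            tick_counter[e.task] = k + 1
    return pd.DataFrame(rows, columns=["task", "epoch", "tick", "start"])


def reject_emg_segments(
    recording: Recording,
    ticks: pd.DataFrame,
    baseline: BaselineProfile,
    multiplier: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Drop ticks whose rectified EMG mean exceeds baseline + 2 SD.

    Uses the same gate as the online engine, tick-for-tick.  Returns the
    kept rows and the rejected fraction.
    """
    for ch in EMG_CHANNELS:
        if ch not in recording.channels:
            raise KeyError(f"recording lacks EMG channel {ch!r}")
        if ch not in baseline.emg_mean:
            raise KeyError("baseline lacks EMG statistics")
    if ticks.empty:
        return ticks.copy(), 0.0
    emg = recording.pick(EMG_CHANNELS)
    flags = np.zeros(len(ticks), dtype=bool)
    for i, start in enumerate(ticks["start"].to_numpy()):
        seg = emg[:, start : start + TICK_SAMPLES]
        means = {
            ch: float(np.mean(np.abs(seg[j]))) for j, ch in enumerate(EMG_CHANNELS)
        }
        flags[i] = emg_gate_from_means(means, baseline, multiplier)
    kept = ticks.loc[~flags].reset_index(drop=True)
    return kept, float(flags.mean())


def baseline_band_powers(
    recording: Recording,
    window: tuple[int, int],
    band: MuBand = MuBand(),
) -> np.ndarray:
    """Mean per-tick mu power of the EEG sensors over a sample window."""
    start, stop = window
    if stop - start < TICK_SAMPLES:
        raise ValueError("baseline window shorter than one tick")
    n_ticks = (stop - start) // TICK_SAMPLES
    eeg = recording.pick(EEG_CHANNELS)[:, start : start + n_ticks * TICK_SAMPLES]
    ticks = eeg.reshape(len(EEG_CHANNELS), n_ticks, TICK_SAMPLES).transpose(1, 0, 2)
    return band_power(ticks, band).mean(axis=0)


def compute_erds_table(
    recording: Recording,
    kept_ticks: pd.DataFrame,
    baseline_powers: np.ndarray,
    band: MuBand = MuBand(),
    group: str = "nfb",
    session: int = 1,
) -> pd.DataFrame:
    """Per-tick log2 ERD/S, hemisphere-averaged, in tidy long format.

    The left-hemisphere value of a tick is the mean of the C3 and CP3
    log2 ratios to ``baseline_powers`` (order C3, CP3, C4, CP4); the
    right-hemisphere value uses C4 and CP4.
    """
    if np.any(np.asarray(baseline_powers) <= 0):
        raise ValueError("baseline powers must be strictly positive")
    rows = []
    eeg = recording.pick(EEG_CHANNELS)
    left_idx = [EEG_CHANNELS.index(c) for c in LEFT_HEMI]
    right_idx = [EEG_CHANNELS.index(c) for c in RIGHT_HEMI]
    for task, tick, start in kept_ticks[["task", "tick", "start"]].itertuples(
        index=False
    ):
        seg = eeg[:, start : start + TICK_SAMPLES]
        power = band_power(seg, band)
        with np.errstate(divide="ignore"):
            log2r = np.log2(power / np.asarray(baseline_powers))
        log2r = np.where(np.isfinite(log2r), log2r, -20.0)
        rows.append((group, session, task, "left", tick, float(log2r[left_idx].mean())))
        rows.append(
            (group, session, task, "right", tick, float(log2r[right_idx].mean()))
        )
    return pd.DataFrame(rows, columns=ERDS_COLUMNS)


def summarize_group_session(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of log2 ERD/S per group x session x task x hemisphere.

    Empty input raises; cells absent from the table are simply omitted
    (with a warning naming the populated cells).
    """
    if table.empty:
        raise ValueError("empty ERD/S table")
    grouped = (
        table.groupby(["group", "session", "task", "hemisphere"], sort=True)[
            "log2_erds"
        ]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)
    full = (
        table["group"].nunique()
        * table["session"].nunique()
        * table["task"].nunique()
        * table["hemisphere"].nunique()
    )
    if len(grouped) < full:
        warnings.warn("some group/session/task/hemisphere cells are empty")
    return grouped


# ---------------------------------------------------------------------------
# whole-session convenience pipeline
# ---------------------------------------------------------------------------

def analyze_session(
    recording: Recording,
    config: EngineConfig = EngineConfig(),
    group: str = "nfb",
    session: int = 1,
    preproc_config: PreprocConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Offline chain on one raw session recording.

    Preprocesses (zero-phase 0.5-Hz high-pass, notch, DC correction,
    ocular PCA), epochs by markers, rejects feedback-task ticks with
    excessive EMG, and computes the tidy ERD/S table using the
    task-specific 4-s baselines.  Returns the table and the rejected
    fraction of feedback ticks.
    """
    clean = preprocess_offline(recording, preproc_config)
    epochs = epoch_by_markers(clean)
    base_stop = _baseline_stop(clean)
    baseline = compute_baseline_profile(clean.slice(0, base_stop), config.band)

    ticks = epoch_tick_table(epochs, kind="task")
    nfb_ticks = ticks[ticks["task"] == "nfb"].reset_index(drop=True)
    mi_ticks = ticks[ticks["task"] == "mi"].reset_index(drop=True)
    kept_nfb, rejected = reject_emg_segments(
        clean, nfb_ticks, baseline, config.emg_sd_multiplier
    )

    nbase = int(BASELINE_WINDOW_S * clean.sfreq)
    nfb_base = baseline_band_powers(clean, (base_stop - nbase, base_stop), config.band)
    frames = [
        compute_erds_table(clean, kept_nfb, nfb_base, config.band, group, session)
    ]
    mi_rests = [e for e in epochs if e.task == "mi" and e.kind == "rest"]
    if not mi_ticks.empty:
        if not mi_rests:
            raise ValueError("MI epochs present but no MI rest baseline window")
        first_rest = mi_rests[0]
        mi_base = baseline_band_powers(
            clean, (first_rest.stop - nbase, first_rest.stop), config.band
        )
        frames.append(
            compute_erds_table(clean, mi_ticks, mi_base, config.band, group, session)
        )
    table = pd.concat(frames, ignore_index=True)
    return table, rejected


def _baseline_stop(recording: Recording) -> int:
    """End of the pre-session baseline block (first block_start marker)."""
    starts = recording.marker_samples("baseline_start")
    if not starts:
        raise ValueError("recording lacks a baseline_start marker")
    blocks = recording.marker_samples("block_start")
    if not blocks:
        raise ValueError("recording lacks block_start markers")
    return blocks[0]
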