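"""Closed-loop neurofeedback controller.

Implements the feedback score

    score = rw * log2(C4/C4b + CP4/CP4b) - lw * log2(C3/C3b + CP3/CP3b)

on 6-tick-smoothed mu-band channel powers, the 17-row difficulty table
(levels -1..15) that sets the hemisphere weights (lw, rw) and the score
thresholds, the 1-6 video-score state machine with its 2-s lockout and EMG
reset, end-of-trial difficulty titration over the final 20 s, full-session
orchestration (15-s baseline, 3 blocks of 10 x 50-s trials with 10-s
rests, then 10 x 20-s motor-imagery trials with randomized 8-12-s rests),
and verbatim sham replay from a yoked session log.

Note the score's rest-state offset: with all four power ratios at 1 each
hemisphere term is log2(1+1) = 1, so the expected rest score is rw - lw,
i.e. -1 whenever the ipsilateral weight is zero (levels <= 4).  The
printed sum-of-ratios form is kept as-is; ``normalize=True`` divides each
sum by two to remove the offset but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mu import (
    BaselineProfile,
    ChannelPowerSet,
    ERD_LOG2_FLOOR,
    MuBand,
    RunningMean,
    band_power,
    rectified_emg_means,
)
from .preproc import (
    FilterState,
    PreprocConfig,
    attenuate_artifact_pca,
    detect_eog_events,
    filter_stream,
)
from .recording import (
    ALL_CHANNELS,
    EEG_CHANNELS,
    EMG_CHANNELS,
    EOG_CHANNELS,
    TICK_SAMPLES,
    Recording,
)

VIDEO_MIN = 1
VIDEO_MAX = 6
LEVEL_MIN = -1
LEVEL_MAX = 15


@dataclass(frozen=True)
class DifficultyRow:
    """One row of the difficulty table: weights and score thresholds."""

    level: int
    lw: float
    rw: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.level <= LEVEL_MAX:
            raise ValueError(f"level {self.level} outside [-1, 15]")
        if self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper threshold")


def _build_table() -> dict[int, DifficultyRow]:
    # (level, lw, rw, lower, upper) exactly as printed
    rows = [
        (-1, 1, 0.0, -8, -4),
        (0, 1, 0.0, -6, -2),
        (1, 1, 0.0, -4, 0),
        (2, 1, 0.0, -2, 2),
        (3, 1, 0.0, 0, 4),
        (4, 1, 0.0, 2, 6),
        (5, 1, 0.1, 2, 6),
        (6, 1, 0.2, 2, 6),
        (7, 1, 0.3, 2, 6),
        (8, 1, 0.4, 2, 6),
        (9, 1, 0.5, 2, 6),
        (10, 1, 0.6, 2, 6),
        (11, 1, 0.7, 2, 6),
        (12, 1, 0.8, 2, 6),
        (13, 1, 0.9, 2, 6),
        (14, 1, 1.0, 2, 6),
        (15, 1, 1.0, 2, 2),
    ]
    return {
        lvl: DifficultyRow(lvl, float(lw), float(rw), float(lo), float(hi))
        for lvl, lw, rw, lo, hi in rows
    }


DIFFICULTY_TABLE: dict[int, DifficultyRow] = _build_table()


def difficulty_params(level: int) -> DifficultyRow:
    """Difficulty-table row for ``level`` (-1..15)."""
    try:
        return DIFFICULTY_TABLE[int(level)]
    except KeyError:
        raise ValueError(f"difficulty level {level} outside [-1, 15]") from None


@dataclass(frozen=True)
class FeedbackState:
    """Mutable controller state (video score, lockout, difficulty level)."""

    video_score: int = VIDEO_MIN
    lockout_remaining: int = 0
    level: int = 1
    level1_streak: int = 0
    tick_index: int = 0

    def __post_init__(self) -> None:
        if not VIDEO_MIN <= self.video_score <= VIDEO_MAX:
            raise ValueError("video score outside [1, 6]")
        if self.lockout_remaining < 0:
            raise ValueError("negative lockout")


@dataclass(frozen=True)
class EngineConfig:
    """Session schedule and controller constants (all printed defaults)."""

    tick_s: float = 0.5
    trial_s: float = 50.0
    rest_s: float = 10.0
    trials_per_block: int = 10
    blocks: int = 3
    titration_window_s: float = 20.0
    lockout_s: float = 2.0
    baseline_s: float = 15.0
    mi_trials: int = 10
    mi_duration_s: float = 20.0
    mi_rest_range: tuple[float, float] = (8.0, 12.0)
    emg_sd_multiplier: float = 2.0
    band: MuBand = MuBand()
    start_level: int = 1
    normalize_score: bool = False
    smoothing_ticks: int = 6

    def __post_init__(self) -> None:
        for name in (
            "tick_s", "trial_s", "rest_s", "titration_window_s",
            "lockout_s", "baseline_s", "mi_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.titration_window_s > self.trial_s:
            raise ValueError("titration window longer than the trial")
        if self.mi_rest_range[0] > self.mi_rest_range[1]:
            raise ValueError("invalid MI rest range")

    def _ticks(self, seconds: float) -> int:
        n = seconds / self.tick_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{seconds} s is not a whole number of ticks")
        return int(round(n))

    @property
    def trial_ticks(self) -> int:
        return self._ticks(self.trial_s)

    @property
    def rest_ticks(self) -> int:
        return self._ticks(self.rest_s)

    @property
    def baseline_ticks(self) -> int:
        return self._ticks(self.baseline_s)

    @property
    def titration_ticks(self) -> int:
        return self._ticks(self.titration_window_s)

    @property
    def lockout_ticks(self) -> int:
        return self._ticks(self.lockout_s)

    @property
    def mi_ticks(self) -> int:
        return self._ticks(self.mi_duration_s)

    @property
    def nfb_trial_count(self) -> int:
        return self.blocks * self.trials_per_block

    @property
    def nfb_tick_count(self) -> int:
        """Feedback ticks in a session (trial ticks only)."""
        return self.nfb_trial_count * self.trial_ticks


# ---------------------------------------------------------------------------
# score, gate, state machine
# ---------------------------------------------------------------------------

def compute_nfb_score(
    powers: ChannelPowerSet,
    baseline: BaselineProfile,
    row: DifficultyRow,
    normalize: bool = False,
    floor: float = ERD_LOG2_FLOOR,
) -> float:
    """Hemisphere-weighted feedback score from (smoothed) channel powers.

    The inner term per hemisphere is the log2 of the *sum* of the two
    channel power ratios, exactly as printed; ``normalize`` divides the
    sum by 2 so that a rest-state input scores 0 at any weights.
    """
    b = baseline.mu_power
    left = powers.c3 / b.c3 + powers.cp3 / b.cp3
    right = powers.c4 / b.c4 + powers.cp4 / b.cp4
    if normalize:
        left, right = left / 2.0, right / 2.0
    left_term = math.log2(left) if left > 0 else floor
    right_term = math.log2(right) if right > 0 else floor
    return row.rw * right_term - row.lw * left_term


def emg_gate(
    segment: np.ndarray,
    baseline: BaselineProfile,
    multiplier: float = 2.0,
    channels=None,
) -> bool:
    """True iff either EMG channel's rectified 500-ms mean exceeds its
    baseline mean by strictly more than ``multiplier`` baseline SDs."""
    means = rectified_emg_means(segment, channels)
    return emg_gate_from_means(means, baseline, multiplier)


def emg_gate_from_means(
    means: dict[str, float], baseline: BaselineProfile, multiplier: float = 2.0
) -> bool:
    for ch in EMG_CHANNELS:
        if ch not in baseline.emg_mean:
            raise KeyError(f"baseline lacks EMG statistics for {ch!r}")
        if means[ch] > baseline.emg_mean[ch] + multiplier * baseline.emg_sd[ch]:
            return True
    return False


def step_video_score(
    state: FeedbackState,
    score: float,
    row: DifficultyRow,
    emg_flag: bool,
    lockout_ticks: int = 4,
) -> FeedbackState:
    """Advance the video-score state machine by one tick.

    Excessive EMG resets the score to 1 and restarts the lockout (the
    safety gate dominates).  Otherwise, during lockout the score is
    frozen; out of lockout, a score above the upper threshold raises the
    video score by one (capped at 6) and one below the lower threshold
    lowers it by one (floored at 1), and any actual change starts a new
    lockout of ``lockout_ticks`` ticks.
    """
    tick = state.tick_index + 1
    if emg_flag:
        return replace(
            state, video_score=VIDEO_MIN, lockout_remaining=lockout_ticks,
            tick_index=tick,
        )
    if state.lockout_remaining > 0:
        return replace(
            state, lockout_remaining=state.lockout_remaining - 1, tick_index=tick
        )
    vs = state.video_score
    if score > row.upper and vs < VIDEO_MAX:
        return replace(
            state, video_score=vs + 1, lockout_remaining=lockout_ticks,
            tick_index=tick,
        )
    if score < row.lower and vs > VIDEO_MIN:
        return replace(
            state, video_score=vs - 1, lockout_remaining=lockout_ticks,
            tick_index=tick,
        )
    return replace(state, tick_index=tick)


def end_of_trial_update(
    trial_video_scores,
    state: FeedbackState,
    config: EngineConfig = EngineConfig(),
) -> int:
    """Difficulty titration from the trial's final 20 s of video scores.

    Mean video score > 4 promotes one level (cap 15); < 2 demotes one
    level, except that dropping below level 1 requires three completed
    trials in a row at level 1 (``state.level1_streak >= 3``); the floor
    is level -1.  ``state.level1_streak`` counts the current trial.
    """
    scores = list(trial_video_scores)
    if len(scores) < config.titration_ticks:
        raise ValueError(
            f"trial has {len(scores)} ticks, titration needs {config.titration_ticks}"
        )
    mean_vs = float(np.mean(scores[-config.titration_ticks:]))
    level = state.level
    if mean_vs > 4:
        return min(level + 1, LEVEL_MAX)
    if mean_vs < 2:
        if level > 1:
            return level - 1
        if level == 1:
            return 0 if state.level1_streak >= 3 else 1
        return max(level - 1, LEVEL_MIN)
    return level


# ---------------------------------------------------------------------------
# session logs
# ---------------------------------------------------------------------------

TICK_COLUMNS = [
    "tick", "time_s", "block", "trial", "nfb_score",
    "video_score", "level", "emg_flag",
]
TRIAL_COLUMNS = [
    "block", "trial", "level_before", "level_after", "mean_video_score",
]


@dataclass
class SessionLog:
    """Per-tick and per-trial records of one session.

    The per-tick table doubles as the yoke file for sham feedback: the
    ``video_score`` and ``level`` columns are the presented stimulus
    stream, replayed verbatim for a yoked sham subject.
    """

    ticks: pd.DataFrame
    trials: pd.DataFrame
    mode: str = "real"
    mi_rest_ticks: list[int] = field(default_factory=list)

    @property
    def final_level(self) -> int:
        return int(self.trials["level_after"].iloc[-1])

    @property
    def n_ticks(self) -> int:
        return len(self.ticks)

    def presented(self) -> pd.DataFrame:
        """The audiovisual stimulus stream (what the subject saw)."""
        return self.ticks[["video_score", "level"]].reset_index(drop=True)

    def equals_presented(self, other: "SessionLog") -> bool:
        return self.presented().equals(other.presented())


# ---------------------------------------------------------------------------
# session orchestration
# ---------------------------------------------------------------------------

class ScheduleMismatchError(ValueError):
    """Yoke log inconsistent with the configured schedule."""


def _chunk_tick_powers(chunk: np.ndarray, band: MuBand) -> np.ndarray:
    """Per-tick EEG band powers of a (10, n_ticks*500) chunk -> (n_ticks, 4)."""
    n_ticks = chunk.shape[1] // TICK_SAMPLES
    eeg = chunk[: len(EEG_CHANNELS), : n_ticks * TICK_SAMPLES]
    ticks = eeg.reshape(len(EEG_CHANNELS), n_ticks, TICK_SAMPLES).transpose(1, 0, 2)
    return band_power(ticks, band)


def _chunk_emg_means(chunk: np.ndarray) -> list[dict[str, float]]:
    n_ticks = chunk.shape[1] // TICK_SAMPLES
    rows = [ALL_CHANNELS.index(ch) for ch in EMG_CHANNELS]
    emg = chunk[rows, : n_ticks * TICK_SAMPLES]
    means = np.abs(emg).reshape(len(rows), n_ticks, TICK_SAMPLES).mean(axis=-1)
    return [
        {ch: float(means[j, t]) for j, ch in enumerate(EMG_CHANNELS)}
        for t in range(n_ticks)
    ]


class _OnlineChain:
    """Streaming preprocessing: continuous causal filter + chunk-local
    EOG-triggered PCA attenuation."""

    def __init__(self, config: PreprocConfig | None = None):
        self.config = config or PreprocConfig.online()
        self.state: FilterState | None = None

    def process(self, chunk: np.ndarray) -> np.ndarray:
        if self.state is None:
            self.state = FilterState.initial(self.config, chunk.shape[0])
            self.state.prime(chunk[:, 0])
        filtered, self.state = filter_stream(self.config, chunk, self.state)
        eog_rows = [ALL_CHANNELS.index(c) for c in EOG_CHANNELS]
        events = detect_eog_events(filtered[eog_rows], self.config.eog_threshold)
        if events:
            rec = Recording(filtered, ALL_CHANNELS)
            filtered = attenuate_artifact_pca(
                rec, events, self.config.artifact_window
            ).data
        return filtered


def run_session(
    source,
    config: EngineConfig = EngineConfig(),
    mode: str = "real",
    yoke: SessionLog | None = None,
    schedule_rng: np.random.Generator | None = None,
    preproc_config: PreprocConfig | None = None,
) -> tuple[Recording, SessionLog, BaselineProfile]:
    """Run one full session through the streaming pipeline.

    ``source`` supplies raw 10-channel data: ``source.chunk(state, n_ticks)``
    with state in {"rest", "ii", "mi"}; if it defines
    ``notify_trial(mean_video_score)`` it is told each trial's outcome
    (closing the loop for adaptive virtual subjects).

    Real mode runs preprocessing, mu-power estimation and the controller
    per tick; difficulty starts at level 1 and the video score resets to 1
    at every trial start.  Sham mode replays the presented video-score/level
    stream verbatim from ``yoke``; EMG flags are still computed and logged
    but never alter the presented scores.
    """
    if mode not in ("real", "sham"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "sham":
        if yoke is None:
            raise ValueError("sham mode requires a yoke log")
        if len(yoke.ticks) != config.nfb_tick_count:
            raise ScheduleMismatchError(
                f"yoke has {len(yoke.ticks)} ticks, schedule expects "
                f"{config.nfb_tick_count}"
            )
        yoke_vs = yoke.ticks["video_score"].to_numpy()
        yoke_level = yoke.ticks["level"].to_numpy()
    rng = schedule_rng or np.random.default_rng(0)

    chain = _OnlineChain(preproc_config)
    raw_parts: list[np.ndarray] = []
    markers: list[tuple[str, int]] = []
    cursor = 0

    def ingest(state_label: str, n_ticks: int) -> np.ndarray:
        nonlocal cursor
        raw = np.asarray(source.chunk(state_label, n_ticks), dtype=np.float64)
        if raw.shape != (len(ALL_CHANNELS), n_ticks * TICK_SAMPLES):
            raise ValueError(f"source returned chunk of shape {raw.shape}")
        raw_parts.append(raw)
        cursor += raw.shape[1]
        return chain.process(raw)

    # --- baseline block ------------------------------------------------
    markers.append(("baseline_start", 0))
    base_filt = ingest("rest", config.baseline_ticks)
    from .mu import compute_baseline_profile  # local import avoids cycle

    baseline = compute_baseline_profile(
        Recording(base_filt, ALL_CHANNELS), config.band
    )

    # --- NFB blocks -----------------------------------------------------
    tick_rows: list[tuple] = []
    trial_rows: list[tuple] = []
    level = config.start_level
    level1_streak = 0
    global_tick = 0

    for block in range(1, config.blocks + 1):
        markers.append(("block_start", cursor))
        for trial in range(1, config.trials_per_block + 1):
            markers.append(("trial_start", cursor))
            filt = ingest("ii", config.trial_ticks)
            powers = _chunk_tick_powers(filt, config.band)
            emg_means = _chunk_emg_means(filt)
            smoother = RunningMean(config.smoothing_ticks)
            state = FeedbackState(
                video_score=VIDEO_MIN, lockout_remaining=0, level=level,
                level1_streak=level1_streak,
            )
            row = difficulty_params(level)
            presented_scores: list[int] = []
            for t in range(config.trial_ticks):
                smoothed = ChannelPowerSet.from_array(smoother.push(powers[t]))
                score = compute_nfb_score(
                    smoothed, baseline, row, normalize=config.normalize_score
                )
                flag = emg_gate_from_means(
                    emg_means[t], baseline, config.emg_sd_multiplier
                )
                if mode == "real":
                    # the score presented during this tick is the state at
                    # its start; the comparison updates what the next tick
                    # presents (trial tick 0 therefore always shows 1)
                    vs, lvl = state.video_score, level
                    state = step_video_score(
                        state, score, row, flag, config.lockout_ticks
                    )
                else:
                    vs = int(yoke_vs[global_tick])
                    lvl = int(yoke_level[global_tick])
                presented_scores.append(vs)
                tick_rows.append(
                    (global_tick, round(global_tick * config.tick_s, 3),
                     block, trial, score, vs, lvl, flag)
                )
                global_tick += 1
            markers.append(("trial_end", cursor - 1))
            mean_vs = float(np.mean(presented_scores[-config.titration_ticks:]))
            if mode == "real":
                level1_streak = level1_streak + 1 if level == 1 else 0
                state = replace(state, level=level, level1_streak=level1_streak)
                new_level = end_of_trial_update(presented_scores, state, config)
                if new_level != 1:
                    level1_streak = 0
                trial_rows.append((block, trial, level, new_level, mean_vs))
                level = new_level
            else:
                lvl_before = int(yoke_level[global_tick - config.trial_ticks])
                nxt = global_tick
                lvl_after = (
                    int(yoke_level[nxt]) if nxt < len(yoke_level)
                    else int(yoke_level[-1])
                )
                trial_rows.append((block, trial, lvl_before, lvl_after, mean_vs))
            if hasattr(source, "notify_trial"):
                source.notify_trial(mean_vs)
            markers.append(("rest_start", cursor))
            ingest("rest", config.rest_ticks)
        markers.append(("block_end", cursor - 1))

    # --- MI block --------------------------------------------------------
    mi_rest_ticks: list[int] = []
    if config.mi_trials > 0:
        markers.append(("block_start", cursor))
        lo, hi = config.mi_rest_range
        for _ in range(config.mi_trials):
            rest_s = rng.uniform(lo, hi)
            n_rest = max(1, int(round(rest_s / config.tick_s)))
            mi_rest_ticks.append(n_rest)
            markers.append(("rest_start", cursor))
            ingest("rest", n_rest)
            markers.append(("mi_start", cursor))
            ingest("mi", config.mi_ticks)
            markers.append(("mi_end", cursor - 1))
        markers.append(("block_end", cursor - 1))

    data = np.concatenate(raw_parts, axis=1)
    recording = Recording(data, ALL_CHANNELS, markers)
    log = SessionLog(
        ticks=pd.DataFrame(tick_rows, columns=TICK_COLUMNS),
        trials=pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS),
        mode=mode,
        mi_rest_ticks=mi_rest_ticks,
    )
    return recording, log, baseline
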