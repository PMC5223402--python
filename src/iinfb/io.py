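"""File formats, configuration and run manifests.

Recordings round-trip through two formats: a plain CSV dialect (one
column per channel, 17-significant-digit decimals, LF endings, marker
sidecar ``<path>.markers.csv``) that is bit-exact, and EDF+ (16-bit,
physical range fixed at ±3276.7 µV so one digital unit is 0.1 µV, 0.5-s
data records, markers stored as EDF+ annotations).  Session logs are
plain CSV; the per-tick log doubles as the yoke file for sham feedback.
All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import (
    EngineConfig,
    ScheduleMismatchError,
    SessionLog,
    TICK_COLUMNS,
    TRIAL_COLUMNS,
)
from .mu import MuBand
from .recording import ALL_CHANNELS, SFREQ, Recording
from .synth import SubjectProfile

__version__ = "0.1.0"

EDF_PHYS_MAX = 3276.7  # µV; with ±32767 digital units -> 0.1 µV resolution
EDF_DIG_MAX = 32767
EDF_RECORD_S = 0.5


# ---------------------------------------------------------------------------
# atomic write helper
# ---------------------------------------------------------------------------

def _atomic_write(path: Path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name)
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# CSV recordings
# ---------------------------------------------------------------------------

def _marker_sidecar(path: Path) -> Path:
    return Path(str(path) + ".markers.csv")


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    lines = [",".join(recording.channels)]
    cols = recording.data.T
    for row in cols:
        lines.append(",".join(format(v, ".17g") for v in row))
    _atomic_write(path, ("\n".join(lines) + "\n").encode())
    mk = ["label,sample"] + [f"{lbl},{idx}" for lbl, idx in recording.markers]
    _atomic_write(_marker_sidecar(path), ("\n".join(mk) + "\n").encode())


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    channels = tuple(df.columns)
    _validate_channels(channels)
    data = df.to_numpy(dtype=np.float64).T
    markers: list[tuple[str, int]] = []
    sidecar = _marker_sidecar(path)
    if sidecar.exists():
        mk = pd.read_csv(sidecar)
        markers = [(str(l), int(s)) for l, s in zip(mk["label"], mk["sample"])]
    return Recording(data, channels, markers)


def _validate_channels(channels: tuple[str, ...]) -> None:
    missing = [c for c in ALL_CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"recording is missing channels: {missing}")
    unknown = [c for c in channels if c not in ALL_CHANNELS]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")


# ---------------------------------------------------------------------------
# EDF+
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {value!r}")
    return b.ljust(width)


def _annotation_payloads(
    markers: list[tuple[str, int]], n_records: int
) -> list[bytes]:
    """Per-record TAL byte strings (timekeeping TAL + marker annotations)."""
    per_record: list[list[tuple[float, str]]] = [[] for _ in range(n_records)]
    for label, sample in markers:
        onset = sample / SFREQ
        rec = min(int(onset // EDF_RECORD_S), n_records - 1)
        per_record[rec].append((onset, label))
    payloads = []
    for rec in range(n_records):
        t0 = rec * EDF_RECORD_S
        tal = f"+{t0:.1f}\x14\x14\x00".encode("ascii")
        for onset, label in per_record[rec]:
            tal += f"+{onset:.3f}\x14{label}\x14\x00".encode("ascii")
        payloads.append(tal)
    return payloads


def write_recording_edf(recording: Recording, path: str | Path) -> None:
    """Write as EDF+C with a 0.5-s record length and annotation markers.

    Data outside ±3276.7 µV are clipped; recordings that are not a whole
    number of 0.5-s records are zero-padded to the next record boundary
    (with a warning), which a subsequent read will retain.
    """
    path = Path(path)
    n_samples = recording.n_samples
    rec_len = int(EDF_RECORD_S * recording.sfreq)
    n_records = -(-n_samples // rec_len)
    if n_records * rec_len != n_samples:
        warnings.warn("recording zero-padded to a whole number of EDF records")
    n_sig = len(recording.channels)

    payloads = _annotation_payloads(recording.markers, n_records)
    ann_bytes = max(max(len(p) for p in payloads) + 2, 60)
    ann_bytes += ann_bytes % 2  # even byte count -> whole 2-byte samples
    ann_samples = ann_bytes // 2

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (n_sig + 2)), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field(f"{EDF_RECORD_S:g}", 8)
    header += _edf_field(str(n_sig + 1), 4)

    labels = list(recording.channels) + ["EDF Annotations"]
    phys_dim = ["uV"] * n_sig + [""]
    phys_min = [f"{-EDF_PHYS_MAX:g}"] * n_sig + ["-1"]
    phys_max = [f"{EDF_PHYS_MAX:g}"] * n_sig + ["1"]
    dig_min = [str(-EDF_DIG_MAX)] * n_sig + ["-32768"]
    dig_max = [str(EDF_DIG_MAX)] * n_sig + ["32767"]
    n_per_rec = [str(rec_len)] * n_sig + [str(ann_samples)]
    for values, width in (
        (labels, 16), (["" for _ in labels], 80), (phys_dim, 8),
        (phys_min, 8), (phys_max, 8), (dig_min, 8), (dig_max, 8),
        (["" for _ in labels], 80), (n_per_rec, 8), (["" for _ in labels], 32),
    ):
        for v in values:
            header += _edf_field(str(v), width)

    scale = EDF_PHYS_MAX / EDF_DIG_MAX
    clipped = np.clip(recording.data, -EDF_PHYS_MAX, EDF_PHYS_MAX)
    digital = np.round(clipped / scale).astype("<i2")
    padded = np.zeros((n_sig, n_records * rec_len), dtype="<i2")
    padded[:, :n_samples] = digital

    body = bytearray()
    for rec in range(n_records):
        sl = slice(rec * rec_len, (rec + 1) * rec_len)
        for s in range(n_sig):
            body += padded[s, sl].tobytes()
        body += payloads[rec].ljust(ann_bytes, b"\x00")
    _atomic_write(path, bytes(header) + bytes(body))


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file written by :func:`write_recording_edf`."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("not an EDF file (truncated header)")
    n_records = int(raw[236:244].decode().strip())
    record_s = float(raw[244:252].decode().strip())
    n_sig = int(raw[252:256].decode().strip())
    off = 256

    def sig_fields(width: int):
        nonlocal off
        out = [raw[off + i * width : off + (i + 1) * width].decode().strip()
               for i in range(n_sig)]
        off += n_sig * width
        return out

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)   # dimension
    pmin = [float(v) for v in sig_fields(8)]
    pmax = [float(v) for v in sig_fields(8)]
    dmin = [float(v) for v in sig_fields(8)]
    dmax = [float(v) for v in sig_fields(8)]
    sig_fields(80)  # prefiltering
    nper = [int(v) for v in sig_fields(8)]
    sig_fields(32)  # reserved
    if off != 256 * (n_sig + 1):
        raise ValueError("malformed EDF header")

    is_ann = [lbl == "EDF Annotations" for lbl in labels]
    data_cols = [i for i in range(n_sig) if not is_ann[i]]
    channels = tuple(labels[i] for i in data_cols)
    _validate_channels(channels)

    traces: dict[int, list[np.ndarray]] = {i: [] for i in data_cols}
    ann_raw = bytearray()
    pos = off
    for _rec in range(n_records):
        for i in range(n_sig):
            nbytes = nper[i] * 2
            chunk = raw[pos : pos + nbytes]
            if len(chunk) < nbytes:
                raise ValueError("truncated EDF data record")
            pos += nbytes
            if is_ann[i]:
                ann_raw += chunk
            else:
                traces[i].append(np.frombuffer(chunk, dtype="<i2"))
    sfreq = nper[data_cols[0]] / record_s
    if sfreq != SFREQ:
        raise ValueError(f"sample rate {sfreq} Hz, expected {SFREQ}")
    data = np.empty((len(data_cols), n_records * nper[data_cols[0]]))
    for row, i in enumerate(data_cols):
        digital = np.concatenate(traces[i]).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[row] = (digital - dmin[i]) * gain + pmin[i]

    markers: list[tuple[str, int]] = []
    for tal in bytes(ann_raw).split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        if len(parts) < 2:
            continue
        onset = float(parts[0].replace(b"+", b"", 1))
        for text in parts[1:]:
            label = text.decode("ascii", "replace").strip()
            if label:
                markers.append((label, int(round(onset * SFREQ))))
    markers.sort(key=lambda m: m[1])
    return Recording(data, channels, markers)


def write_recording(
    recording: Recording, path: str | Path, format: str | None = None
) -> None:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "csv")
    if fmt == "csv":
        write_recording_csv(recording, path)
    elif fmt == "edf":
        write_recording_edf(recording, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "csv")
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "edf":
        return read_recording_edf(path)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# session logs / yoke files
# ---------------------------------------------------------------------------

def _trials_sidecar(path: Path) -> Path:
    return Path(str(path) + ".trials.csv")


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write the per-tick log (the yoke file) plus a per-trial sidecar."""
    path = Path(path)
    _atomic_write(path, log.ticks.to_csv(index=False, lineterminator="\n").encode())
    _atomic_write(
        _trials_sidecar(path),
        log.trials.to_csv(index=False, lineterminator="\n").encode(),
    )


def read_session_log(path: str | Path) -> SessionLog:
    path = Path(path)
    ticks = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TICK_COLUMNS if c not in ticks.columns]
    if missing:
        raise ValueError(f"session log missing columns: {missing}")
    sidecar = _trials_sidecar(path)
    if sidecar.exists():
        trials = pd.read_csv(sidecar, float_precision="round_trip")
    else:
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
    return SessionLog(ticks=ticks, trials=trials)


def read_yoke(path: str | Path, config: EngineConfig = EngineConfig()) -> SessionLog:
    """Load a yoke file, validating its tick count against the schedule."""
    log = read_session_log(path)
    expected = config.nfb_tick_count
    if len(log.ticks) != expected:
        raise ScheduleMismatchError(
            f"yoke file has {len(log.ticks)} ticks; schedule expects {expected}"
        )
    return log


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def config_to_dict(config: EngineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["band"] = {"lower": config.band.lower, "upper": config.band.upper}
    d["mi_rest_range"] = list(config.mi_rest_range)
    return d


def config_from_dict(d: dict) -> EngineConfig:
    d = dict(d)
    if "band" in d:
        d["band"] = MuBand(**d["band"])
    if "mi_rest_range" in d:
        d["mi_rest_range"] = tuple(d["mi_rest_range"])
    return EngineConfig(**d)


def profile_to_dict(profile: SubjectProfile) -> dict:
    return dataclasses.asdict(profile)


def profile_from_dict(d: dict) -> SubjectProfile:
    return SubjectProfile(**d)


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a plain dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    mode: str
    seed: int
    config: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    yoke_path: str | None = None
    yoke_sha256: str | None = None
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> None:
        _atomic_write(
            Path(path),
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True).encode(),
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
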