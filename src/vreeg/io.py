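"""Recording I/O: EDF+ interchange and a transparent CSV fallback.

EDF (European Data Format) is the study pipeline's native export, so
recordings round-trip through EDF+C files: 14 EEG signals in µV, the
per-channel quality series as auxiliary signals named ``CQ_<label>`` /
``EQ_<label>`` (EDF has no native quality field; this dialect is
documented here), and the four time events as EDF+ annotations
``Event <id>``. Samples are quantized to the 16-bit EDF grid with a
symmetric physical range per signal, so write→read agrees with the
original to within one quantization step.

The CSV fallback stores samples at full ``%.17g`` precision (bit-exact
round trip) as three sibling files: ``<stem>.csv`` (samples),
``<stem>_quality.csv`` (CQ/EQ) and ``<stem>_meta.json`` (rates, labels,
events).

This module implements the EDF codec directly; the independent EDF
reader in MNE is used in the test suite as a cross-check oracle.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .montage import CHANNELS, Montage
from .synth_eeg import EEGRecording

__all__ = ["write_edf", "read_edf", "write_csv", "read_csv", "quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _phys_range(values: np.ndarray) -> float:
    """Symmetric physical bound, rounded up so it prints in <= 8 chars."""
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    return max(math.ceil(peak * 10.0 + 1e-9) / 10.0, 0.1)


def quantization_step(values: np.ndarray) -> float:
    """EDF 16-bit quantization step for a signal's symmetric range."""
    bound = _phys_range(np.asarray(values, dtype=float))
    return 2.0 * bound / (_DIG_MAX - _DIG_MIN)


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ParameterError(f"EDF field {text!r} exceeds {width} bytes")
    return raw.ljust(width)


def _digitize(values: np.ndarray, bound: float) -> np.ndarray:
    scaled = np.rint((values + bound) / (2.0 * bound) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN)
    return np.clip(scaled, _DIG_MIN, _DIG_MAX).astype("<i2")


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as an EDF+C file (see module docstring).

    Requires the recording length and the quality series to tile into
    whole one-second data records; synthetic cohorts satisfy this by
    construction. Use :func:`write_csv` for arbitrary lengths.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples / fs
    if abs(n_records - round(n_records)) > 1e-9:
        raise ParameterError("EDF export requires a whole number of seconds")
    n_records = int(round(n_records))
    q_per_record = recording.quality_rate
    if abs(q_per_record - round(q_per_record)) > 1e-9 or q_per_record < 1:
        raise ParameterError("EDF export requires an integer quality rate >= 1 Hz")
    q_per_record = int(round(q_per_record))
    if recording.cq.shape[1] < n_records * q_per_record:
        raise ParameterError("quality series shorter than the recording")

    labels = list(recording.montage.labels)
    eeg_bounds = [_phys_range(recording.data[i]) for i in range(14)]

    # annotation payload per record: a timestamp TAL plus event TALs
    record_tals: list[bytes] = []
    for rec_i in range(n_records):
        tal = f"+{rec_i}\x14\x14\x00".encode("ascii")
        for event_id in sorted(recording.events):
            onset, length = recording.events[event_id]
            onset_s = onset / fs
            if int(onset_s) == rec_i:
                tal += (
                    f"+{onset_s:g}\x15{length / fs:g}\x14Event {event_id}\x14\x00"
                ).encode("ascii")
        record_tals.append(tal)
    ann_bytes = max(len(t) for t in record_tals)
    ann_samples = (ann_bytes + 1) // 2 + 8  # int16 samples per record, with slack

    signals = []  # (label, phys_dim, bound, samples_per_record, data or None)
    for i, label in enumerate(labels):
        signals.append((label, "uV", eeg_bounds[i], fs, recording.data[i]))
    for prefix, series in (("CQ", recording.cq), ("EQ", recording.eq)):
        for i, label in enumerate(labels):
            signals.append((f"{prefix}_{label}", "%", 100.0, q_per_record, series[i]))
    n_signals = len(signals) + 1  # + annotations

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate 01-JAN-2000 X X X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (n_signals + 1)), 8),
            _fixed("EDF+C", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(n_signals), 4),
        ]
    )

    def column(width: int, values: list) -> bytes:
        return b"".join(_fixed(v, width) for v in values)

    sig_labels = [s[0] for s in signals] + ["EDF Annotations"]
    phys_dims = [s[1] for s in signals] + [""]
    phys_mins = [f"{-s[2]:g}" for s in signals] + ["-1"]
    phys_maxs = [f"{s[2]:g}" for s in signals] + ["1"]
    spr = [s[3] for s in signals] + [ann_samples]
    header += column(16, sig_labels)
    header += column(80, [""] * n_signals)  # transducer
    header += column(8, phys_dims)
    header += column(8, phys_mins)
    header += column(8, phys_maxs)
    header += column(8, [str(_DIG_MIN)] * n_signals)
    header += column(8, [str(_DIG_MAX)] * n_signals)
    header += column(80, [""] * n_signals)  # prefiltering
    header += column(8, [str(s) for s in spr])
    header += column(32, [""] * n_signals)

    with path.open("wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            for label, _dim, bound, per_rec, values in signals:
                chunk = values[rec_i * per_rec : (rec_i + 1) * per_rec]
                fh.write(_digitize(np.asarray(chunk, dtype=float), bound).tobytes())
            tal = record_tals[rec_i].ljust(2 * ann_samples, b"\x00")
            fh.write(tal)
    return path


def _parse_tals(payload: bytes, fs: float) -> dict:
    events = {}
    for match in re.finditer(
        rb"\+(?P<onset>[0-9.]+)\x15(?P<dur>[0-9.]+)\x14Event (?P<id>\d+)\x14", payload
    ):
        onset = float(match.group("onset"))
        duration = float(match.group("dur"))
        events[int(match.group("id"))] = (
            int(round(onset * fs)),
            int(round(duration * fs)),
        )
    return events


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ recording written by :func:`write_edf`.

    The file must contain the 14 montage EEG channels (any order);
    ``CQ_``/``EQ_`` quality signals and ``Event <id>`` annotations are
    reconstructed when present.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ConfigError(f"{path}: not an EDF file (truncated header)")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_duration = float(raw[244:252].decode("ascii").strip())
        n_signals = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise ConfigError(f"{path}: malformed EDF header") from exc

    def fields(offset: int, width: int) -> list:
        base = 256 + offset * n_signals
        return [
            raw[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_signals)
        ]

    # per-signal header arrays are laid out field-by-field
    pos = 0
    labels = fields(pos, 16); pos += 16
    pos += 80  # transducer
    pos += 8  # phys dim
    phys_min = [float(v) for v in fields(pos, 8)]; pos += 8
    phys_max = [float(v) for v in fields(pos, 8)]; pos += 8
    dig_min = [int(v) for v in fields(pos, 8)]; pos += 8
    dig_max = [int(v) for v in fields(pos, 8)]; pos += 8
    pos += 80  # prefiltering
    spr = [int(v) for v in fields(pos, 8)]; pos += 8

    header_bytes = 256 * (n_signals + 1)
    record_len = sum(spr) * 2
    body = raw[header_bytes:]
    if len(body) < n_records * record_len:
        raise ConfigError(f"{path}: EDF body shorter than header promises")

    chunks: dict[str, list] = {label: [] for label in labels}
    ann_payload = b""
    for rec_i in range(n_records):
        offset = rec_i * record_len
        for si, label in enumerate(labels):
            n = spr[si]
            segment = body[offset : offset + 2 * n]
            offset += 2 * n
            if label == "EDF Annotations":
                ann_payload += segment
            else:
                dig = np.frombuffer(segment, dtype="<i2").astype(float)
                phys = (dig - dig_min[si]) * (phys_max[si] - phys_min[si]) / (
                    dig_max[si] - dig_min[si]
                ) + phys_min[si]
                chunks[label].append(phys)

    signal_labels = [lb for lb in labels if lb != "EDF Annotations"]
    eeg_labels = [lb for lb in signal_labels if lb in CHANNELS]
    if len(eeg_labels) != 14:
        raise ConfigError(
            f"{path}: expected the 14 montage channels, found {len(eeg_labels)}"
        )
    montage = Montage(tuple(eeg_labels))
    data = np.vstack([np.concatenate(chunks[lb]) for lb in eeg_labels])
    fs = spr[labels.index(eeg_labels[0])] / record_duration

    n_q = None
    cq_labels = [f"CQ_{lb}" for lb in eeg_labels]
    eq_labels = [f"EQ_{lb}" for lb in eeg_labels]
    if all(lb in chunks and chunks[lb] for lb in cq_labels + eq_labels):
        cq = np.vstack([np.concatenate(chunks[lb]) for lb in cq_labels])
        eq = np.vstack([np.concatenate(chunks[lb]) for lb in eq_labels])
        quality_rate = spr[labels.index(cq_labels[0])] / record_duration
    else:
        cq = np.full((14, 0), np.nan)
        eq = np.full((14, 0), np.nan)
        quality_rate = 1.0

    # quality values may land a hair outside [0, 100] after quantization
    cq = np.clip(cq, 0.0, 100.0)
    eq = np.clip(eq, 0.0, 100.0)

    return EEGRecording(
        data=data,
        sampling_rate=fs,
        montage=montage,
        cq=cq,
        eq=eq,
        events=_parse_tals(ann_payload, fs),
        quality_rate=quality_rate,
        participant=path.stem,
    )


# ---------------------------------------------------------------------------
# CSV fallback (bit-exact)
# ---------------------------------------------------------------------------

def _csv_paths(path: Path) -> tuple:
    stem = path.with_suffix("")
    return path, Path(f"{stem}_quality.csv"), Path(f"{stem}_meta.json")


def write_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as full-precision CSV plus JSON metadata."""
    data_path, quality_path, meta_path = _csv_paths(Path(path))
    labels = list(recording.montage.labels)
    np.savetxt(
        data_path,
        recording.data.T,
        delimiter=",",
        fmt="%.17g",
        header=",".join(labels),
        comments="",
    )
    quality = np.vstack([recording.cq, recording.eq]).T
    np.savetxt(
        quality_path,
        quality,
        delimiter=",",
        fmt="%.17g",
        header=",".join([f"CQ_{lb}" for lb in labels] + [f"EQ_{lb}" for lb in labels]),
        comments="",
    )
    meta = {
        "sampling_rate": recording.sampling_rate,
        "quality_rate": recording.quality_rate,
        "labels": labels,
        "events": {str(k): list(v) for k, v in recording.events.items()},
        "participant": recording.participant,
        "group": recording.group,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return data_path


def read_csv(path: str | Path) -> EEGRecording:
    """Read a CSV recording written by :func:`write_csv` (bit-exact)."""
    data_path, quality_path, meta_path = _csv_paths(Path(path))
    meta = json.loads(meta_path.read_text())
    frame = pd.read_csv(data_path, float_precision="round_trip")
    if list(frame.columns) != meta["labels"]:
        raise ConfigError(f"{data_path}: channel labels disagree with metadata")
    quality = pd.read_csv(quality_path, float_precision="round_trip")
    labels = meta["labels"]
    return EEGRecording(
        data=frame.to_numpy().T,
        sampling_rate=meta["sampling_rate"],
        montage=Montage(tuple(labels)),
        cq=quality[[f"CQ_{lb}" for lb in labels]].to_numpy().T,
        eq=quality[[f"EQ_{lb}" for lb in labels]].to_numpy().T,
        events={int(k): tuple(v) for k, v in meta["events"].items()},
        quality_rate=meta["quality_rate"],
        participant=meta.get("participant", ""),
        group=meta.get("group", ""),
    )
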