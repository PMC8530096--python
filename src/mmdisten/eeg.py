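"""EDF recording I/O, seizure annotations and epoch extraction.

A self-contained reader/writer for plain EDF (European Data Format): the
fixed 256-byte ASCII header, per-signal subheaders, and little-endian 16-bit
data records.  EDF+ embedded annotations, per-signal sampling rates and
montage handling are out of scope — seizure times come from a side-car
annotation table instead (CSV with ``onset_s,offset_s`` columns, or a
best-effort parser for CHB-MIT style summary text).

Epoching slices a recording into fixed-length windows and labels each by the
majority state of its samples: *ictal* inside an annotated seizure,
*preictal* within a configurable horizon before an onset, *interictal*
elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MultichannelSeries
from .signals import STATES

__all__ = [
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_annotations_csv",
    "write_annotations_csv",
    "parse_chbmit_summary",
    "epoch_and_label",
    "epoch_with_intervals",
]


@dataclass(frozen=True)
class EpochSet:
    """Equal-length labelled epochs cut from one recording."""

    epochs: tuple[MultichannelSeries, ...]
    labels: tuple[str, ...]
    epoch_length_s: float
    stride_s: float
    start_times_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.epochs) or len(self.start_times_s) != len(self.epochs):
            raise ValueError("epochs, labels and start_times_s must have equal length")
        if self.epochs:
            c0, n0 = self.epochs[0].n_channels, self.epochs[0].n_samples
            for ep in self.epochs:
                if ep.n_channels != c0 or ep.n_samples != n0:
                    raise ValueError("all epochs must share channel and sample counts")
        for lab in self.labels:
            if lab not in STATES:
                raise ValueError(f"unknown state label {lab!r}")

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(field: str, width: int) -> bytes:
    out = field.encode("ascii", errors="replace")[:width]
    return out + b" " * (width - len(out))


def _fit8(value: float) -> str:
    """Render a float into <= 8 ASCII chars, losslessly re-parseable."""
    for prec in (7, 6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def _physical_bounds(channel: np.ndarray) -> tuple[float, float]:
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        hi = lo + 1.0
    # widen until the 8-char renderings still bracket the data
    span = hi - lo
    lo2, hi2 = lo - 0.001 * span, hi + 0.001 * span
    for _ in range(10):
        plo, phi = float(_fit8(lo2)), float(_fit8(hi2))
        if plo <= lo and phi >= hi and phi > plo:
            return plo, phi
        lo2 -= 0.01 * span
        hi2 += 0.01 * span
    raise ValueError("could not fit physical bounds into EDF header fields")


def write_recording(path: str | Path, series: MultichannelSeries) -> None:
    """Write a multichannel series as a plain EDF file.

    Uses 1-second data records when the sampling rate is a whole number and
    divides the length, otherwise a single record spanning the recording.
    Amplitudes are quantised to 16 bits over each channel's physical range.
    """
    if series.sampling_rate is None:
        raise ValueError("series needs a sampling_rate to be written as EDF")
    fs = series.sampling_rate
    c, N = series.n_channels, series.n_samples
    if float(fs).is_integer() and N % int(fs) == 0 and N // int(fs) >= 1:
        spr, n_records, rec_dur = int(fs), N // int(fs), 1.0
    else:
        spr, n_records, rec_dur = N, 1, N / fs
    names = series.channel_names or tuple(f"CH{i + 1}" for i in range(c))

    bounds = [_physical_bounds(series.values[ch]) for ch in range(c)]
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (c + 1)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii(_fit8(rec_dur), 8),
            _ascii(str(c), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(nm, 16) for nm in names),
            b"".join(_ascii("", 80) for _ in range(c)),
            b"".join(_ascii("uV", 8) for _ in range(c)),
            b"".join(_ascii(_fit8(b[0]), 8) for b in bounds),
            b"".join(_ascii(_fit8(b[1]), 8) for b in bounds),
            b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(c)),
            b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(c)),
            b"".join(_ascii("", 80) for _ in range(c)),
            b"".join(_ascii(str(spr), 8) for _ in range(c)),
            b"".join(_ascii("", 32) for _ in range(c)),
        ]
    )

    digital = np.empty((c, N), dtype="<i2")
    for ch in range(c):
        plo, phi = bounds[ch]
        scale = (_DIG_MAX - _DIG_MIN) / (phi - plo)
        d = np.round((series.values[ch] - plo) * scale) + _DIG_MIN
        digital[ch] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records interleave channels: per record, all samples of ch1, ch2, ...
        blocks = digital.reshape(c, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def _read_fields(buf: bytes, width: int, count: int) -> list[str]:
    return [buf[i * width : (i + 1) * width].decode("ascii").strip() for i in range(count)]


def read_recording(
    path: str | Path, channel_subset: Sequence[str] | None = None
) -> MultichannelSeries:
    """Read a plain EDF file, optionally selecting channels by name.

    All selected channels must share one sampling rate.  Requesting a channel
    that is not in the file raises with the available names listed.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IOError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
        labels = _read_fields(sig[0 : 16 * ns], 16, ns)
        off = 16 * ns + 80 * ns + 8 * ns
        pmin = [float(v) for v in _read_fields(sig[off : off + 8 * ns], 8, ns)]
        off += 8 * ns
        pmax = [float(v) for v in _read_fields(sig[off : off + 8 * ns], 8, ns)]
        off += 8 * ns
        dmin = [int(v) for v in _read_fields(sig[off : off + 8 * ns], 8, ns)]
        off += 8 * ns
        dmax = [int(v) for v in _read_fields(sig[off : off + 8 * ns], 8, ns)]
        off += 8 * ns + 80 * ns
        spr = [int(v) for v in _read_fields(sig[off : off + 8 * ns], 8, ns)]
        raw = fh.read()

    if channel_subset is not None:
        missing = [nm for nm in channel_subset if nm not in labels]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not found in {path.name}; available: {labels}"
            )
        pick = [labels.index(nm) for nm in channel_subset]
    else:
        pick = list(range(ns))

    rates = {spr[i] / rec_dur for i in pick}
    if len(rates) != 1:
        raise ValueError(f"selected channels have mixed sampling rates: {sorted(rates)}")
    fs = rates.pop()

    rec_words = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", count=n_records * rec_words)
    data = data.reshape(n_records, rec_words)
    starts = np.concatenate([[0], np.cumsum(spr)])
    channels = []
    for i in pick:
        d = data[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        channels.append((d - dmin[i]) * gain + pmin[i])
    return MultichannelSeries(
        values=np.vstack(channels),
        sampling_rate=fs,
        channel_names=tuple(labels[i] for i in pick),
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read seizure intervals from a CSV with header ``onset_s,offset_s``."""
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"annotation CSV must have a {col!r} column, got {list(df.columns)}")
    return [(float(a), float(b)) for a, b in zip(df["onset_s"], df["offset_s"])]


def write_annotations_csv(path: str | Path, seizures: Sequence[tuple[float, float]]) -> None:
    pd.DataFrame(seizures, columns=["onset_s", "offset_s"]).to_csv(path, index=False)


_CHB_FILE = re.compile(r"File Name:\s*(\S+)")
_CHB_START = re.compile(r"Seizure(?:\s+\d+)?\s+Start Time:\s*(\d+(?:\.\d+)?)\s*sec")
_CHB_END = re.compile(r"Seizure(?:\s+\d+)?\s+End Time:\s*(\d+(?:\.\d+)?)\s*sec")


def parse_chbmit_summary(text: str, file_name: str | None = None) -> list[tuple[float, float]]:
    """Best-effort parser for CHB-MIT style patient summary text.

    Scans ``Seizure Start/End Time: N seconds`` lines, optionally restricted
    to the block describing ``file_name``.  The summary files follow no fixed
    standard; the CSV annotation format is the normative input and this
    helper is a convenience only.
    """
    if file_name is not None:
        blocks = re.split(r"(?=File Name:)", text)
        blocks = [b for b in blocks if (m := _CHB_FILE.search(b)) and m.group(1) == file_name]
        text = "\n".join(blocks)
    starts = [float(m.group(1)) for m in _CHB_START.finditer(text)]
    ends = [float(m.group(1)) for m in _CHB_END.finditer(text)]
    if len(starts) != len(ends):
        raise ValueError(
            f"mismatched seizure start/end counts: {len(starts)} vs {len(ends)}"
        )
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def _validate_seizures(seizures: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    ordered = sorted((float(a), float(b)) for a, b in seizures)
    for a, b in ordered:
        if b <= a:
            raise ValueError(f"empty or inverted seizure interval [{a}, {b})")
    for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
        if a2 < b1:
            raise ValueError(f"overlapping seizure intervals [{a1}, {b1}) and [{a2}, {b2})")
    return ordered


def sample_states(
    rec: MultichannelSeries,
    seizures: Sequence[tuple[float, float]],
    preictal_horizon_min: float = 30.0,
) -> np.ndarray:
    """Per-sample state indices (0 interictal, 1 preictal, 2 ictal).

    Samples within ``preictal_horizon_min`` before an onset are preictal;
    samples inside a seizure interval are ictal; ictal wins where the
    horizon of a later seizure overlaps an earlier one.
    """
    if rec.sampling_rate is None:
        raise ValueError("recording needs a sampling_rate for state labelling")
    fs = rec.sampling_rate
    states = np.zeros(rec.n_samples, dtype=np.int8)
    horizon_s = preictal_horizon_min * 60.0
    ordered = _validate_seizures(seizures)
    for onset, offset in ordered:
        a = max(int(np.ceil((onset - horizon_s) * fs)), 0)
        b = min(int(np.ceil(onset * fs)), rec.n_samples)
        states[a:b] = np.maximum(states[a:b], 1)
    for onset, offset in ordered:
        a = max(int(np.ceil(onset * fs)), 0)
        b = min(int(np.ceil(offset * fs)), rec.n_samples)
        states[a:b] = 2
    return states


def epoch_and_label(
    rec: MultichannelSeries,
    seizures: Sequence[tuple[float, float]],
    epoch_length_s: float = 10.0,
    stride_s: float | None = None,
    preictal_horizon_min: float = 30.0,
) -> EpochSet:
    """Slice a recording into labelled fixed-length epochs.

    Epochs are non-overlapping by default (stride = length) and never extend
    past the recording end.  Each epoch's label is the majority state of its
    samples; on an exact tie the more severe state wins (ictal > preictal >
    interictal).
    """
    if rec.sampling_rate is None:
        raise ValueError("recording needs a sampling_rate for epoching")
    fs = rec.sampling_rate
    if stride_s is None:
        stride_s = epoch_length_s
    ep_n = int(round(epoch_length_s * fs))
    st_n = int(round(stride_s * fs))
    if ep_n < 1 or st_n < 1:
        raise ValueError("epoch length and stride must cover at least one sample")
    if ep_n > rec.n_samples:
        raise ValueError(
            f"epoch of {epoch_length_s}s ({ep_n} samples) exceeds recording "
            f"length {rec.n_samples} samples"
        )
    states = sample_states(rec, seizures, preictal_horizon_min)
    return _epoch_by_states(rec, states, epoch_length_s, stride_s, ep_n, st_n)


def epoch_with_intervals(
    rec: MultichannelSeries,
    intervals,
    epoch_length_s: float = 10.0,
    stride_s: float | None = None,
) -> EpochSet:
    """Epoch a recording whose ground-truth state intervals are known.

    ``intervals`` is a sequence of objects with ``start_s``, ``end_s`` and
    ``state`` attributes (e.g. the intervals of a synthetic
    :class:`~mmdisten.signals.LabeledRecording`); labelling is by majority
    state per epoch, as in :func:`epoch_and_label`.
    """
    if rec.sampling_rate is None:
        raise ValueError("recording needs a sampling_rate for epoching")
    fs = rec.sampling_rate
    if stride_s is None:
        stride_s = epoch_length_s
    ep_n = int(round(epoch_length_s * fs))
    st_n = int(round(stride_s * fs))
    if ep_n < 1 or st_n < 1 or ep_n > rec.n_samples:
        raise ValueError("invalid epoch length or stride for this recording")
    states = np.zeros(rec.n_samples, dtype=np.int8)
    for iv in intervals:
        a = max(int(np.ceil(iv.start_s * fs)), 0)
        b = min(int(np.ceil(iv.end_s * fs)), rec.n_samples)
        states[a:b] = STATES.index(iv.state)
    return _epoch_by_states(rec, states, epoch_length_s, stride_s, ep_n, st_n)


def _epoch_by_states(
    rec: MultichannelSeries,
    states: np.ndarray,
    epoch_length_s: float,
    stride_s: float,
    ep_n: int,
    st_n: int,
) -> EpochSet:
    fs = rec.sampling_rate
    epochs, labels, starts = [], [], []
    for a in range(0, rec.n_samples - ep_n + 1, st_n):
        window = rec.values[:, a : a + ep_n]
        counts = np.bincount(states[a : a + ep_n], minlength=3)
        # argmax over reversed counts -> ties resolve to the higher (severer) state
        lab = 2 - int(np.argmax(counts[::-1]))
        epochs.append(
            MultichannelSeries(
                values=window, sampling_rate=fs, channel_names=rec.channel_names
            )
        )
        labels.append(STATES[lab])
        starts.append(a / fs)
    return EpochSet(
        epochs=tuple(epochs),
        labels=tuple(labels),
        epoch_length_s=epoch_length_s,
        stride_s=stride_s,
        start_times_s=tuple(starts),
    )
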