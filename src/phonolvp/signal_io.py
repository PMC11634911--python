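"""Reading, writing and validation of synchronized multichannel recordings.

A recording couples four channels sampled on a common clock (nominally
1 kHz): ECG [V], invasive left-ventricular pressure LVP [mmHg], a
phonocardiogram MIC [mmHg] and a pulse-oximetry waveform POX [mmHg].
LVP exists only in instrumented (catheterized) recordings and is optional;
ECG, MIC and POX are mandatory for the prediction pipeline.

Supported formats:

* CSV — one header row of channel names, optional leading ``#``-prefixed
  metadata lines (``# fs=<Hz>``, ``# step=<label>``, ``# subject=<label>``,
  ``# start=<s>``). A ``time`` column is optional and, when present, must be
  consistent with ``fs``.
* EDF — European Data Format, 16-bit; a minimal codec is implemented here.
* WAV — export of the MIC channel only, rescaled to full scale with the
  scale factor logged in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io.wavfile

logger = logging.getLogger(__name__)

#: canonical channel order and units
CANONICAL_CHANNELS = ("ECG", "LVP", "MIC", "POX")
CHANNEL_UNITS = {"ECG": "V", "LVP": "mmHg", "MIC": "mmHg", "POX": "mmHg"}
#: channels the prediction pipeline cannot run without
REQUIRED_CHANNELS = ("ECG", "MIC", "POX")


class SignalIOError(Exception):
    """Base class for recording I/O failures."""


class ChannelMissingError(SignalIOError):
    """A mandatory channel is absent from the file."""


class StructureError(SignalIOError):
    """Channel sequences are inconsistent (lengths, emptiness, header)."""


class RecordParseError(SignalIOError):
    """A cell could not be parsed; carries the offending row number."""


@dataclass
class SignalRecord:
    """A synchronized multichannel physiological recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, > 0.
    channels : dict
        Mapping from canonical channel name to a 1-D float array. All
        present channels must share the same length >= 1.
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    step_label: str = ""
    subject_label: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.channels:
                raise ChannelMissingError(f"required channel {name!r} is missing")


@dataclass
class ValidationIssue:
    """One validation finding: the channel, sample range and rule violated."""

    channel: str
    rule: str
    first_sample: int = -1
    last_sample: int = -1
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" samples {self.first_sample}..{self.last_sample}" if self.first_sample >= 0 else ""
        return f"[{self.channel}] {self.rule}{loc}: {self.message}"


def validate_record(record: SignalRecord) -> list[ValidationIssue]:
    """Check structural invariants and finiteness; always returns a report.

    An empty list means the record satisfies every invariant and contains
    no non-finite sample. Non-finite samples are reported, never imputed:
    segmentation correctness depends on contiguous data.
    """
    issues: list[ValidationIssue] = []
    if not np.isfinite(record.sampling_rate) or record.sampling_rate <= 0:
        issues.append(ValidationIssue("*", "nonpositive sampling rate",
                                      message=f"fs={record.sampling_rate}"))
    if not record.channels:
        issues.append(ValidationIssue("*", "empty record", message="no channels"))
        return issues
    lengths = {name: len(x) for name, x in record.channels.items()}
    if len(set(lengths.values())) > 1:
        issues.append(ValidationIssue("*", "inconsistent channel lengths",
                                      message=str(lengths)))
    for name, n in lengths.items():
        if n < 1:
            issues.append(ValidationIssue(name, "empty channel"))
    for name in REQUIRED_CHANNELS:
        if name not in record.channels:
            issues.append(ValidationIssue(name, "missing required channel",
                                          message=f"{name} is mandatory for the pipeline"))
    for name, x in record.channels.items():
        bad = ~np.isfinite(x)
        if bad.any():
            idx = np.flatnonzero(bad)
            issues.append(ValidationIssue(name, "non-finite samples",
                                          first_sample=int(idx[0]), last_sample=int(idx[-1]),
                                          message=f"{bad.sum()} non-finite value(s)"))
    return issues


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _canonical_name(col: str) -> str | None:
    u = col.strip().upper()
    return u if u in CANONICAL_CHANNELS else None


def _read_csv(path: Path) -> SignalRecord:
    meta: dict[str, str] = {}
    header: list[str] | None = None
    data_rows: list[list[str]] = []
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
            else:
                data_rows.append(line.split(","))
    if header is None or not data_rows:
        raise StructureError(f"{path}: no header/data rows found")

    ncol = len(header)
    columns: dict[str, np.ndarray] = {}
    raw_cols: list[list[str]] = [[] for _ in range(ncol)]
    for rownum, row in enumerate(data_rows, start=1):
        if len(row) != ncol:
            raise StructureError(
                f"{path}: row {rownum} has {len(row)} fields, header has {ncol}")
        for j, cell in enumerate(row):
            raw_cols[j].append(cell)
    for j, colname in enumerate(header):
        try:
            columns[colname] = np.array([float(c) for c in raw_cols[j]])
        except ValueError:
            for rownum, cell in enumerate(raw_cols[j], start=1):
                try:
                    float(cell)
                except ValueError:
                    raise RecordParseError(
                        f"{path}: non-numeric cell {cell!r} in column {colname!r}, "
                        f"data row {rownum}") from None
            raise

    channels: dict[str, np.ndarray] = {}
    time_col: np.ndarray | None = None
    for colname, values in columns.items():
        canon = _canonical_name(colname)
        if canon is not None:
            channels[canon] = values
        elif colname.strip().lower() == "time":
            time_col = values
        else:
            logger.warning("%s: ignoring unknown column %r", path, colname)

    fs: float | None = float(meta["fs"]) if "fs" in meta else None
    if fs is None and time_col is not None and len(time_col) > 1:
        fs = 1.0 / float(np.median(np.diff(time_col)))
    if fs is None:
        raise StructureError(f"{path}: sampling rate not given ('# fs=' line or time column)")

    start_time = float(meta.get("start", time_col[0] if time_col is not None else 0.0))
    if time_col is not None:
        expected = start_time + np.arange(len(time_col)) / fs
        if np.max(np.abs(time_col - expected)) > 1e-6:
            raise StructureError(f"{path}: time column inconsistent with fs={fs}")

    for name in REQUIRED_CHANNELS:
        if name not in channels:
            raise ChannelMissingError(f"{path}: mandatory channel {name!r} not found")
    return SignalRecord(sampling_rate=fs, channels=channels,
                        step_label=meta.get("step", ""),
                        subject_label=meta.get("subject", ""),
                        start_time=start_time)


def _write_csv(record: SignalRecord, path: Path) -> None:
    names = [c for c in CANONICAL_CHANNELS if c in record.channels]
    t = record.times()
    with open(path, "w") as fh:
        fh.write(f"# fs={record.sampling_rate:.17g}\n")
        if record.step_label:
            fh.write(f"# step={record.step_label}\n")
        if record.subject_label:
            fh.write(f"# subject={record.subject_label}\n")
        fh.write(f"# start={record.start_time:.17g}\n")
        fh.write("time," + ",".join(names) + "\n")
        cols = [t] + [record.channels[n] for n in names]
        for row in zip(*cols):
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format, minimal codec)
# ---------------------------------------------------------------------------

def _edf_str(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _edf_float8(value: float) -> str:
    """Format a float into at most 8 ASCII characters losslessly parseable."""
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def _write_edf(record: SignalRecord, path: Path) -> None:
    fs = record.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise StructureError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    names = [c for c in CANONICAL_CHANNELS if c in record.channels]
    n = record.n_samples
    if n == 0:
        raise StructureError("cannot write an empty record")
    n_records = int(np.ceil(n / fs))

    phys: list[tuple[float, float]] = []
    digital: list[np.ndarray] = []
    for name in names:
        x = record.channels[name]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-30:
            hi = lo + 1.0
        # widen to the 8-character header representation so the scaling the
        # reader reconstructs matches the one used for quantization
        lo = float(_edf_float8(np.nextafter(lo, -np.inf)))
        hi = float(_edf_float8(np.nextafter(hi, np.inf)))
        while lo > np.min(x):
            lo = float(_edf_float8(lo - abs(lo) * 1e-6 - 1e-12))
        while hi < np.max(x):
            hi = float(_edf_float8(hi + abs(hi) * 1e-6 + 1e-12))
        phys.append((lo, hi))
        # pad the last data record with the edge value
        padded = np.concatenate([x, np.full(n_records * fs - n, x[-1])])
        scaled = (padded - lo) / (hi - lo) * 65535.0 - 32768.0
        digital.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    ns = len(names)
    header = b"0" + b" " * 7
    header += _edf_str(f"subject={record.subject_label}", 80)
    header += _edf_str(f"step={record.step_label};start={record.start_time:.9g};n={n}", 80)
    header += _edf_str("01.01.00", 8) + _edf_str("00.00.00", 8)
    header += _edf_str(str(256 * (ns + 1)), 8)
    header += _edf_str("", 44)
    header += _edf_str(str(n_records), 8)
    header += _edf_str("1", 8)
    header += _edf_str(str(ns), 4)
    header += b"".join(_edf_str(f"{nm} {CHANNEL_UNITS[nm]}", 16) for nm in names)
    header += b"".join(_edf_str("", 80) for _ in names)
    header += b"".join(_edf_str(CHANNEL_UNITS[nm], 8) for nm in names)
    header += b"".join(_edf_str(_edf_float8(p[0]), 8) for p in phys)
    header += b"".join(_edf_str(_edf_float8(p[1]), 8) for p in phys)
    header += b"".join(_edf_str("-32768", 8) for _ in names)
    header += b"".join(_edf_str("32767", 8) for _ in names)
    header += b"".join(_edf_str("", 80) for _ in names)
    header += b"".join(_edf_str(str(fs), 8) for _ in names)
    header += b"".join(_edf_str("", 32) for _ in names)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for sig in digital:
                fh.write(sig[r * fs:(r + 1) * fs].tobytes())


def _read_edf(path: Path) -> SignalRecord:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise StructureError(f"{path}: truncated EDF header")
        recording = head[88:168].decode("ascii", errors="replace").strip()
        n_records = int(head[236:244].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig = fh.read(256 * ns)
        labels = [sig[16 * i:16 * (i + 1)].decode().strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        phys_min = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(ns)]
        off += 8 * ns
        dig_min = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(ns)]
        off += 8 * ns
        dig_max = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(ns)]
        fh.seek(256 * (ns + 1))
        raw = fh.read()

    rec_len = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", count=n_records * rec_len)
    data = data.reshape(n_records, rec_len)
    channels: dict[str, np.ndarray] = {}
    col = 0
    fs = None
    for i, label in enumerate(labels):
        dig = data[:, col:col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        x = phys_min[i] + (dig - dig_min[i]) * gain
        canon = _canonical_name(label.split()[0] if label else label)
        if canon is None:
            logger.warning("%s: ignoring unknown EDF channel %r", path, label)
            continue
        channels[canon] = x
        fs = spr[i]  # record duration is 1 s

    meta = dict(kv.partition("=")[::2] for kv in recording.split(";") if "=" in kv)
    n = int(meta.get("n", len(next(iter(channels.values()))) if channels else 0))
    channels = {k: v[:n] for k, v in channels.items()}
    for name in REQUIRED_CHANNELS:
        if name not in channels:
            raise ChannelMissingError(f"{path}: mandatory channel {name!r} not found")
    return SignalRecord(sampling_rate=float(fs), channels=channels,
                        step_label=meta.get("step", ""),
                        subject_label="",
                        start_time=float(meta.get("start", 0.0)))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_record(path: str | Path, format_hint: str = "auto") -> SignalRecord:
    """Read a recording from CSV or EDF and validate its structure.

    ``format_hint`` is one of ``csv``, ``edf`` or ``auto`` (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        record = _read_csv(path)
    elif fmt == "edf":
        record = _read_edf(path)
    else:
        raise ValueError(f"unknown format hint {format_hint!r}")
    lengths = {len(x) for x in record.channels.values()}
    if len(lengths) > 1:
        raise StructureError(f"{path}: channels have inconsistent lengths")
    return record


def write_record(record: SignalRecord, path: str | Path, format: str = "csv") -> Path:
    """Write a record as ``csv``, ``edf``, or ``wav_mic`` (MIC channel only).

    CSV output is byte-deterministic for identical inputs. ``wav_mic``
    rescales the MIC channel to full scale and logs the scale factor in a
    ``<path>.json`` sidecar.
    """
    path = Path(path)
    if record.n_samples == 0 or not record.channels:
        raise StructureError("cannot write an empty record")
    if format == "csv":
        _write_csv(record, path)
    elif format == "edf":
        _write_edf(record, path)
    elif format == "wav_mic":
        record.require("MIC")
        mic = record.channels["MIC"]
        peak = float(np.max(np.abs(mic)))
        if peak == 0:
            peak = 1.0
        scipy.io.wavfile.write(path, int(round(record.sampling_rate)),
                               (mic / peak).astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "scale_mmHg": peak,
            "sampling_rate": record.sampling_rate,
            "step": record.step_label,
            "subject": record.subject_label,
        }, indent=2))
        logger.info("wav_mic export: full-scale factor %g mmHg", peak)
    else:
        raise ValueError(f"unknown output format {format!r}")
    return path
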