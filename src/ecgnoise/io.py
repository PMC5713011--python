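"""Reading and writing of ECG signals, label tracks and derived tables.

Formats owned by this module:

* ECG signals as CSV (metadata line + lead-name header) or as a minimal
  WFDB subset (``.hea``/``.dat`` pairs, sample format 16, gain/baseline
  scaling to millivolts).
* Segment severity label tracks as TSV (``segment_id, start_s, end_s, label``).
* Noise-bar tables and confusion matrices as CSV.
* Human-readable duration strings such as ``"3 h 27 m 56 s"``.

Time convention: seconds, half-open sample intervals
``[t0 + i/fs, t0 + (i+1)/fs)``, recording-relative unless a container
supplies an absolute origin.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_LABELS = (0, 1, 2, 3, 4)

__all__ = [
    "ECGRecord",
    "LabelSegment",
    "SegmentLabelTrack",
    "read_ecg",
    "write_ecg",
    "read_label_track",
    "write_label_track",
    "parse_duration",
    "format_duration",
    "parse_decimal",
    "read_confusion_matrix_csv",
    "write_confusion_matrix_csv",
    "write_noise_bars_csv",
    "read_noise_bars_csv",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ECGRecord:
    """Sampled multi-lead ECG.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_leads)
        Amplitudes in millivolts. Sample ``i`` covers the half-open interval
        ``[t0 + i/fs, t0 + (i+1)/fs)``.
    fs : float
        Sampling rate in Hz.
    lead_names : list of str
        One identifier per column.
    t0 : float
        Start time of the recording in seconds.
    gaps : list of (float, float)
        Disjoint, sorted intervals within the record extent where no signal
        was stored (event recorders store discontinuous bursts). Gaps are
        declared, not zero-filled.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str]
    t0: float = 0.0
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1 and len(self.lead_names) == 1:
            self.samples = self.samples.T
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (n_samples, n_leads) array")
        if len(self.lead_names) != self.samples.shape[1]:
            raise ValidationError(
                f"{len(self.lead_names)} lead names for {self.samples.shape[1]} signal columns"
            )
        end = self.t0 + self.n_samples / self.fs
        prev = self.t0
        for a, b in self.gaps:
            if not (self.t0 <= a < b <= end):
                raise ValidationError(f"gap ({a}, {b}) outside record extent [{self.t0}, {end})")
            if a < prev:
                raise ValidationError("gaps must be disjoint and sorted")
            prev = b

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample start times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def lead(self, which: int | str) -> np.ndarray:
        """Return one lead as a 1-D array (by index or name)."""
        if isinstance(which, str):
            try:
                which = self.lead_names.index(which)
            except ValueError:
                raise KeyError(f"no lead named {which!r}; have {self.lead_names}") from None
        return self.samples[:, which]


LabelSegment = tuple  # (segment_id, start_s, end_s, label)


@dataclass
class SegmentLabelTrack:
    """Ordered, non-overlapping severity-labeled segments.

    Each entry is ``(segment_id, start_s, end_s, label)`` with labels drawn
    from the clinical taxonomy 0-4. Segments use half-open intervals, so a
    shared boundary is not an overlap.
    """

    entries: list[tuple[int, float, float, int]]

    def __post_init__(self) -> None:
        for seg_id, start, end, label in self.entries:
            if not start < end:
                raise ValidationError(f"segment {seg_id}: start {start} must precede end {end}")
            if label not in VALID_LABELS:
                raise ValidationError(f"segment {seg_id}: label {label} outside {VALID_LABELS}")
        starts = [e[1] for e in self.entries]
        if starts != sorted(starts):
            logger.warning("label track entries out of order; sorting by start time")
            self.entries = sorted(self.entries, key=lambda e: e[1])
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur[1] < prev[2]:
                raise ValidationError(
                    f"segments {prev[0]} and {cur[0]} overlap ({prev[2]} > {cur[1]})"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(e[2] - e[1] for e in self.entries)


# ---------------------------------------------------------------------------
# ECG signal I/O
# ---------------------------------------------------------------------------

def read_ecg(path: str | Path, format: str | None = None, decimal: str = ".") -> ECGRecord:
    """Read an ECG record from CSV or a WFDB header/signal pair.

    ``format`` is inferred from the extension (``.hea`` -> wfdb, else csv)
    when not given. ``decimal=','`` selects the comma-decimal CSV dialect
    (fields then separated by ``;``).
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix == ".hea" else "csv"
    if format == "wfdb":
        return _read_wfdb(path)
    if format == "csv":
        return _read_csv(path, decimal=decimal)
    raise FormatError(f"unknown ECG format {format!r} (expected 'wfdb' or 'csv')")


def write_ecg(record: ECGRecord, path: str | Path, format: str | None = None) -> Path:
    """Write an ECG record; returns the path of the header/CSV file written."""
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") else "csv"
    if format == "wfdb":
        return _write_wfdb(record, path)
    if format == "csv":
        return _write_csv(record, path)
    raise FormatError(f"unknown ECG format {format!r} (expected 'wfdb' or 'csv')")


def _read_csv(path: Path, decimal: str = ".") -> ECGRecord:
    sep = ";" if decimal == "," else ","
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise FormatError(f"{path}: CSV must start with a '# fs=...' metadata line")
    meta: dict[str, str] = {}
    for token in first.lstrip("#").split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    if "fs" not in meta:
        raise FormatError(f"{path}: metadata line does not declare fs")
    fs = float(meta["fs"].replace(",", ".") if decimal == "," else meta["fs"])
    t0 = float(meta.get("t0", "0"))
    units = meta.get("units", "mV")
    if units != "mV":
        logger.warning("%s: units declared as %r, passing values through unchanged", path, units)
    frame = pd.read_csv(path, skiprows=1, sep=sep, decimal=decimal)
    if frame.isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric sample rows")
    gaps = []
    if "gaps" in meta and meta["gaps"]:
        for interval in meta["gaps"].split(";"):
            a, _, b = interval.partition(":")
            gaps.append((float(a), float(b)))
    return ECGRecord(
        samples=frame.to_numpy(dtype=float),
        fs=fs,
        lead_names=[str(c) for c in frame.columns],
        t0=t0,
        gaps=gaps,
    )


def _write_csv(record: ECGRecord, path: Path) -> Path:
    meta = f"# fs={record.fs:g} t0={record.t0:g} units=mV"
    if record.gaps:
        meta += " gaps=" + ";".join(f"{a:g}:{b:g}" for a, b in record.gaps)
    frame = pd.DataFrame(record.samples, columns=record.lead_names)
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        frame.to_csv(fh, index=False, float_format="%.6f")
    return path


# Minimal WFDB subset: single-segment records, one .dat per record,
# sample format 16 (interleaved little-endian int16), gain(baseline)/units.
_WFDB_GAIN = 1000.0  # ADC units per mV -> 0.001 mV resolution
_GAIN_RE = re.compile(r"^([0-9.]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?$")


def _read_wfdb(header_path: Path) -> ECGRecord:
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{header_path}: header line needs 'name nsig fs nsamples'")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    if fs <= 0:
        raise FormatError(f"{header_path}: non-positive sampling rate {fs}")
    if len(lines) - 1 < n_sig:
        raise FormatError(f"{header_path}: {n_sig} signals declared, {len(lines)-1} spec lines")
    dat_names, gains, baselines, leads = [], [], [], []
    for spec in lines[1 : 1 + n_sig]:
        fields = spec.split()
        if len(fields) < 3 or fields[1] != "16":
            raise FormatError(f"{header_path}: only sample format 16 is supported: {spec!r}")
        match = _GAIN_RE.match(fields[2])
        if not match:
            raise FormatError(f"{header_path}: cannot parse gain field {fields[2]!r}")
        gain = float(match.group(1)) or 200.0  # WFDB convention: 0 means default
        baseline = int(match.group(2) or 0)
        units = match.group(3) or "mV"
        if units != "mV":
            logger.warning("%s: signal units %r, passing through unchanged", header_path, units)
        dat_names.append(fields[0])
        gains.append(gain)
        baselines.append(baseline)
        leads.append(fields[-1])
    if len(set(dat_names)) != 1:
        raise FormatError(f"{header_path}: all signals must share one .dat file")
    raw = np.fromfile(header_path.with_name(dat_names[0]), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(
            f"{header_path}: expected {n_sig * n_samp} samples in .dat, found {raw.size}"
        )
    adc = raw.reshape(n_samp, n_sig).astype(float)
    samples = (adc - np.asarray(baselines)) / np.asarray(gains)
    return ECGRecord(samples=samples, fs=fs, lead_names=leads)


def _write_wfdb(record: ECGRecord, path: Path) -> Path:
    base = path.with_suffix("")
    dat_name = base.with_suffix(".dat").name
    adc = np.rint(record.samples * _WFDB_GAIN)
    if np.abs(adc).max(initial=0) > 32767:
        raise FormatError(
            "signal exceeds the int16 range at gain "
            f"{_WFDB_GAIN:g} ADC units/mV (|x| > {32767 / _WFDB_GAIN:.3f} mV)"
        )
    adc = adc.astype("<i2")
    lines = [f"{base.name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for j, lead in enumerate(record.lead_names):
        first = int(adc[0, j]) if record.n_samples else 0
        lines.append(f"{dat_name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} 0 0 {lead}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.tofile(base.with_suffix(".dat"))
    return base.with_suffix(".hea")


# ---------------------------------------------------------------------------
# Label track I/O
# ---------------------------------------------------------------------------

def read_label_track(path: str | Path) -> SegmentLabelTrack:
    """Read a TSV severity track (segment_id, start_s, end_s, label)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"segment_id", "start_s", "end_s", "label"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}, got {list(frame.columns)}")
    entries = [
        (int(r.segment_id), float(r.start_s), float(r.end_s), int(r.label))
        for r in frame.itertuples()
    ]
    return SegmentLabelTrack(entries=entries)


def write_label_track(track: SegmentLabelTrack, path: str | Path) -> Path:
    frame = pd.DataFrame(track.entries, columns=["segment_id", "start_s", "end_s", "label"])
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Duration strings and decimal dialects
# ---------------------------------------------------------------------------

_DURATION_TOKEN = re.compile(r"(\d+)\s*(d|h|m|s)\b")
_UNIT_SECONDS = {"d": 86400, "h": 3600, "m": 60, "s": 1}


def parse_duration(text: str) -> int:
    """Parse ``"5 d 18 h 54 m 2 s"``-style strings into integer seconds.

    Tokens may appear in any subset (``"53 m 27 s"``) but each at most once
    and in descending unit order.
    """
    tokens = _DURATION_TOKEN.findall(text)
    leftover = _DURATION_TOKEN.sub("", text).replace(",", " ").strip()
    if not tokens or leftover:
        raise FormatError(f"unrecognized duration string {text!r}")
    units = [u for _, u in tokens]
    order = [u for u in "dhms" if u in units]
    if len(set(units)) != len(units) or units != order:
        raise FormatError(f"duration units repeated or out of order in {text!r}")
    return sum(int(v) * _UNIT_SECONDS[u] for v, u in tokens)


def format_duration(seconds: int) -> str:
    """Inverse of :func:`parse_duration` for non-negative integer seconds."""
    if seconds < 0 or seconds != int(seconds):
        raise ValidationError(f"duration must be a non-negative integer, got {seconds}")
    seconds = int(seconds)
    if seconds == 0:
        return "0 s"
    parts = []
    for unit in "dhms":
        width = _UNIT_SECONDS[unit]
        value, seconds = divmod(seconds, width)
        if value:
            parts.append(f"{value} {unit}")
    return " ".join(parts)


def parse_decimal(text: str, decimal: str = ".") -> float:
    """Parse one number in the requested decimal dialect (``"33602,99"``)."""
    text = text.strip()
    if decimal == ",":
        if "." in text:
            raise FormatError(f"unexpected '.' in comma-decimal number {text!r}")
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"cannot parse number {text!r}") from None


# ---------------------------------------------------------------------------
# Derived tables
# ---------------------------------------------------------------------------

def write_confusion_matrix_csv(class_names, durations, path: str | Path) -> Path:
    """Square duration table; observer-1 classes as rows, observer 2 as columns."""
    frame = pd.DataFrame(np.asarray(durations, dtype=float), index=class_names, columns=class_names)
    frame.to_csv(path)
    return Path(path)


def read_confusion_matrix_csv(path: str | Path):
    """Return ``(class_names, durations)`` from a square CSV table."""
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index.astype(str)) != [str(c) for c in frame.columns]:
        raise FormatError(f"{path}: row and column class names differ")
    return [str(c) for c in frame.columns], frame.to_numpy(dtype=float)


def write_noise_bars_csv(bars, path: str | Path) -> Path:
    """Write a NoiseBarSeries as CSV (one row per bar, per-level fractions)."""
    rows = []
    for index, bar in enumerate(bars.bars):
        row = {"bar_index": index, "bar_start_s": bar.start_s, "is_blank": bar.is_blank}
        for level in range(5):
            row[f"frac_level{level}"] = "" if bar.is_blank else bar.fractions.get(level, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_noise_bars_csv(path: str | Path):
    from .mapping import Bar, NoiseBarSeries  # local import to avoid a cycle

    frame = pd.read_csv(path)
    bars = []
    for r in frame.itertuples():
        if bool(r.is_blank):
            bars.append(Bar(start_s=float(r.bar_start_s), is_blank=True, fractions={}))
        else:
            fractions = {
                level: float(getattr(r, f"frac_level{level}"))
                for level in range(5)
                if not pd.isna(getattr(r, f"frac_level{level}"))
                and float(getattr(r, f"frac_level{level}")) > 0
            }
            bars.append(Bar(start_s=float(r.bar_start_s), is_blank=False, fractions=fractions))
    if len(frame) >= 2:
        bar_s = float(frame.bar_start_s.iloc[1] - frame.bar_start_s.iloc[0])
    else:
        bar_s = float("nan")
    return NoiseBarSeries(bar_s=bar_s, bars=bars)
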