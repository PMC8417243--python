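"""Reading, labeling and windowing of annotated multichannel EEG recordings.

EEG recordings arrive as EDF files (as in the CHB-MIT scalp EEG database,
256 samples/s, 18-channel bipolar montage) together with seizure-onset
annotations, either as a CHB-MIT ``*-summary.txt`` file or as a plain CSV
with columns ``case,onset_s,offset_s``.

The labeling rule: the pre-ictal class is the span from 1 h to 5 min before
each annotated onset; the inter-ictal class is everything at least a guard
distance (default 4 h) away from any seizure. Ictal spans belong to neither
class. Labeled intervals are then cut into fixed-length windows, with 50 %
overlap for pre-ictal windows to balance the two classes.

Time convention: seconds from recording start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PRE_ICTAL = "pre_ictal"
INTER_ICTAL = "inter_ictal"
Label = Literal["pre_ictal", "inter_ictal"]

#: Standard CHB-MIT 18-channel bipolar longitudinal montage.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
)


@dataclass
class Recording:
    """One continuous multichannel EEG recording with seizure annotations.

    ``samples`` is a channels x time array in µV; onset/offset times are in
    seconds from the start of the recording.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    seizure_onsets: list[float] = field(default_factory=list)
    seizure_offsets: list[float] = field(default_factory=list)
    source_id: str = "recording"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time 2-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(self.seizure_onsets) != len(self.seizure_offsets):
            raise ValueError("onset and offset lists differ in length")
        onsets = list(self.seizure_onsets)
        if onsets != sorted(onsets) or len(set(onsets)) != len(onsets):
            raise ValueError("seizure onsets must be strictly increasing")
        for on, off in zip(self.seizure_onsets, self.seizure_offsets):
            if not 0 <= on < off:
                raise ValueError(f"invalid seizure span [{on}, {off})")
            if on >= self.duration:
                raise ValueError(
                    f"seizure onset {on} s beyond recording duration "
                    f"{self.duration} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Total length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open time span ``[start, end)`` carrying a class label."""

    start: float
    end: float
    label: Label

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class EEGSegment:
    """One labeled fixed-length multichannel window of samples (µV)."""

    samples: np.ndarray
    label: Label
    start_time: float
    source_id: str
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("segment samples must be channels x time")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def window_samples(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

def _parse_annotation_csv(path: Path, case: str | None = None) -> list[tuple[float, float]]:
    spans: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if case is not None and row.get("case") not in (None, "", case):
                continue
            spans.append((float(row["onset_s"]), float(row["offset_s"])))
    return sorted(spans)


_SUMMARY_FILE_RE = re.compile(r"^file name\s*:\s*(\S+)", re.IGNORECASE)
_SUMMARY_START_RE = re.compile(
    r"^seizure(?:\s+\d+)?\s+start\s+time\s*:\s*(\d+(?:\.\d+)?)\s*sec", re.IGNORECASE
)
_SUMMARY_END_RE = re.compile(
    r"^seizure(?:\s+\d+)?\s+end\s+time\s*:\s*(\d+(?:\.\d+)?)\s*sec", re.IGNORECASE
)


def _parse_chbmit_summary(path: Path, edf_name: str) -> list[tuple[float, float]]:
    """Tolerant line parser for CHB-MIT ``*-summary.txt`` seizure blocks."""
    spans: list[tuple[float, float]] = []
    current_file = None
    pending_start: float | None = None
    for raw in Path(path).read_text(errors="replace").splitlines():
        line = raw.strip()
        if m := _SUMMARY_FILE_RE.match(line):
            current_file = m.group(1)
            pending_start = None
            continue
        if current_file != edf_name:
            continue
        if m := _SUMMARY_START_RE.match(line):
            pending_start = float(m.group(1))
        elif m := _SUMMARY_END_RE.match(line):
            if pending_start is None:
                raise ValueError(f"seizure end before start in {path}")
            spans.append((pending_start, float(m.group(1))))
            pending_start = None
    return sorted(spans)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, annotation_path: str | Path | None = None) -> Recording:
    """Read an EDF recording plus its seizure annotations.

    ``annotation_path`` may be a CHB-MIT summary text file or a CSV with
    header ``case,onset_s,offset_s`` (rows whose ``case`` matches the EDF
    stem, or with an empty case, are used). ``None`` means no seizures.
    """
    import mne  # heavy import, keep local

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not parse EDF file {path}: {exc}") from exc
    samples = raw.get_data(units="uV")
    rec = Recording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        source_id=path.stem,
    )
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if not annotation_path.exists():
            raise FileNotFoundError(f"annotation file not found: {annotation_path}")
        if annotation_path.suffix.lower() == ".csv":
            spans = _parse_annotation_csv(annotation_path, case=path.stem)
        else:
            spans = _parse_chbmit_summary(annotation_path, edf_name=path.name)
        for on, off in spans:
            if on >= rec.duration or off > rec.duration:
                raise ValueError(
                    f"annotation span [{on}, {off}) s exceeds recording "
                    f"duration {rec.duration} s ({path})"
                )
        rec = Recording(
            samples=rec.samples,
            sampling_rate=rec.sampling_rate,
            channel_names=rec.channel_names,
            seizure_onsets=[s for s, _ in spans],
            seizure_offsets=[e for _, e in spans],
            source_id=rec.source_id,
        )
    return rec


def _norm_label(name: str) -> str:
    return re.sub(r"\s+", "", name).upper()


def select_channels(rec: Recording, wanted: Sequence[str] = DEFAULT_MONTAGE) -> Recording:
    """Reorder/subset channels to ``wanted`` (case/whitespace-insensitive)."""
    index = {_norm_label(name): i for i, name in enumerate(rec.channel_names)}
    rows = []
    for label in wanted:
        key = _norm_label(label)
        if key not in index:
            raise KeyError(
                f"channel {label!r} not in recording; available: {rec.channel_names}"
            )
        rows.append(index[key])
    return Recording(
        samples=rec.samples[rows],
        sampling_rate=rec.sampling_rate,
        channel_names=[rec.channel_names[i] for i in rows],
        seizure_onsets=list(rec.seizure_onsets),
        seizure_offsets=list(rec.seizure_offsets),
        source_id=rec.source_id,
    )


# ---------------------------------------------------------------------------
# labeling and segmentation
# ---------------------------------------------------------------------------

def label_intervals(
    rec: Recording,
    pre_start_offset: float = 3600.0,
    pre_end_offset: float = 300.0,
    inter_guard: float = 4 * 3600.0,
) -> list[LabeledInterval]:
    """Apply the pre-ictal / inter-ictal labeling rule.

    For each onset ``t`` the pre-ictal interval is
    ``[max(0, t - pre_start_offset), t - pre_end_offset)``, truncated at the
    end of any earlier seizure. Inter-ictal intervals are the stretches at
    least ``inter_guard`` from every seizure (before onset and after offset).
    Ictal spans belong to neither class.
    """
    if pre_start_offset <= 0 or pre_end_offset <= 0:
        raise ValueError("offsets must be positive")
    if pre_start_offset <= pre_end_offset:
        raise ValueError("pre_start_offset must exceed pre_end_offset")
    if inter_guard <= 0:
        raise ValueError("inter_guard must be positive")

    onsets = sorted(rec.seizure_onsets)
    offsets = [off for _, off in sorted(zip(rec.seizure_onsets, rec.seizure_offsets))]

    pre: list[LabeledInterval] = []
    for i, t in enumerate(onsets):
        start = max(0.0, t - pre_start_offset)
        for off in offsets[:i]:
            start = max(start, off)
        end = t - pre_end_offset
        if end <= start:
            logger.warning(
                "pre-ictal interval for onset %.1f s is empty (too close to "
                "recording start or a prior seizure); skipped", t,
            )
            continue
        pre.append(LabeledInterval(start, end, PRE_ICTAL))

    # blocked = guarded seizure spans plus the pre-ictal intervals themselves
    blocked: list[tuple[float, float]] = [
        (max(0.0, on - inter_guard), min(rec.duration, off + inter_guard))
        for on, off in zip(onsets, offsets)
    ]
    blocked += [(iv.start, iv.end) for iv in pre]
    blocked.sort()
    merged: list[list[float]] = []
    for s, e in blocked:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    inter: list[LabeledInterval] = []
    cursor = 0.0
    for s, e in merged:
        if s > cursor:
            inter.append(LabeledInterval(cursor, s, INTER_ICTAL))
        cursor = max(cursor, e)
    if cursor < rec.duration:
        inter.append(LabeledInterval(cursor, rec.duration, INTER_ICTAL))

    return sorted(pre + inter, key=lambda iv: iv.start)


def segment_interval(
    rec: Recording,
    iv: LabeledInterval,
    window_seconds: float = 5.0,
    overlap_fraction: float = 0.0,
) -> list[EEGSegment]:
    """Cut one labeled interval into fixed-length windows.

    Window k starts at ``iv.start + k * stride`` with
    ``stride = window_seconds * (1 - overlap_fraction)``. An interval shorter
    than one window yields an empty list.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    length = iv.length
    if length < window_seconds:
        logger.info(
            "interval [%.1f, %.1f) shorter than window (%.1f s); no segments",
            iv.start, iv.end, window_seconds,
        )
        return []
    stride = window_seconds * (1.0 - overlap_fraction)
    # 1e-9 guards float round-off in the count for exact-fit intervals
    count = int(math.floor((length - window_seconds) / stride + 1e-9)) + 1
    fs = rec.sampling_rate
    win = int(round(window_seconds * fs))
    segments = []
    for k in range(count):
        t0 = iv.start + k * stride
        i0 = int(round(t0 * fs))
        if i0 + win > rec.n_samples:
            break
        segments.append(
            EEGSegment(
                samples=rec.samples[:, i0 : i0 + win].copy(),
                label=iv.label,
                start_time=t0,
                source_id=rec.source_id,
                sampling_rate=fs,
            )
        )
    return segments


def segment_recording(
    rec: Recording,
    window_seconds: float = 5.0,
    pre_overlap: float = 0.5,
    inter_overlap: float = 0.0,
    **label_kwargs,
) -> list[EEGSegment]:
    """Label a recording and window every interval with the default
    class-balancing overlap policy (50 % for pre-ictal, none for inter-ictal).
    """
    segments: list[EEGSegment] = []
    for iv in label_intervals(rec, **label_kwargs):
        ov = pre_overlap if iv.label == PRE_ICTAL else inter_overlap
        segments.extend(segment_interval(rec, iv, window_seconds, ov))
    return segments


def write_manifest(segments: Iterable[EEGSegment], path: str | Path) -> None:
    """Write a segment manifest CSV: ``source_id,start_time,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "start_time", "label"])
        for seg in segments:
            writer.writerow([seg.source_id, f"{seg.start_time:.3f}", seg.label])


# ---------------------------------------------------------------------------
# minimal EDF writer (16-bit), so generated recordings can round-trip
# through the EDF reader
# ---------------------------------------------------------------------------

def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def _phys_str(v: float) -> str:
    """Physical min/max as an 8-char-safe decimal string."""
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.1e}"
    return s


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a plain 16-bit EDF file (1-s data records).

    The recording is truncated to a whole number of seconds; the sampling
    rate must be a positive integer. Physical dimension is µV.
    """
    fs = rec.sampling_rate
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.samples[:, : n_records * fs]

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _field("0", 8),
        _field("synthetic", 80),
        _field("seizgraph", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (nch + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(nch), 4),
    ])
    header += b"".join(_field(name, 16) for name in rec.channel_names)
    header += b"".join(_field("", 80) for _ in range(nch))
    header += b"".join(_field("uV", 8) for _ in range(nch))
    header += b"".join(_field(_phys_str(phys_min[i]), 8) for i in range(nch))
    header += b"".join(_field(_phys_str(phys_max[i]), 8) for i in range(nch))
    header += b"".join(_field(str(dig_min), 8) for _ in range(nch))
    header += b"".join(_field(str(dig_max), 8) for _ in range(nch))
    header += b"".join(_field("", 80) for _ in range(nch))
    header += b"".join(_field(str(fs), 8) for _ in range(nch))
    header += b"".join(_field("", 32) for _ in range(nch))

    # physical -> digital, clipped to the 16-bit range. Header stores the
    # rounded physical bounds, so recompute scale from what was written.
    pmin = np.array([float(_phys_str(phys_min[i])) for i in range(nch)])
    pmax = np.array([float(_phys_str(phys_max[i])) for i in range(nch)])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def write_annotation_csv(rec: Recording, path: str | Path) -> None:
    """Write seizure annotations as CSV: ``case,onset_s,offset_s``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "onset_s", "offset_s"])
        for on, off in zip(rec.seizure_onsets, rec.seizure_offsets):
            writer.writerow([rec.source_id, f"{on:.3f}", f"{off:.3f}"])
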