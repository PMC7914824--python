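"""Audio and segmentation I/O for neonatal phonocardiograms.

Recordings are mono PCM WAV files (any rate; clinical stethoscopes record at
44.1 kHz / 16 bit). Samples are exposed as float64 in [-1, 1]. Segmentations
delimit each heartbeat cycle into the four auscultation phases S1, systole
(m1), S2 and diastole (m2) as half-open, 0-based sample ranges; they are
persisted as a small CSV so that manual annotations are diff-able and
round-trip exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

ANALYSIS_RATE = 2000  # Hz; all feature extraction happens at this rate

SEGMENTATION_COLUMNS = [
    "patient_id",
    "point_id",
    "cycle_index",
    "s1_start",
    "m1_start",
    "s2_start",
    "m2_start",
    "cycle_end",
]

INTERVAL_NAMES = ("S1", "m1", "S2", "m2")


class PCGIOError(Exception):
    """Base class for I/O failures in this module."""


class MissingFileError(PCGIOError):
    """The requested file does not exist."""


class MultiChannelError(PCGIOError):
    """The WAV file is not mono."""


class UnsupportedEncodingError(PCGIOError):
    """The WAV sample encoding is not handled."""


class SegmentationFormatError(PCGIOError):
    """A segmentation CSV violates the documented dialect or its invariants."""


@dataclass(frozen=True)
class AudioRecording:
    """One auscultation-point recording.

    samples are dimensionless amplitudes in [-1, 1]; point_id follows the
    standard five-area numeration (1 aortic, 2 pulmonic, 3 tricuspid,
    4 mitral, 5 left sternal border).
    """

    samples: np.ndarray
    rate: float
    patient_id: str
    point_id: int

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.samples) < 1:
            raise ValueError("recording must contain at least one sample")
        if self.point_id not in (1, 2, 3, 4, 5):
            raise ValueError(f"point_id must be in 1..5, got {self.point_id}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SegmentedCycle:
    """One heartbeat cycle as four contiguous half-open sample ranges.

    S1 = [s1_start, m1_start), m1 (systole) = [m1_start, s2_start),
    S2 = [s2_start, m2_start), m2 (diastole) = [m2_start, cycle_end).
    """

    s1_start: int
    m1_start: int
    s2_start: int
    m2_start: int
    cycle_end: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(int(x) != x for x in b):
            raise ValueError("boundaries must be integers")
        diffs = np.diff(b)
        if np.any(diffs < 2):
            raise ValueError(
                f"each interval needs >= 2 samples; boundaries {b} invalid"
            )

    @property
    def boundaries(self) -> tuple[int, int, int, int, int]:
        return (self.s1_start, self.m1_start, self.s2_start, self.m2_start, self.cycle_end)

    @property
    def n_samples(self) -> int:
        return self.cycle_end - self.s1_start

    def interval_slices(self) -> dict[str, slice]:
        b = self.boundaries
        return {name: slice(b[i], b[i + 1]) for i, name in enumerate(INTERVAL_NAMES)}

    def rescaled(self, factor: float) -> "SegmentedCycle":
        """Rescale boundaries proportionally (rounded), e.g. after resampling.

        Rounded boundaries can collapse short intervals; a minimum width of
        2 samples is enforced by pushing later boundaries forward.
        """
        b = [int(round(x * factor)) for x in self.boundaries]
        for i in range(1, 5):
            if b[i] < b[i - 1] + 2:
                b[i] = b[i - 1] + 2
        return SegmentedCycle(*b)


@dataclass
class SegmentationAnnotation:
    """Ordered, non-overlapping heartbeat cycles for one recording."""

    cycles: list[SegmentedCycle]
    patient_id: str = ""
    point_id: int = 1

    def __post_init__(self) -> None:
        for prev, cur in zip(self.cycles, self.cycles[1:]):
            if cur.s1_start < prev.cycle_end:
                raise ValueError("cycles overlap or are out of order")

    def __len__(self) -> int:
        return len(self.cycles)

    def rescaled(self, factor: float) -> "SegmentationAnnotation":
        return replace(self, cycles=[c.rescaled(factor) for c in self.cycles])


def load_recording(path: str | Path, patient_id: str, point_id: int) -> AudioRecording:
    """Read a mono PCM WAV file and scale samples to +/-1 floats."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise MultiChannelError(
            f"multi-channel unsupported: {path} has {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"unsupported WAV encoding {data.dtype} in {path}")
    return AudioRecording(samples=samples, rate=float(rate), patient_id=patient_id, point_id=point_id)


def save_recording(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV (amplitudes clipped to +/-1)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pcm = np.clip(np.round(rec.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rec.rate), pcm)


def resample_recording(rec: AudioRecording, target_rate: int = ANALYSIS_RATE) -> AudioRecording:
    """Downsample a recording with anti-alias filtering.

    Upsampling is refused: analysis only ever moves down to 2 kHz, and an
    annotation made at the original rate stays valid under the proportional
    boundary rescale.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling not supported (rate {rec.rate} -> {target_rate})"
        )
    if target_rate == rec.rate:
        return rec
    from fractions import Fraction

    frac = Fraction(int(round(target_rate)), int(round(rec.rate)))
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    expected = int(round(len(rec.samples) * target_rate / rec.rate))
    # resample_poly returns ceil(n*up/down); trim/pad to the rounded length
    if len(out) > expected:
        out = out[:expected]
    elif len(out) < expected:
        out = np.pad(out, (0, expected - len(out)))
    return replace(rec, samples=out, rate=float(target_rate))


def save_segmentation(annotations: SegmentationAnnotation | list[SegmentationAnnotation],
                      path: str | Path) -> None:
    """Persist one or more annotations to the segmentation CSV dialect."""
    if isinstance(annotations, SegmentationAnnotation):
        annotations = [annotations]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SEGMENTATION_COLUMNS)
        for ann in annotations:
            for idx, cyc in enumerate(ann.cycles):
                writer.writerow([ann.patient_id, ann.point_id, idx, *cyc.boundaries])


def load_segmentation(path: str | Path) -> list[SegmentationAnnotation]:
    """Load a segmentation CSV; one annotation per (patient_id, point_id).

    Rows violating the boundary invariants are rejected with their 1-based
    row number in the message.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    groups: dict[tuple[str, int], list[tuple[int, SegmentedCycle]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SEGMENTATION_COLUMNS:
            raise SegmentationFormatError(
                f"unexpected header {reader.fieldnames}; want {SEGMENTATION_COLUMNS}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                cyc = SegmentedCycle(
                    int(row["s1_start"]), int(row["m1_start"]), int(row["s2_start"]),
                    int(row["m2_start"]), int(row["cycle_end"]),
                )
            except ValueError as exc:
                raise SegmentationFormatError(f"row {rownum}: {exc}") from exc
            key = (row["patient_id"], int(row["point_id"]))
            groups.setdefault(key, []).append((int(row["cycle_index"]), cyc))
    annotations = []
    for (pid, point), items in groups.items():
        items.sort(key=lambda t: t[0])
        try:
            ann = SegmentationAnnotation(
                cycles=[c for _, c in items], patient_id=pid, point_id=point
            )
        except ValueError as exc:
            raise SegmentationFormatError(
                f"patient {pid} point {point}: {exc}"
            ) from exc
        annotations.append(ann)
    return annotations
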