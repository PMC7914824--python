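"""Synthetic neonatal heart-sound cohorts with ground-truth segmentation.

The generator emulates the structure of a clinical auscultation study:
five points per patient, a handful of manually segmented heartbeat cycles
per point, and one diagnosis per patient (healthy, PDA or CHD). Each cycle
is built at the 2 kHz analysis rate from four phases: S1 and S2 are
exponentially decaying sinusoid bursts (valve-closure transients, ~90 and
~110 Hz), the silent intervals carry baseline recording noise. A CHD
patient receives a band-limited systolic murmur (noise in m1 only); a PDA
patient a continuous murmur (noise in both m1 and m2), loudest at the
pulmonic point. The murmur is white Gaussian noise shaped by the same
band-pass operator the feature stage uses, so generator and analyser agree
on what "in-band" means.

This is an engineered stand-in for clinical audio, not a hemodynamic
model; it provides controllable effect sizes and exact cycle boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import bandpass_filter
from .io import (
    ANALYSIS_RATE,
    AudioRecording,
    SegmentationAnnotation,
    SegmentedCycle,
    load_recording,
    load_segmentation,
    save_recording,
    save_segmentation,
)

LABELS = ("healthy", "PDA", "CHD")

S1_FREQ = 90.0  # Hz, centre frequency of the first heart sound burst
S2_FREQ = 110.0
BURST_DECAY_FRACTION = 0.2  # burst amplitude decays to exp(-1/frac) over its interval
SYSTOLE_SHARE = 0.45  # fraction of the silent time assigned to systole


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level generator settings.

    Defaults reflect a term neonate: 143 bpm mean heart rate (cycle about
    0.42 s), 70 ms S1, 50 ms S2. The murmur band 200-400 Hz matches the
    sub-band where systolic murmur energy is most discriminative;
    murmur_gain scales the murmur noise amplitude relative to noise_sd
    (gain 0 = no murmur). point_gains modulate murmur loudness per
    auscultation point, loudest at the pulmonic point 2 where a PDA's
    continuous murmur is best heard.
    """

    heart_rate_mean: float = 143.0  # beats/min
    heart_rate_sd: float = 7.0
    s1_duration: float = 0.070  # s
    s2_duration: float = 0.050
    murmur_band: tuple[float, float] = (200.0, 400.0)
    murmur_gain: float = 3.0
    noise_sd: float = 0.01
    point_gains: tuple[float, ...] = (0.5, 1.0, 0.5, 0.5, 0.5)
    cycles_per_point: int = 5
    s1_amplitude: float = 0.4
    s2_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.cycles_per_point < 2:
            raise ValueError("cycles_per_point must be >= 2")
        lo, hi = self.murmur_band
        if not (0 < lo < hi <= 1000):
            raise ValueError("murmur_band must lie within (0, 1000] Hz")
        if self.murmur_gain < 0 or any(g < 0 for g in self.point_gains):
            raise ValueError("gains must be >= 0")
        if len(self.point_gains) != 5:
            raise ValueError("point_gains must have 5 entries")
        if self.heart_rate_mean <= 0 or self.noise_sd < 0:
            raise ValueError("invalid heart rate or noise level")


@dataclass
class PatientRecord:
    """One patient: a diagnosis plus per-point audio and segmentation."""

    patient_id: str
    label: str
    recordings: dict[int, AudioRecording] = field(default_factory=dict)
    segmentations: dict[int, SegmentationAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


def _burst(n: int, freq: float, amplitude: float, rate: float,
           rng: np.random.Generator) -> np.ndarray:
    """Exponentially decaying sinusoid with a random phase."""
    t = np.arange(n) / rate
    tau = BURST_DECAY_FRACTION * n / rate
    phase = rng.uniform(0, 2 * np.pi)
    return amplitude * np.exp(-t / tau) * np.sin(2 * np.pi * freq * t + phase)


def _murmur(n: int, amplitude: float, band: tuple[float, float],
            rate: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, amplitude, n)
    if n < 8:
        return white
    return bandpass_filter(white, rate, *band)


def simulate_cycle(label: str, params: SimulationParams, rng: np.random.Generator,
                   duration: float | None = None, point_gain: float = 1.0,
                   rate: float = ANALYSIS_RATE) -> tuple[np.ndarray, SegmentedCycle]:
    """One heartbeat cycle with its exact phase boundaries.

    ``duration`` defaults to 60 / heart_rate_mean; systole gets
    SYSTOLE_SHARE of the silent time. The murmur amplitude is
    murmur_gain * point_gain * noise_sd before band-pass shaping.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if duration is None:
        duration = 60.0 / params.heart_rate_mean
    n_total = int(round(duration * rate))
    n_s1 = max(int(round(params.s1_duration * rate)), 2)
    n_s2 = max(int(round(params.s2_duration * rate)), 2)
    n_silent = n_total - n_s1 - n_s2
    if n_silent < 4:
        raise ValueError("cycle too short for the configured S1/S2 durations")
    n_m1 = max(int(round(SYSTOLE_SHARE * n_silent)), 2)
    n_m2 = n_silent - n_m1
    if n_m2 < 2:
        raise ValueError("diastole collapsed; check durations")

    x = rng.normal(0.0, params.noise_sd, n_total)
    b1 = n_s1
    b2 = b1 + n_m1
    b3 = b2 + n_s2
    x[:b1] += _burst(n_s1, S1_FREQ, params.s1_amplitude, rate, rng)
    x[b2:b3] += _burst(n_s2, S2_FREQ, params.s2_amplitude, rate, rng)

    murmur_amp = params.murmur_gain * point_gain * params.noise_sd
    if murmur_amp > 0 and label in ("CHD", "PDA"):
        x[b1:b2] += _murmur(n_m1, murmur_amp, params.murmur_band, rate, rng)
        if label == "PDA":  # continuous murmur runs through diastole too
            x[b3:] += _murmur(n_total - b3, murmur_amp, params.murmur_band, rate, rng)

    cycle = SegmentedCycle(0, b1, b2, b3, n_total)
    return x, cycle


def simulate_patient(patient_id: str, label: str, params: SimulationParams,
                     seed: int) -> PatientRecord:
    """Five auscultation points, ``cycles_per_point`` cycles each.

    Cycle durations are drawn per cycle from the patient's heart-rate
    distribution (Normal, truncated to positive rates). All randomness
    flows through one generator seeded per patient.
    """
    rng = np.random.default_rng(seed)
    patient = PatientRecord(patient_id=patient_id, label=label)
    for point_id in range(1, 6):
        gain = params.point_gains[point_id - 1]
        samples_parts: list[np.ndarray] = []
        cycles: list[SegmentedCycle] = []
        offset = 0
        for _ in range(params.cycles_per_point):
            hr = rng.normal(params.heart_rate_mean, params.heart_rate_sd)
            hr = float(np.clip(hr, 60.0, 250.0))
            x, cyc = simulate_cycle(label, params, rng, duration=60.0 / hr,
                                    point_gain=gain)
            cycles.append(SegmentedCycle(*(b + offset for b in cyc.boundaries)))
            samples_parts.append(x)
            offset += len(x)
        samples = np.concatenate(samples_parts)
        patient.recordings[point_id] = AudioRecording(
            samples=samples, rate=float(ANALYSIS_RATE),
            patient_id=patient_id, point_id=point_id,
        )
        patient.segmentations[point_id] = SegmentationAnnotation(
            cycles=cycles, patient_id=patient_id, point_id=point_id,
        )
    return patient


def simulate_cohort(n_healthy: int, n_pda: int, n_chd: int,
                    params: SimulationParams | None = None,
                    seed: int = 0) -> list[PatientRecord]:
    """A labelled cohort with exact label counts and per-patient seeds
    derived deterministically from the master seed."""
    if n_healthy < 0 or n_pda < 0 or n_chd < 0:
        raise ValueError("counts must be >= 0")
    if n_healthy + n_pda + n_chd == 0:
        raise ValueError("cohort must contain at least one patient")
    if params is None:
        params = SimulationParams()
    seed_rng = np.random.default_rng(seed)
    labels = ["healthy"] * n_healthy + ["PDA"] * n_pda + ["CHD"] * n_chd
    patients = []
    for i, label in enumerate(labels):
        child_seed = int(seed_rng.integers(0, 2**31 - 1))
        patients.append(simulate_patient(f"P{i:04d}", label, params, child_seed))
    return patients


def write_cohort(patients: list[PatientRecord], root: str | Path) -> None:
    """Write a cohort as one directory per patient (point WAVs + one
    segmentation CSV) plus a cohort-level labels CSV."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    labels = []
    for patient in patients:
        pdir = root / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        for point_id, rec in sorted(patient.recordings.items()):
            save_recording(rec, pdir / f"point{point_id}.wav")
        save_segmentation(
            [patient.segmentations[p] for p in sorted(patient.segmentations)],
            pdir / "segmentation.csv",
        )
        labels.append({"patient_id": patient.patient_id, "label": patient.label})
    pd.DataFrame(labels).to_csv(root / "labels.csv", index=False)


def load_cohort(root: str | Path) -> list[PatientRecord]:
    """Read back a cohort written by write_cohort."""
    root = Path(root)
    labels = pd.read_csv(root / "labels.csv", dtype={"patient_id": str})
    patients = []
    for _, row in labels.iterrows():
        pid, label = row["patient_id"], row["label"]
        pdir = root / pid
        patient = PatientRecord(patient_id=pid, label=label)
        for ann in load_segmentation(pdir / "segmentation.csv"):
            patient.segmentations[ann.point_id] = ann
        for point_id in sorted(patient.segmentations):
            patient.recordings[point_id] = load_recording(
                pdir / f"point{point_id}.wav", pid, point_id
            )
        patients.append(patient)
    return patients
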