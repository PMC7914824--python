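"""Combining cycle-level information across cycles and auscultation points.

Feature-level fusion either averages all of a patient's cycle vectors into
one 200-feature vector, or averages per auscultation point and concatenates
the five point means into a 1000-feature vector. Decision-level fusion
reduces cycle probabilities to one patient probability, optionally per
point first, with mean or max at each stage; the baseline pools all cycle
probabilities and takes their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, META_COLUMNS

MODES = ("cycle_level_baseline", "mean_of_features", "concat_per_point")
RULES = ("mean", "max")


@dataclass(frozen=True)
class AggregationSpec:
    """How to fuse cycles and points into one decision per patient."""

    mode: str = "cycle_level_baseline"
    decision_rule_point: str = "none"  # 'mean' | 'max' | 'none' (pool cycles)
    decision_rule_patient: str = "mean"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.decision_rule_point not in RULES + ("none",):
            raise ValueError("decision_rule_point must be mean/max/none")
        if self.decision_rule_patient not in RULES:
            raise ValueError("decision_rule_patient must be mean/max")


def _feature_cols(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in META_COLUMNS]


def mean_of_features(patient_cycles: pd.DataFrame) -> pd.Series:
    """Element-wise mean of all cycle vectors of one patient (200 entries)."""
    if len(patient_cycles) == 0:
        raise ValueError("need at least one cycle")
    return patient_cycles[_feature_cols(patient_cycles)].mean(axis=0)


def concat_per_point(patient_cycles: pd.DataFrame) -> pd.Series:
    """Per-point mean vectors concatenated in point order 1..5 (1000 entries).

    Names are point-prefixed, e.g. ``p2_m1_b4_en_lin``.
    """
    cols = _feature_cols(patient_cycles)
    pieces = []
    for point_id in range(1, 6):
        sub = patient_cycles[patient_cycles["point_id"] == point_id]
        if len(sub) == 0:
            raise ValueError(f"missing auscultation point {point_id}")
        mean_vec = sub[cols].mean(axis=0)
        mean_vec.index = [f"p{point_id}_{c}" for c in cols]
        pieces.append(mean_vec)
    return pd.concat(pieces)


def aggregate_features(frame: pd.DataFrame, spec: AggregationSpec) -> pd.DataFrame:
    """Apply the spec's feature-level transformation to a cohort table.

    Baseline returns the table unchanged (one row per cycle); the other
    modes return one row per patient.
    """
    if spec.mode == "cycle_level_baseline":
        return frame.copy()
    fn = mean_of_features if spec.mode == "mean_of_features" else concat_per_point
    rows = []
    for pid, group in frame.groupby("patient_id", sort=True):
        vec = fn(group)
        row = {"patient_id": pid, "label": group["label"].iloc[0]}
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _reduce(values: np.ndarray, rule: str) -> float:
    return float(np.max(values) if rule == "max" else np.mean(values))


def aggregate_probabilities(cycle_probs: dict[int, list[float]],
                            spec: AggregationSpec) -> float:
    """Reduce per-cycle probabilities to one patient probability.

    With ``decision_rule_point='none'`` all cycles are pooled and reduced
    once by the patient rule (the baseline); otherwise cycles are reduced
    within each point first, then across points.
    """
    if not cycle_probs or all(len(v) == 0 for v in cycle_probs.values()):
        raise ValueError("no probabilities to aggregate")
    for probs in cycle_probs.values():
        arr = np.asarray(probs, dtype=np.float64)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    if spec.decision_rule_point == "none":
        pooled = np.concatenate(
            [np.asarray(v, dtype=np.float64) for v in cycle_probs.values() if len(v)]
        )
        return _reduce(pooled, spec.decision_rule_patient)
    per_point = np.array(
        [_reduce(np.asarray(v, dtype=np.float64), spec.decision_rule_point)
         for v in cycle_probs.values() if len(v)]
    )
    return _reduce(per_point, spec.decision_rule_patient)
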