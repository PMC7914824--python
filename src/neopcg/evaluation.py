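"""Model evaluation and selection with patient-independent cross-validation.

The screening task is binary (PDA vs healthy, or CHD vs healthy) and the
metric is the ROC AUC computed on one probability per patient. Because a
patient contributes many cycles from five auscultation points, evaluation
must keep all of a patient's data on one side of every split — otherwise
the model can learn patient identity rather than pathology. Three settings
quantify that leakage:

* Setting 1 — patient-independent outer (evaluation) and inner
  (early-stopping/model-selection) splits; the honest protocol.
* Setting 2 — patient-independent outer split, but the inner split
  shuffles at cycle level, leaking identity into model selection.
* Setting 3 — cycle-level shuffles everywhere; leaks identity into the
  test estimate itself and produces an over-optimistic AUC.

Each outer training set is fitted as a 10-model ensemble: 10-fold CV where
every member trains on 9 folds and early-stops on the held-out fold. The
single test AUC is computed once over pooled out-of-fold patient
probabilities.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .aggregation import AggregationSpec, aggregate_features, aggregate_probabilities
from .boosting import (
    BoostingParams,
    fit_production_model,
    gain_importance,
    predict_ensemble,
    select_top_n,
)
from .features import META_COLUMNS

DEFAULT_GRID: list[dict] = [
    {"max_depth": d, "subsample": s, "colsample_bytree": c}
    for d, s, c in itertools.product((2, 3, 4, 5), (0.5, 0.7, 0.9), (0.5, 0.7, 0.9))
]

TASKS = {"pda_vs_healthy": "PDA", "chd_vs_healthy": "CHD"}



def _derive_seed(seed: int, mult: int, offset: int = 0) -> int:
    """Deterministic child seed kept within the 31-bit range the underlying
    libraries accept."""
    return (seed * mult + offset) % (2**31 - 1)

def auc(scores, labels) -> float:
    """Area under the ROC curve as the rank statistic: the probability that
    a random positive outscores a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-to-fold map for cross-validation."""

    folds: dict[str, int]
    mode: str  # 'patient_independent' | 'patient_dependent'
    seed: int
    k: int

    def fold_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.folds.items() if f == fold]


def stratified_patient_folds(patient_labels: dict[str, int], k: int,
                             seed: int) -> FoldAssignment:
    """Stratified k-fold at patient level: every patient wholly in one fold,
    fold sizes within 1 of each other, class counts within 1 of proportional."""
    patients = sorted(patient_labels)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    y = np.array([patient_labels[p] for p in patients])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(patients)), y)):
        for i in test_idx:
            folds[patients[i]] = fold
    return FoldAssignment(folds=folds, mode="patient_independent", seed=seed, k=k)


def task_frame(frame: pd.DataFrame, task: str) -> pd.DataFrame:
    """Restrict a cohort feature table to one binary task, dropping the
    third diagnosis group entirely."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {sorted(TASKS)}")
    positive = TASKS[task]
    out = frame[frame["label"].isin(["healthy", positive])].reset_index(drop=True)
    if out["label"].nunique() < 2:
        raise ValueError("task frame must contain both classes")
    return out


def _labels01(frame: pd.DataFrame) -> np.ndarray:
    return (frame["label"] != "healthy").to_numpy(dtype=int)


def _feature_cols(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in META_COLUMNS]


def _row_fold_indices(frame: pd.DataFrame, k: int, seed: int,
                      patient_independent: bool) -> np.ndarray:
    """Fold index per row: by patient for independent splits, by a seeded
    stratified row shuffle for dependent ones.

    k is clamped to the minority-class count (patients or rows as
    appropriate) so small cohorts still evaluate with fewer folds.
    """
    y = _labels01(frame)
    if patient_independent:
        patient_labels = {
            pid: int(grp.iloc[0])
            for pid, grp in pd.Series(y, index=frame["patient_id"]).groupby(level=0)
        }
        counts = pd.Series(list(patient_labels.values())).value_counts()
        k = max(2, min(k, int(counts.min())))
        assignment = stratified_patient_folds(patient_labels, k, seed)
        return frame["patient_id"].map(assignment.folds).to_numpy(dtype=int)
    k = max(2, min(k, int(pd.Series(y).value_counts().min())))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(frame), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(frame)), y)):
        folds[test_idx] = fold
    return folds


def fit_cv_ensemble(train_frame: pd.DataFrame, params: BoostingParams,
                    seed: int, patient_independent: bool = True,
                    k: int = 10, feature_cols: list[str] | None = None):
    """k-model ensemble: each member trains on k-1 folds and early-stops on
    the held-out fold. Returns (models, per-member validation AUCs)."""
    if feature_cols is None:
        feature_cols = _feature_cols(train_frame)
    folds = _row_fold_indices(train_frame, k, seed, patient_independent)
    k = int(folds.max()) + 1  # may have been clamped for tiny cohorts
    y = _labels01(train_frame)
    X = train_frame[feature_cols]
    models, val_aucs = [], []
    for fold in range(k):
        val_mask = folds == fold
        # a validation fold can end up single-class in very small cohorts;
        # AUC is undefined there, so that member trains without early stopping
        validation = (X[val_mask], y[val_mask]) if len(np.unique(y[val_mask])) == 2 else None
        model = fit_production_model(
            X[~val_mask], y[~val_mask], params,
            validation=validation,
            seed=_derive_seed(seed, 1000, fold),
        )
        models.append(model)
        val_aucs.append(model.validation_auc)
    return models, val_aucs


def tune_hyperparameters(frame: pd.DataFrame, grid: list[dict],
                         seed: int, base_params: BoostingParams | None = None,
                         tune_rounds: int = 200, n_repeats: int = 5,
                         patient_independent: bool = True) -> dict:
    """Pick (max_depth, subsample, colsample_bytree) by mean out-of-fold AUC
    over ``n_repeats`` random 2-fold splits; ties resolved to the first grid
    entry (deterministic)."""
    if not grid:
        raise ValueError("grid must be non-empty")
    if base_params is None:
        base_params = BoostingParams()
    feature_cols = _feature_cols(frame)
    y = _labels01(frame)
    X = frame[feature_cols]
    splits = []
    for rep in range(n_repeats):
        folds = _row_fold_indices(frame, 2, _derive_seed(seed, 1, rep), patient_independent)
        for half in (0, 1):
            splits.append((folds != half, folds == half))
    scores = []
    for config in grid:
        params = BoostingParams(
            eta=base_params.eta, lambda_=base_params.lambda_,
            gamma=base_params.gamma, n_rounds=tune_rounds, **config,
        )
        fold_scores = []
        for i, (train_mask, test_mask) in enumerate(splits):
            model = fit_production_model(X[train_mask], y[train_mask], params,
                                         seed=_derive_seed(seed, 100, i))
            fold_scores.append(auc(model.predict(X[test_mask]), y[test_mask]))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return dict(grid[best])


def _patient_probabilities(frame: pd.DataFrame, probs: np.ndarray,
                           spec: AggregationSpec) -> tuple[dict[str, float], dict[str, int]]:
    """One probability and label per patient from out-of-fold row scores."""
    y = _labels01(frame)
    patient_probs: dict[str, float] = {}
    patient_y: dict[str, int] = {}
    work = frame[["patient_id"]].copy()
    work["prob"] = probs
    work["y"] = y
    if "point_id" in frame.columns:
        work["point_id"] = frame["point_id"]
    else:
        work["point_id"] = 1
    for pid, grp in work.groupby("patient_id", sort=True):
        by_point = {int(pt): list(sub["prob"]) for pt, sub in grp.groupby("point_id")}
        patient_probs[pid] = aggregate_probabilities(by_point, spec)
        patient_y[pid] = int(grp["y"].iloc[0])
    return patient_probs, patient_y


@dataclass
class EvaluationReport:
    """Outcome of one cross-validated experiment."""

    setting: int
    task: str
    aggregation_mode: str
    validation_auc_mean: float
    validation_auc_sd: float
    test_auc: float
    training_auc_mean: float
    training_auc_sd: float
    patient_probabilities: dict[str, float]
    patient_labels: dict[str, int]
    chosen_params: dict
    n_patients: int
    n_rows: int
    importance: list = field(default_factory=list)
    topn_results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["importance"] = [[name, gain] for name, gain in self.importance]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def run_setting(frame: pd.DataFrame, setting: int, spec: AggregationSpec,
                seed: int, params: BoostingParams | None = None,
                grid: list[dict] | None = None, task: str = "pda_vs_healthy",
                k_outer: int = 10, k_inner: int = 10) -> EvaluationReport:
    """One full cross-validated experiment under a leakage setting.

    ``frame`` is a cohort cycle-feature table (any label mix; the task's
    third class is excluded here). When ``grid`` is given, the
    (max_depth, subsample, colsample_bytree) triple is tuned inside each
    outer training set by repeated 2-fold CV before the ensemble fit.
    """
    if setting not in (1, 2, 3):
        raise ValueError("setting must be 1, 2 or 3")
    if params is None:
        params = BoostingParams()
    data = aggregate_features(task_frame(frame, task), spec)
    feature_cols = _feature_cols(data)
    outer_independent = setting in (1, 2)
    inner_independent = setting == 1
    outer_folds = _row_fold_indices(data, k_outer, seed, outer_independent)
    k_outer = int(outer_folds.max()) + 1  # may have been clamped
    y = _labels01(data)
    X = data[feature_cols]

    oof_probs = np.full(len(data), np.nan)
    val_aucs: list[float] = []
    train_aucs: list[float] = []
    all_models = []
    chosen = {"max_depth": params.max_depth, "subsample": params.subsample,
              "colsample_bytree": params.colsample_bytree}
    for fold in range(k_outer):
        test_mask = outer_folds == fold
        train_data = data[~test_mask].reset_index(drop=True)
        fold_params = params
        if grid:
            chosen = tune_hyperparameters(train_data, grid,
                                          seed=_derive_seed(seed, 10, fold),
                                          base_params=params,
                                          patient_independent=inner_independent)
            fold_params = BoostingParams(
                eta=params.eta, lambda_=params.lambda_, gamma=params.gamma,
                n_rounds=params.n_rounds,
                early_stopping_patience=params.early_stopping_patience, **chosen,
            )
        models, fold_val_aucs = fit_cv_ensemble(
            train_data, fold_params, seed=_derive_seed(seed, 10, fold),
            patient_independent=inner_independent, k=k_inner,
            feature_cols=feature_cols,
        )
        all_models.extend(models)
        val_aucs.extend(v for v in fold_val_aucs if v is not None)
        train_probs = predict_ensemble(models, train_data[feature_cols])
        train_aucs.append(auc(train_probs, _labels01(train_data)))
        oof_probs[test_mask] = predict_ensemble(models, X[test_mask])

    assert not np.any(np.isnan(oof_probs))
    patient_probs, patient_y = _patient_probabilities(data, oof_probs, spec)
    test_auc = auc(list(patient_probs.values()),
                   [patient_y[p] for p in patient_probs])
    ranking = gain_importance(all_models, feature_order=feature_cols)
    return EvaluationReport(
        setting=setting, task=task, aggregation_mode=spec.mode,
        validation_auc_mean=float(np.mean(val_aucs)),
        validation_auc_sd=float(np.std(val_aucs)),
        test_auc=test_auc,
        training_auc_mean=float(np.mean(train_aucs)),
        training_auc_sd=float(np.std(train_aucs)),
        patient_probabilities=patient_probs,
        patient_labels=patient_y,
        chosen_params=chosen,
        n_patients=len(patient_probs),
        n_rows=len(data),
        importance=ranking,
    )


def run_topn_sweep(frame: pd.DataFrame, spec: AggregationSpec, seed: int,
                   params: BoostingParams | None = None,
                   n_list: tuple[int, ...] = (60, 30, 15, 10, 5),
                   task: str = "pda_vs_healthy",
                   k_outer: int = 10, k_inner: int = 10) -> EvaluationReport:
    """Full-feature run plus re-runs restricted to the Top-N gain-ranked
    features for each N. Results per N live in ``report.topn_results``."""
    full = run_setting(frame, 1, spec, seed, params=params, task=task,
                       k_outer=k_outer, k_inner=k_inner)
    base = task_frame(frame, task)
    feature_cols = _feature_cols(aggregate_features(base, spec))
    full.topn_results["all"] = {
        "n_features": len(feature_cols),
        "training_auc_mean": full.training_auc_mean,
        "training_auc_sd": full.training_auc_sd,
        "validation_auc_mean": full.validation_auc_mean,
        "validation_auc_sd": full.validation_auc_sd,
        "test_auc": full.test_auc,
    }
    for n in n_list:
        if n >= len(feature_cols):
            sub_frame = frame
        else:
            top = select_top_n(full.importance, n)
            keep = [c for c in frame.columns if c in META_COLUMNS] + [
                c for c in top if c in frame.columns
            ]
            sub_frame = frame[keep]
        report = run_setting(sub_frame, 1, spec, seed, params=params, task=task,
                             k_outer=k_outer, k_inner=k_inner)
        full.topn_results[f"top{n}"] = {
            "n_features": min(n, len(feature_cols)),
            "features": select_top_n(full.importance, n),
            "training_auc_mean": report.training_auc_mean,
            "training_auc_sd": report.training_auc_sd,
            "validation_auc_mean": report.validation_auc_mean,
            "validation_auc_sd": report.validation_auc_sd,
            "test_auc": report.test_auc,
        }
    return full


def inject_patient_offsets(frame: pd.DataFrame, scale: float = 1.0,
                           seed: int = 0,
                           columns: list[str] | None = None) -> pd.DataFrame:
    """Add a fixed per-patient random offset to each feature column.

    This plants patient identity into the features: a split that sees some
    cycles of a patient during training can recognise the patient's other
    cycles, which is exactly the leakage the patient-independent protocol
    guards against. Offsets are N(0, scale * column sd)."""
    out = frame.copy()
    if columns is None:
        columns = _feature_cols(frame)
    rng = np.random.default_rng(seed)
    col_sd = out[columns].std(ddof=0).to_numpy()
    col_sd[col_sd == 0] = 1.0
    for pid in sorted(out["patient_id"].unique()):
        offsets = rng.normal(0.0, scale, len(columns)) * col_sd
        mask = out["patient_id"] == pid
        out.loc[mask, columns] = out.loc[mask, columns].to_numpy() + offsets
    return out
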