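"""Regularised gradient-boosted decision trees for binary screening.

The reference booster implements the regularised boosting objective in its
standard second-order form: with per-instance gradient g_i = p_i - y_i and
hessian h_i = p_i (1 - p_i) of the logistic loss, the optimal leaf weight
is w* = -G / (H + lambda) and the gain of a split is

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                 - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma,

with the split rejected when the gain (gamma already subtracted) is not
positive. Trees are grown by exhaustive greedy search over midpoint
thresholds, with optional row/column subsampling and shrinkage (learning
rate eta scaling each leaf). Per-split gain is accumulated per feature to
yield gain importance.

The reference booster is exact and transparent but O(rounds * n * p *
thresholds); `fit_production_model` provides the same contract through
xgboost (exact tree method, no minimum-child-weight pruning) and is
cross-checked against the reference by an agreement suite in the tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb


@dataclass(frozen=True)
class BoostingParams:
    """Hyperparameters of the boosted ensemble.

    eta (learning rate) defaults to 0.03; objective is binary logistic and
    the evaluation metric AUC throughout. lambda_ penalises squared leaf
    weights, gamma penalises each additional leaf (split pruning).
    """

    eta: float = 0.03
    max_depth: int = 3
    subsample: float = 0.9
    colsample_bytree: float = 0.9
    lambda_: float = 1.0
    gamma: float = 0.0
    n_rounds: int = 1000
    early_stopping_patience: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.eta <= 1):
            raise ValueError("eta must be in (0, 1]")
        if not (0 < self.subsample <= 1 and 0 < self.colsample_bytree <= 1):
            raise ValueError("subsample fractions must be in (0, 1]")
        if self.lambda_ < 0 or self.gamma < 0:
            raise ValueError("lambda and gamma must be >= 0")
        if self.max_depth < 1 or self.n_rounds < 1:
            raise ValueError("max_depth and n_rounds must be >= 1")


@dataclass(frozen=True)
class GradHess:
    """First and second derivative of the loss at one instance."""

    g: float
    h: float


def logistic_grad_hess(prob: float, y: int) -> GradHess:
    """Gradient and hessian of the logistic loss at predicted probability."""
    if not (0 < prob < 1):
        raise ValueError("prob must be in (0, 1)")
    return GradHess(g=prob - y, h=prob * (1.0 - prob))


def leaf_weight(G: float, H: float, lambda_: float) -> float:
    """Optimal leaf weight w* = -G / (H + lambda)."""
    if H + lambda_ <= 0:
        raise ValueError("H + lambda must be positive")
    return -G / (H + lambda_)


def split_gain(GL: float, HL: float, GR: float, HR: float,
               lambda_: float, gamma: float) -> float:
    """Objective reduction of a candidate split, gamma subtracted."""
    return 0.5 * (
        GL * GL / (HL + lambda_)
        + GR * GR / (HR + lambda_)
        - (GL + GR) ** 2 / (HL + HR + lambda_)
    ) - gamma


def _sigmoid(margin: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-margin))


@dataclass
class TreeNode:
    """One node of a reference tree; leaves carry the (eta-scaled) weight."""

    feature: int = -1
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    weight: float = 0.0
    gain: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"weight": self.weight}
        return {
            "feature": self.feature, "threshold": self.threshold, "gain": self.gain,
            "left": self.left.to_dict(), "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "weight" in d:
            return cls(weight=d["weight"])
        return cls(feature=d["feature"], threshold=d["threshold"], gain=d["gain"],
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


def _best_split(X: np.ndarray, g: np.ndarray, h: np.ndarray, rows: np.ndarray,
                cols: np.ndarray, lambda_: float, gamma: float):
    """Exhaustive greedy split over midpoint thresholds.

    Returns (gain, feature, threshold, left_rows, right_rows) or None.
    Ties in gain are broken by lower feature index, then lower threshold,
    so the fit is deterministic.
    """
    G = g[rows].sum()
    H = h[rows].sum()
    best = None
    for j in cols:
        xj = X[rows, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        gs = g[rows][order]
        hs = h[rows][order]
        gl = np.cumsum(gs)[:-1]
        hl = np.cumsum(hs)[:-1]
        # candidate split after position i iff the value strictly increases
        distinct = xs[1:] > xs[:-1]
        if not np.any(distinct):
            continue
        idx = np.flatnonzero(distinct)
        GL, HL = gl[idx], hl[idx]
        GR, HR = G - GL, H - HL
        gains = 0.5 * (GL**2 / (HL + lambda_) + GR**2 / (HR + lambda_)
                       - G**2 / (H + lambda_)) - gamma
        k = int(np.argmax(gains))
        gain = float(gains[k])
        thr = 0.5 * (xs[idx[k]] + xs[idx[k] + 1])
        if best is None or gain > best[0] + 1e-15:
            left_mask = xj < thr
            best = (gain, int(j), float(thr), rows[left_mask], rows[~left_mask])
    if best is None or best[0] <= 0:
        return None
    return best


@dataclass
class ReferenceBooster:
    """Boosted ensemble of exact-greedy regression trees (reference path)."""

    params: BoostingParams
    feature_names: list[str]
    base_margin: float = 0.0
    trees: list[TreeNode] = field(default_factory=list)
    feature_gain: dict[str, float] = field(default_factory=dict)

    def predict_margin(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        margin = np.full(len(X), self.base_margin)
        for tree in self.trees:
            for i in range(len(X)):
                node = tree
                while not node.is_leaf:
                    node = node.left if X[i, node.feature] < node.threshold else node.right
                margin[i] += node.weight
        return margin

    def predict(self, X) -> np.ndarray:
        """Predicted probability of the positive class."""
        return _sigmoid(self.predict_margin(X))

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": "reference",
            "params": asdict(self.params),
            "feature_names": self.feature_names,
            "base_margin": self.base_margin,
            "trees": [t.to_dict() for t in self.trees],
            "feature_gain": self.feature_gain,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceBooster":
        payload = json.loads(Path(path).read_text())
        return cls(
            params=BoostingParams(**payload["params"]),
            feature_names=payload["feature_names"],
            base_margin=payload["base_margin"],
            trees=[TreeNode.from_dict(t) for t in payload["trees"]],
            feature_gain=payload["feature_gain"],
        )


def _as_matrix(X, feature_names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            X = X[feature_names]
        return X.to_numpy(dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def _names_of(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return [f"f{j}" for j in range(np.asarray(X).shape[1])]


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    return y


def _build_tree(X, g, h, rows, cols, params: BoostingParams, depth: int,
                gain_acc: dict[int, float]) -> TreeNode:
    if depth < params.max_depth:
        found = _best_split(X, g, h, rows, cols, params.lambda_, params.gamma)
        if found is not None:
            gain, j, thr, left_rows, right_rows = found
            gain_acc[j] = gain_acc.get(j, 0.0) + gain
            node = TreeNode(feature=j, threshold=thr, gain=gain)
            node.left = _build_tree(X, g, h, left_rows, cols, params, depth + 1, gain_acc)
            node.right = _build_tree(X, g, h, right_rows, cols, params, depth + 1, gain_acc)
            return node
    G = g[rows].sum()
    H = h[rows].sum()
    return TreeNode(weight=params.eta * leaf_weight(G, H, params.lambda_))


def fit_reference_booster(X, y, params: BoostingParams | None = None,
                          seed: int = 0) -> ReferenceBooster:
    """Train the self-contained exact-greedy booster.

    The base score is the log-odds of the training prevalence. With
    subsample = colsample_bytree = 1 the fit is fully deterministic.
    """
    if params is None:
        params = BoostingParams()
    names = _names_of(X)
    Xm = _as_matrix(X)
    y = _check_labels(y)
    if len(Xm) < 2:
        raise ValueError("need at least 2 instances")
    rng = np.random.default_rng(seed)
    prevalence = float(np.mean(y))
    base_margin = float(np.log(prevalence / (1.0 - prevalence)))
    model = ReferenceBooster(params=params, feature_names=names, base_margin=base_margin)
    margin = np.full(len(Xm), base_margin)
    n, p = Xm.shape
    for _ in range(params.n_rounds):
        prob = _sigmoid(margin)
        g = prob - y
        h = prob * (1.0 - prob)
        if params.subsample < 1.0:
            rows = rng.choice(n, size=max(int(round(params.subsample * n)), 1),
                              replace=False)
            rows.sort()
        else:
            rows = np.arange(n)
        if params.colsample_bytree < 1.0:
            cols = rng.choice(p, size=max(int(round(params.colsample_bytree * p)), 1),
                              replace=False)
            cols.sort()
        else:
            cols = np.arange(p)
        gain_acc: dict[int, float] = {}
        tree = _build_tree(Xm, g, h, rows, cols, params, 0, gain_acc)
        model.trees.append(tree)
        for j, gain in gain_acc.items():
            name = names[j]
            model.feature_gain[name] = model.feature_gain.get(name, 0.0) + gain
        # update margins for all rows (subsampling affects tree building only)
        for i in range(n):
            node = tree
            while not node.is_leaf:
                node = node.left if Xm[i, node.feature] < node.threshold else node.right
            margin[i] += node.weight
    return model


# ---------------------------------------------------------------------------
# production path (xgboost-backed, same contract)
# ---------------------------------------------------------------------------

@dataclass
class ProductionModel:
    """xgboost-backed booster honouring the reference contract.

    tree_method=exact and min_child_weight=0 keep the split search aligned
    with the reference booster; the base score is the training prevalence.
    """

    booster: xgb.Booster
    params: BoostingParams
    feature_names: list[str]
    best_iteration: int
    validation_auc: float | None = None
    auc_trace: list[float] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        Xm = _as_matrix(X, self.feature_names)
        dm = xgb.DMatrix(Xm, feature_names=self.feature_names, nthread=1)
        return self.booster.predict(dm, iteration_range=(0, self.best_iteration + 1))

    @property
    def n_trees(self) -> int:
        return self.best_iteration + 1

    @property
    def feature_gain(self) -> dict[str, float]:
        return self.booster.get_score(importance_type="total_gain")

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        raw = self.booster.save_raw(raw_format="json").decode()
        payload = {
            "kind": "production",
            "params": asdict(self.params),
            "feature_names": self.feature_names,
            "best_iteration": self.best_iteration,
            "validation_auc": self.validation_auc,
            "booster": json.loads(raw),
        }
        path.write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProductionModel":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        return cls(
            booster=booster,
            params=BoostingParams(**payload["params"]),
            feature_names=payload["feature_names"],
            best_iteration=payload["best_iteration"],
            validation_auc=payload["validation_auc"],
        )


def _xgb_param_dict(params: BoostingParams, prevalence: float, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eval_metric": "auc",
        "eta": params.eta,
        "max_depth": params.max_depth,
        "subsample": params.subsample,
        "colsample_bytree": params.colsample_bytree,
        "lambda": params.lambda_,
        "gamma": params.gamma,
        "min_child_weight": 0,
        "tree_method": "exact",
        "base_score": prevalence,
        "seed": seed,
        "nthread": 1,
    }


def fit_production_model(X, y, params: BoostingParams | None = None,
                         validation: tuple | None = None,
                         seed: int = 0) -> ProductionModel:
    """Train the production booster, optionally with early stopping.

    ``validation`` is an (X_val, y_val) pair disjoint from the training
    data at patient level; boosting stops once validation AUC has not
    improved for ``early_stopping_patience`` rounds, and predictions use
    the best iteration.
    """
    if params is None:
        params = BoostingParams()
    names = _names_of(X)
    Xm = _as_matrix(X)
    y = _check_labels(y)
    prevalence = float(np.mean(y))
    dtrain = xgb.DMatrix(Xm, label=y, feature_names=names, nthread=1)
    xgb_params = _xgb_param_dict(params, prevalence, seed)
    evals_result: dict = {}
    if validation is not None:
        Xv, yv = validation
        dval = xgb.DMatrix(_as_matrix(Xv, names), label=np.asarray(yv, dtype=np.float64),
                           feature_names=names, nthread=1)
        booster = xgb.train(
            xgb_params, dtrain, num_boost_round=params.n_rounds,
            evals=[(dval, "validation")],
            early_stopping_rounds=params.early_stopping_patience,
            evals_result=evals_result, verbose_eval=False,
        )
        trace = [float(v) for v in evals_result["validation"]["auc"]]
        # best round = LAST iteration attaining the maximum validation AUC:
        # on ties (e.g. an early plateau at AUC 1.0) the longer-trained model
        # has larger margins, which keeps pooled probabilities comparable
        # across CV folds
        arr = np.asarray(trace)
        best_iter = int(len(arr) - 1 - np.argmax(arr[::-1]))
        val_auc = trace[best_iter]
    else:
        booster = xgb.train(xgb_params, dtrain, num_boost_round=params.n_rounds,
                            verbose_eval=False)
        trace = []
        best_iter = params.n_rounds - 1
        val_auc = None
    return ProductionModel(booster=booster, params=params, feature_names=names,
                           best_iteration=best_iter, validation_auc=val_auc,
                           auc_trace=trace)


def predict_ensemble(models: list, X) -> np.ndarray:
    """Arithmetic mean of the member models' predicted probabilities."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    return np.mean([m.predict(X) for m in models], axis=0)


def gain_importance(model_or_models, feature_order: list[str] | None = None
                    ) -> list[tuple[str, float]]:
    """Per-feature total split gain, summed over ensemble members, sorted
    descending; ties broken by canonical feature order."""
    models = model_or_models if isinstance(model_or_models, (list, tuple)) else [model_or_models]
    totals: dict[str, float] = {}
    for model in models:
        for name, gain in model.feature_gain.items():
            totals[name] = totals.get(name, 0.0) + float(gain)
    if feature_order is None:
        feature_order = models[0].feature_names
    order_index = {name: i for i, name in enumerate(feature_order)}
    return sorted(totals.items(),
                  key=lambda kv: (-kv[1], order_index.get(kv[0], len(order_index))))


def select_top_n(ranking: list[tuple[str, float]], n: int) -> list[str]:
    """First n feature names of a gain ranking (all of them if n exceeds)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [name for name, _ in ranking[:n]]


def save_importance(ranking: list[tuple[str, float]], path: str | Path) -> None:
    df = pd.DataFrame(ranking, columns=["feature", "gain"])
    df.insert(2, "rank", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
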