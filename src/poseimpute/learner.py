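"""Reference dual-head learner: pose score + affinity from one trunk.

The predictor contract is deliberately small — anything that maps a
per-pose feature vector to ``(pose_score in [0,1], affinity in pK)``
can drive the imputation engine.  The reference implementation is a
feed-forward network with two hidden ReLU layers and a shared trunk
feeding a logistic pose-classification head and a linear affinity
head.  The shared trunk matters: it couples the two tasks, which is
what lets extra (imputed) affinity labels move the pose-classification
behaviour as well.

Training is plain SGD with momentum and weight decay on balanced,
pocket-stratified batches under the combined hinged objective, with
early stopping driven by the loss on a fixed reduced subset of
training complexes: every ``eval_interval`` iterations the reduced-set
loss is recorded; after ``patience_evals`` evaluations without
improvement the learning rate divides by ``lr_drop_factor``; after
``max_lr_drops`` drops the next stall terminates training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import DatasetTable, is_missing
from .objective import LossConfig, make_balanced_batches

__all__ = [
    "TrainConfig",
    "EarlyStoppingSchedule",
    "ModelHandle",
    "DualHeadNet",
    "train_model",
    "predict_poses",
    "train_seed_ensemble",
    "ensemble_predict",
]


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule. Defaults are the full-scale schedule (evaluate the
    reduced set every 1000 iterations, patience 200 evaluations); use
    :meth:`desk` for the minutes-scale variant used on synthetic
    corpora."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.001
    batch_size: int = 50
    eval_interval: int = 1000
    patience_evals: int = 200
    lr_drop_factor: float = 10.0
    max_lr_drops: int = 3
    percent_reduced: float = 0.132
    max_iterations: int = 250_000
    hidden: Tuple[int, int] = (64, 64)
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        for name in ("learning_rate", "momentum", "weight_decay", "batch_size",
                     "eval_interval", "patience_evals", "lr_drop_factor",
                     "max_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.percent_reduced <= 1.0:
            raise ValueError("percent_reduced must lie in (0, 1]")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Minutes-scale schedule for small synthetic corpora."""
        params = dict(eval_interval=100, patience_evals=10,
                      max_iterations=20_000, seed=seed)
        params.update(overrides)
        return cls(**params)


class EarlyStoppingSchedule:
    """Patience-driven learning-rate ladder.

    Feed it one reduced-set loss per evaluation.  When the loss fails
    to improve for ``patience_evals`` consecutive evaluations the
    learning rate divides by ``lr_drop_factor``; once ``max_lr_drops``
    drops have been spent, the next stall stops training instead.
    """

    def __init__(self, initial_lr: float, patience_evals: int,
                 lr_drop_factor: float, max_lr_drops: int):
        self.lr = initial_lr
        self.patience_evals = patience_evals
        self.lr_drop_factor = lr_drop_factor
        self.max_lr_drops = max_lr_drops
        self.best = float("inf")
        self.evals_since_best = 0
        self.n_drops = 0
        self.stopped = False

    def update(self, loss: float) -> bool:
        """Record one evaluation; returns True when training must stop."""
        if self.stopped:
            return True
        if loss < self.best:
            self.best = loss
            self.evals_since_best = 0
        else:
            self.evals_since_best += 1
        if self.evals_since_best >= self.patience_evals:
            if self.n_drops >= self.max_lr_drops:
                self.stopped = True
                return True
            self.n_drops += 1
            self.lr /= self.lr_drop_factor
            self.evals_since_best = 0
        return False


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _init_params(rng: np.random.Generator, d: int,
                 hidden: Sequence[int]) -> Dict[str, np.ndarray]:
    h1, h2 = hidden
    return {
        "W1": rng.normal(scale=np.sqrt(2.0 / d), size=(d, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(scale=np.sqrt(2.0 / h1), size=(h1, h2)),
        "b2": np.zeros(h2),
        "w_pose": rng.normal(scale=np.sqrt(1.0 / h2), size=h2),
        "b_pose": np.zeros(1),
        "w_aff": rng.normal(scale=np.sqrt(1.0 / h2), size=h2),
        "b_aff": np.zeros(1),
    }


def _forward(params: Dict[str, np.ndarray], X: np.ndarray):
    a1 = X @ params["W1"] + params["b1"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ params["W2"] + params["b2"]
    h2 = np.maximum(a2, 0.0)
    logit = h2 @ params["w_pose"] + params["b_pose"][0]
    aff = h2 @ params["w_aff"] + params["b_aff"][0]
    score = 1.0 / (1.0 + np.exp(-logit))
    return h1, h2, score, aff


def _eval_loss(params, X, is_good, affinity, loss: LossConfig) -> float:
    """Combined loss over an arbitrary pose set (vectorized)."""
    _, _, score, aff = _forward(params, X)
    p = np.where(is_good, score, 1.0 - score)
    p = np.clip(p, loss.prob_floor, 1.0 - loss.prob_floor)
    pose_term = float(np.mean(-np.log(p)))
    labeled = np.isfinite(affinity)
    if labeled.any():
        d = aff[labeled] - affinity[labeled]
        d = np.where(is_good[labeled], d, np.maximum(d, 0.0))
        delta = loss.delta
        aff_term = float(np.mean(delta * delta *
                                 (np.sqrt(1.0 + (d / delta) ** 2) - 1.0)))
    else:
        aff_term = 0.0
    return loss.pose_weight * pose_term + loss.affinity_weight * aff_term


def _batch_gradients(params, X, is_good, affinity, loss: LossConfig):
    """Gradients of the combined batch loss (same formula the forward
    loss uses; clipped pose probabilities get zero gradient)."""
    n = len(X)
    h1, h2, score, aff = _forward(params, X)
    y = is_good.astype(float)

    p = np.where(is_good, score, 1.0 - score)
    in_range = (p > loss.prob_floor) & (p < 1.0 - loss.prob_floor)
    dlogit = loss.pose_weight * (score - y) * in_range / n

    labeled = np.isfinite(affinity)
    daff = np.zeros(n)
    n_labeled = int(labeled.sum())
    if n_labeled:
        d = aff - np.where(labeled, affinity, 0.0)
        hinge_active = is_good | (d > 0.0)
        dph = d / np.sqrt(1.0 + (d / loss.delta) ** 2)
        daff = loss.affinity_weight * np.where(
            labeled & hinge_active, dph, 0.0) / n_labeled

    grads: Dict[str, np.ndarray] = {}
    grads["w_pose"] = h2.T @ dlogit
    grads["b_pose"] = np.array([dlogit.sum()])
    grads["w_aff"] = h2.T @ daff
    grads["b_aff"] = np.array([daff.sum()])
    dh2 = (np.outer(dlogit, params["w_pose"])
           + np.outer(daff, params["w_aff"]))
    dh2 *= h2 > 0
    grads["W2"] = h1.T @ dh2
    grads["b2"] = dh2.sum(axis=0)
    dh1 = dh2 @ params["W2"].T
    dh1 *= h1 > 0
    grads["W1"] = X.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    return grads


@dataclass
class ModelHandle:
    """A fitted reference model: parameters, provenance and history.

    ``history`` rows are ``(iteration, reduced_set_loss, learning_rate)``.
    Predictions from a handle are deterministic.
    """

    params: Dict[str, np.ndarray]
    input_dim: int
    hidden: Tuple[int, int]
    seed: int
    loss: LossConfig
    history: List[Tuple[int, float, float]] = field(default_factory=list)

    def predict_arrays(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} features, got {X.shape[1]}")
        _, _, score, aff = _forward(self.params, X)
        return score, aff

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "architecture": {"input_dim": self.input_dim,
                             "hidden": list(self.hidden)},
            "seed": self.seed,
            "loss": asdict(self.loss),
            "history": [list(row) for row in self.history],
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ModelHandle":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            params={k: np.asarray(v) for k, v in doc["params"].items()},
            input_dim=doc["architecture"]["input_dim"],
            hidden=tuple(doc["architecture"]["hidden"]),
            seed=doc["seed"],
            loss=LossConfig(**doc["loss"]),
            history=[tuple(row) for row in doc["history"]],
        )

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history,
                            columns=["iteration", "loss", "lr"])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(train_table: DatasetTable, features: pd.DataFrame,
                config: TrainConfig) -> ModelHandle:
    """Fit the reference learner on a pose table.

    A reduced evaluation subset of ``percent_reduced`` of the training
    complexes is fixed at start (drawn complex-wise without
    replacement) and its combined loss drives the early-stopping
    ladder.  Deterministic given ``config.seed``.
    """
    n_good = sum(1 for r in train_table if r.is_good)
    if n_good == 0 or n_good == len(train_table):
        raise ValueError("training table must contain both pose classes")

    rng = np.random.default_rng(config.seed)
    d = features.shape[1]
    params = _init_params(rng, d, config.hidden)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}

    # fixed reduced evaluation subset, complex-wise
    complex_ids = sorted(train_table.complexes)
    n_reduced = max(1, int(round(config.percent_reduced * len(complex_ids))))
    reduced_cids = set(rng.choice(complex_ids, size=n_reduced, replace=False))
    reduced_recs = [r for r in train_table if r.complex_id in reduced_cids]
    Xr = features.loc[[r.pose_id for r in reduced_recs]].to_numpy(dtype=float)
    gr = np.array([r.is_good for r in reduced_recs])
    ar = np.array([r.affinity for r in reduced_recs])

    sampler = make_balanced_batches(train_table, features,
                                    batch_size=config.batch_size,
                                    seed=config.seed)
    schedule = EarlyStoppingSchedule(config.learning_rate,
                                     config.patience_evals,
                                     config.lr_drop_factor,
                                     config.max_lr_drops)
    history: List[Tuple[int, float, float]] = []

    loss0 = _eval_loss(params, Xr, gr, ar, config.loss)
    if not np.isfinite(loss0):
        raise FloatingPointError("non-finite loss at initialization")
    history.append((0, loss0, schedule.lr))
    schedule.update(loss0)

    for it in range(1, config.max_iterations + 1):
        batch = next(sampler)
        grads = _batch_gradients(params, batch.features, batch.is_good,
                                 batch.affinity, config.loss)
        for k in params:
            velocity[k] = (config.momentum * velocity[k]
                           - schedule.lr * (grads[k]
                                            + config.weight_decay * params[k]))
            params[k] = params[k] + velocity[k]
        if it % config.eval_interval == 0:
            loss = _eval_loss(params, Xr, gr, ar, config.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reduced-set loss at iteration {it}")
            history.append((it, loss, schedule.lr))
            if schedule.update(loss):
                break

    return ModelHandle(params=params, input_dim=d, hidden=config.hidden,
                       seed=config.seed, loss=config.loss, history=history)


def predict_poses(model: ModelHandle, table: DatasetTable,
                  features: pd.DataFrame) -> pd.DataFrame:
    """Per-pose predictions: DataFrame indexed by pose_id with columns
    ``pose_score`` (in [0, 1]) and ``affinity_pred`` (pK)."""
    missing = [p for p in table.pose_ids if p not in features.index]
    if missing:
        raise KeyError(f"features missing rows for poses {missing[:3]}...")
    X = features.loc[table.pose_ids].to_numpy(dtype=float)
    score, aff = model.predict_arrays(X)
    return pd.DataFrame(
        {"pose_score": score, "affinity_pred": aff},
        index=pd.Index(table.pose_ids, name="pose_id"),
    )


def train_seed_ensemble(train_table: DatasetTable, features: pd.DataFrame,
                        base_config: TrainConfig,
                        seeds: Sequence[int]) -> List[ModelHandle]:
    """One independently trained model per seed, order preserved."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    return [
        train_model(train_table, features, replace(base_config, seed=int(s)))
        for s in seeds
    ]


def ensemble_predict(models: Sequence[ModelHandle], table: DatasetTable,
                     features: pd.DataFrame,
                     reduce: str = "mean") -> pd.DataFrame:
    """Per-pose arithmetic mean of pose_score and affinity_pred across
    models."""
    if not models:
        raise ValueError("empty model list")
    if reduce != "mean":
        raise ValueError(f"unknown reduction {reduce!r}")
    tables = [predict_poses(m, table, features) for m in models]
    out = tables[0].copy()
    for t in tables[1:]:
        out += t
    return out / len(tables)


# ---------------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------------

class DualHeadNet(BaseEstimator):
    """sklearn-style facade over the reference learner for array users.

    ``fit(X, y)`` takes ``y`` of shape (n, 2): column 0 the good-pose
    flag (0/1), column 1 the affinity in pK with NaN for missing
    labels.  Optional ``groups`` (pocket per row) and ``complex_ids``
    control stratification and label sharing; by default each row is
    its own complex in one shared pocket.

    Fitted attributes: ``handle_`` (the trained :class:`ModelHandle`),
    ``history_`` and ``n_iterations_``.  ``predict`` returns an (n, 2)
    array ``[pose_score, affinity_pred]``.
    """

    def __init__(self, learning_rate: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.001, batch_size: int = 50,
                 eval_interval: int = 100, patience_evals: int = 10,
                 lr_drop_factor: float = 10.0, max_lr_drops: int = 3,
                 percent_reduced: float = 0.132,
                 max_iterations: int = 20_000,
                 hidden: Tuple[int, int] = (64, 64),
                 random_state: int = 0):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.eval_interval = eval_interval
        self.patience_evals = patience_evals
        self.lr_drop_factor = lr_drop_factor
        self.max_lr_drops = max_lr_drops
        self.percent_reduced = percent_reduced
        self.max_iterations = max_iterations
        self.hidden = hidden
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            eval_interval=self.eval_interval,
            patience_evals=self.patience_evals,
            lr_drop_factor=self.lr_drop_factor,
            max_lr_drops=self.max_lr_drops,
            percent_reduced=self.percent_reduced,
            max_iterations=self.max_iterations, hidden=tuple(self.hidden),
            seed=self.random_state,
        )

    def fit(self, X, y, groups=None, complex_ids=None):
        from .corpus import (MISSING, SOURCE_EXPERIMENTAL, SOURCE_MISSING,
                             PoseRecord)

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must have shape (n, 2): [is_good, affinity]")
        n = len(X)
        groups = (["pocket"] * n if groups is None
                  else [str(g) for g in groups])
        complex_ids = ([f"cx{i}" for i in range(n)] if complex_ids is None
                       else [str(c) for c in complex_ids])
        records = []
        for i in range(n):
            good = bool(y[i, 0])
            aff = float(y[i, 1])
            missing = not np.isfinite(aff)
            records.append(PoseRecord(
                pose_id=f"row{i}",
                pocket_id=groups[i],
                complex_id=f"{groups[i]}/{complex_ids[i]}",
                rmsd=1.0 if good else 5.0,  # stand-in consistent with flag
                is_good=good,
                affinity=MISSING if missing else aff,
                affinity_source=SOURCE_MISSING if missing
                else SOURCE_EXPERIMENTAL,
            ))
        table = DatasetTable(records)
        features = pd.DataFrame(
            X, index=pd.Index([f"row{i}" for i in range(n)], name="pose_id"))
        self.handle_ = train_model(table, features, self._config())
        self.history_ = self.handle_.history
        self.n_iterations_ = self.handle_.history[-1][0]
        return self

    def predict(self, X):
        score, aff = self.handle_.predict_arrays(np.asarray(X, dtype=float))
        return np.column_stack([score, aff])
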