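"""Self-training label imputation: schemes, fractions, and rounds.

Eight imputation schemes fill missing affinity labels from model
predictions.  Two are per-pose: *individual* keeps each seed model's
raw per-pose predictions (each seed then trains on its own labels) and
*individual_ensemble* averages the seeds into one per-pose label.  The
remaining six are per-complex: for each seed, take the median, max or
min of that seed's predicted affinities over the complex's poses —
optionally restricted to good (RMSD < 2 Å) poses — then average the
per-seed values into a single label shared by every pose of the
complex, just as an experimental label would be.

Good-only variants exist because the hinged training loss pushes
predictions on bad poses down, so statistics over all poses are
dragged toward artificially low affinities.

The iterative loop is: train a seed ensemble on the labeled data,
impute the missing labels, rebuild the training set, retrain from
scratch, and repeat until the test-set RMSE stops improving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import (
    DatasetTable,
    SOURCE_MISSING,
    apply_imputed_labels,
)
from .learner import (
    ModelHandle,
    TrainConfig,
    predict_poses,
    train_model,
)
from . import evaluation

SCHEME_NAMES = (
    "individual",
    "individual_ensemble",
    "median_ensemble",
    "median_good_only_ensemble",
    "max_ensemble",
    "max_good_only_ensemble",
    "min_ensemble",
    "min_good_only_ensemble",
)


@dataclass(frozen=True)
class ImputationScheme:
    """One of the eight label-imputation schemes (see module docstring)."""

    name: str

    def __post_init__(self):
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}; "
                             f"choose from {SCHEME_NAMES}")

    @property
    def granularity(self) -> str:
        return ("per_pose"
                if self.name in ("individual", "individual_ensemble")
                else "per_complex")

    @property
    def statistic(self) -> str:
        if self.granularity == "per_pose":
            return "none"
        return self.name.split("_", 1)[0]  # median | max | min

    @property
    def good_only(self) -> bool:
        return "good_only" in self.name


@dataclass(frozen=True)
class ImputationPlan:
    """One self-training experiment: scheme, rounds, label fraction."""

    scheme: ImputationScheme
    n_seeds: int = 5
    max_rounds: int = 1
    fraction: float = 1.0
    fraction_seed: int = 0
    stop_metric: str = "test_rmse"
    clamp_low: float = 2.0
    clamp_high: float = 12.0

    def __post_init__(self):
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.stop_metric != "test_rmse":
            raise ValueError("only test_rmse stopping is supported")


def aggregate_complex(
    pose_predictions: Sequence[Tuple[float, bool]],
    statistic: str,
    good_only: bool,
) -> Tuple[float, bool]:
    """Aggregate one complex's per-pose predicted affinities.

    *pose_predictions* is ``[(affinity_pred, is_good), ...]``.  With
    ``good_only`` the statistic runs over good poses; when the complex
    has none, it falls back to the all-pose statistic and flags
    ``fallback_used=True``.  Median of an even count is the midpoint of
    the two central values.
    """
    if not pose_predictions:
        raise ValueError("empty pose prediction list")
    if statistic not in ("median", "max", "min"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = [v for v, _ in pose_predictions]
    fallback = False
    if good_only:
        good_values = [v for v, g in pose_predictions if g]
        if good_values:
            values = good_values
        else:
            fallback = True
    agg = {"median": np.median, "max": np.max, "min": np.min}[statistic]
    return float(agg(values)), fallback


@dataclass
class ImputedLabels:
    """Imputation output plus provenance.

    Per-complex schemes fill ``mapping`` (complex_id -> pK) and
    ``fallback`` (complex_id -> whether the good-only fallback fired).
    ``individual_ensemble`` fills ``mapping`` keyed by pose_id.  The
    ``individual`` scheme fills ``per_seed`` instead: one pose-keyed
    mapping per seed, producing per-seed training sets.
    """

    scheme: ImputationScheme
    mode: str  # per_pose | per_complex
    mapping: Optional[Dict[str, float]] = None
    per_seed: Optional[List[Dict[str, float]]] = None
    fallback: Dict[str, bool] = field(default_factory=dict)

    def write(self, path, round_index: int = 0) -> None:
        key = "complex_id" if self.mode == "per_complex" else "pose_id"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{key},affinity,scheme,round,seed,fallback_used\n")
            if self.per_seed is not None:
                for s, mapping in enumerate(self.per_seed):
                    for k in sorted(mapping):
                        fh.write(f"{k},{mapping[k]:.4f},{self.scheme.name},"
                                 f"{round_index},{s},\n")
            else:
                for k in sorted(self.mapping):
                    fb = self.fallback.get(k, "")
                    fh.write(f"{k},{self.mapping[k]:.4f},{self.scheme.name},"
                             f"{round_index},,{fb}\n")


def impute_labels(
    per_seed_predictions: Sequence[pd.DataFrame],
    table: DatasetTable,
    scheme: ImputationScheme,
    clamp: Tuple[float, float] = (2.0, 12.0),
) -> ImputedLabels:
    """Impute labels for every unlabeled complex of *table*.

    *per_seed_predictions* is one prediction table per seed model
    (indexed by pose_id with column ``affinity_pred``; ``is_good``
    comes from the pose table, not the model).  Values are clamped to
    the physically plausible pK range.  Only unlabeled complexes are
    imputed; labeled ones are untouched by construction.
    """
    if not per_seed_predictions:
        raise ValueError("need at least one prediction table")
    unlabeled = table.unlabeled_complexes()
    lo, hi = clamp

    def _clamp(x: float) -> float:
        return min(max(float(x), lo), hi)

    def _seed_mean(values) -> float:
        # exact when all seeds agree (e.g. an oracle predictor), so a
        # perfect prediction round-trips to the label bit-for-bit
        if all(v == values[0] for v in values):
            return float(values[0])
        return float(np.mean(values))

    for preds in per_seed_predictions:
        for cid in unlabeled:
            missing = [p for p in table.complexes[cid]
                       if p not in preds.index]
            if missing:
                raise ValueError(
                    f"predictions missing poses {missing[:3]} of {cid!r}")

    if scheme.name == "individual":
        per_seed = []
        for preds in per_seed_predictions:
            mapping = {}
            for cid in unlabeled:
                for pid in table.complexes[cid]:
                    mapping[pid] = _clamp(preds.at[pid, "affinity_pred"])
            per_seed.append(mapping)
        return ImputedLabels(scheme=scheme, mode="per_pose",
                             per_seed=per_seed)

    if scheme.name == "individual_ensemble":
        mapping = {}
        for cid in unlabeled:
            for pid in table.complexes[cid]:
                mean = _seed_mean([p.at[pid, "affinity_pred"]
                                   for p in per_seed_predictions])
                mapping[pid] = _clamp(mean)
        return ImputedLabels(scheme=scheme, mode="per_pose", mapping=mapping)

    # per-complex ensemble schemes: aggregate per seed, then average seeds
    mapping = {}
    fallback: Dict[str, bool] = {}
    for cid in unlabeled:
        pose_ids = table.complexes[cid]
        flags = [table.get(p).is_good for p in pose_ids]
        per_seed_values = []
        fb_any = False
        for preds in per_seed_predictions:
            pairs = [(float(preds.at[p, "affinity_pred"]), g)
                     for p, g in zip(pose_ids, flags)]
            value, fb = aggregate_complex(pairs, scheme.statistic,
                                          scheme.good_only)
            per_seed_values.append(value)
            fb_any = fb_any or fb
        mapping[cid] = _clamp(_seed_mean(per_seed_values))
        fallback[cid] = fb_any
    return ImputedLabels(scheme=scheme, mode="per_complex",
                         mapping=mapping, fallback=fallback)


def select_fraction(
    imputed: Mapping[str, float], fraction: float, seed: int = 0
) -> Dict[str, float]:
    """Uniformly random sub-mapping of exactly ``round(fraction * n)``
    keys, nested across fractions under one seed (the 20% subset is
    contained in the 40% subset, and so on)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    keys = sorted(imputed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_take = int(round(fraction * len(keys)))
    chosen = [keys[i] for i in order[:n_take]]
    return {k: imputed[k] for k in chosen}


@dataclass
class RoundRecord:
    round_index: int
    per_seed_rmse: List[float]
    mean_rmse: float
    metrics: Dict[str, float]
    n_imputed: int
    n_fallback: int


@dataclass
class RoundHistory:
    """Per-round metrics of one self-training run; round 0 is the
    no-imputation baseline."""

    rounds: List[RoundRecord] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def mean_rmse_trace(self) -> List[float]:
        return [r.mean_rmse for r in self.rounds]

    def to_json(self, path=None) -> str:
        doc = {
            "stop_reason": self.stop_reason,
            "rounds": [
                {
                    "round": r.round_index,
                    "per_seed_rmse": r.per_seed_rmse,
                    "mean_rmse": r.mean_rmse,
                    "metrics": r.metrics,
                    "n_imputed": r.n_imputed,
                    "n_fallback": r.n_fallback,
                }
                for r in self.rounds
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def run_rounds(
    train_table: DatasetTable,
    test_table: DatasetTable,
    features: pd.DataFrame,
    plan: ImputationPlan,
    train_config: TrainConfig,
    seeds: Sequence[int],
    out_dir=None,
    train_fn: Callable = None,
    predict_fn: Callable = None,
) -> RoundHistory:
    """Iterative train -> impute -> retrain loop.

    Round 0 trains the seed ensemble on the original labels and records
    test metrics.  Each later round re-imputes *all* missing labels
    with the previous round's models, applies the plan's fraction,
    rebuilds the training table and retrains from scratch (each round's
    models get fresh, round-derived seeds).  Stops when the mean
    per-seed test RMSE fails to improve on the previous round, or at
    ``max_rounds``.  ``train_fn`` / ``predict_fn`` exist to inject stub
    learners in tests.

    Train and test tables must be pocket-disjoint (clustered folds
    guarantee this for real splits).
    """
    leaked = set(train_table.pockets) & set(test_table.pockets)
    if leaked:
        raise ValueError(f"pockets straddle train/test: {sorted(leaked)[:5]}")
    if len(set(seeds)) != plan.n_seeds:
        raise ValueError("seeds must be distinct and match plan.n_seeds")

    if train_fn is None:
        train_fn = lambda table, cfg: train_model(table, features, cfg)
    if predict_fn is None:
        predict_fn = lambda model, table: predict_poses(model, table, features)

    def round_seeds(r: int) -> List[int]:
        # fresh models each round ("five new models"), still deterministic
        return [int((s + 10007 * r) % (2 ** 31)) for s in seeds]

    def fit_ensemble(tables: List[DatasetTable], r: int) -> List[ModelHandle]:
        cfgs = [dc_replace(train_config, seed=s) for s in round_seeds(r)]
        return [train_fn(t, c) for t, c in zip(tables, cfgs)]

    history = RoundHistory()
    baseline_tables = [train_table] * plan.n_seeds
    models = fit_ensemble(baseline_tables, 0)
    per_seed_rmse, metrics = _evaluate_round(models, test_table, features,
                                             predict_fn)
    history.rounds.append(RoundRecord(0, per_seed_rmse,
                                      float(np.mean(per_seed_rmse)),
                                      metrics, 0, 0))
    _persist_round(out_dir, history, None, 0)

    for r in range(1, plan.max_rounds + 1):
        preds = [predict_fn(m, train_table) for m in models]
        imputed = impute_labels(preds, train_table, plan.scheme,
                                clamp=(plan.clamp_low, plan.clamp_high))

        if imputed.per_seed is not None:  # individual: per-seed tables
            seed_tables = []
            for mapping in imputed.per_seed:
                mapping = select_fraction(mapping, plan.fraction,
                                          plan.fraction_seed)
                seed_tables.append(
                    apply_imputed_labels(train_table, mapping, "per_pose"))
            n_imputed = len(imputed.per_seed[0])
        else:
            mapping = select_fraction(imputed.mapping, plan.fraction,
                                      plan.fraction_seed)
            mode = imputed.mode
            shared = apply_imputed_labels(train_table, mapping, mode)
            seed_tables = [shared] * plan.n_seeds
            n_imputed = len(mapping)

        models_r = fit_ensemble(seed_tables, r)
        per_seed_rmse, metrics = _evaluate_round(models_r, test_table,
                                                 features, predict_fn)
        mean_rmse = float(np.mean(per_seed_rmse))
        n_fallback = sum(bool(v) for v in imputed.fallback.values())
        history.rounds.append(RoundRecord(r, per_seed_rmse, mean_rmse,
                                          metrics, n_imputed, n_fallback))
        _persist_round(out_dir, history, imputed, r)

        if mean_rmse >= history.rounds[-2].mean_rmse:
            history.stop_reason = "no improvement"
            break
        models = models_r
    else:
        history.stop_reason = "max rounds"

    if out_dir is not None:
        import pathlib
        history.to_json(pathlib.Path(out_dir) / "history.json")
    return history


def _evaluate_round(models, test_table, features, predict_fn):
    per_seed_rmse = []
    pred_tables = []
    for m in models:
        preds = predict_fn(m, test_table)
        pred_tables.append(preds)
        cands = evaluation.select_top_pose(preds, test_table)
        rmse, _, _ = evaluation.affinity_metrics(cands)
        per_seed_rmse.append(rmse)
    ens = sum(pred_tables[1:], pred_tables[0].copy()) / len(pred_tables)
    cands = evaluation.select_top_pose(ens, test_table)
    rmse, r, r2 = evaluation.affinity_metrics(cands)
    auc, top1 = evaluation.pose_metrics(ens, test_table, cands)
    return per_seed_rmse, {
        "ensemble_rmse": rmse, "ensemble_pearson_r": r,
        "ensemble_r_squared": r2, "auc": auc, "top1": top1,
    }


def _persist_round(out_dir, history: RoundHistory,
                   imputed: Optional[ImputedLabels], r: int) -> None:
    if out_dir is None:
        return
    import pathlib
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if imputed is not None:
        imputed.write(out / f"round{r}.labels", round_index=r)
    history.to_json(out / "history.json")
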