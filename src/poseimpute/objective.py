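"""Training objective: hinged pseudo-Huber affinity loss, logistic pose
loss, their combination, and the balanced pocket-stratified sampler.

The affinity loss is asymmetric in pose quality.  For a good pose
(RMSD < 2 Å) the pseudo-Huber penalty applies to the signed error in
both directions; for a bad pose the loss is *hinged* — zero whenever
the model under-predicts the label, penalizing only over-prediction,
because a bad pose should not be rewarded with a high predicted
affinity.  The same rule applies whether the label is experimental or
imputed.  Poses with a MISSING label contribute nothing to the
affinity term and are excluded from its normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import DatasetTable, is_missing


@dataclass(frozen=True)
class LossConfig:
    """Knobs of the combined objective.

    delta is the pseudo-Huber transition scale in pK units: errors well
    below delta are penalized quadratically, errors well above it
    linearly.  The default 4.0 keeps the loss quadratic over typical pK
    errors (a 4-log-unit error is already enormous).
    """

    delta: float = 4.0
    pose_weight: float = 1.0
    affinity_weight: float = 1.0
    prob_floor: float = 1e-6

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.pose_weight < 0 or self.affinity_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if not 0.0 < self.prob_floor < 0.5:
            raise ValueError("prob_floor must lie in (0, 0.5)")


def pseudo_huber(d, delta: float = 4.0):
    """Pseudo-Huber penalty  delta^2 (sqrt(1 + (d/delta)^2) - 1).

    Quadratic (~d^2/2) for |d| << delta, linear (~delta*|d|) for
    |d| >> delta; even in d and strictly increasing in |d|.  Accepts a
    scalar or array.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("d must be finite")
    out = delta * delta * (np.sqrt(1.0 + (d / delta) ** 2) - 1.0)
    return float(out) if out.ndim == 0 else out


def affinity_loss(pred: float, label: float, is_good: bool,
                  config: LossConfig = LossConfig()) -> float:
    """Hinged pseudo-Huber affinity loss for one pose.

    MISSING label -> 0 (the pose is also excluded from the affinity
    normalization in a batch).  Good pose -> symmetric pseudo-Huber on
    pred - label.  Bad pose -> pseudo-Huber on max(0, pred - label):
    under-prediction is free, over-prediction is penalized.
    """
    if not math.isfinite(pred):
        raise ValueError("pred must be finite")
    if is_missing(label):
        return 0.0
    d = pred - label
    if not is_good:
        d = max(0.0, d)
    return pseudo_huber(d, config.delta)


def pose_loss(prob_good: float, is_good: bool,
              config: LossConfig = LossConfig()) -> float:
    """Logistic (cross-entropy) pose-classification loss, clipped."""
    if not 0.0 <= prob_good <= 1.0:
        raise ValueError(f"prob_good must lie in [0, 1], got {prob_good}")
    p = prob_good if is_good else 1.0 - prob_good
    p = min(max(p, config.prob_floor), 1.0 - config.prob_floor)
    return -math.log(p)


@dataclass
class Batch:
    """One training minibatch; exactly half good, half bad poses."""

    pose_ids: List[str]
    features: np.ndarray
    is_good: np.ndarray
    affinity: np.ndarray  # NaN where MISSING
    complex_ids: List[str]
    pocket_ids: List[str]

    def __post_init__(self):
        n = len(self.pose_ids)
        if not (len(self.features) == len(self.is_good) == len(self.affinity)
                == len(self.complex_ids) == len(self.pocket_ids) == n):
            raise ValueError("batch fields misaligned")
        n_good = int(np.sum(self.is_good))
        if n_good * 2 != n:
            raise ValueError(
                f"batch not class-balanced: {n_good} good of {n}"
            )


def combined_batch_loss(
    predictions: Sequence[Tuple[float, float]],
    batch: Batch,
    config: LossConfig = LossConfig(),
) -> Tuple[float, Dict[str, float]]:
    """pose_weight * mean(pose losses) + affinity_weight * mean(affinity
    losses over labeled poses).

    *predictions* is per-pose ``(prob_good, affinity_pred)`` aligned to
    the batch.  If no pose in the batch carries a label the affinity
    term is 0.  Returns (total, breakdown).
    """
    if len(predictions) != len(batch.pose_ids):
        raise ValueError("predictions misaligned with batch")
    pose_terms = [
        pose_loss(p, bool(g), config)
        for (p, _), g in zip(predictions, batch.is_good)
    ]
    aff_terms = [
        affinity_loss(a, lab, bool(g), config)
        for (_, a), g, lab in zip(predictions, batch.is_good, batch.affinity)
        if not is_missing(float(lab))
    ]
    pose_term = float(np.mean(pose_terms))
    aff_term = float(np.mean(aff_terms)) if aff_terms else 0.0
    total = config.pose_weight * pose_term + config.affinity_weight * aff_term
    return total, {
        "pose_term": pose_term,
        "affinity_term": aff_term,
        "n_labeled": len(aff_terms),
        "total": total,
    }


def make_balanced_batches(
    table: DatasetTable,
    features: pd.DataFrame,
    batch_size: int = 50,
    seed: int = 0,
) -> Iterator[Batch]:
    """Infinite iterator of class-balanced, pocket-stratified batches.

    Each batch holds exactly batch_size/2 good and batch_size/2 bad
    poses.  Each slot is filled by drawing a pocket uniformly at random
    (among pockets possessing the required class) and then a pose of
    that class within the pocket uniformly, with replacement — so the
    minority class (good poses, typically ~4% of a cross-docked corpus)
    is upsampled and every pocket is sampled evenly regardless of size.
    Deterministic given *seed*.
    """
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even")
    half = batch_size // 2

    good_by_pocket: Dict[str, List[str]] = {}
    bad_by_pocket: Dict[str, List[str]] = {}
    for rec in table:
        target = good_by_pocket if rec.is_good else bad_by_pocket
        target.setdefault(rec.pocket_id, []).append(rec.pose_id)
    if not good_by_pocket or not bad_by_pocket:
        raise ValueError("table must contain at least one good and one bad pose")

    good_pockets = sorted(good_by_pocket)
    bad_pockets = sorted(bad_by_pocket)
    feat = features.loc[table.pose_ids]
    feat_idx = {pid: i for i, pid in enumerate(feat.index)}
    X = feat.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def draw(pockets: List[str], pool: Dict[str, List[str]]) -> str:
        pocket = pockets[int(rng.integers(len(pockets)))]
        poses = pool[pocket]
        return poses[int(rng.integers(len(poses)))]

    def emit() -> Batch:
        ids = [draw(good_pockets, good_by_pocket) for _ in range(half)]
        ids += [draw(bad_pockets, bad_by_pocket) for _ in range(half)]
        recs = [table.get(pid) for pid in ids]
        return Batch(
            pose_ids=ids,
            features=X[[feat_idx[p] for p in ids]],
            is_good=np.array([r.is_good for r in recs]),
            affinity=np.array([r.affinity for r in recs]),
            complex_ids=[r.complex_id for r in recs],
            pocket_ids=[r.pocket_id for r in recs],
        )

    while True:
        yield emit()
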