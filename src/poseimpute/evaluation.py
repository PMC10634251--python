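"""Pose selection, affinity/pose metrics and significance machinery.

Evaluation follows the pose-selection protocol: per pocket–ligand
complex, the single candidate pose is the one with the highest
predicted pose score; affinity metrics (RMSE, Pearson's R, R²) are
computed over the candidates of labeled complexes only.  Pose metrics
are the ROC AUC of good-vs-bad separation by pose score over all test
poses, and Top1 — the fraction of complexes whose candidate lies
within 2 Å RMSD of the crystal pose.

Significance tools: percentile bootstrap CI of a mean, a two-sample
Student's t-test between rounds, and a 10,000-replicate bootstrap of
the RMSE with the overlapping-CI significance rule plus a one-tailed
bootstrap p-value on the difference of means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import GOOD_RMSD_THRESHOLD, DatasetTable, is_missing

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    pearson_r: float
    r_squared: float
    pearson_r_squared: float
    auc: float
    top1: float
    n_complexes_evaluated: int
    rmse_ci: Tuple[float, float] | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def select_top_pose(predictions: pd.DataFrame,
                    table: DatasetTable) -> pd.DataFrame:
    """One candidate pose per complex: the highest pose score.

    Exact ties break to the lexicographically smallest pose_id (logged).
    Returns a DataFrame indexed by complex_id with columns pose_id,
    pose_score, affinity_pred, rmsd, label (NaN where unlabeled).
    """
    rows = {}
    for cid, pose_ids in table.complexes.items():
        missing = [p for p in pose_ids if p not in predictions.index]
        if missing:
            raise KeyError(f"complex {cid!r} lacks predictions for "
                           f"{missing[:3]}")
        scores = predictions.loc[pose_ids, "pose_score"]
        best = scores.max()
        tied = sorted(scores.index[scores == best])
        if len(tied) > 1:
            logger.info("pose-score tie in %s: %s; taking %s",
                        cid, tied, tied[0])
        pid = tied[0]
        rec = table.get(pid)
        rows[cid] = {
            "pose_id": pid,
            "pose_score": float(predictions.at[pid, "pose_score"]),
            "affinity_pred": float(predictions.at[pid, "affinity_pred"]),
            "rmsd": rec.rmsd,
            "label": table.complex_affinity(cid),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "complex_id"
    return out


def affinity_metrics(candidates: pd.DataFrame) -> Tuple[float, float, float]:
    """(RMSE, Pearson R, R²) over labeled candidate complexes.

    R² is the coefficient of determination 1 - SS_res/SS_tot; the
    squared Pearson correlation is available via
    :func:`metrics_report`.
    """
    labeled = candidates.dropna(subset=["label"])
    if len(labeled) < 2:
        raise ValueError("need >= 2 labeled complexes")
    y = labeled["label"].to_numpy(dtype=float)
    yhat = labeled["affinity_pred"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("labels are constant; correlation undefined")
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    r = float(stats.pearsonr(yhat, y).statistic)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return rmse, r, 1.0 - ss_res / ss_tot


def pose_metrics(predictions: pd.DataFrame, table: DatasetTable,
                 candidates: pd.DataFrame) -> Tuple[float, float]:
    """(AUC, Top1).

    AUC is the rank-based probability that a random good pose outscores
    a random bad pose (ties count 1/2), over all poses of the table.
    Top1 is the fraction of complexes whose candidate has RMSD < 2 Å.
    """
    flags = np.array([table.get(p).is_good for p in table.pose_ids])
    if flags.all() or not flags.any():
        raise ValueError("AUC undefined: only one pose class present")
    scores = predictions.loc[table.pose_ids, "pose_score"].to_numpy(float)
    n_pos = int(flags.sum())
    n_neg = len(flags) - n_pos
    # Mann–Whitney U from midranks handles ties at 1/2 exactly
    ranks = stats.rankdata(scores)
    u = float(ranks[flags].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    top1 = float((candidates["rmsd"] < GOOD_RMSD_THRESHOLD).mean())
    return auc, top1


def metrics_report(predictions: pd.DataFrame, table: DatasetTable,
                   n_boot: int = 10_000, seed: int = 0) -> MetricsReport:
    """Full report for one prediction table, with a bootstrap RMSE CI."""
    candidates = select_top_pose(predictions, table)
    rmse, r, r2 = affinity_metrics(candidates)
    auc, top1 = pose_metrics(predictions, table, candidates)
    labeled = candidates.dropna(subset=["label"])
    resid = (labeled["affinity_pred"] - labeled["label"]).to_numpy(float)
    lo, hi = _bootstrap_rmse_dist(resid, n_boot,
                                  np.random.default_rng(seed))
    return MetricsReport(
        rmse=rmse, pearson_r=r, r_squared=r2, pearson_r_squared=r * r,
        auc=auc, top1=top1, n_complexes_evaluated=len(labeled),
        rmse_ci=(lo, hi),
    )


# ---------------------------------------------------------------------------
# significance machinery
# ---------------------------------------------------------------------------

def bootstrap_ci_mean(values: Sequence[float], n_boot: int = 10_000,
                      alpha: float = 0.05,
                      seed: int = 0) -> Tuple[float, float, float]:
    """(mean, lower, upper): percentile bootstrap CI of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    if np.all(values == values[0]):
        # exact zero-width interval at the constant
        v = float(values[0])
        return v, v, v
    rng = np.random.default_rng(seed)
    idx = rng.integers(values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(values.mean()), float(lo), float(hi)


def compare_rounds_ttest(metrics_a: Sequence[float],
                         metrics_b: Sequence[float]) -> float:
    """Two-sided p-value of an unpaired, pooled-variance Student's
    t-test between two groups of per-model metric values."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate: identical spread-free groups
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def _bootstrap_rmse_dist(residuals: np.ndarray, n_boot: int,
                         rng: np.random.Generator,
                         alpha: float = 0.05) -> Tuple[float, float]:
    idx = rng.integers(residuals.size, size=(n_boot, residuals.size))
    rmses = np.sqrt(np.mean(residuals[idx] ** 2, axis=1))
    lo, hi = np.percentile(rmses, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RmseComparison:
    rmse_a: float
    rmse_b: float
    ci_a: Tuple[float, float]
    ci_b: Tuple[float, float]
    significant: bool
    one_tailed_p: float
    n_boot: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def bootstrap_rmse_compare(errors_a: Sequence[float],
                           errors_b: Sequence[float],
                           n_boot: int = 10_000, alpha: float = 0.05,
                           seed: int = 0) -> RmseComparison:
    """Bootstrap RMSE comparison between two residual vectors.

    Complexes are resampled with replacement ``n_boot`` times per
    vector; ``significant`` means the two 95% percentile intervals do
    not overlap.  ``one_tailed_p`` is the bootstrap probability that
    the apparent ordering of the two RMSEs reverses (a one-tailed test
    on the difference of means of the bootstrap RMSE distributions).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("residual vectors must be non-empty")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(a.size, size=(n_boot, a.size))
    idx_b = rng.integers(b.size, size=(n_boot, b.size))
    rmse_a_dist = np.sqrt(np.mean(a[idx_a] ** 2, axis=1))
    rmse_b_dist = np.sqrt(np.mean(b[idx_b] ** 2, axis=1))
    lo_a, hi_a = np.percentile(rmse_a_dist,
                               [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo_b, hi_b = np.percentile(rmse_b_dist,
                               [100 * alpha / 2, 100 * (1 - alpha / 2)])
    rmse_a = float(np.sqrt(np.mean(a ** 2)))
    rmse_b = float(np.sqrt(np.mean(b ** 2)))
    significant = bool(hi_a < lo_b or hi_b < lo_a)
    diff = rmse_a_dist - rmse_b_dist
    if rmse_a > rmse_b:
        p = float(np.mean(diff <= 0.0))
    else:
        p = float(np.mean(diff >= 0.0))
    return RmseComparison(
        rmse_a=rmse_a, rmse_b=rmse_b,
        ci_a=(float(lo_a), float(hi_a)), ci_b=(float(lo_b), float(hi_b)),
        significant=significant, one_tailed_p=p, n_boot=n_boot,
    )
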