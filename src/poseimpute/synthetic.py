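"""Seeded synthetic pose corpora with the structure self-training assumes.

The generator emulates a cross-docked pose collection: many poses per
pocket–ligand complex, a small good-pose fraction, one latent pK per
complex shared by all of its poses, and a feature vector whose affinity
information is *attenuated by pose quality* — a high-RMSD pose carries
little signal about the true pK, which is what makes good-only label
aggregation meaningfully different from all-pose aggregation.

Per pose the feature vector is

    x = signal_weight * pK * q * u  +  quality_weight * q * v  +  eps

with q = exp(-rmsd / 2) the latent pose quality, u and v fixed random
unit directions drawn once per corpus, and eps isotropic Gaussian noise.
A linear read-out can therefore recover pK * q and q, from which pK is
approximately linearly decodable on good poses (q large and narrow).

Label hiding is a separate step so that the fully labeled corpus and
its truth table remain available as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .corpus import (
    MISSING,
    SOURCE_EXPERIMENTAL,
    SOURCE_MISSING,
    DatasetTable,
    PoseRecord,
    is_missing,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror the cross-docked regime the framework targets:
    ~20 poses per complex, ~5% good poses (so bad poses dominate at
    roughly the 96% level once the cognate pose is accounted for), and
    59% of complexes missing their affinity label.  pK ~ Normal(6.0,
    1.5) truncated to the plausible assay range [2, 12].
    """

    n_pockets: int = 40
    ligands_per_pocket: int = 4
    poses_per_complex: int = 20
    good_pose_rate: float = 0.05
    cognate_good_prob: float = 0.8
    pk_mean: float = 6.0
    pk_sd: float = 1.5
    feature_dim: int = 16
    signal_weight: float = 1.0
    quality_weight: float = 1.0
    noise_sd: float = 0.1
    missing_fraction: float = 0.59
    missing_mechanism: str = "by_complex"

    def __post_init__(self):
        for name in ("n_pockets", "ligands_per_pocket", "poses_per_complex",
                     "feature_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("good_pose_rate", "cognate_good_prob", "missing_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.pk_sd <= 0:
            raise ValueError("pk_sd must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.missing_mechanism not in ("by_complex", "by_pocket"):
            raise ValueError(
                f"unknown missing_mechanism {self.missing_mechanism!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class TruthTable:
    """Generator-side oracle: true pK per complex, latent quality per pose."""

    complex_pk: Dict[str, float]
    pose_quality: Dict[str, float] = field(default_factory=dict)

    def write(self, pk_path, quality_path=None) -> None:
        with open(pk_path, "w", encoding="utf-8") as fh:
            fh.write("complex_id,true_pk\n")
            for cid in sorted(self.complex_pk):
                fh.write(f"{cid},{self.complex_pk[cid]:.3f}\n")
        if quality_path is not None:
            with open(quality_path, "w", encoding="utf-8") as fh:
                fh.write("pose_id,quality\n")
                for pid in sorted(self.pose_quality):
                    fh.write(f"{pid},{self.pose_quality[pid]:.6f}\n")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (narrow truncation, cheap)."""
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size - n)
        keep = draw[(draw >= low) & (draw <= high)]
        out[n:n + keep.size] = keep
        n += keep.size
    return out


def generate_corpus(
    config: SyntheticConfig, seed: int
) -> Tuple[DatasetTable, TruthTable, pd.DataFrame]:
    """Generate a fully labeled corpus, its truth table and features.

    Every complex gets ``poses_per_complex`` poses; pose 0 is the
    cognate redock (good with probability ``cognate_good_prob``), the
    rest are cross-docked poses (good with probability
    ``good_pose_rate``).  Good RMSDs are Uniform(0.2, 1.8) Å, bad ones
    Uniform(2.5, 10) Å — only the 2 Å dichotomy matters downstream.
    All labels are present; hiding is :func:`hide_labels`.
    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    d = config.feature_dim

    def unit(vec: np.ndarray) -> np.ndarray:
        return vec / np.linalg.norm(vec)

    u = unit(rng.normal(size=d))
    v = unit(rng.normal(size=d))

    n_complexes = config.n_pockets * config.ligands_per_pocket
    pks = np.round(
        _truncated_normal(rng, config.pk_mean, config.pk_sd, 2.0, 12.0,
                          n_complexes),
        3,
    )

    records: List[PoseRecord] = []
    complex_pk: Dict[str, float] = {}
    pose_quality: Dict[str, float] = {}
    rows: List[np.ndarray] = []
    pose_ids: List[str] = []

    ci = 0
    for pi in range(config.n_pockets):
        pocket = f"P{pi:03d}"
        rec_path = f"{pocket}/{pocket}_rec.pdb"
        for li in range(config.ligands_per_pocket):
            stem = f"{pocket}_lig{li:02d}"
            complex_id = f"{pocket}/{stem}"
            lig_path = f"{pocket}/{stem}.sdf"
            pk = float(pks[ci])
            ci += 1
            complex_pk[complex_id] = pk
            for k in range(config.poses_per_complex):
                p_good = config.cognate_good_prob if k == 0 else config.good_pose_rate
                good = bool(rng.random() < p_good)
                rmsd = float(
                    np.round(
                        rng.uniform(0.2, 1.8) if good else rng.uniform(2.5, 10.0),
                        4,
                    )
                )
                q = math.exp(-rmsd / 2.0)
                pose_id = f"{complex_id}#{k}"
                pose_quality[pose_id] = q
                x = (
                    config.signal_weight * pk * q * u
                    + config.quality_weight * q * v
                    + rng.normal(scale=config.noise_sd, size=d)
                )
                rows.append(x)
                pose_ids.append(pose_id)
                records.append(
                    PoseRecord(
                        pose_id=pose_id,
                        pocket_id=pocket,
                        complex_id=complex_id,
                        rmsd=rmsd,
                        is_good=good,
                        affinity=pk,
                        affinity_source=SOURCE_EXPERIMENTAL,
                        rec_path=rec_path,
                        lig_path=lig_path,
                    )
                )

    features = pd.DataFrame(
        np.asarray(rows), index=pd.Index(pose_ids, name="pose_id"),
        columns=[f"f{j}" for j in range(d)],
    )
    return DatasetTable(records), TruthTable(complex_pk, pose_quality), features


def hide_labels(
    table: DatasetTable,
    missing_fraction: float,
    mechanism: str = "by_complex",
    seed: int = 0,
) -> DatasetTable:
    """Blank affinity labels to emulate incomplete assay coverage.

    ``by_complex`` (missing-at-random): exactly
    ``round(missing_fraction * n_complexes)`` complexes, chosen without
    replacement, lose the labels of all their poses.  ``by_pocket``:
    whole pockets are masked, in shuffled order, until the masked
    complex fraction first reaches the target — probing pocket-level
    missingness bias.  Deterministic given *seed*.
    """
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError(f"missing_fraction must lie in [0, 1]")
    if any(is_missing(r.affinity) for r in table):
        raise ValueError("table must be fully labeled before hiding")
    rng = np.random.default_rng(seed)
    complex_ids = sorted(table.complexes)

    if mechanism == "by_complex":
        n_hide = int(round(missing_fraction * len(complex_ids)))
        hidden = set(
            rng.choice(complex_ids, size=n_hide, replace=False)
        ) if n_hide else set()
    elif mechanism == "by_pocket":
        pockets = sorted(table.pockets)
        order = rng.permutation(len(pockets))
        hidden = set()
        n_total = len(complex_ids)
        for idx in order:
            if len(hidden) / n_total >= missing_fraction:
                break
            hidden.update(table.pockets[pockets[idx]])
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    from dataclasses import replace

    new_records = [
        replace(r, affinity=MISSING, affinity_source=SOURCE_MISSING)
        if r.complex_id in hidden
        else r
        for r in table.records
    ]
    return DatasetTable(new_records)


@dataclass(frozen=True)
class CorpusSummary:
    n_poses: int
    n_complexes: int
    good_fraction: float
    missing_fraction: float
    pk_min: float
    pk_max: float


def corpus_summary(table: DatasetTable, truth: TruthTable) -> CorpusSummary:
    """Realized corpus statistics against the generator's truth table."""
    missing_cids = set(table.complexes) - set(truth.complex_pk)
    if missing_cids:
        raise ValueError(
            f"truth table does not cover complexes {sorted(missing_cids)[:3]}..."
        )
    n_poses = len(table)
    n_good = sum(1 for r in table if r.is_good)
    unlabeled = table.unlabeled_complexes()
    pks = [truth.complex_pk[c] for c in table.complexes]
    return CorpusSummary(
        n_poses=n_poses,
        n_complexes=len(table.complexes),
        good_fraction=n_good / n_poses,
        missing_fraction=len(unlabeled) / len(table.complexes),
        pk_min=min(pks),
        pk_max=max(pks),
    )
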