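"""Pose-level affinity dataset model and the ``.types`` table dialect.

A corpus is a flat table of docked poses.  Each pose belongs to a
pocket–ligand *complex* (one ligand docked against one binding pocket;
the unit that carries a single experimental affinity label) and each
complex belongs to a *pocket* (a group of similar receptor binding
sites treated as one target).  A pose is *good* when its RMSD to the
crystal pose is below 2 Å, *bad* otherwise.

Affinity labels are on the pK scale (negative log of Kd/Ki/IC50,
roughly 2–12).  Many complexes have no experimental label; on disk the
missing-label sentinel is ``0.000`` (pK 0 is outside the meaningful
range), in memory it is NaN paired with an explicit ``affinity_source``
of ``"missing"`` so a real value can never be confused with absence.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import PurePosixPath
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: RMSD threshold (Å) below which a docked pose counts as good.
GOOD_RMSD_THRESHOLD = 2.0

#: In-memory missing-affinity marker.  Compare with :func:`is_missing`,
#: never with ``==``.
MISSING = float("nan")

SOURCE_EXPERIMENTAL = "experimental"
SOURCE_IMPUTED = "imputed"
SOURCE_MISSING = "missing"
_SOURCES = (SOURCE_EXPERIMENTAL, SOURCE_IMPUTED, SOURCE_MISSING)


def is_missing(affinity: float) -> bool:
    """True when *affinity* is the missing-label marker."""
    return isinstance(affinity, float) and math.isnan(affinity)


class TypesParseError(ValueError):
    """Raised for a malformed ``.types`` line; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class PoseRecord:
    """One docked pose.

    ``is_good`` is always derived from ``rmsd`` (< 2 Å); the pose-label
    column of the file dialect is advisory only.
    """

    pose_id: str
    pocket_id: str
    complex_id: str
    rmsd: float
    is_good: bool
    affinity: float
    affinity_source: str
    rec_path: str = ""
    lig_path: str = ""

    def __post_init__(self):
        if not math.isfinite(self.rmsd) or self.rmsd < 0:
            raise ValueError(f"rmsd must be finite and >= 0, got {self.rmsd}")
        if self.is_good != (self.rmsd < GOOD_RMSD_THRESHOLD):
            raise ValueError(
                f"is_good={self.is_good} inconsistent with rmsd={self.rmsd}"
            )
        if self.affinity_source not in _SOURCES:
            raise ValueError(f"unknown affinity_source {self.affinity_source!r}")
        if is_missing(self.affinity) != (self.affinity_source == SOURCE_MISSING):
            raise ValueError(
                "affinity_source must be 'missing' exactly when affinity is MISSING"
            )
        if not is_missing(self.affinity) and not math.isfinite(self.affinity):
            raise ValueError("affinity must be finite or MISSING")


@dataclass
class DatasetTable:
    """Ordered collection of :class:`PoseRecord` with derived groupings.

    ``complexes`` maps complex_id -> pose_ids (record order preserved);
    ``pockets`` maps pocket_id -> complex_ids.  Experimental labels must
    agree across all poses of a complex.
    """

    records: List[PoseRecord]
    complexes: Dict[str, List[str]] = field(init=False)
    pockets: Dict[str, List[str]] = field(init=False)

    def __post_init__(self):
        self._rebuild_index()
        self._validate()

    def _rebuild_index(self):
        self._by_id: Dict[str, PoseRecord] = {}
        self.complexes = {}
        self.pockets = {}
        for rec in self.records:
            if rec.pose_id in self._by_id:
                raise ValueError(f"duplicate pose_id {rec.pose_id!r}")
            self._by_id[rec.pose_id] = rec
            self.complexes.setdefault(rec.complex_id, []).append(rec.pose_id)
            cxs = self.pockets.setdefault(rec.pocket_id, [])
            if rec.complex_id not in cxs:
                cxs.append(rec.complex_id)

    def _validate(self):
        for cid, pose_ids in self.complexes.items():
            labels = {
                round(self._by_id[p].affinity, 6)
                for p in pose_ids
                if self._by_id[p].affinity_source == SOURCE_EXPERIMENTAL
            }
            if len(labels) > 1:
                raise ValueError(
                    f"complex {cid!r} carries conflicting experimental labels {sorted(labels)}"
                )

    # -- accessors -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, pose_id: str) -> PoseRecord:
        return self._by_id[pose_id]

    @property
    def pose_ids(self) -> List[str]:
        return [r.pose_id for r in self.records]

    def complex_affinity(self, complex_id: str) -> float:
        """The complex's label (experimental or imputed), or MISSING."""
        for pid in self.complexes[complex_id]:
            rec = self._by_id[pid]
            if rec.affinity_source != SOURCE_MISSING:
                return rec.affinity
        return MISSING

    def complex_source(self, complex_id: str) -> str:
        sources = {self._by_id[p].affinity_source for p in self.complexes[complex_id]}
        if SOURCE_EXPERIMENTAL in sources:
            return SOURCE_EXPERIMENTAL
        if sources == {SOURCE_MISSING}:
            return SOURCE_MISSING
        return SOURCE_IMPUTED

    def unlabeled_complexes(self) -> List[str]:
        return [
            cid
            for cid in self.complexes
            if self.complex_source(cid) == SOURCE_MISSING
        ]

    def subset_pockets(self, pocket_ids: Iterable[str]) -> "DatasetTable":
        keep = set(pocket_ids)
        return DatasetTable([r for r in self.records if r.pocket_id in keep])

    def to_frame(self) -> pd.DataFrame:
        """Flat per-pose view (one row per pose, indexed by pose_id)."""
        df = pd.DataFrame(
            {
                "pose_id": [r.pose_id for r in self.records],
                "pocket_id": [r.pocket_id for r in self.records],
                "complex_id": [r.complex_id for r in self.records],
                "rmsd": [r.rmsd for r in self.records],
                "is_good": [r.is_good for r in self.records],
                "affinity": [r.affinity for r in self.records],
                "affinity_source": [r.affinity_source for r in self.records],
            }
        )
        return df.set_index("pose_id")


@dataclass
class FoldAssignment:
    """Pocket -> fold map from cluster-level random assignment.

    All pockets of one similarity cluster share a fold, so related
    pockets never straddle a train/test split.
    """

    n_folds: int
    pocket_to_fold: Dict[str, int]
    cluster_map: Dict[str, List[str]]

    def fold_of(self, pocket_id: str) -> int:
        return self.pocket_to_fold[pocket_id]

    def pockets_in_fold(self, fold: int) -> List[str]:
        return sorted(p for p, f in self.pocket_to_fold.items() if f == fold)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pocket in sorted(self.pocket_to_fold):
                fh.write(f"{pocket}\t{self.pocket_to_fold[pocket]}\n")

    @classmethod
    def read(cls, path, cluster_map: Mapping[str, Sequence[str]] | None = None):
        mapping: Dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                pocket, fold = line.split("\t")
                mapping[pocket] = int(fold)
        n_folds = max(mapping.values()) + 1 if mapping else 0
        clusters = (
            {k: list(v) for k, v in cluster_map.items()}
            if cluster_map
            else {p: [p] for p in mapping}
        )
        return cls(n_folds=n_folds, pocket_to_fold=mapping, cluster_map=clusters)


@dataclass(frozen=True)
class DatasetStats:
    n_pockets: int
    n_complexes: int
    n_poses: int
    n_unlabeled_poses: int
    pct_unlabeled: float
    n_good: int
    n_bad: int
    pct_bad: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def percentage(part: int, total: int) -> float:
    """``100 * part / total`` rounded to one decimal, as printed in stats."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, 1)


# ---------------------------------------------------------------------------
# .types dialect
# ---------------------------------------------------------------------------

def _ids_from_paths(rec_path: str, lig_path: str) -> tuple[str, str]:
    pocket_id = PurePosixPath(rec_path).parts[0]
    lig_stem = PurePosixPath(lig_path).stem
    return pocket_id, f"{pocket_id}/{lig_stem}"


def read_types_table(path) -> DatasetTable:
    """Parse a ``.types`` pose table.

    Dialect: whitespace-separated ``pose_label affinity rmsd rec_path
    lig_path``, one pose per line, ``#`` starts a comment.  The affinity
    sentinel ``0.0`` maps to MISSING.  ``is_good`` is recomputed from
    the RMSD column; a disagreement with the pose-label column is logged
    and the RMSD wins.  Pose ids are synthesized as
    ``<complex_id>#<k>`` with ``k`` counting poses within the complex in
    file order, so a write/read round trip is stable.
    """
    records: List[PoseRecord] = []
    per_complex_count: Dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 5:
                raise TypesParseError(
                    f"expected >= 5 fields, got {len(fields)}", lineno
                )
            label_s, aff_s, rmsd_s, rec_path, lig_path = fields[:5]
            try:
                pose_label = int(label_s)
                affinity = float(aff_s)
                rmsd = float(rmsd_s)
            except ValueError as exc:
                raise TypesParseError(str(exc), lineno) from None
            if affinity < 0:
                raise TypesParseError(
                    f"negative affinity {affinity}: signed-affinity dialects are "
                    "not supported (good/bad is encoded via rmsd)",
                    lineno,
                )
            if rmsd < 0:
                raise TypesParseError(f"negative rmsd {rmsd}", lineno)
            is_good = rmsd < GOOD_RMSD_THRESHOLD
            if bool(pose_label) != is_good:
                logger.warning(
                    "line %d: pose label %d disagrees with rmsd %.3f; using rmsd",
                    lineno,
                    pose_label,
                    rmsd,
                )
            pocket_id, complex_id = _ids_from_paths(rec_path, lig_path)
            k = per_complex_count.get(complex_id, 0)
            per_complex_count[complex_id] = k + 1
            if affinity == 0.0:
                aff, source = MISSING, SOURCE_MISSING
            else:
                aff, source = affinity, SOURCE_EXPERIMENTAL
            records.append(
                PoseRecord(
                    pose_id=f"{complex_id}#{k}",
                    pocket_id=pocket_id,
                    complex_id=complex_id,
                    rmsd=rmsd,
                    is_good=is_good,
                    affinity=aff,
                    affinity_source=source,
                    rec_path=rec_path,
                    lig_path=lig_path,
                )
            )
    return DatasetTable(records)


def write_types_table(table: DatasetTable, path) -> None:
    """Serialize *table* in the ``.types`` dialect (MISSING -> ``0.000``).

    Affinities are written to 3 decimals, RMSD to 4; a round trip
    reproduces the table field-exactly when values respect those
    precisions (the synthetic generator does).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rec in table.records:
            aff = 0.0 if is_missing(rec.affinity) else rec.affinity
            rec_path = rec.rec_path or f"{rec.pocket_id}/{rec.pocket_id}_rec.pdb"
            lig_path = rec.lig_path or f"{rec.complex_id.split('/', 1)[1]}.sdf"
            fh.write(
                f"{int(rec.is_good)} {aff:.3f} {rec.rmsd:.4f} {rec_path} {lig_path}\n"
            )


# ---------------------------------------------------------------------------
# folds / stats / label application
# ---------------------------------------------------------------------------

def assign_clustered_folds(
    cluster_map: Mapping[str, Sequence[str]], n_folds: int = 3, seed: int = 0
) -> FoldAssignment:
    """Assign each pocket-similarity cluster a uniformly random fold.

    Every pocket of a cluster lands in the cluster's fold, so similar
    pockets never straddle folds.  Deterministic given *seed* (clusters
    are processed in sorted-name order).
    """
    if not cluster_map:
        raise ValueError("cluster_map is empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    seen: Dict[str, str] = {}
    for cluster, pockets in cluster_map.items():
        for pocket in pockets:
            if pocket in seen:
                raise ValueError(
                    f"pocket {pocket!r} in clusters {seen[pocket]!r} and {cluster!r}"
                )
            seen[pocket] = cluster
    rng = np.random.default_rng(seed)
    pocket_to_fold: Dict[str, int] = {}
    for cluster in sorted(cluster_map):
        fold = int(rng.integers(n_folds))
        for pocket in cluster_map[cluster]:
            pocket_to_fold[pocket] = fold
    return FoldAssignment(
        n_folds=n_folds,
        pocket_to_fold=pocket_to_fold,
        cluster_map={k: list(v) for k, v in cluster_map.items()},
    )


def compute_dataset_stats(table: DatasetTable) -> DatasetStats:
    """Counts and one-decimal percentages for a pose table."""
    if len(table) == 0:
        raise ValueError("empty table")
    n_poses = len(table)
    n_unlabeled = sum(1 for r in table if r.affinity_source == SOURCE_MISSING)
    n_good = sum(1 for r in table if r.is_good)
    n_bad = n_poses - n_good
    return DatasetStats(
        n_pockets=len(table.pockets),
        n_complexes=len(table.complexes),
        n_poses=n_poses,
        n_unlabeled_poses=n_unlabeled,
        pct_unlabeled=percentage(n_unlabeled, n_poses),
        n_good=n_good,
        n_bad=n_bad,
        pct_bad=percentage(n_bad, n_poses),
    )


def apply_imputed_labels(
    table: DatasetTable,
    labels: Mapping[str, float],
    mode: str = "per_complex",
) -> DatasetTable:
    """Return a new table with imputed affinities written in.

    ``mode="per_complex"`` keys *labels* by complex_id and writes one
    value to every pose of the complex (mirroring how experimental
    labels are shared); ``mode="per_pose"`` keys by pose_id.  Targets
    must currently be unlabeled — experimental labels are never
    overwritten.
    """
    if mode not in ("per_pose", "per_complex"):
        raise ValueError(f"unknown mode {mode!r}")

    per_pose: Dict[str, float] = {}
    if mode == "per_complex":
        for cid, value in labels.items():
            if cid not in table.complexes:
                raise KeyError(f"unknown complex_id {cid!r}")
            if table.complex_source(cid) == SOURCE_EXPERIMENTAL:
                raise ValueError(
                    f"complex {cid!r} has an experimental label; refusing to overwrite"
                )
            for pid in table.complexes[cid]:
                per_pose[pid] = float(value)
    else:
        for pid, value in labels.items():
            try:
                rec = table.get(pid)
            except KeyError:
                raise KeyError(f"unknown pose_id {pid!r}") from None
            if rec.affinity_source == SOURCE_EXPERIMENTAL:
                raise ValueError(
                    f"pose {pid!r} has an experimental label; refusing to overwrite"
                )
            per_pose[pid] = float(value)

    new_records = []
    for rec in table.records:
        if rec.pose_id in per_pose:
            new_records.append(
                replace(
                    rec,
                    affinity=per_pose[rec.pose_id],
                    affinity_source=SOURCE_IMPUTED,
                )
            )
        else:
            new_records.append(rec)
    return DatasetTable(new_records)
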