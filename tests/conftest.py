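import numpy as np
import pytest

import poseimpute as pi


@pytest.fixture(scope="session")
def default_corpus():
    """Fully labeled default synthetic corpus (seed 7) + truth + features."""
    cfg = pi.SyntheticConfig()
    table, truth, features = pi.generate_corpus(cfg, seed=7)
    return cfg, table, truth, features


@pytest.fixture(scope="session")
def hidden_corpus(default_corpus):
    """Default corpus with 59% of complexes unlabeled (by complex)."""
    cfg, table, truth, features = default_corpus
    hidden = pi.hide_labels(table, cfg.missing_fraction, "by_complex", seed=7)
    return cfg, hidden, truth, features


@pytest.fixture(scope="session")
def small_corpus():
    """Small corpus for fast learner tests: 8 pockets x 2 ligands x 10 poses."""
    cfg = pi.SyntheticConfig(n_pockets=8, ligands_per_pocket=2,
                             poses_per_complex=10, good_pose_rate=0.2)
    table, truth, features = pi.generate_corpus(cfg, seed=3)
    return cfg, table, truth, features


def random_pose_table(rng: np.random.Generator, n_pockets=3,
                      ligands_per_pocket=2, max_poses=6,
                      labeled_prob=0.6) -> pi.DatasetTable:
    """Small random pose table for property tests (not via the generator,
    so table invariants get exercised independently)."""
    records = []
    for p in range(n_pockets):
        pocket = f"K{p}"
        for l in range(ligands_per_pocket):
            cid = f"{pocket}/{pocket}_l{l}"
            labeled = rng.random() < labeled_prob
            pk = float(np.round(rng.uniform(2.5, 11.5), 3))
            n_poses = int(rng.integers(1, max_poses + 1))
            for k in range(n_poses):
                good = bool(rng.random() < 0.3)
                rmsd = float(np.round(
                    rng.uniform(0.2, 1.9) if good else rng.uniform(2.1, 9.0), 4))
                records.append(pi.PoseRecord(
                    pose_id=f"{cid}#{k}", pocket_id=pocket, complex_id=cid,
                    rmsd=rmsd, is_good=good,
                    affinity=pk if labeled else pi.MISSING,
                    affinity_source="experimental" if labeled else "missing",
                ))
    return pi.DatasetTable(records)
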