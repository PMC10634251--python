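"""Tests of the imputation schemes, fractions, and the round loop."""

import numpy as np
import pandas as pd
import pytest

import poseimpute as pi
from poseimpute.imputation import (
    ImputationPlan,
    ImputationScheme,
    aggregate_complex,
)


def pred_table(table, values):
    """PredictionTable with given per-pose affinities, score 0.5."""
    return pd.DataFrame(
        {"pose_score": 0.5, "affinity_pred": [values[p] for p in table.pose_ids]},
        index=pd.Index(table.pose_ids, name="pose_id"),
    )


class TestSchemeTaxonomy:
    @pytest.mark.parametrize("name,gran,stat,good_only", [
        ("individual", "per_pose", "none", False),
        ("individual_ensemble", "per_pose", "none", False),
        ("median_ensemble", "per_complex", "median", False),
        ("median_good_only_ensemble", "per_complex", "median", True),
        ("max_ensemble", "per_complex", "max", False),
        ("max_good_only_ensemble", "per_complex", "max", True),
        ("min_ensemble", "per_complex", "min", False),
        ("min_good_only_ensemble", "per_complex", "min", True),
    ])
    def test_all_eight_schemes(self, name, gran, stat, good_only):
        s = ImputationScheme(name)
        assert (s.granularity, s.statistic, s.good_only) == (gran, stat,
                                                             good_only)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            ImputationScheme("mean_ensemble")


class TestAggregateComplex:
    def test_median_good_only_midpoint(self):
        value, fb = aggregate_complex(
            [(5, True), (6, True), (9, False)], "median", good_only=True)
        assert value == 5.5 and not fb

    def test_max_all_poses(self):
        value, fb = aggregate_complex(
            [(5, True), (6, True), (9, False)], "max", good_only=False)
        assert value == 9 and not fb

    def test_good_only_fallback_when_no_good_pose(self):
        value, fb = aggregate_complex(
            [(5, False), (6, False), (9, False)], "median", good_only=True)
        assert value == 6 and fb

    def test_guards(self):
        with pytest.raises(ValueError):
            aggregate_complex([], "median", False)
        with pytest.raises(ValueError):
            aggregate_complex([(5, True)], "mean", False)

    def test_min_le_median_le_max_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            pairs = [(float(rng.uniform(2, 12)), bool(rng.random() < 0.5))
                     for _ in range(int(rng.integers(1, 12)))]
            for good_only in (False, True):
                lo, _ = aggregate_complex(pairs, "min", good_only)
                mid, _ = aggregate_complex(pairs, "median", good_only)
                hi, _ = aggregate_complex(pairs, "max", good_only)
                assert lo <= mid <= hi


def brute_force_impute(per_seed_preds, table, scheme, clamp=(2.0, 12.0)):
    """Independent oracle: explicit loops over poses and seeds."""
    lo, hi = clamp
    out = {}
    for cid in table.unlabeled_complexes():
        pose_ids = table.complexes[cid]
        seed_values = []
        for preds in per_seed_preds:
            vals = []
            for pid in pose_ids:
                if not scheme.good_only or table.get(pid).is_good:
                    vals.append(preds.at[pid, "affinity_pred"])
            if not vals:  # fallback to all poses
                vals = [preds.at[pid, "affinity_pred"] for pid in pose_ids]
            if scheme.statistic == "median":
                vals = sorted(vals)
                n = len(vals)
                v = (vals[n // 2] if n % 2
                     else (vals[n // 2 - 1] + vals[n // 2]) / 2)
            elif scheme.statistic == "max":
                v = max(vals)
            else:
                v = min(vals)
            seed_values.append(v)
        out[cid] = min(max(sum(seed_values) / len(seed_values), lo), hi)
    return out


class TestImputeLabels:
    @pytest.fixture()
    def fixture(self):
        cfg = pi.SyntheticConfig(n_pockets=4, ligands_per_pocket=2,
                                 poses_per_complex=6, good_pose_rate=0.3)
        table, truth, _ = pi.generate_corpus(cfg, seed=2)
        hidden = pi.hide_labels(table, 0.5, "by_complex", seed=2)
        rng = np.random.default_rng(0)
        preds = [pred_table(hidden, {p: float(rng.uniform(2, 12))
                                     for p in hidden.pose_ids})
                 for _ in range(5)]
        return hidden, preds

    def test_individual_ensemble_is_per_pose_mean(self, fixture):
        hidden, preds = fixture
        out = pi.impute_labels(preds[:2], hidden,
                               ImputationScheme("individual_ensemble"))
        pid = hidden.complexes[hidden.unlabeled_complexes()[0]][0]
        expect = (preds[0].at[pid, "affinity_pred"]
                  + preds[1].at[pid, "affinity_pred"]) / 2
        assert out.mapping[pid] == pytest.approx(np.clip(expect, 2, 12))

    def test_individual_keeps_per_seed_mappings(self, fixture):
        hidden, preds = fixture
        out = pi.impute_labels(preds, hidden, ImputationScheme("individual"))
        assert out.per_seed is not None and len(out.per_seed) == 5
        assert out.per_seed[0] != out.per_seed[1]

    def test_two_stage_aggregation_by_hand(self):
        # seed A good-pose predictions {5, 6}, seed B {7}: mean(5.5, 7) = 6.25
        recs = [
            pi.PoseRecord("c#0", "P", "P/l", 1.0, True, pi.MISSING, "missing"),
            pi.PoseRecord("c#1", "P", "P/l", 1.5, True, pi.MISSING, "missing"),
            pi.PoseRecord("c#2", "P", "P/l", 5.0, False, pi.MISSING, "missing"),
        ]
        table = pi.DatasetTable(recs)
        seed_a = pred_table(table, {"c#0": 5.0, "c#1": 6.0, "c#2": 11.0})
        seed_b = pred_table(table, {"c#0": 7.0, "c#1": 7.0, "c#2": 3.0})
        out = pi.impute_labels([seed_a, seed_b], table,
                               ImputationScheme("median_good_only_ensemble"))
        assert out.mapping["P/l"] == pytest.approx(6.25)

    @pytest.mark.parametrize("name", [
        "median_ensemble", "median_good_only_ensemble", "max_ensemble",
        "max_good_only_ensemble", "min_ensemble", "min_good_only_ensemble",
    ])
    def test_per_complex_schemes_match_brute_force_oracle(self, name):
        scheme = ImputationScheme(name)
        rng = np.random.default_rng(7)
        for _ in range(150):
            n_poses = int(rng.integers(1, 31))
            recs = []
            for k in range(n_poses):
                good = bool(rng.random() < 0.3)
                rmsd = float(rng.uniform(0.3, 1.9)) if good \
                    else float(rng.uniform(2.1, 9))
                recs.append(pi.PoseRecord(f"c#{k}", "P", "P/l",
                                          round(rmsd, 4), good,
                                          pi.MISSING, "missing"))
            table = pi.DatasetTable(recs)
            preds = [pred_table(table,
                                {p: float(rng.uniform(0, 14))
                                 for p in table.pose_ids})
                     for _ in range(5)]
            got = pi.impute_labels(preds, table, scheme)
            expect = brute_force_impute(preds, table, scheme)
            assert got.mapping == pytest.approx(expect)
            assert got.fallback["P/l"] == (
                scheme.good_only and not any(r.is_good for r in recs))

    def test_only_unlabeled_complexes_receive_labels(self, fixture):
        hidden, preds = fixture
        out = pi.impute_labels(preds, hidden,
                               ImputationScheme("median_ensemble"))
        assert set(out.mapping) == set(hidden.unlabeled_complexes())

    def test_values_clamped_to_pk_range(self, fixture):
        hidden, _ = fixture
        wild = [pred_table(hidden, {p: 99.0 for p in hidden.pose_ids})]
        out = pi.impute_labels(wild, hidden, ImputationScheme("max_ensemble"))
        assert all(v == 12.0 for v in out.mapping.values())

    def test_coverage_gap_rejected(self, fixture):
        hidden, preds = fixture
        with pytest.raises(ValueError, match="missing poses"):
            pi.impute_labels([preds[0].iloc[:3]], hidden,
                             ImputationScheme("median_ensemble"))


class TestSelectFraction:
    MAPPING = {f"c{i}": float(i) for i in range(100)}

    def test_full_and_empty(self):
        assert pi.select_fraction(self.MAPPING, 1.0, seed=0) == self.MAPPING
        assert pi.select_fraction(self.MAPPING, 0.0, seed=0) == {}

    def test_exact_count(self):
        assert len(pi.select_fraction(self.MAPPING, 0.2, seed=3)) == 20

    def test_nested_across_fraction_grid(self):
        for seed in (0, 1, 42):
            prev = set()
            for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
                cur = set(pi.select_fraction(self.MAPPING, frac, seed))
                assert prev <= cur
                assert len(cur) == round(frac * 100)
                prev = cur

    def test_deterministic(self):
        a = pi.select_fraction(self.MAPPING, 0.5, seed=9)
        b = pi.select_fraction(self.MAPPING, 0.5, seed=9)
        assert a == b


def stub_train(predictions_by_round):
    """Make a train_fn returning stub 'models' that remember their round."""
    calls = {"n": 0}

    def train_fn(table, cfg):
        r = calls["n"] // 2  # two seeds per round in these tests
        calls["n"] += 1
        return ("stub", r)

    def predict_fn(model, table):
        _, r = model
        return predictions_by_round[min(r, len(predictions_by_round) - 1)](table)

    return train_fn, predict_fn


class TestRunRounds:
    @pytest.fixture()
    def split(self):
        cfg = pi.SyntheticConfig(n_pockets=8, ligands_per_pocket=2,
                                 poses_per_complex=6, good_pose_rate=0.3)
        table, truth, feats = pi.generate_corpus(cfg, seed=4)
        hidden = pi.hide_labels(table, 0.5, "by_complex", seed=4)
        pockets = sorted(table.pockets)
        train_t = hidden.subset_pockets(pockets[:6])
        test_t = table.subset_pockets(pockets[6:])
        return train_t, test_t, truth, feats

    @staticmethod
    def noisy_predictor(truth, sd, seed):
        def make(table):
            rng = np.random.default_rng(seed)
            vals = {p: truth.complex_pk[table.get(p).complex_id]
                    + rng.normal(0, sd) for p in table.pose_ids}
            return pd.DataFrame(
                {"pose_score": [np.exp(-table.get(p).rmsd)
                                for p in table.pose_ids],
                 "affinity_pred": [vals[p] for p in table.pose_ids]},
                index=pd.Index(table.pose_ids, name="pose_id"))
        return make

    def test_max_rounds_zero_gives_baseline_only(self, split):
        train_t, test_t, truth, feats = split
        train_fn, predict_fn = stub_train([self.noisy_predictor(truth, 0.5, 0)])
        plan = ImputationPlan(ImputationScheme("median_ensemble"),
                              n_seeds=2, max_rounds=0)
        h = pi.run_rounds(train_t, test_t, feats, plan,
                          pi.TrainConfig.desk(seed=0), [1, 2],
                          train_fn=train_fn, predict_fn=predict_fn)
        assert len(h.rounds) == 1
        assert h.stop_reason == "max rounds"

    def test_worsening_rmse_stops_with_no_improvement(self, split):
        train_t, test_t, truth, feats = split
        preds = [self.noisy_predictor(truth, 0.2, 0),   # round 0 models
                 self.noisy_predictor(truth, 0.2, 0),   # round 1: same rmse
                 self.noisy_predictor(truth, 2.0, 1)]
        train_fn, predict_fn = stub_train(preds)
        plan = ImputationPlan(ImputationScheme("median_ensemble"),
                              n_seeds=2, max_rounds=5)
        h = pi.run_rounds(train_t, test_t, feats, plan,
                          pi.TrainConfig.desk(seed=0), [1, 2],
                          train_fn=train_fn, predict_fn=predict_fn)
        assert h.stop_reason == "no improvement"
        assert len(h.rounds) == 2  # baseline + the non-improving round

    def test_perfect_predictor_recovers_true_pk_exactly(self, hidden_corpus):
        cfg, hidden, truth, _ = hidden_corpus
        perfect = pd.DataFrame(
            {"pose_score": 0.5,
             "affinity_pred": [truth.complex_pk[hidden.get(p).complex_id]
                               for p in hidden.pose_ids]},
            index=pd.Index(hidden.pose_ids, name="pose_id"))
        out = pi.impute_labels([perfect] * 5, hidden,
                               ImputationScheme("median_good_only_ensemble"))
        for cid, value in out.mapping.items():
            assert value == truth.complex_pk[cid]
        # applying them reconstructs the fully labeled training targets
        relabeled = pi.apply_imputed_labels(hidden, out.mapping, "per_complex")
        for cid in out.mapping:
            assert relabeled.complex_affinity(cid) == truth.complex_pk[cid]

    def test_experimental_labels_survive_every_round(self, split):
        train_t, test_t, truth, feats = split
        train_fn, predict_fn = stub_train(
            [self.noisy_predictor(truth, 0.5, 0),
             self.noisy_predictor(truth, 0.4, 1),
             self.noisy_predictor(truth, 0.3, 2)])
        seen_tables = []
        wrapped_train = lambda t, cfg: (seen_tables.append(t),
                                        train_fn(t, cfg))[1]
        plan = ImputationPlan(ImputationScheme("median_good_only_ensemble"),
                              n_seeds=2, max_rounds=2)
        pi.run_rounds(train_t, test_t, feats, plan,
                      pi.TrainConfig.desk(seed=0), [1, 2],
                      train_fn=wrapped_train, predict_fn=predict_fn)
        exp = {r.pose_id: r.affinity for r in train_t
               if r.affinity_source == "experimental"}
        for t in seen_tables:
            for pid, aff in exp.items():
                rec = t.get(pid)
                assert rec.affinity == aff
                assert rec.affinity_source == "experimental"

    def test_pocket_leakage_rejected(self, split):
        train_t, _, truth, feats = split
        plan = ImputationPlan(ImputationScheme("median_ensemble"),
                              n_seeds=2, max_rounds=1)
        with pytest.raises(ValueError, match="straddle"):
            pi.run_rounds(train_t, train_t, feats, plan,
                          pi.TrainConfig.desk(seed=0), [1, 2])

    def test_history_persisted(self, split, tmp_path):
        train_t, test_t, truth, feats = split
        train_fn, predict_fn = stub_train(
            [self.noisy_predictor(truth, 0.5, 0),
             self.noisy_predictor(truth, 0.4, 1)])
        plan = ImputationPlan(ImputationScheme("median_ensemble"),
                              n_seeds=2, max_rounds=1)
        pi.run_rounds(train_t, test_t, feats, plan,
                      pi.TrainConfig.desk(seed=0), [1, 2],
                      out_dir=tmp_path, train_fn=train_fn,
                      predict_fn=predict_fn)
        assert (tmp_path / "history.json").exists()
        assert (tmp_path / "round1.labels").exists()
        text = (tmp_path / "round1.labels").read_text()
        assert text.startswith("complex_id,affinity,scheme,round")
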