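# poseimpute

Self-training imputation of binding-affinity labels for structure-based
pose scoring and affinity regression.

## The problem

Cross-docked pose corpora pair each receptor binding pocket with many
docked ligand poses: ~20 poses per pocket–ligand complex, of which only
a small fraction lie within 2 Å RMSD of the crystal pose ("good"
poses). Affinity labels (pK = −log Kd/Ki, roughly 2–12) come from
binding assays and exist for only a minority of complexes — in a
CrossDocked-scale corpus, 13,301,254 of 22,566,449 poses (58.9%) have
no affinity label. Models for such data are *dual-head*: a shared trunk
feeds a logistic pose-classification head and a linear affinity head,
trained jointly with

* a logistic loss on the good/bad pose label, and
* a **hinged pseudo-Huber** affinity loss
  `L(d) = δ²(√(1+(d/δ)²) − 1)` on `d = pred − label`, applied
  symmetrically on good poses but clipped to `d ≤ 0` on bad poses —
  a bad pose is never rewarded for predicting high affinity.

`poseimpute` implements the *self-training* remedy for the missing
labels: train a five-seed ensemble on the labeled complexes, predict
affinities for the unlabeled ones, turn those predictions into
pseudo-labels under one of eight aggregation schemes, retrain from
scratch on the augmented label set, and iterate until the held-out RMSE
stops improving. The schemes differ along three axes — per-pose vs
per-complex labels, ensemble-averaged vs single-model, and whether the
per-complex statistic (median/max/min) uses all poses or good poses
only. The *median good-only ensemble* (median over a complex's good
poses per seed model, averaged across seeds) is the recommended
default: the hinged loss systematically deflates predictions on bad
poses, so statistics over all poses drag pseudo-labels down.

Everything runs on a synthetic corpus generator that reproduces the
statistical shape of cross-docked data (pose-quality-attenuated
affinity signal, ~5% good poses, 59% missing labels), so the machinery
is testable without any external downloads.

## Worked example

```python
import poseimpute as pi
from poseimpute.experiments import run_one_replicate

history = run_one_replicate(exp_seed=1)   # default 40-pocket corpus
for r in history.rounds:
    print(r.round_index, round(r.mean_rmse, 3),
          round(r.metrics["ensemble_pearson_r"], 3),
          round(r.metrics["top1"], 3))
```

prints

```
0 1.211 0.704 0.923
1 1.156 0.702 0.923
```

Round 0 is the baseline (five seed models trained on the 41% of
complexes that kept their labels; mean held-out-fold RMSE 1.211 pK).
Round 1 retrains after imputing every missing training label with the
median good-only ensemble: mean test RMSE drops to 1.156 pK while pose
classification (Top1 = fraction of complexes whose top-scored pose is
within 2 Å) is unchanged.

The same pipeline is scriptable from the shell:

```bash
poseimpute generate --seed 5 --out-dir corpus       # .types + features + truth
poseimpute stats --types corpus/corpus.types
poseimpute train --types corpus/corpus.types --features corpus/features.csv \
                 --seed 1 --out model.json
poseimpute rounds --train-types train.types --test-types test.types \
                  --features corpus/features.csv --seed 2 --out-dir run/
```

## Layout

| module | contents |
|---|---|
| `poseimpute.corpus` | pose records, `.types` dialect, clustered folds, stats, label application |
| `poseimpute.synthetic` | seeded synthetic corpus generator + truth tables |
| `poseimpute.objective` | hinged pseudo-Huber + logistic losses, balanced pocket-stratified sampler |
| `poseimpute.learner` | numpy dual-head MLP, SGD schedule with patience-driven LR ladder, seed ensembles |
| `poseimpute.imputation` | the eight schemes, fractional label inclusion, the round loop |
| `poseimpute.evaluation` | top-pose selection, RMSE/R/R²/AUC/Top1, bootstrap + t-test machinery |

See `docs/methods.md` for the model, parameter and design details.
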