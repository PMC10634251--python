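# Methods

## Data model

A corpus is a flat table of docked poses. Each pose belongs to a
*complex* (one ligand docked against one binding pocket) and each
complex to a *pocket* (a Pocketome-style group of similar binding
sites treated as one target). A pose is **good** iff its RMSD to the
crystal pose is strictly below 2 Å; the threshold is the single
source of truth — a pose-label column that disagrees with the RMSD is
logged and overridden. Ties at exactly 2.0 Å classify as bad ("less
than 2 Å" read strictly).

Affinity labels are pK values shared by every pose of a complex. On
disk (the `.types` dialect: `pose_label affinity rmsd rec_path
lig_path`) the missing-label sentinel is `0.000`, which is outside the
meaningful pK range; in memory a missing label is NaN paired with an
explicit `affinity_source ∈ {experimental, imputed, missing}` so a
real value can never be silently conflated with absence. Negative
affinities are rejected outright: some public dialects encode the
pose hinge in the label's sign, but here good/bad is carried by RMSD
alone, and accepting both conventions invites silent misreads.

Cross-validation folds are assigned at the level of pocket-similarity
*clusters* (cluster → uniformly random fold), so related pockets never
straddle a train/test split. The fold of a complex is the fold of its
pocket; three folds by default.

## Synthetic corpus generator

The generator emulates the statistical structure of a cross-docked
corpus, not its chemistry. Defaults (the study conditions used
throughout the tests):

| parameter | default | meaning |
|---|---|---|
| n_pockets × ligands_per_pocket | 40 × 4 | 160 complexes |
| poses_per_complex | 20 | docking request size |
| good_pose_rate / cognate_good_prob | 0.05 / 0.8 | non-cognate vs cognate redock success |
| pk_mean, pk_sd | 6.0, 1.5 | per-complex pK ~ Normal, truncated to [2, 12] |
| feature_dim | 16 | per-pose feature vector |
| signal_weight, quality_weight, noise_sd | 1.0, 1.0, 0.1 | see below |
| missing_fraction / mechanism | 0.59 / by_complex | label coverage |

Good-pose RMSDs are Uniform(0.2, 1.8) Å, bad Uniform(2.5, 10) Å —
only the 2 Å dichotomy matters downstream. Per pose the feature
vector is `pK·q·u + q·v + ε`, with latent quality `q = exp(−rmsd/2)`,
`u, v` fixed random unit directions per corpus and `ε` isotropic
Gaussian noise. The multiplicative `pK·q` term is the load-bearing
choice: affinity information is *attenuated by pose quality*, so
high-RMSD poses carry weak affinity signal, which is what makes
good-only aggregation meaningfully different from all-pose
aggregation. `noise_sd = 0.1` is set so that the closed-form
least-squares decode of pK from good-pose features attains Pearson
R ≳ 0.83 — a stated recoverability floor (R ≥ 0.8) that leaves
headroom between the linear oracle and the trained learner.

The pK distribution is a stand-in, not a calibrated fit to any real
label set. Label hiding is missing-at-random at the complex level by
default (assay coverage is a property of the ligand, not the pose); a
`by_pocket` mechanism exists to probe pocket-level missingness bias.
What passing tests on this corpus show is that the machinery behaves
as specified and that the benefit of imputation holds *when the
generator's assumptions hold*; they say nothing about docking physics,
chemical series effects, or distribution shift in real corpora.

## Objective

* Pose head: logistic loss `−ln clip(p, 10⁻⁶, 1−10⁻⁶)`; the clip
  bounds the loss for numerical safety.
* Affinity head: pseudo-Huber `δ²(√(1+(d/δ)²) − 1)` with `d = pred −
  label`, hinged to `max(0, d)` on bad poses. Default `δ = 4.0` pK
  keeps the loss quadratic over realistic errors; the transition scale
  is a knob, not a fitted constant. The rule applies identically to
  experimental and imputed labels. Missing labels contribute nothing
  and are excluded from the affinity-term normalization (not averaged
  in as zeros).
* Combined batch loss: `1.0·mean(pose) + 1.0·mean(affinity over
  labeled)`; equal weights by default since no principled ratio is
  available.

Batches (default 50) are exactly class-balanced: each slot draws a
pocket uniformly at random among pockets possessing the required
class, then a pose of that class within the pocket uniformly with
replacement. This upsamples the minority class (good poses) and
samples every pocket evenly regardless of its pose count.
Stratification is pocket-level; sampling individual receptors within
a pocket is not modeled since the generator has one receptor per
pocket.

## Reference learner

A feed-forward network (16 → 64 → 64 ReLU, shared trunk, logistic
pose head + linear affinity head) in plain numpy, trained by SGD with
momentum 0.9, weight decay 0.001 and initial learning rate 0.01. The
shared trunk couples the two tasks, which is what lets imputed
affinity labels move pose classification as a side effect. The
learner is deliberately pluggable: the imputation engine only needs a
`(pose_score, affinity)` predictor, and any stronger model (e.g. a 3D
CNN over voxelized complexes) can stand behind the same contract.

Early stopping monitors the combined loss on a *reduced set* — 13.2%
of training complexes drawn complex-wise without replacement at
training start and fixed thereafter. Every `eval_interval` iterations
the reduced-set loss is recorded; after `patience_evals` evaluations
without improvement the learning rate divides by 10; after three
drops, the next stall terminates training. The monitored quantity is
the loss (the only always-defined choice). Two schedules ship:
the full-scale one (eval every 1000 iterations, patience 200) and a
desk-scale one (`TrainConfig.desk()`: eval every 100, patience 10,
cap 20,000 iterations) used for all synthetic-corpus experiments,
where a model trains in seconds. No feature-space analog of geometric
train-time augmentation is applied.

Everything is deterministic given the config seed: initialization,
the reduced-set draw and the batch stream all derive from it.

## Imputation schemes

For the per-pose schemes, *individual* gives each seed model its own
pseudo-labels (five different training sets); *individual_ensemble*
averages the five models per pose (one shared training set, but
pose-specific labels — unlike experimental data). The six per-complex
schemes compute, per seed model, the median/max/min of the predicted
affinities over the complex's poses — optionally good poses only —
then average the per-seed aggregates into a single label written to
every pose of the complex, exactly as an experimental label would be.

Design points the underlying protocol leaves open, resolved here:

* **No-good-pose fallback.** A good-only scheme on a complex with zero
  good poses falls back to the all-pose statistic and flags it in
  provenance, rather than silently shrinking the imputed set.
* **Clamping.** Imputed labels are clamped to [2, 12] pK so model
  extrapolations cannot inject physically impossible targets.
* **Re-imputation.** Each round re-imputes *all* missing labels with
  the current models rather than accumulating labels across rounds.
* **Fresh retraining.** Each round trains new models from fresh
  initialization (round-derived seeds), never warm-starts.
* **Stopping.** The loop stops when mean per-seed test RMSE fails to
  improve on the previous round, or at `max_rounds`.

Fractional inclusion (`select_fraction`) draws one random permutation
per seed and takes the first `round(f·n)` complexes, so the 20%
subset is contained in the 40% subset and so on — cumulative by
construction.

## Evaluation and statistics

Per complex the candidate pose is the highest pose score (exact ties
break to the lexicographically smallest pose id, for determinism).
RMSE, Pearson R and R² are computed over labeled complexes only; R² is
reported primarily as 1 − SS_res/SS_tot with the squared Pearson
correlation as a secondary column, since "coefficient of
determination" is ambiguous between the two. AUC is computed globally
over all test poses via midranks (ties count ½), and equals exhaustive
pair counting exactly; Top1 uses all complexes in the denominator,
whether or not they possess a good pose.

Significance machinery: percentile bootstrap CI of a mean
(zero-width by construction on constant input); unpaired
pooled-variance Student's t-test between per-model metric populations
(the compared models differ in seed and training data, so pairing has
no basis; degenerate zero-variance equal-mean input returns p = 1 by
convention); and a 10,000-replicate bootstrap of the RMSE that
resamples complexes, declares significance on non-overlapping 95%
intervals, and also reports a one-tailed bootstrap p for the
difference of means.

## Problem sizes

The default benefit experiment uses the 40-pocket corpus (3,200
poses), a 2:1 clustered pocket split, five seed models per round and
one imputation round, replicated over five experiment seeds — about
half a minute per replicate on one CPU. These sizes are the package's
chosen desk-scale study conditions; the directional conclusion
(imputation does not hurt, and usually helps, held-out RMSE) is the
claim under test, not any particular magnitude, which at this scale
is corpus-dependent.

## Known limitations

* Fallback labels are biased low: on a complex with no good pose the
  all-pose statistic runs over predictions the hinged loss has
  deliberately deflated, and a handful of such labels in a replicate
  can measurably hurt the retrained models (fallback counts are
  flagged in provenance for exactly this diagnosis). Replicates with
  few fallbacks show the clearest imputation benefit.
* The generator's linear-plus-noise feature model is far simpler than
  real scoring-function inputs; absolute metric values on it do not
  transfer.
* Pockets are generated independently — no inter-pocket similarity,
  hence singleton clusters in the fold assignment; the clustered-fold
  machinery is exercised structurally, not statistically.
* The reference learner is a small MLP; conclusions about CNN-scale
  capacity effects are out of scope.
* Multiple-imputation variants with uncertainty propagation and
  imputation from external label sources are not implemented.
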