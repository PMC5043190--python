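# Methods

## The paradigm being modelled

A recognition-memory experiment on movie events. The stimulus unit is a
*shot*: a contiguous run of frames between two cuts, 1–90 frames long at
30 frames/s. Subjects watch one episode of a serial drama; their memory is
then probed in an old/new task in up to six sessions at nominal retention
intervals of 0, 1, 7, 30, 90 and 365 days. Probes mix shots from the
watched episode (*targets*) with shots from the unwatched consecutive
episode (*foils*) in equal proportion, so chance is 50%. Because
consecutive episodes share characters, wardrobe, locations and filming
style, and because foils are explicitly matched to targets on character
and viewpoint annotations and on duration, the discrimination rests on
genuine episodic memory rather than low-level cues. A small fraction (3%)
of queries is repeated later in the experiment to measure self-consistency.
Each shot carries a content-annotation vector **x**: presence bits for 29
characters (with per-character viewpoint bits), 13 sounds, 20 emotions and
25 objects; scalar flags (action, indoor/outdoor, emotion depicted,
emotion elicited); counts (characters, objects in shot); and continuous
measures (frames, contrast, color content, sound level).

## The synthetic generator

No raw data are distributed with this paradigm, so every analysis stage is
validated against a simulator whose ground truth is known. The generative
model is deliberately the simplest monotone model consistent with the
paradigm's empirical regularities (performance rising with shot duration,
falling with retention interval, modulated by content and by manipulation
condition):

```
logit p(correct) = base_logit + β·x
                 + γ·log(n_frames)            # duration_weight
                 − δ·log(1 + elapsed_days)    # retention_rate
                 + a_s                        # subject ability ~ N(0, σ_a²)
                 + foil_bias·[foil]
                 + manipulation_offset[condition]
```

with `p` clipped to `[0.02, 0.98]` and trial correctness an independent
Bernoulli draw. Single-frame presentations use `n_frames = 1` with the
parent shot's content vector. Real data certainly violate several of these
assumptions — content and retention interval are treated as additive (no
"emotional shots decay slower" interaction), trials are conditionally
independent given the shot and subject, and there is no serial-position,
fatigue or learning-across-sessions structure — so passing tests certify
the *estimators*, not any claim about real memory.

Key defaults, chosen once to land the simulation in the empirically
realistic regime and left alone thereafter:

| parameter | default | unit / rationale |
|---|---|---|
| `base_logit` | 0.8 | log-odds; with the defaults below gives overall pc ≈ 0.80–0.83 and single-frame pc ≈ 0.73–0.79, inside the range spanned by multi-session and single-session variants of the paradigm |
| `true_weights` | 12 features, &#124;β&#124; 0.5–1.2, both signs | log-odds per feature; sparse strong drivers over a mostly-null inventory, so shots span a wide difficulty range and a sizable minority is consistently forgotten |
| `duration_weight` γ | 0.35 | log-odds per log-frame; reproduces the rising duration curve |
| `retention_rate` δ | 0.25 | log-odds per log-day; gives a clearly decaying but above-chance retention curve out to a year |
| `subject_ability_sd` σ_a | 0.5 | log-odds; inter-subject pc SD ≈ 0.05–0.08 |
| `foil_bias` | 0.0 | targets and foils equally hard, matching the paradigm's null target/foil difference |
| `manipulation_offsets` | sound −0.5, occlusion −1.2, reversal −0.6, flip/grayscale 0 | high-level disruptions impair, low-level ones do not |
| `session_days` | 0, 1, 7, 30, 90, 365 | test times sampled uniformly in each session's scheduling window (15–30 min; 22–26 h; days 6–8; 27–33; 85–95; 335–395) |
| `repeat_fraction` | 0.03 | repeats scheduled as whole target+foil pairs in a strictly later session, preserving per-session class balance |
| inventory | 29/13/20/25 (+viewpoints, flags) | the annotation vocabulary of the paradigm |
| `feature_probs` | weighted features pinned (0.25–0.5); others ~ Beta(1.2, 3.5) clipped to [0.02, 0.9] | recurring characters appear in a stable fraction of shots; pinning makes the difficulty composition reproducible across seeds, while unpinned features span common-to-rare |
| `n_subjects`, `n_shots_per_episode` | 41, 300 | a cohort of the paradigm's size over a desk-scale movie |

Shot durations are log-uniform on [1, 90] frames (only the range is an
empirical constraint; the log-uniform shape produces the realistic
preponderance of short shots) and tile each episode's frame axis exactly
(0-based frames, half-open spans). Foil matching is greedy over all
target×foil pairs sorted by Hamming distance on character+viewpoint bits,
then absolute duration difference, then shot id — deterministic, and
verified in tests against an exhaustive optimal-assignment oracle on small
instances. All randomness flows from one seed through four named
substreams (shots, annotations, schedule, responses), so identical configs
give byte-identical tables.

## Analysis conventions and numerical choices

- **Percent correct** pools target and foil trials; with the balanced
  design, pooled pc equals (p_hit + 1 − p_FA)/2 exactly on counts. Pooled
  summaries weight subjects equally (subjects, not trials, are the
  replication unit); per-trial weighting would change little here but is
  not offered as a default.
- **d′** clips rates to [1/(2N), 1 − 1/(2N)] before the normal quantile so
  degenerate rates in finite samples stay finite.
- **Exclusions**: first 5 trials of each session; subjects with <400
  trials, >75% "old" responses, or <60% overall accuracy. No proportion is
  reported from fewer than 20 trials (suppressed cells are flagged, never
  numeric).
- **Retention curves** correlate accuracy with the session's *ordinal
  rank*, since the session spacing is strongly non-linear in time; constant
  curves report r = 0 with a flag rather than NaN.
- **Permutation tests** use the add-one estimator
  (1 + #{|perm| ≥ |obs|})/(n_perm + 1), so p ∈ [1/(n_perm+1), 1];
  Bonferroni-adjusted p is min(1, m·p). With heavily tied small binary
  samples the estimator is conservative (super-uniform p); at the
  package's operating sizes (groups of per-subject accuracies, or
  hundreds of trials) it is calibrated, which the test suite checks.
- **Content-property inference** permutes the property assignment *across
  shots* rather than across subjects. This matters: shots vary widely in
  difficulty and every subject sees the same shot sample, so a
  subject-level permutation mistakes shared shot-sampling noise for a
  content effect (measured ≈50% false positives under a null property in
  a high-heterogeneity regime); the shot-level null is exact under the
  hypothesis that the property is unrelated to shot difficulty, and is the
  same construction as the classifier's shuffle null. Significance flags
  use α = 0.01 after Bonferroni (configurable).
- **Consistency nulls**: under independence the inconsistent-pair count is
  Binomial(n, q) with q = 2p(1−p) (self) or p_i(1−p_j) + p_j(1−p_i)
  (pairwise — completed by the complement rule so each triple sums to 1);
  two-sided Monte-Carlo p from 10,000 binomial draws. Majority votes with
  ties are excluded rather than broken at random, keeping every statistic
  deterministic.
- **Classifier**: linear-kernel SVM (hinge loss, fixed C = 1), features
  z-scored on the training folds only, shots assigned to stratified folds
  so no shot straddles train and test. Classes are balanced before
  training (all of the minority class plus an equal-size random subsample
  of the majority), anchoring chance at 50%; accuracy mean ± SD is over 25
  subsample repetitions × 10 folds by default. The shuffle null re-runs
  the entire pipeline per label permutation (one subsample repetition per
  iteration); the CLI defaults to 1,000 iterations, with 10,000 the
  full-scale setting.
- **Group regression** is OLS, switching to ridge (α = 1, reported) when
  shots number fewer than five per feature; r² is the squared Pearson
  correlation between held-out predictions and actual group accuracy.
- **Upper bounds**: the majority-based predictor predicts a subject's
  correctness per shot from the untied majority of ≥3 other subjects; the
  self-prediction predictor predicts a repeat presentation from the first
  one, so its accuracy is identically 1 − (inconsistent fraction) — an
  identity the tests assert across modules.
- Open choices resolved as package policy: foil trials use the presented
  shot's own annotations (a `targets_only` switch exists); repeats are
  included in pc; per-subject classification trains within subject;
  per-subject labels aggregate repeated presentations by majority with
  ties dropped; label sets must come from a single presentation condition.

## Problem sizes

The shipped test-and-validation configurations use 12–20 subjects and
200–2,000 shots, with 150–1,000 permutation/null iterations — sizes at
which every statistical check (chance anchoring, null calibration,
parameter recovery, the behaviour-over-content ordering) is decisively
powered while a full run of the suite plus the acceptance script completes
in a couple of minutes on one core. Scaling the generator or the iteration
counts up is a matter of configuration, not code.

## Known limitations

- The generator's logistic-additive form is an artifact of parsimony; it
  cannot produce interaction effects (e.g. content-dependent forgetting
  rates) and so cannot validate estimators of such interactions.
- Manipulations exist only as condition labels with log-odds offsets; no
  frames or audio are rendered, and annotation noise (inter-annotator
  disagreement) is not modelled.
- Eye movements, response times and serial-order effects are out of scope.
- The pairwise consistency p-value treats the two subjects' accuracies as
  known rather than estimated; with ≥20 shared shots and the Monte-Carlo
  null this bias is negligible at the package's operating sizes.
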