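# Methods

This note records the models, parameter choices and numerical conventions
behind `stabselect`, and what the synthetic cohort does and does not
emulate.

## Study setting

The package targets two-group (autistic vs non-autistic) classification
from movement-imitation data: per participant, per experimental block
(general instruction vs attention instruction) and per condition (direct,
elevated, direct-fast), trial-level kinematic and gaze measures are
aggregated into mean and SD features. One block yields 168 features
(120 kinematic = 3 × 20 × 2; 48 eye = 3 × 8 × 2) against development
samples of 15+15 participants and an independent test sample of 7+7 —
a regime where selection stability and leakage control dominate.

## Synthetic cohort generator

### Matrix route (`generate_feature_matrix`)

Each modality within a block shares one standard-normal latent factor g;
feature j of sample i is x_ij = a·g_i + √(1−a²)·ε_ij with ε iid N(0,1).
Features therefore have unit variance and pairwise correlation a², so the
loading a = √r̄ hits a target mean inter-feature correlation exactly
(defaults r̄ = 0.20 kinematic, 0.48 eye). Planted effects are group mean
shifts of d on the named features (autistic lower for mean-statistics,
higher for SD-statistics); because features are standardised, the realized
population effect size equals d by construction.

Trial-level variability inflation (default 1.3× on autistic trial SDs)
appears in this route as a mean shift of (v−1)·0.25/0.3 SD units on every
SD-statistic feature of the autistic group — at v = 1.3 a d ≈ 0.25 shift,
which makes roughly three quarters of variability features higher in the
autistic sample at n = 15+15. Planted ids override (rather than add to)
this shift so specified effect sizes stay exact. Development and test
samples are independent seeded draws from the same shifted population.

### Trial route (`generate_trials`)

Movement trials are synthesised from five generative parameters per
participant × condition: movement time D, apex height h, apex position p,
a longitudinal time-warp (skew) s and a lateral amplitude. The
longitudinal profile is minimum-jerk over warped time τ^s covering 0.15 m;
the vertical component is a smooth beta-shaped bump of height h peaking at
p (a generalisation of a parabolic arc that supports timing asymmetry);
0.3 mm Gaussian measurement noise is added at 120 Hz. Condition baselines
(direct 0.45 s / 0.02 m, elevated 0.55 s / 0.08 m, direct-fast 0.30 s /
0.02 m) and the parameter SDs are plausibility-scaled for adult pointing
movements — per-condition means/SDs of the original kinematic measures are
not published, so magnitudes are chosen once as realistic rather than
calibrated.

Group effects are injected on the parameters: a planted mean-statistic
effect d shifts the autistic mean of the driving parameter by d times the
between-participant SD of the corresponding extracted feature,
√(σ_p² + σ̄_t²/T). The mapping is exact where the measure is the parameter
(vertical amplitude ← h, duration ← D, pct-to-peak-height ← p) and
approximate where measures share a driver: all timing percentages ride on
the single skew parameter (so coupled plants use the averaged shift — the
physiologically coupled "earlier peak acceleration, later peak
deceleration" pattern emerges from one parameter), and peak/mean
velocity, acceleration and jerk ride on D. `n_velocity_peaks` has no
monotone single-parameter driver and cannot be planted at trial level.
SD-statistic plants scale the autistic trial-level parameter noise using
the c₄ bias factor of the sample SD. Monte-Carlo checks recover a planted
d = 0.93 on elevated vertical amplitude to within ±0.25 at 22/22.

Gaze trials carry pre-parsed saccade and fixation events synthesised from
per-trial target values of the 8 eye measures (per-condition latents with
a shared eye factor); event-level resampling (Poisson-like saccade counts,
Bernoulli dwell flags) adds within-trial noise beyond the specified trial
SDs, so trial-route eye effect sizes are mildly attenuated. A configurable
fraction of gaze trials (default 0.12) is marked with a missing-data
fraction drawn uniformly on [0, 0.6]; screening later drops those above
1/3.

What the generator does **not** emulate: raw eye-tracker sample streams,
pupil data, sequence-level task structure, age/IQ covariates,
non-Gaussian heavy tails, or block-order learning effects. Passing tests
on this cohort show the pipeline's statistical machinery is correct and
calibrated — not that comparable accuracies would be reached on any
particular real cohort.

## Feature extraction

Positions are zero-phase filtered (4th-order Butterworth low-pass, 10 Hz
cutoff — standard for reaching; forward–backward filtering squares the
gain, and the nominal recording-rate figure sometimes quoted for such
filters cannot be a cutoff at a 120 Hz sampling rate). Derivatives use
central differences with one-sided ends (`np.gradient`). Conventions: the
longitudinal axis is the start→end chord; vertical amplitude is the
maximum elevation above the chord baseline in z; peak deceleration is the
magnitude of the most negative longitudinal acceleration; timing measures
are percentages of movement duration; `mean_velocity` is path-integrated
speed over duration; normalized jerk is √(½·∫j²dt·D⁵/L²); velocity peaks
are counted with a 5 % prominence threshold. Cells backed by fewer than
two retained trials are left missing for imputation.

## Preprocessing

Trial-level outliers use the non-recursive sample-size-dependent criterion
(remove points beyond C(n)·SD; C rises from 1.458 at n = 4 to 2.50 at
n ≥ 100, linearly interpolated, single pass, no removal below n = 4) —
a fixed 2.5·SD rule would remove almost nothing at small n. Gaze trials
with missing-data fraction strictly above 1/3 are dropped (exactly 1/3 is
retained). Group-level outliers (same criterion across participants) and
remaining missing cells are replaced by group means; a held-out set is
imputed from development-set group means so the test sample never informs
its own imputation, and a strict mode ignores labels entirely (pooled
means) for sensitivity analysis. Z-scoring uses training-only means and
unbiased SDs, with divisor 1 recorded for constant training features.

## Selection

All selectors return exactly k features (default k = 10, the small-sample
optimum commonly used at these training sizes) and share one
deterministic tie-break: primary score, then |t|, then lexicographic
feature id.

* **t**: pooled-variance two-sample t, ranked by |t|.
* **SVM-RFE**: linear-kernel weight magnitudes, dropping 10 % (≥1) of
  remaining features per iteration (a step-1 variant backs the tests);
  the linear kernel is used for elimination because weight-based ranking
  requires it, even though the final classifier is RBF.
* **ReliefF**: range-scaled Manhattan diffs, k = 10 nearest hits/misses
  (clipped to class size − 1), every sample used once.
* **mRMR**: 3-bin discretisation at mean ± SD, greedy MID
  (relevance − mean redundancy, mutual information in nats); MIQ available.
* **Ensemble**: Borda (rank-sum) aggregation of the four rankings.
* **Bagged t**: 100 stratified half-size subsamples without replacement;
  final set = most frequently top-k-ranked features, ties by mean |t|.
* **Wrapped t**: described in the README. The fold partition is frozen
  for the run so KI measures selection stability, not partition noise;
  per-fold base |t| is precomputed and only adjustments evolve, and fold
  accuracies are cached per (fold, set). Inside the loop the SVM uses
  fixed hyperparameters (C = 4, γ = 2⁻⁴, configurable) — grid-searching
  per fold per iteration would be prohibitive and is unspecified; the
  reported models are re-tuned by the evaluation module's full grid
  search afterwards. Adjustments are applied per fold as the iteration
  proceeds. δ defaults to 0.0001 with a 100 000-iteration guard.

**Known failure mode (deadlock).** If two competing features are each
selected by exactly half the folds, their adjustments accumulate at equal
rates and the disagreement never resolves: KI plateaus below 1 and the
run hits the iteration cap, raising a `ConvergenceError` that carries the
full state. This is a property of the update rule itself, observed in
roughly one in ten seeded runs at moderate signal; re-running with a
different fold partition typically converges.

**Recoverability.** Whether the stabilised set matches a planted signal
depends on the instance, not just the algorithm: at d ≈ 0.8 and n = 15+15
the planted |t| values (≈2.0–2.6) interleave with the upper order
statistics of 158 null features, so no filter — including the population
oracle — can reliably return 8 of 10 planted features. Recovery tests
therefore use d = 1.5, the smallest round effect size at which the
population top-10 coincides with the planted set with high probability;
the study-scale effect sizes are exercised by the development/testing
agreement checks instead.

## Evaluation

Outer and inner folds are stratified (the balanced design underlies the
50 % chance level the wrapped update rule assumes). The SVM-RBF grid is
C ∈ {2¹…2⁷} × γ ∈ {2⁻⁷…2⁻¹}, tuned by inner 10-fold CV accuracy; ties
prefer the smallest C, then the largest γ (the smoother model).
Development accuracy is the mean of the ten fold accuracies; the ten fold
models (each with its own normalisation, feature subset and classifier)
are applied to the held-out sample and their metrics averaged, with
autistic as the positive class — on a balanced test set accuracy equals
(sensitivity + specificity)/2 identically. `repeat_runs` redraws outer
partitions (default 50 repeats) for distributional summaries. The
permutation test permutes development and test labels jointly and reruns
the entire pipeline, selection included, per permutation (required for
the p-value to cover the whole procedure); with 100 permutations the
attainable floor is 1/101 ≈ 0.0099. Permuted pipelines redraw fold
partitions rather than reusing the observed ones, and p is computed
against the observed mean testing accuracy.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the study's own scale where
the quantity demands it (15+15 cohorts, 168 features, 20 seeds for the
null-calibration and agreement checks; 10 seeds for wrapped convergence)
and at reduced scale elsewhere (wrapped δ scaled to 0.01 so stabilisation
takes hundreds rather than tens of thousands of iterations; repeat counts
of 1–5 in examples). Correlation and effect-size calibrations are checked
at n = 500–2500 per group via direct recomputation.

## Known limitations

* The 20 kinematic and 8 eye base measures are this package's canonical
  decomposition of the published feature counts (120 and 48 per block);
  the original measure lists are not fully published, so individual
  measures may differ even though the layout matches.
* Trial-level planting is approximate for measures sharing a generative
  driver, and unavailable for `n_velocity_peaks`.
* Group-mean imputation uses class labels (as published); the strict
  pooled mode exists precisely because label-aware imputation is a known
  leakage vector worth auditing.
* The wrapped selector can deadlock (above); the guard surfaces rather
  than hides this.
* No ROC/AUC reporting and no classifiers beyond SVM-RBF; no model-based
  imputation.
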