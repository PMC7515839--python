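# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `feardecode`: what the synthetic cohort emulates, how
each analysis stage is defined, and what the passing test suite does and
does not establish about real data.

## The synthetic cohort

The generator produces everything the analysis consumes, with the
statistical structure the method assumes. It is first-class, tested code,
not a fixture.

**Design.** Six runs of 600 image presentations, one per TR (2 s), in
chunks of 2, 3, 4, or 6 images of one animal category. The per-run chunk
composition {2:12, 3:12, 4:18, 6:78} is chosen to satisfy the recoverable
totals — 600 presentations and 120 chunks per run, hence 720 chunk-first
trials per subject — since only those totals are pinned down; the
per-size counts themselves are a feasibility default. The pseudo-random
chunk order and category assignment are balanced per run (each category
gets 4 chunks/run) and, as in the study, the sequence is fixed across
participants. Inter-chunk breaks are not modeled.

**Fear ratings.** Offline semantics: one ordinal 0–5 rating per subject
and category, constant across that subject's trials of the category. A
latent normal `z = sqrt(0.35)·category + sqrt(0.15)·subject +
sqrt(0.50)·residual` is cut at fixed standard-normal quantiles so the
marginal level distribution matches the study's printed group shares
(41% no fear; 14.7/15.9/12.8/11.0/4.6% for levels 1–5, renormalized if
`fear_zero_target` is changed). Category variance must be substantial for
a category-level rating–SCR correlation to exist at all; its flip side is
irreducible seed-to-seed variation in any single cohort's summary
statistics (see *Calibration checks* below).

**SCR amplitudes.** Zero-inflated and right-skewed. Per chunk-first
trial, a drive `d = coupling·z(rating) + b_category + g_subject` with
`b ~ N(0, 0.55²)` (category-specific reactivity, shared across subjects,
independent of the fear latent) and `g ~ N(0, 0.3²)`. The trial responds
with probability `expit(a + d)`, where the intercept `a` is solved by
bisection so the expected sub-0.2 μS share equals its target (71.79% by
default) exactly under the realized ratings. Responders draw
`0.2 + lognormal(log 0.25 + 0.3·d, 1.0)` μS. The lognormal dispersion
(σ = 1.0) matters: it spreads the within-subject quintile means of
√amplitude so that the 0–5 SCR level scale is reasonably linear in the
underlying signal; with a narrow dispersion the 0→1 jump dominates the
scale, capping every pooled prediction–level correlation for the SCR
decoder well below the fear decoder's and distorting the region
comparison. The default `coupling = 0.45` was calibrated once, by a
sweep over 20–30 seeds, so the group category-level correlation
(computed by the package's own scoring pipeline) averages ≈ 0.43.

**Encodings.** Regions (40 by default, 50 voxels each, contiguous
blocks) are assigned roles — fear-only 20%, SCR-only 20%, both 10%,
null 50% — with exact largest-remainder counts, shuffled. Voxels in
fear-coding regions get `w_fear ~ N(0, effect_size²)`, analogously for
SCR; role-zero constraints hold exactly. Trial betas are
`w_fear·rating + w_scr·sqrt(amplitude) + N(0, noise_sd²)` with
`noise_sd = 3` — strong trial-level noise that binning attenuates.

**BOLD and electrodermal traces.** BOLD run series are sums of
HRF-convolved impulses at presentation onsets (canonical double-gamma,
peak normalized to 1, positive lobe peaking at 5 s, undershoot at 15 s,
32 s support), optional linear drift and Gaussian noise, with 16 tail
scans per run so late responses complete. The electrodermal trace is a
tonic baseline (2 μS) plus one Gaussian phasic bump per chunk-first trial
(peak 2.5 s post onset, σ = 0.3 s, peak height = planted amplitude) at
10 Hz, padded before the run start so the first baseline window exists.
The narrow bump keeps neighboring trials' scoring windows essentially
uncontaminated — except when a responding chunk of size 2 precedes
another chunk-first trial by 4 s, whose baseline window then overlaps the
previous bump; this affects ≈ 3% of trials and keeps the noise-free
round-trip error near 1% of the amplitude scale, mirroring the
window-overlap artifact the scoring convention is known for.

**What the generator does not emulate:** spatially correlated fMRI noise,
physiological confounds, motion, scanner drift beyond a linear term,
habituation across runs, and image-level stimulus content. Tests passing
on this cohort establish that the machinery is correct and that the
planted structure is recoverable under honest noise — not that real data
carry such structure.

## SCR scoring

Raw reactivity = max over (onset+1, onset+5] minus the *mean* over
[onset−2, onset); the baseline summary is a mean (the convention is not
fully pinned by practice — value-at-onset and minimum are alternatives;
mean is the least noisy). Window membership uses half-open interval
comparisons with a half-sample tolerance at the trace's sampling rate.
Raw values below 0.2 μS (including negative deflections) are recoded to
0; survivors are square-root transformed. Only chunk-first trials are
scored.

The group-level coupling procedure: per subject, drop the first
chunk-first trial of each run (6 of 720; first-of-run reactivity is
atypically large), winsorize the transformed values at the 5th/95th
percentiles (linear-interpolation percentiles; winsorizing is applied
after the √ transform, following the pipeline's stated order), average
within category, z-score across categories (ddof = 1); average the
standardized vectors across subjects, z-score at the group level, and
correlate. Zero-variance standardization returns zeros with a warning
rather than NaNs.

## LSS beta estimation

Per run, data are linearly detrended (least-squares [1, t] projection).
Each chunk-first trial gets its own GLM with four columns: the target
trial's HRF-convolved impulse; all *other* chunk-first trials pooled; all
non-first presentations pooled; an intercept. This two-way split of "all
other trials" is one plausible reading of a two-nuisance-parameter LSS;
the alternative (same-chunk repeats vs everything else) makes the target
nearly collinear with its own chunk's repeats at a 2 s SOA and estimates
far worse, so it was rejected. Event regressors are convolved on a
16x-oversampled grid and read out at scan times; all-zero columns
(degenerate designs) are dropped with a warning; rank deficiency is an
error naming the trial.

The same detrending projection applied to the data is also applied to
the event regressors. By Frisch–Waugh this is equivalent to including
constant + linear drift columns in every trial model, and it is what
makes noiseless signals recoverable without detrending bias; detrending
the data alone would remove signal components the model then misses.

Two facts about recovery at zero noise are worth recording.
*Exactness* holds only when the signal lies in the trial model's column
space — for non-overlapping responses this means within-run-constant
amplitudes — and the exactness test is defined accordingly.
*With overlap*, the pooled nuisance columns cannot absorb per-chunk
amplitude variation: when repeat presentations carry their chunk's full
amplitude, the pooled correlation between recovered and planted
amplitudes is ≈ 0.83 on the default design, a structural property of the
two-nuisance-regressor model rather than an implementation defect (a
per-trial-regressor model would be exact). The machinery round trip is
therefore defined with responses at the modeled chunk-first events only,
where the recovered betas correlate at r ≈ 0.99 with the planted
amplitudes; both numbers are reported by
`analysis/03_lss_validation.py`.

## Binning

Fear bins average trials per rating level; absent levels are omitted.
SCR levels: sub-0.2 μS trials are level 0; suprathreshold trials split at
the within-subject {20,40,60,80}% linear-interpolation percentiles into
levels 1–5, ties toward the lower level; fewer than 5 suprathreshold
trials flags the subject and skips SCR binning. The level-0 image
averages a random, seed-reproducible subsample of level-0 trials sized as
the rounded mean of the five quintile bins (the stated rule does not say
which bin when sizes differ by one; the mean is the symmetric choice).
Binned images are mean-centered within subject, after all bins (including
the level-0 subsample) are formed. Categorical mean images drop each
run's first chunk-first trial (714 of 720 survive) and average within
category.

## Decoding

Linear epsilon-insensitive SVR (C = 1, ε = 0.1 — unstated in the source
procedure, so standard defaults, recorded in results metadata), features
voxelwise z-scored with training-fold statistics only; the scaling is
folded back into the stored weight vector so a decoder is a plain affine
map on raw images. LOSO cross-validation pools held-out predictions over
all subjects; a construction audit verifies no decoder's training-fold
list contains its test subject.

AUC over the 6 ordinal levels is pairwise concordance — over all pairs
with different levels, the fraction where the higher level received the
higher prediction, ties counting 0.5 — which reduces to the standard ROC
AUC for binary labels. It is computed from per-level-pair Mann–Whitney
rank sums.

The permutation test permutes labels within subject and recomputes the
AUC on the *fixed* LOSO predictions (no per-permutation retraining; the
source procedure applies existing decoders to permuted data). The
p-value uses the add-one convention, `p = (1 + #{null ≥ obs})/(B + 1)`,
and the critical value is the order statistic consistent with it (the
⌈0.95(B+1)⌉-th of B null values), so that "observed exceeds the critical
value" coincides with p ≤ 0.05 and the test is calibrated at its nominal
level (rejection probability 10/201 at B = 200 under the null).

Cross-decoding applies each subject's *held-out* fold decoder (trained on
the other outcome's data from the other subjects) to that subject's
other-outcome images; subject overlap raises a leakage error. A caveat
established during development: under a strict independence null the
cross-decoding AUC of a *single* cohort is widely dispersed around 0.5,
because the held-out outcome's signal is effectively one-dimensional and
the decoder's noise loading onto it is a single random scalar; the
chance-level property is an expectation, and the tests estimate it by
averaging over many independent small cohorts.

Categorical prediction: each subject's 30 category-mean images are
predicted by their held-out decoder; predictions are winsorized
(5th/95th) and z-scored within subject, averaged per category across
subjects, z-scored, and correlated with the identically processed
outcome vector. Cohort generalization refits one decoder on all
discovery subjects and applies it frozen. Single-trial evaluation
mean-centers each subject's trial betas (matching the centered training
space) and reuses the same predict + AUC path.

## Region comparison

Per region and outcome, the full LOSO pipeline runs on that region's
voxels; the pooled prediction–level Pearson r and the concordance AUC are
recorded. The two correlations are compared with the Fisher r-to-z
difference; `n` is the pooled prediction count per outcome (subjects
times bins — which `n` belongs in the formula is ambiguous; pooled
points is the adopted reading and both counts are reported). The two
correlations share test images, so the tests are dependent; the
difference test does not correct for this — the dependence is instead
acknowledged by controlling the family's FDR with Benjamini–Yekutieli
(step-up with the harmonic-sum penalty c(m), implemented via statsmodels
and cross-checked against hand arithmetic), which is valid under
arbitrary dependence. Preferences are assigned by the sign of Z where
q < 0.05; ΔAUC = AUC_fear − AUC_scr is reported for every region. The
conjunction flags regions whose AUC exceeds its own permutation critical
value for *both* outcomes.

## Calibration checks and their reading

Three generator calibrations are asserted over ≥ 20 seeds as
across-seed means: the no-fear trial share (0.41 ± 0.05), the sub-0.2 μS
share (0.72 ± 0.05), and the group rating–SCR correlation ([0.3, 0.55]).
Single seeds carry irreducible sampling noise from 30 category and 20
subject random effects (sd ≈ 0.05 for the shares; sd ≈ 0.17 for one
r(28)), so per-seed bands of that width would reject valid generators;
the targets are population quantities and the mean is their estimator.

## Problem sizes

Defaults were chosen so the full suite runs on one CPU in minutes: 20
subjects, 2000 voxels, 40 regions (50 voxels each) for the pipeline
recovery checks; 200 voxels for the noiseless LSS round trip; 200
permutations for region-level critical values and the type-I calibration
(500 datasets); 300 ten-subject cohorts for the cross-decoding null; the
whole-brain permutation test uses the full 1000.

## Known limitations

- The region comparison inherits the source procedure's dependence
  between the two per-region correlations; Z-values are interpretable as
  rankings and the FDR control is the safeguard, but the per-region p is
  not exact.
- LSS with pooled nuisance regressors is biased under amplitude-carrying
  repeat presentations (quantified above); real repeat responses likely
  sit between the two regimes reported.
- The synthetic noise model is spatially white; real-data AUCs and
  region statistics will be less favorable at matched effect sizes.
- Winsorizing under linear-interpolation percentiles is a fixed point
  only when percentile positions align with order statistics; repeated
  application shrinks tails by a vanishing amount otherwise.
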