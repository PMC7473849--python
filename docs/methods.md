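# Methods

This note documents the models, defaults and numerical choices behind
`memdecode`, and what the synthetic validation does and does not
establish.

## Task and schedule model

The simulated experiment is an item-recognition decision task with a
delayed, counterbalanced motor report. Retrieval trials present an image
for 1.5 s with a peripheral target, impose an 8 s delay, then a 1 s
go-signal for a saccade or pointing movement toward the remembered target;
the inter-trial interval is drawn uniformly from {2, 3, 4} MR frames at
TR = 1.914 s. The full design has 12 runs of 30 trials, 5 per retrieval
stimulus type. The six stimulus types tie memory status to evidence
level: old items were encoded once / three times / five times
(low / middle / high evidence), new items are perceptually-and-semantically
related / semantically related / unrelated lures (low / middle / high).
The encoding session (15 blocks; per block 4 once-presented, 4
encoding-only, 12 thrice-presented, 20 five-times-presented images from 60
scene categories; 240 distinct images, 420 over the whole experiment) is
generated for completeness; its BOLD is not simulated because no analysis
consumes it.

Decisions that the design left open and were fixed here once: group A1
maps old→eye / new→hand and A2 the reverse (only the reversal matters;
the assignment is recorded in each cohort's sidecar); the ITI distribution
is uniform over its stated 2–4-frame range; target side is balanced
within run; the go/execution epoch is 1 s, matching the execution
regressor.

The simulated observer chooses the true status with probability
`p_correct[(status, evidence)]` per trial. The default table —
old/low 0.50, new/low 0.65, both 0.75 at middle and 0.87 at high —
follows the behavioral profile this design produces in practice: graded
accuracy in evidence, chance performance for weakly encoded old items,
and residual discriminability for the hardest lures. The behavioral
three-way mixed ANOVA (status × evidence within, group between) is the
standard balanced split-plot decomposition: each within-subject effect is
tested against its own factor-by-subject stratum, the group effect against
subjects-within-groups. No installed package covers the 2-within ×
1-between case, so the sums of squares are computed directly from cell
means; the suite checks them against an explicit design-matrix projection
oracle (and they agree with R's `aov` to machine precision). Post-hoc
comparisons use pairwise paired t tests with Holm correction, a
conservative substitute for range-based post-hoc procedures.

## Forward model

BOLD for voxel v at frame t is

    y_v(t) = Σ_p w_pv · a_p · g_p(ev) · s_p(group) · d_p(trial) · (B_p ⊗ h)(t)
             + drift_v(t) + ε_v(t)

where `w_p` are the pattern's spatial weights (zero-mean, unit L2 norm on
a compact ball of in-mask voxels, so information lies in the spatial
distribution, not the mean level — the reason the pipeline z-scores maps),
`a_p` the base amplitude, `g_p` an evidence gain, `s_p` a per-group sign,
`d_p(trial) ∈ {−1, +1}` the condition driver (choice, response, image
type, target side), `B_p` a rectangle at image onset + lag, and `h` the
HRF. Drift is a polynomial with random per-voxel coefficients (order 1,
sd 0.5 by default); ε is AR(1)-filtered white noise (innovation sd 1.0,
φ = 0.3). Everything is sampled on the TR grid with onsets rounded to the
nearest frame, and the simulator and the GLM share the same
regressor-construction code, so noiseless data are exactly representable
by the estimation model (the single-trial recovery test asserts agreement
to 1e-6).

The default five-pattern suite places disjoint radius-2 balls (~33 voxels)
at seeded random in-mask locations:

| pattern     | driver      | lag  | duration | properties |
|-------------|-------------|------|----------|------------|
| choice      | choice sign | 0 s  | 2 s      | evidence gains 0.5/1.0/1.5; undershoot 0.4 |
| action      | response    | 6 s  | 3.5 s    | sustained to the go-signal |
| association | choice      | 6 s  | 3.5 s    | per-subject spatial code; group sign ±1 |
| image type  | image type  | 0 s  | 2 s      | shared |
| target side | target side | 0 s  | 2 s      | shared |

Two modeling points deserve emphasis.

*The association pattern carries an idiosyncratic code.* A shared spatial
code whose sign flips with the mapping group is algebraically identical to
a response-driven pattern (choice sign × group sign ≡ response sign under
the counterbalanced mappings) and would be read out by the between-subject
action decoder. A signal that is decodable within subject yet invisible to
*both* between-subject decoders — the defining property of
association-dependent activity — requires a code that does not transfer
across subjects. The generator therefore re-draws the association
pattern's weights per subject (seeded by the subject id on a fixed voxel
set), with the group sign applied on top. The group-sign mechanism itself
is retained and unit-tested with shared weights, where it produces the
exact cross-group cancellation it is designed for.

*The transient choice event has an offset undershoot.* With a single-gamma
HRF, a 2 s event still carries roughly a third of its peak amplitude
9–10 s after onset, which would leave the "early, transient" choice signal
decodable late into the delay and make early-trained classifiers
generalize to late frames. The choice pattern therefore subtracts a
delayed copy of its event regressor (gain 0.4), i.e. post-stimulus offset
suppression, so its BOLD footprint ends during the delay as a transient
decision signal's should. Sustained patterns use no undershoot.

Amplitude defaults (base 3.0 against unit noise) are calibrated once so
that planted effects are recoverable on desk-scale grids; they are not
tuned per analysis.

## Estimation

The HRF is the gamma-family kernel h(t) = ((t−δ)/τ)^(n−1) e^(−(t−δ)/τ)
for t ≥ δ, unit-peak normalized, with n = 3, τ = 1.25 s, δ = 2 s (peak at
δ + (n−1)τ = 4.5 s) — a standard parameterization of the classic
single-gamma response. The condition GLM crosses status × evidence ×
accuracy at image onset (1.5 s rectangle; up to 12 regressors) and
response × accuracy at the go-signal (1 s; up to 4), plus per-run
intercept and linear drift; empty cells are dropped with a warning.
Estimation is ordinary least squares without prewhitening.

The *residual dataset* for temporal analyses projects the data onto the
orthogonal complement of the execution + nuisance subspace only. This
matches the procedure of removing execution-locked activity *first* and
keeps all decision-phase activity, fitted or not; it also makes the
operation an exact idempotent projection with residuals orthogonal to the
execution regressors. Single-trial betas use least-squares-all (one
regressor per trial, estimated jointly per run with execution and nuisance
covariates); least-squares-separate is available as an option and is
documented as biased where responses overlap. Rank-deficient single-trial
designs (overlapping trials) raise an error rather than silently
regularizing.

## Decoding pipeline

Per subject, trial maps are z-scored across in-mask voxels (removing the
overall activation level), then each voxel is linearly detrended and
z-scored across trials. The classifier is a soft-margin linear SVM with
C = 1, solved exactly (libsvm); its boundary matches a brute-force
constrained-optimization oracle on toy sets to 1e-4, with ties at decision
value 0 assigned to the first class and equal F scores broken toward the
lower feature index — all deterministic. Between-subject analyses use
leave-one-subject-out folds; within-subject analyses use k = 7 folds
grouped by run blocks (contiguous runs per fold) to avoid temporal
leakage. Feature selection, where used (regional and temporal analyses,
k = 50), is computed on training rows only.

The searchlight scrolls a radius-3 sphere (123 offsets, clipped at mask
edges) across all in-mask centers without per-sphere feature selection,
randomly retaining 50% of each subject's trials (class-balanced, seeded)
to bound the cost of the LOSO fits. Group inference is a voxelwise
one-sample t against 50% — the study's "paired t test versus chance" is
ambiguous between one-sample and paired formulations, and versus a
constant they coincide — followed by Benjamini–Hochberg FDR (α = 0.01)
and cluster-extent thresholding with face (6-) connectivity. The 50-voxel
extent is the whole-brain default; desk-scale grids scale it down via
configuration.

The evidence-modulation test fits accuracy ~ 1 + β·evidence with evidence
coded −1/0/+1 and a random intercept per subject (REML, Wald z on β);
singular fits fall back to a one-sample t on subject-wise slopes, flagged
in the result. Accuracy is treated as Gaussian at the subject level,
reasonable at ≥30 test trials per cell. On balanced designs the REML
slope and its variance reduce to closed forms, which the suite checks.

Temporal analyses cut 7-frame epochs starting at the first frame at or
after image onset (frame 0 convention; outputs also carry seconds) from
the residual dataset. Temporal generalization trains at frame i within
each training fold and tests at every frame j of the held-out fold; the
time course and the matrix share fold construction and code, so the
diagonal identity is exact. Bonferroni factors are frames × ROIs for time
courses and 49 × ROIs for matrices. Peak detection marks strict local
maxima by neighbor comparison, excluding endpoints, with plateaus reported
at their first index.

## Validation scope and problem sizes

All validation is on synthetic cohorts; passing tests show that the
pipeline recovers what the generator planted under its noise model — they
cannot certify performance on real BOLD, which has structured
physiological noise, motion, inter-subject anatomical variability and
unknown effect sizes. Problem sizes were chosen to exercise every code
path at desk scale: the dissociation check runs 12 subjects × 4 runs of
30 trials on a 20³ grid with the default SNR; searchlight unit and null
checks use 9–12³ grids with radius-2 spheres and correspondingly reduced
cluster extents; the permutation-null calibration uses 12 subjects ×
20 trials with 123 noise features and 200 permutations. Exact libsvm
fits dominate runtime on non-separable (noise-label) problems, which is
why between-subject analyses keep per-fold training sets below ~700
samples, mirroring the design's own 50% subsampling rationale.

Known limitations: no physiological noise, motion or spatial smoothing in
the generator; no prewhitening or HRF estimation in the GLM; binary
classification only; no permutation-based cluster inference. The encoding
session's BOLD is not simulated. Whether the original within-subject
analyses subsampled trials is unknown; none is applied within subject
here.
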