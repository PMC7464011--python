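# Methods

`nirscog` simulates and analyzes a two-arm cognitive-training trial in which
the question is whether baseline dorsolateral-prefrontal (DLPFC) activity,
measured by a two-channel single-wavelength fNIRS device while participants
play the training game, predicts cognitive change after the intervention.
This note documents the generative model, the preprocessing chain, the
permutation inference, the cross-validation design, and the choices made
where the design was genuinely open.

## Trial generator

A cohort of `2 * n_per_group` participants (default 72: 48 male, 24 female)
is assigned to a brain-training arm (BT) and an active-control arm (ACT) by
sex-stratified blocked randomization with block size 4 and 1:1 allocation.
Within each stratum every complete block of four contains exactly two
participants per arm; an incomplete final block is a random truncation of a
balanced block, so stratum imbalance never exceeds one. Because both default
strata (48, 24) are multiples of the block size, the default composition
always yields exactly 36 per arm. Assignments are a deterministic function
of the seed; each participant additionally owns an independent child stream
of the master seed, so a cohort is bit-reproducible regardless of generation
order.

Each participant carries latent left and right baseline neural amplitudes
drawn log-normal (activation is positive) with arm-specific means
(BT 1.1 a.u., ACT 0.95 a.u., SD 0.4) — a small-to-medium baseline group
difference of the size this kind of training-game contrast produces.
Pre-scores for the eleven outcomes are Gaussian with means/SDs at
conventional young-adult levels for these test batteries. The change score
for outcome *o* is

```
Δ = control_change_o + training_effect_o·[BT]
    + sd_o · (ρ_L,o z_L + ρ_R,o z_R + sqrt(1 − ρ_L,o² − ρ_R,o²) ε)
```

where `z_L`, `z_R` are the latent amplitudes standardized by the analytic
log-normal moments and `ε ~ N(0,1)`. This decomposition keeps the total
change variance at `sd_o²` while making the latent brain–change correlation
exactly `ρ` (so `ρ = 1`, or noise → 0, makes the latent parameters exactly
recoverable — a property the tests exploit). Default `training_effect` and
`sd` values follow the published group change summaries for this design;
note that those printed means/SDs imply substantially larger standardized
effects for some outcomes (e.g. the working-memory updating task, d ≈ 1.7)
than the small-to-medium η² the same reports quote, so the simulated η² for
those outcomes is correspondingly larger. Default correlations put the
predictive signal on the left hemisphere (ρ_left ≈ 0.36–0.44 on the two
processing-speed and two working-memory outcomes, ρ_right = 0.2, all other
outcomes 0), matching the qualitative finding the pipeline is built to
detect: left-DLPFC activity predicts processing-speed and working-memory
change better than right.

## Recording simulation

One recording per hemisphere: an R-V-R-V-R schedule of 30 s rest/game
blocks (150 s total) sampled at 10 Hz. The device's sampling rate is not
dictated by the emulated hardware documentation; 10 Hz is a typical
continuous-wave NIRS rate and both values are configurable. The deep
(3 cm) channel is

```
deep(t) = A · (game boxcar ⊗ HRF)(t) + a·systemic(t) + drift(t) + ε_d(t)
```

and the shallow (1 cm) channel `shallow(t) = systemic(t) + drift'(t) + ε_s(t)`,
with the systemic term *shared* — that shared structure is what the
short-separation regression exploits. The HRF is the canonical double-gamma
(peak ≈ 5 s, undershoot at 16 s, ratio 1/6), peak-normalized; the discrete
kernel is normalized to unit sum so a sustained block drives the response
toward the amplitude `A`, giving `A` the interpretation of plateau response
in the same arbitrary total-Hb units as the noise amplitudes. The systemic
component sums a slow vasomotion sinusoid (0.02 Hz, 0.3 a.u.), a Mayer wave
(0.08 Hz, 0.4), a cardiac tone (1.1 Hz, 0.25), each with a random phase,
plus AR(1) noise (φ = 0.99, innovation SD 0.02). The slow and Mayer
components matter: they survive the 0.1 Hz low-pass and bias block means,
so the regression step demonstrably improves amplitude recovery; the
cardiac tone exercises the filter. Deep-channel systemic coupling is 0.6,
drift slopes are N(0, 0.003/s), and measurement noise is white with
SD 0.05 per channel.

What the generator does *not* emulate: motion spikes, optode-coupling
drifts, wavelength-dependent chromophore separation (the emulated device is
single-wavelength total-Hb only), inter-regional physiology, or missing
data. Passing tests therefore show the statistical machinery is correct and
well calibrated under plausible block-design physiology — not that the
pipeline is robust to every artifact of real recordings.

## Preprocessing

Per recording, in order: (1) linear detrend of both channels; (2) zero-phase
(forward–backward) 4th-order Butterworth low-pass at 0.1 Hz — zero-phase so
block boundaries are not shifted, with the two-pass magnitude being the
square of the single-pass response (the −3 dB point of one pass becomes
−6 dB); (3) short-separation regression: the OLS residual of deep on
{intercept, shallow}, fitted over the whole recording (a per-block fit is
noisier; the whole-recording coefficient is the default). A constant shallow
channel falls back to mean-centering and is flagged in the log; (4) baseline
correction: each game block minus the mean of its immediately preceding rest
block (rest blocks are centered on their own means); (5) the activity scalar
is the mean of the corrected signal over all game-block samples, with
per-block means reported alongside (averaging both game blocks is the
default; users wanting a single block can read the per-block means).

Filter edge transients decay within a few tens of seconds; with the default
150 s schedule the block structure sits inside the recording and block
averages are insensitive to them. Steady-state filter properties are
verified against the closed-form Butterworth magnitude response, measured
by projection onto the probe tone away from the edges.

The chain is linear, so activity is scale-equivariant (scaling both channels
by c scales activity by c) and strictly increasing in the simulated
amplitude at zero noise. The order of operations matters — regressing before
baseline correction is not the same as the reverse — and the shipped order
is regression first, as listed above.

## Permutation inference

Group comparisons use the partial F for the group factor after covariates
(`F = (SSR_reduced − SSR_full) / (SSR_full / df_resid)`), equivalent to a
Type-III test for a single two-level factor. η² is `SS_group / SS_total`
with `SS_total` the total sum of squares of the response about its mean;
partial η² can be derived from the reported sums if needed. The permutation
null is Freedman–Lane: residuals of the covariates-only model are permuted,
added back to its fitted values, and the full-model F recomputed. This is
the best-characterized covariate-respecting permutation scheme; it differs
from the sequential-SS resampling some R packages implement, and no early
stopping is used. Monte-Carlo p-values are `(b + 1)/(B + 1)` with
B = 10,000 by default, so p is never zero. When the number of distinct
permutations is at most B the test is exact: all `C(n, n₁)` group labelings
when there are no covariates, all `n!` residual permutations when there are.

The analysis models are: baseline activity `activity ~ group + age + sex`
per hemisphere (df_resid = n − 4, i.e. 68 at n = 72 — reports of this
design sometimes print 67, which corresponds to the change-score model
below), and change scores `Δ ~ group + pre + age + sex` (df_resid = 67 at
n = 72).

The permutation multiple regression z-scores all continuous variables
(sample SD, ddof = 1; the binary sex indicator is left untouched) and
reports the focal predictor's standardized coefficient and t, with a
two-sided Freedman–Lane p permuting the focal predictor's contribution.
With no covariates the standardized coefficient equals the Pearson
correlation — a test oracle. A `direction` flag selects whether the change
score is regressed on activity (default, `change_on_brain`) or activity on
the change score (`brain_on_change`); descriptions of this design are
ambiguous about which variable was dependent, so both are available.

FDR control is Benjamini–Hochberg step-up, implemented directly and checked
against an independent reference implementation. Families follow the
analysis structure: the two baseline-brain tests, the eleven change-score
tests, and all pooled prediction regressions are each one family.

## Cross-validated prediction

Within the training arm only (n = 36), each outcome's change score is
predicted from one hemisphere's activity plus pre-score, age and sex by
ordinary least squares, under a shuffled 5-fold split (fold sizes 8,7,7,7,7;
each test fold is the 20% hold-out). The outcome is z-scored with the
*training* fold's mean/SD, so fold RMSEs are in SD units: an uninformative
model converges to RMSE ≈ 1, and RMSE < 1 means genuine predictive signal.
Left and right models share the same fold assignment, making the side
contrast paired. The pipeline reports per-outcome and pooled (mean over
outcomes) RMSEs per side; inside cross-validation the prediction direction
is always change-on-brain regardless of the inference `direction` flag,
since predicting baseline activity from a later change has no prospective
use. Folds with zero training-outcome variance are flagged, reported as NaN
and excluded from the mean. No regularization or hyperparameter tuning is
done — the models are deliberately the plain least-squares fits whose
calibration the permutation tests describe.

## Problem sizes and determinism

The shipped pipeline defaults are the full study conditions (36 per arm,
150 s recordings at 10 Hz, B = 10,000 permutations, k = 5) and run in a few
seconds; simulation-based tests use cohorts of 12–36 per arm and a few
hundred permutations or replicates, sizes at which the Monte-Carlo bands
quoted in each test are computed a priori from the binomial distribution.
Every stochastic step (randomization, cohort, recordings, permutations,
fold shuffling) flows from explicit seeds; a manifest recording the full
configuration and library versions is written with every run and suffices
to reproduce all tables byte-identically.

## Known limitations

- The generator's change model is linear-Gaussian with homoscedastic noise;
  ceiling/floor effects of real test batteries (digit spans are bounded) are
  not modeled, and scores are continuous rather than integer.
- The short-separation model assumes the scalp signal enters the deep
  channel linearly and instantaneously; real superficial contamination has
  depth- and time-varying coupling.
- Exact enumeration with covariates is limited to n ≤ 7 by the factorial
  count; beyond that the test is Monte Carlo.
- η² is reported against the total SS; with strong covariates this is
  conservative relative to partial η².
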