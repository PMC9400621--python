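# Methods

This note documents the models, conventions and numerical choices behind
`pinchbind`: what the synthetic sessions contain, how pinch events are
measured, how trials are screened, and how the similarity statistics are
computed. It also states what the simulator deliberately does *not* emulate.

## Generative model of a session

### Design

A `DesignSpec` fixes the block structure and timing. Two presets are built
in:

| preset | blocks × trials | per block (cong/incong/catch) | catch share | prime cue | tones |
|---|---|---|---|---|---|
| `exp1` | 7 × 30 | 12 / 12 / 6 | 20% | self-initiated | 300 ms, 440/1175 Hz |
| `exp2` | 9 × 40 | 10 / 10 / 20 | 50% | auditory go signal | 150 ms, 440/1175 Hz |

Both use a 600 ms SOA between the prime effect tone and the probe stimulus,
a 1200 ms response window, and a constant 6 ms action→tone hardware delay
(carried as metadata; RT is defined stimulus onset → pinch onset and does
not include it). Trial order is pseudo-randomized per block under the
constraint that the first two trials are never catch trials; per-block
condition counts are exact by construction.

### Pinches and retrieval

Each pinch is parameterized by a peak force and a duration. Participant
means are drawn once per participant (defaults: peak 3.6 ± 1.5 N, duration
300 ± 60 ms between participants); trial-level deviations have SDs 1.1 N
and 45 ms. The planted binding mechanism is linear retrieval: on a trial
with prime deviation Δ (from the participant mean), the probe's deviation is

    λ·Δ + √(1−λ²)·σ_within·ε,   ε ~ N(0,1),

with λ = `lambda_congruent` or `lambda_incongruent` by condition. The
complementary √(1−λ²) noise scale is a deliberate choice: it keeps the
trial-level variance identical in prime and probe and makes the expected
within-participant prime–probe correlation equal λ exactly, so λ is directly
interpretable and the congruent–incongruent λ gap is the ground-truth effect
the analysis must recover. λ_c = λ_i defines the null (exchangeable) regime
used for type-I-error calibration. Defaults λ_c = .65, λ_i = .55 mirror the
magnitude of duration correlations typical of such data (r ≈ .6).

Probe pinches additionally receive a constant forcefulness boost
(`probe_boost_peak_N`, default +1.2 N; optional multiplicative AUC boost),
emulating the robust observation that cued responses are harder than
self-initiated ones.

RTs are lognormal with mean `rt_location_ms` (332 ms) and shape `rt_scale`
(0.32, giving an SD near 110 ms); congruent trials get a mean advantage of
16 ms. Misses (1.9%), false alarms (0.8%), catch errors (6.1% of catch
trials) and trial restarts (7.5% per-attempt probability) are sampled
independently; restarts repeat the same scheduled condition and are recorded
as a per-trial count rather than extra records, so a session always has
exactly its designed number of trials.

### Traces

The rendered force pulse is a raised sine squared,
F(t) = P·sin²(πt/D) on [0, D], chosen because every quantity the pipeline
measures has a closed form: peak P at D/2, full integral P·D/2, and
threshold crossings at t* = (D/π)·asin(√(θ/P)). These closed forms serve as
analytic oracles for the detection and feature tests. Traces are sampled at
1000 Hz, padded with 150/250 ms of rest, carry additive Gaussian sensor
noise (default SD 0.02 N, far below the 0.32 N threshold) and are clipped at
zero. Voltage-channel output uses the inverse of the calibration transform
(below). One root seed drives everything; per-participant streams are
derived from (seed, participant index) so any session is reproducible in
isolation.

## Signal processing

FSR voltage is calibrated to force with the exponential transform
F = a·e^{bV}. The hardware constants are device-specific and unreported for
any given rig; the defaults a = 0.05 N, b = 1.5 /V are stored in
`DetectionParams` and recorded with every analysis. The generator's
`encode_voltage` is the exact inverse above a representable-force floor
(1e-4 N; lower samples clip to the baseline voltage).

Onset detection: the first sample **strictly above** 0.32 N preceded by at
least 10 ms of consecutive at-or-below samples; offset: the first subsequent
at-or-below sample followed by at least 10 ms at-or-below. "Exceeded" is
read as strict inequality and "under" as ≤ (configurable). Trace boundaries
count as satisfied persistence on both sides — otherwise events at the edge
of a recording window would be undetectable, and trial windows begin in
rest. Sub-threshold dips shorter than the persistence are absorbed into a
single merged event. Only the first qualifying event per trace part is used;
later events are counted in a quality flag. A trace that never returns
below threshold has no qualifying offset and reports no event.

Features: peak = max force on [onset, offset]; AUC = trapezoid integral of
the **raw** force between the detected bounds, in N·ms (trapezoid rather
than a rectangular sum for lower discretization error at 1000 Hz; the
alternative of integrating threshold-clipped force is not used). RT = onset −
stimulus onset; a negative RT is returned with a flag, never silently
dropped. No additional low-pass filtering is applied to synthetic traces
(they are band-limited by construction); `identity_filter` is the hook where
a real-data filter would go.

Because detected onsets sit at the threshold crossing, detected durations
are systematically shorter than generative ones by 2·t* (≈ 30–35 ms at
typical amplitudes) and detected RTs are longer by t* (≈ 15–20 ms). This is
a property of threshold-based event measurement, not an error; both
pipelines (ground-truth features vs detected features) give statistically
indistinguishable condition contrasts, which the test suite checks.

## Trial screening

Only trials classified `ok` enter the cascade; catch trials pass through for
error-rate reporting. Classification applies the response window first: a
probe pinch before the probe stimulus is a false alarm, none within the
window a miss. (In designs with an absolute 3 s RT ceiling this means late
responses beyond the window are classified misses before the ceiling could
see them; the ceiling only matters for user-supplied tables that retain late
responses as valid.)

The cascade order is fixed and load-bearing (a test pins a fixture where
reordering changes the outcome): RT floor (100 ms) → RT ceiling →
prime-duration cap → probe-duration cap → per-DV z cut. Conventions:

- the `exp1`-style ceiling is participant×condition mean + 2.5 SD; the
  `exp2`-style ceiling is absolute 3000 ms followed by |z| > 2.5, computed
  per participant×condition (a `group_by_condition` switch relaxes this to
  per participant);
- duration caps are inclusive (exactly 600 ms rejects);
- statistics (means, SDs, z-scores) are computed over the trials still
  eligible at that stage, in a single pass — no iterative re-screening;
- z-scores use the sample SD (n−1); cells with fewer than 2 trials are
  skipped with a warning;
- the per-DV z stage is applied to the prime and probe values of the
  analysed DV separately and is re-run per analysis, so the force analyses
  and the duration analyses see (slightly) different survivor sets.

The report logs, in order, each rule's rejection count and fraction, and the
per-condition survivor counts; eligible = survivors + Σ rejections always
holds.

## Similarity statistics

Per participant × condition and DV: the Pearson correlation r of prime vs
probe values across trials (≥ 3 paired trials and nonzero variance
required), its Fisher transform z = atanh r, the mean absolute prime–probe
difference, and the part means. Numerically singular cells (|r| within
1e-12 of 1) are treated as |r| = 1: infinite z, excluded from z-based tests
but retained for difference measures, with a warning (no clamping by
default).

Condition contrasts are classical two-sided paired t-tests; zero difference
variance is an error, not t = ∞. Effect size d_z = |t|/√n. The JZS Bayes
factor integrates the noncentral-t likelihood over a zero-centred Cauchy
prior (scale 0.707) on the standardized effect by adaptive quadrature
(relative tolerance 1e-8, integration domain split at the prior mode and the
MLE); it is computed from t and n, which reproduces BayesFactor-style
paired-test values to well under the rounding noise of a t reported to two
decimals. The duration analyses are held to a Bonferroni-adjusted α of
.025 (.05/2); all tests are two-sided with no directional option.

Power calculations use the noncentral-t power function of the two-sided
paired t-test; solving for n returns the smallest integer meeting the
target, solving for d uses bracketed root finding to 1e-10. (scipy's `nct`
distribution underflows to NaN deep in its tails; those terms are
mathematically negligible and guarded to zero.)

The 2 (between) × 2 (within) mixed ANOVA treats subjects as random: the
between effect is tested against subjects-within-groups, the within effect
and the interaction against the within×subject residual, using unweighted
cell-mean contrasts for unbalanced groups. Generalized eta squared follows
the additive decomposition ges = SS_effect / (SS_effect + SS_subjects +
SS_within-error). With a single group the within-effect F equals the paired
t², a property the suite asserts to 1e-9. Effect-size tables report signed
d_z with 95% CIs from inverting the noncentral-t CDF in the noncentrality
parameter.

The pooled analysis concatenates participant-level summaries of two
experiments (with a heterogeneity warning — the designs differ); the RT
contrast uses probe RTs only.

## Calibration and recovery

`recover` sweeps (λ_c, λ_i) cells and reports the rejection rate of the
duration-correlation congruency test with Monte-Carlo SEs; a null cell is
always included. Two fidelity levels exist: `pipeline` runs the complete
simulate → detect → screen → test chain per replicate, and `features` draws
trial-level deviations directly from the retrieval model (participant means
cancel out of within-participant correlations) in a fully vectorized form.
The feature level is the default for large replicate counts: rendering and
detection are deterministic feature-recovery steps validated separately, so
omitting them does not change the statistical behaviour being calibrated —
a test confirms both levels agree on a common cell. Under the null the
rejection rate sits at the nominal 5% (e.g. 0.055 ± 0.007 over 1000
replicates at seed 20220606), and power rises monotonically in the λ gap.

Replicate counts used by the shipped checks — 2000 for null calibration,
200 per grid point for monotonicity, 1000 in the narrative script — were
chosen to put the Monte-Carlo SE of a 5% rate near half a percentage point.

## What the simulator does not emulate

- **Participant heterogeneity in retrieval strength.** λ is a population
  constant per condition, so between-participant variance of the Fisher-Z
  correlations is pure sampling noise (≈ 1/√(n−3)), far smaller than in real
  cohorts where λ itself varies. Consequently the simulated congruency
  tests are substantially more powerful at matched λ values than a real
  study of the same size; passing recovery tests demonstrate correctness of
  the machinery, not field-realistic power.
- **Force/duration coupling.** Peak and duration deviations are drawn
  independently, whereas real pinch force and duration are correlated.
- **Continuous inter-trial signal.** Inter-trial wait times (2 s minimum,
  or 3–4 s randomized) exist only as metadata; no inter-trial recording is
  synthesized and screening never uses it.
- **Audio, displays, amplifier hardware**, and on-screen instruction flow
  are out of scope; instruction texts are not modelled.
- The sensor-noise model is white Gaussian; real FSR drift, grip shifts and
  the 200 Hz online anti-aliasing chain are not simulated.

## Degenerate inputs and tie-breaks

Non-positive pulse parameters, invalid probabilities or λ outside [0,1] are
configuration errors; schedules whose catch count leaves fewer than two
non-catch trials per block are infeasible. Detection on an all-subthreshold
trace returns "no event" (a result, not an error). Cells too small for an
SD are skipped with warnings rather than poisoning the cascade. Paired
tests with fewer than two complete pairs, or zero difference variance, raise
typed errors. JZS quadrature failure (non-finite or non-converged integral)
raises with diagnostics rather than returning a silently wrong value.
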