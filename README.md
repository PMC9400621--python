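# pinchbind

Simulation and analysis pipeline for **prime–probe pinch-force experiments**
on action-effect binding.

In these experiments a participant pinches a force-sensing resistor (FSR);
the pinch triggers a tone (the *prime* effect), and 600 ms later a second
tone — identical (*congruent*) or different (*incongruent*), or absent on
catch trials — cues a second pinch (the *probe*). If the tone becomes bound
to metric features of the first pinch (its force profile, its duration),
re-hearing the same tone should retrieve them, making prime and probe
pinches more similar on congruent than on incongruent trials.

`pinchbind` implements the full quantitative chain needed to run, screen and
analyse such sessions — plus a synthetic session generator with a
controllable binding effect, so the whole pipeline can be exercised and
calibrated without any raw recordings:

- **`pinchbind.simulate`** — trial schedules (blocked designs with catch
  trials, first-two-trials-no-catch constraint), raised-sine² pinch pulses,
  a linear retrieval model (probe deviation = λ·prime deviation, λ depending
  on congruency), lognormal RTs with a congruency advantage, sensor noise
  and error events; inverse FSR voltage encoding.
- **`pinchbind.force`** — exponential FSR calibration F = a·e^{bV}, pinch
  onset/offset detection (0.32 N threshold with 10 ms persistence
  hysteresis), and per-pinch features: duration, peak force, AUC (temporal
  integral of force, N·ms), reaction time.
- **`pinchbind.screening`** — outcome classification (ok / miss / false
  alarm / catch error) and the ordered rejection cascade: 100 ms RT floor,
  RT ceiling (participant×condition mean + 2.5 SD, or absolute 3 s followed
  by z > 2.5), inclusive 600 ms pinch-duration caps, per-DV |z| > 2.5 cut.
- **`pinchbind.stats`** — per-cell prime–probe Pearson correlations with
  Fisher's Z = atanh r, mean absolute differences, two-sided paired t-tests
  with Cohen's d_z = |t|/√n, the JZS Bayes factor

  BF₁₀ = ∫ f_nct(t; n−1, δ√n) · Cauchy(δ; 0, 0.707) dδ / f_t(t; n−1),

  a noncentral-t power solver for paired designs, Bonferroni adjustment,
  2 (between) × 2 (within) mixed ANOVA with generalized η², and
  noncentral-t confidence intervals for d_z.
- **`pinchbind.pipeline`** — orchestration (simulate → detect → screen →
  test), pooled two-experiment analysis, effect-size tables, and
  rejection-rate recovery sweeps over the planted binding strength
  (including type-I-error calibration in the λ-equal null regime).

## Worked example

Solve the design's power questions and score a congruency contrast:

```bash
$ pinchbind power --n 19 --power 0.8
n = 19, d = 0.6797, power = 0.8000, alpha = 0.05

$ pinchbind power --d 0.5 --power 0.8
n = 34, d = 0.5000, power = 0.8078, alpha = 0.05

$ pinchbind bf --t 2.67 --n 19
BF10 = 3.600
```

A sample of 19 participants can only detect effects of d_z ≈ 0.68 at 80%
power; 34 are needed for d_z = 0.5; and a t of 2.67 with n = 19 is
moderate evidence (BF₁₀ ≈ 3.6) for a congruency effect.

Run a complete synthetic study (here on ground-truth features; drop
`--no-traces` to render 1000 Hz force traces and run detection on them):

```bash
$ pinchbind analyze --design exp1 --n-participants 19 --seed 20220606 \
      --no-traces --out results/analysis/exp1
participants: 19
trial outcomes: {'ok': 3098, 'catch_correct': 746, 'miss': 67, 'catch_error': 52, 'false_alarm': 27}

auc_corr               t(18) = +3.64, p = 0.002, dz = 0.83, BF10 = 21.406
auc_diff               t(18) = -2.56, p = 0.020, dz = 0.59, BF10 = 2.974
auc_prime_vs_probe     t(18) = -17.42, p = 0.000, dz = 4.00, BF10 = 6500405885.933
duration_corr          t(18) = +5.06, p = 0.000, dz = 1.16, BF10 = 333.961
...
```

`duration_corr` is the headline contrast: the paired t on Fisher-Z-
transformed prime–probe duration correlations, congruent vs incongruent.
Its positive t says congruent correlations are higher — the planted binding
effect (λ congruent .65 vs incongruent .55) is recovered. The
`*_prime_vs_probe` rows show the systematic probe-harder-than-prime offset
the generator also plants.

The numbered scripts under `analysis/` run the same steps as a narrative:
`01_simulate_sessions.py` → `02_extract_features.py` → `03_screen_trials.py`
→ `04_similarity_analysis.py` (both cohorts, pooled analysis and ANOVA) →
`05_power_and_bayes.py` → `06_recovery.py` (calibration/power sweep, e.g.
null rejection rate 0.055 ± 0.007 at nominal α = .05 over 1000 replicates).

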