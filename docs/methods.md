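# Methods

## The charting model

Each patient contributes an ordered series of PASAT scores (counts of
correct responses; higher is better). The individuals chart is a Shewhart
I-chart with two deliberate departures from textbook practice, both driven
by the early-rehabilitation setting:

1. **Two-point frozen baseline.** The centreline is the mean of the first
   two observations only, so the chart exists before most of the therapy
   has happened. The baseline pair is excluded from signal evaluation — it
   defines the limits and cannot signal against itself.
2. **Cohort-pooled sigma (default).** A two-point spread estimate is very
   unstable, so the default chart sigma pools the within-pair variance over
   all m patients' baseline pairs, σ̂ = √(Σ(x₁−x₂)²/2 / m) — each pair's
   two-point sample variance carries one degree of freedom, and pooling
   averages them. The package also offers the classical per-patient
   moving-range estimate |x₁−x₂|/1.128 (d₂ for n = 2) via
   `sigma_strategy="individual-moving-range"`. Pooling is done over the
   whole cohort, not within treatment arm; with arms drawn from the same
   measurement process the within-pair spread is a property of the
   instrument, not the treatment.

Signal rules, evaluated at positions ≥ 3 in observed order (session-label
gaps are ignored for windowing):

- **Rule i** — one point strictly outside a 3σ control limit ("outside"
  read as exclusive: a point exactly on the limit does not fire).
- **Rule ii** — 2 of 3 consecutive evaluated points at or beyond the 2σ
  warning line ("≥ 2 SD" read as inclusive) on the same side of the
  centreline, reported at the window's last point. A qualifying point must
  also lie strictly off the centreline; this only matters in the
  degenerate σ = 0 chart, where otherwise every on-centreline point of a
  constant series would "fire" the inclusive rule.

Direction defaults to improvement-only (above-centreline signals), because
the outcome of interest is improvement on a higher-is-better scale; a
both-sides mode serves deterioration monitoring. CHANGE ⇔ at least one
signal. Series with fewer than eight observations get a warning (the
measurement design this chart was built for calls for at least eight);
fewer than two is an error.

## Association battery

All tests follow standard definitions: Pearson χ² without continuity
correction (the no-correction choice is what reproduces the reference
trial's printed statistics exactly, and is verified against the 2×2 closed
form N(ad−bc)²/margins); two-sided Fisher exact p by the probability-mass
rule; Cramér's V = √(χ²/(N·min(r−1,c−1))); odds ratios in the trial's
orientation (odds of NO CHANGE under APT over ABAT; the headline
"times-higher" figure is the reciprocal) with Woolf CIs, which require all
cells positive — a zero cell flags the CI unavailable unless the
Haldane-Anscombe +0.5 correction is enabled; one-way ANOVA with
η² = SS_b/SS_t (F ≡ 0, p ≡ 1 when all observations are identical); OLS on
the 0/1 outcome (a linear-probability model, matching the trial's analysis
choice rather than logistic regression); and the Mantel-Haenszel
linear-by-linear statistic (N−1)r² on 1 df with default integer scores.
Effect-size bands: V ≤ 0.2 weak / < 0.6 moderate / ≥ 0.6 strong (boundary
0.2 takes the lower band); η² ≥ 0.01/0.06/0.14 small/medium/large. No
multiplicity adjustment is applied (α = 0.05 two-tailed), but the CLI logs
the number of tests run. Confidence intervals for η² are available via
noncentral-F inversion in principle but are deliberately out of scope.

## Synthetic cohort generator

The generator emulates the *statistical structure* the pipeline assumes,
not any mechanistic model of recovery:

    score_t = baseline_i + drift·min(t−1, 3)
              + responder_i·δ·σ_ε·1[t ≥ changepoint] + ε_t,
    ε_t ~ N(0, σ_ε²) i.i.d., clipped to [0, 60], rounded to integers.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_patients | 59 | reference cohort size |
| arm split | 32/59 APT | reference allocation |
| n_sessions | 9 | baseline + every 3rd hour of 20 h + completion |
| responder prob. | 27/32 APT, 15/27 ABAT | observed CHANGE fractions per arm |
| baseline_mean / sd | 30 / 8 | mid-scale PASAT performance with realistic between-patient spread for an ABI cohort |
| noise_sd σ_ε | 2.5 | a few points of session-to-session fluctuation |
| learning_drift | 0.5/session, first 3 transitions | a modest practice effect (~1.5 points total) present in both arms; sized so that the learning effect alone stays inside the chart limits, consistent with a design in which a third of patients remain NO CHANGE |
| δ (step) | 4 (in σ_ε units) | a clearly detectable sustained response |
| changepoint_session | 4 | group differences emerged from the fourth administration |
| score range | 0–60 | a common PASAT trial count; the version is configurable |
| covariate frequencies | stroke 46/59, high CR 42/59, lesion side 25/22/12, unifocal 29/63 | reference-table frequencies (the focal/multifocal row is normalised because its printed counts sum to 63) |

Responder status is a latent Bernoulli per arm — equal to the observed
CHANGE rates, so with good detection the simulated pipeline's arm odds
ratio converges to the design value log[(5/27)/(12/15)] ≈ −1.463.

What the generator does *not* emulate: dropout and missing visits,
correlation between covariates and responder status (covariates are
sampled independently), non-Gaussian or autocorrelated within-patient
noise, ceiling-driven score compression beyond hard clipping, and the full
neuropsychological battery. Passing pipeline tests therefore show the
machinery is correct under the stated model, not that the chart rules are
well-calibrated for real PASAT noise.

### Operating characteristics

With the default settings, Monte-Carlo runs give detection probability
≈ 1.0 for responders and a false-alarm probability of roughly 0.1–0.15 for
non-responders. Two genuine properties of the method drive the false-alarm
rate above the textbook per-point level: the two-point centreline is
itself noisy (a post-baseline point deviates from the *estimated*
centreline with variance 1.5σ_ε², while the limits are multiples of σ_ε),
and the shared learning drift pushes everyone slightly above a baseline
that only half-absorbs it. Adding rule ii to rule i buys power at the cost
of more false alarms — the trade-off is inherent, and is why the
end-to-end odds-ratio recovery check is stated within Monte-Carlo error
rather than exactly.

## Numerical choices and degenerate inputs

- Ties: rule i exclusive at 3σ, rule ii inclusive at 2σ (see above).
- σ = 0 charts (all baseline pairs identical) are legal; with the
  strictly-off-centreline qualifier a constant series yields no signals.
- Tables with a zero row/column margin raise a degenerate-table error for
  χ²; zero cells make the Woolf CI unavailable rather than infinite.
- ANOVA with zero total variance returns F = 0, p = 1, η² = 0; zero
  within-variance with non-zero between returns F = ∞, p = 0.
- Pearson correlation on a zero-variance input is an error, not NaN.
- The z-quantile in the Woolf CI is 1.959964.
- Determinism: one `numpy` Generator per simulation call, seeded
  explicitly; identical config + seed gives byte-identical output.

## Problem sizes in the verification suite

The test-suite and acceptance-script sizes — 1,000 random series for the
signal-scan oracle, 10⁵ evaluated null points for false-alarm calibration,
10⁴ random tables for the χ² closed form, Fisher enumeration up to N = 100,
and a 5,000-patient pipeline run — were chosen as the package's own
verification scale: each is large enough that the Monte-Carlo bounds
asserted (3 binomial/Woolf SEs) are meaningful, while keeping the whole
suite in the tens of seconds.

## Known limitations

- The pooled-sigma formula is one reasonable reading of "a pooled SD
  measure based on the two first observations"; the original computation
  is not published in full, so exact per-patient CHANGE labels from the
  trial cannot be reproduced, only its table-level statistics.
- Only the two stated run rules are implemented; the remaining Western
  Electric rules, CUSUM and EWMA charts are out of scope.
- The linear-probability regression inherits the usual LPM caveats
  (heteroscedastic errors, predictions outside [0,1]); it is provided for
  fidelity to the analysis it mirrors, not as the recommended model.
- Subgroup statistics whose published values are internally inconsistent
  (the unifocal/multifocal and right-hemisphere tables, and the
  cognitive-reserve odds-ratio CI) are not reproduced; their tables cannot
  be reconstructed from the published margins.
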