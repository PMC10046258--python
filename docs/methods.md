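# Methods

This note documents the generative model, the scoring and statistical
procedures, the default calibration with its rationale, numerical choices, and
what the synthetic experiments can and cannot establish.

## Task structure

One session presents 32 words at a fixed 3.0 s pace (1.5 s word + 1.5 s
fixation; 96 s total): 8 congruent color words (each of RED/BLUE/GREEN/PURPLE
in its own color, twice), 8 incongruent (each color word twice, in two
distinct non-matching inks, arranged as the two cyclic derangements of the
four colors so that every ink also appears twice — a balanced 8-cell design
that avoids color-frequency confounds), and 16 neutral animal words (the full
DOG/BEAR/TIGER/MONKEY × 4-color cross product). Trial order is an
unconstrained uniform shuffle (immediate repeats allowed). Times are stored in
seconds; trial windows are half-open `[onset, onset + 3.0)`; trial indices are
0-based internally and 1-based in serialized tables.

## Latency model

Trial latency is ex-Gaussian around a latent condition mean:

```
RT = mu_c(i) + u_i + s_ij + beta_conc*(conc-50) + beta_days*days
     + beta_days_ama*AMA*days + N(0, sigma) + (Exp(tau) - tau)
```

The exponential component is **mean-centered**, so `mu_c(i)` is the full
latent mean of the condition, not the Gaussian-component location. This keeps
the calibration transparent (the configured condition means are exactly the
latent means the pipeline should recover), preserves the noiseless limit
(`tau = 0` gives the condition mean exactly), and changes nothing about
condition differences, which are invariant to any common shift.

Latent condition means per participant: `mu_neutral + u_i`, plus the
interference delta for incongruent and minus the facilitation delta for
congruent. Optional fields `sd_interference_s` / `sd_facilitation_s` add
between-participant heterogeneity to the deltas; **they default to 0**, i.e.
every participant shares the group effect. See "Design choices" for why.

Responses: with probability `p_lapse` no utterance; with probability
`p_wrong_word` a different color word is spoken (color words only — the
recognizer vocabulary is color-tuned, so out-of-vocabulary errors surface as
substitutions or misses anyway). Utterance durations are
`N(dur_mean(i), dur_sd)` truncated at 0.05 s, with a participant-level
duration mean (`sd_dur_between_s`). Latencies may exceed 3 s and spill into
the next trial window; the scoring stage, not the generator, decides
attribution.

Covariates: concentration and helplessness are uniform integers 0–100 per
session (sliders); patients get a discharge day drawn uniformly from 14–28
days and sessions spaced every 2 days, so `days_to_discharge` counts down
across sessions; AMA (against medical advice) status is Bernoulli per patient.

## Measurement model

Detected onset = `floor((true_onset − b)/frame) * frame`, truncated at 0, with
one bias draw `b ~ N(onset_bias_mean, onset_bias_sd)` per utterance applied to
both onset and offset — the early-detection shift is a property of the
utterance, and sharing the draw keeps measured durations from double-counting
it. Transcripts are substituted by a different color word with probability
`wer`. Floor (frame-start) indexing is the default because it matches the
moving-window decoding description; round-to-nearest is available via the
`rounding` config field. The onset bias is a configurable default, not a
validated constant: per-session bias estimates of this kind come from very
limited manual-annotation comparisons.

Floor quantization of an onset with uniform phase has bias −frame/2 and
variance frame²/12 (−5 ms and 8.33×10⁻⁶ s² at 10 ms). Both the bias and the
recognizer's early shift are common to all conditions, so difference scores
(interference, facilitation) are unbiased in expectation; what the measurement
layer adds to difference scores is *variance*.

## Scoring rules and numerical choices

* Assignment: first detected utterance in a trial's window is its response;
  later utterances in the same window are discarded (hesitations like "uh"
  never become events — the recognizer only emits in-vocabulary words).
* Accuracy = correct detected responses / 32 presentations, before RT filters.
  It confounds participant errors with recognizer errors by construction; the
  generator exposes the three underlying probabilities separately.
* RT filters: correct-only; RT ≥ 0.2 s; RT ≤ group cutoff = mean + 3·sample SD
  of the group's pooled correct RTs (≥ 0.2 s). Boundaries are kept on the
  "keep" side ("less than 200 ms removed" means 200 ms stays), with a 1 ns
  float tolerance because RTs are differences of frame-aligned timestamps and
  can sit one ulp below a nominal boundary. Cutoffs are computed once per
  cohort per group and applied to all of that group's sessions.
* Session features: per-condition/overall mean RT; interference =
  max(0, incongruent − neutral); facilitation = max(0, neutral − congruent);
  CV = 100·SD/mean over kept RTs (sample SD, ddof 1); duration means and
  clamped duration effects. Raw (unclamped) effects are retained in
  `*_raw_s` columns — presence-rate analyses must use them, since clamped
  scores are nonnegative by construction.
* Winsorization: feature columns are clipped at grand mean ± 3.5·sample SD of
  the original column (bounds from the pre-replacement column; in-bound values
  untouched). Applied to feature tables before group statistics, not inside
  the per-session scorer.
* Facilitation sign: defined as neutral − congruent so that a positive score
  means speeding by congruence, matching how positive facilitation magnitudes
  are conventionally reported.

## Statistics

* ICC(3,k): two-way (subjects × sessions) mean squares,
  `(MS_subjects − MS_error)/MS_subjects` — consistency, average of k. Ragged
  session counts are handled by a first-k complete-case rule (participants
  with fewer than k sessions are dropped); a practice-effect check recomputes
  the ICC excluding session 1. The implementation is cross-checked in the
  tests against an independent brute-force ANOVA decomposition and against
  `pingouin.intraclass_corr` (ICC(C,k)).
* Welch t (scipy) for group contrasts, with Welch–Satterthwaite df.
* Mixed models: `statsmodels` MixedLM with a participant random intercept,
  fitted by **maximum likelihood** (not REML) so the likelihood-ratio
  chi-square against the intercept-only random-intercept model is valid.
  Continuous covariates are grand-mean centered; binaries are 0/1 dummies;
  fixed-effect p-values use the normal approximation on t (documented as
  approximate). Near-zero random-intercept variance is flagged (`singular`),
  not silently returned.

## Default calibration

| parameter | nonpatient | patient | rationale |
|---|---|---|---|
| condition means (cong/neut/incong, s) | 0.702 / 0.749 / 0.862 | 0.735 / 0.814 / 0.926 | group condition means of the study populations being emulated |
| interference / facilitation (s) | 0.113 / 0.047 | 0.112 / 0.079 | implied by the condition means |
| sd_between (s) | 0.075 | 0.090 | reproduces participant-level speed SDs ≈ 0.08–0.09 s |
| sd_session (s) | 0.040 | 0.045 | day-to-day state variation; keeps speed ICCs high |
| exg sigma / tau (s) | 0.040 / 0.050 | 0.040 / 0.050 | see below |
| duration mean / sd (s) | 0.494 / 0.07 | 0.563 / 0.08 | patients utter response words ~65 ms longer |
| p_lapse / p_wrong_word / wer | 0.015 / 0.010 / 0.025 | 0.050 / 0.035 / 0.0626 | composite detected-correct rates ≈ 0.95 and ≈ 0.86 |
| beta_concentration (s/unit) | −0.0004 | −0.0004 | ≈ −4 ms per 10 slider units |
| beta_days / beta_days_ama (s/day) | 0 / 0 | −0.002 / +0.003 | discharge trend and AMA interaction |
| sessions (fixed) | 5 | 6 | typical completed-session counts |

The trial-noise level (sigma 0.040, tau 0.050; trial SD ≈ 0.064 s) was set by
a design constraint of the scoring pipeline rather than by matching observed
trial variability: with 8 congruent and 16 neutral kept trials, a session's
facilitation score has sampling SD ≈ trial_SD·√(1/8+1/16), and the
clamp-at-zero step inflates the cohort mean of a clamped score by
`sigma_d·phi(mu/sigma_d) − mu·Phi(−mu/sigma_d)`. At trial SD 0.064 this
inflation is < 1 ms even for the smallest calibrated effect (47 ms), so
cohort-mean effect scores recover the latent deltas to within ~2 ms. A trial
SD matching clinically observed coefficients of variation (~17–19%) would
inflate the smallest clamped facilitation mean by ~9 ms — a real property of
clamped difference scores at that noise level, worth knowing when comparing
clamped means across studies.

Consequences of this calibration, stated plainly:

* within-session CVs at default come out ≈ 8–12%, *below* the 17–19% typical
  of real voice-Stroop data — the generator is under-dispersed at trial level;
* the pooled-RT outlier cutoffs land around 1.1–1.2 s rather than the 1.4–1.6 s
  seen with heavier-tailed empirical data (the cutoff is mean + 3 SD, so it is
  a direct function of the configured mixture);
* with homogeneous deltas (default), participant-averaged effect scores have
  essentially no true between-person variance, so effect-score ICCs are near
  zero and effect-presence rates are near 1. Analyses of presence rates and
  effect-score reliability therefore use the heterogeneous configuration
  (`sd_interference_s ≈ 0.078`, `sd_facilitation_s ≈ 0.053`, participant-level
  SDs typical of such scores), as in `analysis/03_effects_and_reliability.py`.
  Heterogeneity is not the default because it re-introduces clamping inflation
  (~10 ms on the nonpatient facilitation mean), and the two regimes answer
  different questions: mean-recovery vs individual-differences structure.

## Power study

`power_curve` simulates cohorts *through the measurement model and RT filters*
(vectorized, but the same quantization, bias and filter rules as the scoring
pipeline; lapse-free, since power concerns timing, not compliance).
Within-participant design: paired t across participant condition means (8
effect-condition vs 16 neutral trials). Between-group design: Welch t on
participant-level effect scores whose between-participant SD defaults to
0.078 s. Identical seeds are reused across frame settings (common random
numbers), so "quantization never helps" comparisons are paired. Default 1000
simulations per cell; all results carry Monte-Carlo standard errors. Ward's
order-of-magnitude rule (`effect ≥ 10× precision`) is reported alongside as
the field's rule-of-thumb counterpart to the simulated power.

## Reproducibility and sizes

Every stochastic stage derives its stream from one master seed via
`numpy.random.SeedSequence` spawning; a config plus seed reproduces a cohort
byte-for-byte. Output CSVs carry a `# config_hash=` header. The analysis
scripts use cohorts of 113 nonpatients × ~5 sessions and 85 patients × ~6
sessions (the emulated study sizes); the mixed-model coverage experiment uses
200 replicate cohorts at 113 × 5, and power tables use 1000 simulations per
cell — sizes chosen so each script completes in at most a few minutes on a
laptop while keeping Monte-Carlo error well inside the tolerances asserted.

## Limitations

* No acoustics: the recognizer is a parametric error model, not a decoder;
  background noise, speech rate and pronunciation effects enter only through
  the aggregate bias/WER parameters.
* The onset-bias magnitude (36 ± 12 ms) is treated as a constant of the
  measurement model; in reality it likely varies by speaker and word onset
  (plosives vs fricatives).
* Covariates act additively on all conditions, so the generator cannot by
  itself produce covariate effects specific to interference/facilitation
  scores; such models can still be fitted, and recover zero, which is itself a
  useful null calibration.
* Passing recovery tests here shows the *pipeline* is unbiased under the
  stated generative assumptions; it cannot validate those assumptions against
  real recordings.
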