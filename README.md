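# voicestroop

Simulation and scoring pipeline for a **voice-response Stroop task** whose
spoken answers are timed by automatic speech recognition (ASR).

## The problem

Mobile Stroop testing with spoken responses is attractive for repeated
clinical measurement: a 96-second session (32 words, one every 3 s) can be
self-administered daily, and an ASR system timestamps each utterance's onset,
offset and transcript. But recognizer timestamps come on a fixed frame grid —
typically 10 ms, from the moving-window decoder — carry a systematic early
bias relative to manual annotation (≈36 ± 12 ms per utterance), and a few
percent of transcripts are wrong. Whether interference and facilitation
effects, their test–retest reliability, and small clinical covariate effects
survive this measurement layer is a quantitative question.

`voicestroop` answers it with a generative model plus the exact scoring rules
such a task uses, so every analysis can be run as a parameter-recovery
experiment: you know the latent truth, you measure what the pipeline returns.
It is aimed at researchers designing speech-based cognitive assessments and at
methodologists studying measurement-resolution limits in reaction-time data.

## The model

Per trial, the voice-onset latency of participant *i*, session *j*, condition
*c* is

```
RT_ijc = mu_c(i) + u_i + s_ij + beta' x_ij + N(0, sigma) + (Exp(tau) - tau)
```

an ex-Gaussian around the latent condition mean `mu_c(i)`, with participant
random intercept `u_i ~ N(0, sd_between)`, session effect
`s_ij ~ N(0, sd_session)` and session-level covariates `x_ij` (self-reported
concentration 0–100, days to discharge, an against-medical-advice
interaction). Condition means differ by the **interference** delta
(incongruent − neutral) and the **facilitation** delta (neutral − congruent).

The recognizer reports `floor((onset - b) / frame) * frame` with per-utterance
bias `b ~ N(0.036, 0.012)` s and frame 10 ms, and substitutes the transcript
with probability equal to the word error rate.

Scoring follows the task's rules exactly: responses are attributed to the
trial whose half-open 3 s window contains the detected onset (first utterance
wins); accuracy = correct / 32; RT processing keeps correct responses with
0.2 s ≤ RT ≤ (group mean + 3 SD); session features are per-condition mean RTs,
clamped interference/facilitation, coefficients of variation
(100·SD/mean), and utterance-duration analogues. Statistics: ICC(3,k)
(two-way consistency, average of k), Welch t, effect-presence rates on
unclamped scores, and random-intercept mixed models (ML) with
likelihood-ratio chi-square against the intercept-only model.

## Worked example

```python
from voicestroop import default_config, simulate_cohort, score_cohort, ward_check
from voicestroop.resolution import power_curve

cfg = default_config(42)
cfg.n_nonpatients, cfg.n_patients = 0, 85     # patient cohort, 6 sessions each
cohort = simulate_cohort(cfg)
groups = cohort.participants.set_index("participant_id")["group"]
scores, log = score_cohort(cohort.schedules_frame(), cohort.events_frame(), groups)
print(f"sessions scored:        {len(scores)}")
print(f"patient RT cutoff:      {log['cutoffs_s']['patient']:.3f} s")
print(f"mean accuracy:          {scores['accuracy'].mean():.3f}")
print(f"mean interference:      {scores['interference_s'].mean()*1000:.1f} ms")
print(f"mean facilitation:      {scores['facilitation_s'].mean()*1000:.1f} ms")

ratio, ok = ward_check(0.010, 0.027)
print(f"27 ms group difference: ratio {ratio:.1f}x the 10 ms frame -> "
      f"{'meets' if ok else 'fails'} the 10x precision rule")
pr = power_curve(0.027, n_participants=85, n_sims=500, rng_seed=1, design="between")
print(f"between-group power at 27 ms: {pr.power:.2f} (MC SE {pr.mc_se:.2f})")
```

prints

```
sessions scored:        510
patient RT cutoff:      1.159 s
mean accuracy:          0.858
mean interference:      111.6 ms
mean facilitation:      78.8 ms
27 ms group difference: ratio 2.7x the 10 ms frame -> fails the 10x precision rule
between-group power at 27 ms: 0.53 (MC SE 0.02)
```

The 510 patient sessions (85 × 6) were generated with latent interference
112 ms and facilitation 79 ms; the full measurement-plus-scoring chain returns
111.6 and 78.8 ms — the frame grid, onset bias, word errors and RT filters
cost almost nothing *for cohort means of large effects*. A 27 ms group
difference, by contrast, sits far below the 10× precision rule of thumb, and
even with 85 participants per group a Welch test detects it only about half
the time.

## Repository layout

- `src/voicestroop/` — the library: `paradigm` (stimuli, schedules),
  `synthesize` (cohort generator), `measurement` (recognizer model),
  `scoring` (assignment, filters, session features), `stats` (ICC, Welch,
  mixed models), `resolution` (quantization moments, Ward's rule, power),
  `config`/`pipeline`/`cli` (configuration, artifact bundle, `voicestroop`
  command).
- `analysis/01_…05_….py` — the narrative analyses: cohort simulation and data
  usability, scoring, effects/presence/reliability, mixed models, and the
  temporal-resolution power study. Each writes small tables under `results/`.
- `docs/methods.md` — model, parameter and design documentation.

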