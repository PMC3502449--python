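# emadiary

A branching ecological-momentary-assessment (EMA) diary engine for psychotic
and mood symptoms, with the psychometric analyses used to evaluate such an
instrument — exercised end to end on simulated respondents.

## What it is for

Semi-structured interviews such as the PANSS (Positive and Negative Syndrome
Scale, items rated 1 = absent to 7 = severe) and the Calgary Depression Scale
(items rated 1–4) are the standard way of assessing psychosis, but they rely
on week-scale recall and trained raters. An alternative is ambulatory
self-report: a phone prompts the participant several times a day and
administers a short, adaptive questionnaire about symptoms since the last
entry. `emadiary` implements the full machinery of such a system for
researchers who want to study its measurement properties:

- **Item bank** — a 14-scale instrument (guilt, hopelessness, depression,
  social withdrawal, conceptual disorganisation, excitement and
  hallucinations in set one; anxiety, grandiosity, hostility, somatic
  concern, guilty ideas of reference, suspiciousness and delusions in set
  two), split into two sets administered at alternating prompts. Items
  branch: follow-up questions appear only when a stem response crosses a
  threshold, so a set-one session presents between 15 and 30 questions and a
  set-two session between 11 and 31. Delusion content is personalised per
  participant from a menu of six belief templates (at most two), each scored
  for preoccupation, distress and behavioural impact.
- **Scheduler** — six pseudo-random prompts per day for seven days (42
  occasions), drawn within equal stratification epochs of the 09:00–21:00
  window, at least one hour apart, with a single 5-minute snooze and a
  15-minute response window anchored to the initial alarm.
- **Scoring** — analogue slider positions are binned onto a 7-point Likert
  scale; a scale score at a timepoint is the mean of its answered items
  (the first grandiosity item is recoded 1-4→1, 5→2, 6→3, 7→4 so only
  grandiose self-appraisals score); the delusions and depression scores are
  composites that fold in the scale means informing the matching interview
  item; a participant is compliant when at least 33% of the 42 scheduled
  entries (14 or more) were completed.
- **Psychometrics** — within-person instability via the mean squared
  successive difference, MSSD = Σ(xᵢ₊₁−xᵢ)²/(n−1), and the within-person SD;
  internal consistency via Cronbach's α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ); convergent
  validity via Spearman's ρ between person-level diary means and interview
  ratings; and a reactivity (safety) score from two dedicated items.
- **Simulator** — synthetic cohorts of three severity groups (acute,
  remitted, ultra-high-risk; 12 each). Each construct follows a stationary
  person-level AR(1) trajectory; items are noisy analogue renderings of the
  latent state; per-prompt completion is Bernoulli with a logistic model in
  which positive-symptom severity lowers completion (odds ratio 0.68 per
  unit); interviews are noisy monotone transforms of the latent means, so
  the diary–interview concordance the pipeline should recover is known.

## Worked example

Simulate a cohort, score it, and build the full report set:

```bash
emadiary report --seed 1 --out-dir demo/
# compliance 36/36 (100%); reports in demo
```

`demo/table2.csv` holds the validity table, sorted by descending ρ (first
rows shown):

```
scale_id,rho,p,n,flag,alpha
somatic_concern,0.85,0.00,36,,0.93
anxiety,0.84,0.00,36,,0.93
excitement,0.83,0.00,36,,0.94
```

Each row correlates 36 simulated participants' mean diary scores with their
follow-up interview rating for the mapped item; `alpha` is the scale's
internal consistency over pooled completed entries. `demo/table3.csv` holds
the instability metrics — the across-person mean (and SD) of each person's
MSSD and within-person SD:

```
scale_id,mssd_mean,mssd_sd,sd_mean,sd_sd,n_participants
guilt,1.01,0.64,0.72,0.23,36
hopelessness,1.25,0.48,0.84,0.16,36
depression,0.88,0.46,0.73,0.17,36
```

Under the default generator, stable-belief constructs (delusions,
grandiosity) show the lowest MSSD and social withdrawal the highest,
while all 36 simulated participants clear the 14-of-42 compliance threshold
(`demo/compliance.json`); per-group reactivity means are in
`demo/reactivity.json`. The same pipeline is available as library functions
(`emadiary.run_validity_study`) and as separate `schedule`, `simulate`,
`score` and `validate` subcommands operating on CSV files.

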