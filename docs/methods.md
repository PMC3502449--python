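# Methods

This note documents the measurement model, the design choices made where the
published description of such instruments leaves the mechanism open, and what
the synthetic-respondent generator does and does not emulate.

## The instrument

The item bank defines 14 symptom scales split into two sets of seven,
administered at alternating prompts so that no single session carries the
whole instrument. Twelve scales mirror PANSS constructs and two (hopelessness
and guilty ideas of reference) mirror Calgary Depression Scale items; the
mapping is carried per scale as an `interview_map` code and is used by the
validity analysis to pair diary and interview scores.

Items are either stems (always shown) or branches (shown only when a
designated earlier item's response satisfies a comparator against a
threshold on the 7-point scale). Validation requires every branch source to
precede its dependant within the same set, which simultaneously rules out
dangling references and condition cycles. The packaged default bank uses a
branch trigger of "stem ≥ 2" — any endorsement above the scale floor — with
one deliberate exception: the follow-up grandiosity item triggers at ≥ 5,
because responses 1–4 on its self-comparison stem carry no grandiose content
(see the recode below). Exhaustive enumeration over all satisfiable branch
outcomes gives session lengths of 15–30 questions for set one and 11–31 for
set two (the latter spanning zero to two configured delusion blocks), and the
loader enforces these bounds on any bank it accepts.

The enumeration is exact: for every item that gates at least one condition,
response values are partitioned into equivalence classes by the vector of
condition outcomes they produce, and a depth-first walk over class
representatives visits items in presentation order so chained
branch-on-branch conditions resolve correctly. The unit tests check this
against brute force over all source-response assignments on random banks.

Delusional beliefs vary too widely for fixed items, so the bank ships six
belief-statement templates; a researcher configures at most two per
participant, and each configured belief contributes an unconditional block of
four questions (the statement plus preoccupation, distress and behavioural
impact). With no beliefs configured the delusion block is absent from
administration entirely.

Two reactivity items ("keeping the diary has influenced my thoughts/mood")
are appended to every session. They belong to no symptom scale, are excluded
from the enumerated question counts, and are reported only as a magnitude:
the items do not measure the direction of any change.

The exact wordings of the original instrument's stems and branches are not
public; the packaged bank uses the published scale names, the six published
belief statements, and item wordings written for this package, with the
branch structure engineered to reproduce the published session-length bounds.
Every structural property the engine relies on (set membership, counts,
branching, recodes, composites) is therefore faithful even though the prose
of individual items is not.

## Response capture and scoring

Responses are captured as analogue-slider positions in [0, 1] and converted
to Likert 1–7 by seven equal-width bins (bin k covers [(k−1)/7, k/7), top bin
right-closed). No anchoring offsets are applied. An unanswered branch source
evaluates false, i.e. the branch stays hidden.

A scale score at a timepoint is the unweighted mean of the scale's answered
items. Hidden branch items are excluded from the mean, not imputed at the
floor: imputing 1s would deflate scores for participants who endorse stems
weakly. The first grandiosity item is recoded 1-4→1, 5→2, 6→3, 7→4 before
averaging, and the recode is applied exactly once, at scoring.

Two scores are composites so their content matches the interview item they
are compared against. The delusions score is the mean of the vector
[each delusion item response …, grandiosity mean, somatic-concern mean,
suspiciousness mean]; with no delusions configured it degenerates to the mean
of the three scale means. The depression score is the mean of
[each depression item response …, hopelessness mean]. Sub-items of a
configured belief are weighted equally; nothing in the published description
suggests differential weighting.

Person-level scores are unweighted means over all available timepoints.
Compliance uses the smallest integer not less than 33% of the scheduled
entries — 14 of 42 at defaults (the ceiling is taken after rounding the
product to 9 decimals so binary floating-point noise cannot shift the
threshold). Partial sessions are recorded as missed with no item data: entry
counts are complete-or-nothing, so there is no partial credit anywhere
downstream. Completion percentages round half-up to the nearest integer.

## Scheduling

Each day's prompts are drawn within equal-width epochs of the sampling
window (six 120-minute epochs of 09:00–21:00 at defaults), one prompt
uniform per epoch, in whole minutes on the local clock. A draw closer than
60 minutes to the previous prompt is redrawn up to 100 times, then repaired
deterministically to the earliest feasible instant (previous prompt + gap);
with equal epochs at least as wide as the gap this repair always lands
inside the epoch, and a property test confirms that after repair more than
90% of each epoch's interior minutes are still reachable. One snooze per
alarm schedules a reminder five minutes later; the 15-minute response window
is anchored to the initial alarm and never moves. Day 1 is the first full
day after briefing; 7 days × 6 prompts gives the 42 possible entries the
compliance rule divides by.

## Psychometric statistics

- **MSSD** = Σ(xᵢ₊₁−xᵢ)²/(n−1) over a participant's time-ordered available
  scores; missing timepoints are dropped before differencing, so differences
  may span gaps and days. Undefined below two points. For an i.i.d. series
  E[MSSD] = 2σ², and for a stationary AR(1) with innovation σ and
  persistence φ, E[MSSD] = 2σ²/(1+φ) — both are used as analytic checks.
- **Within-person SD** is the sample SD (n−1 denominator).
- **Cronbach's α** = k/(k−1)·(1 − Σ item variances / total-score variance),
  sample variances, computed on pooled completed entries (rows are entries
  across participants and timepoints; the row unit is flagged in the output).
  Rows are listwise-complete on the scale's items, so branched scales are
  assessed on occasions where the full item set was triggered. For the
  delusions scale, configured belief blocks are pooled by position
  (statement, preoccupation, distress, impact), treating sub-items as
  parallel across templates. α is undefined (never 0) when the total-score
  variance vanishes. Item responses enter α untransformed.
- **Spearman's ρ** uses average-rank ties and the t-approximation with n−2
  df for the two-sided p-value (adequate at the n = 36 scale of a cohort);
  an exact permutation p is used below n = 10. The validity table pairs each
  scale's person-level diary means with its mapped follow-up interview item
  — the follow-up interview covers the same week the diary sampled — sorts
  defined rows by descending ρ, and excludes (with a flag) any scale
  endorsed above the floor by fewer than three participants, since a rank
  correlation on a scale almost nobody endorses is noise.
- The instability table reports the across-person mean and SD of the
  person-level MSSD and SD per scale; delusion rows are restricted to
  participants who actually had delusion questions configured.

Undefined statistics propagate as absent values (empty CSV cells, JSON
nulls), never as zeros.

## The synthetic-respondent generator

The generator defines the study conditions the engine is tested under: three
groups of 12 (acute, remitted, ultra-high-risk), 6 prompts/day for 7 days.

Each construct's latent state follows a stationary AR(1),
L₁ ~ N(μ, σ²/(1−φ²)), L_{t+1} = μ + φ(L_t−μ) + ε, with the person-level mean
μ drawn from a group-specific normal (acute above UHR above remitted on
positive constructs; similar across groups on affective ones) and truncated
to the 1–6.5 band of the response continuum. Persistence is graded by
construct: beliefs are stable (φ = 0.85 delusions, 0.80 grandiosity), social
withdrawal is labile (φ = 0.20), the rest sit between — the simplest process
that produces the stable-beliefs-versus-labile-behaviour contrast an EMA
instrument is meant to resolve. Innovation SD defaults to 0.7 on the 1–7
continuum; guilty ideas of reference is given a near-floor mean (≈1.2) and
small spread so it is rarely endorsed, reproducing the situation where that
scale cannot be analysed.

An item response is the latent state squashed linearly from [1, 7] onto the
analogue slider, plus N(0, 0.06) item noise, clamped to [0, 1]; the engine
then bins it to Likert as it would a real response. Per-prompt completion is
Bernoulli with person-level probability logistic(β₀ + ln(OR)·(positive
severity − 2.5)), OR = 0.68 per unit of the mean positive-construct latent
and β₀ = 0.944 (a 72% completion rate at reference severity, matching the
overall completion typical of compliant EMA cohorts). Missingness is
independent across prompts given the person; there are no within-week
dropout dynamics. Interview ratings are the latent mean plus N(0, σ_int)
noise, rounded and clipped to 1–7 (PANSS-mapped) or compressed onto 1–4
(CDS-mapped); both baseline and follow-up occasions are generated, and the
analysis uses the follow-up.

Because the interview transform is known, the diary–interview concordance
the pipeline should recover is known too: `calibrate_interview_noise` finds
by bisection the σ_int giving a target mean recovered ρ, and the recovery
experiment (vectorised single-scale pipeline, 36 participants per cohort)
verifies the calibrated target is recovered to within ±0.05 over 200
cohorts. Delusion configuration is probabilistic in the belief latent, so
roughly the participants with belief-laden trajectories carry delusion
blocks.

What the generator does **not** emulate: response styles (acquiescence,
extreme responding), diurnal cycles, reactive change in symptoms from being
sampled, within-week dropout, context-dependent missingness, or any
dependence between constructs beyond their shared group means. Passing
tests therefore demonstrate that the engine and analyses are correct and
internally consistent under a plausible generative model — not that a real
population would show the same table values, which is also why no attempt is
made to reproduce published per-scale correlation or instability magnitudes.

## Problem sizes and determinism

The test suite runs the scheduler constraint sweep over 1000 seeds, the
metric-versus-oracle comparisons over 500 random instances each at 1e-10,
the analytic MSSD limits at n = 10⁵, and the concordance recovery over 200
cohorts of 36 — sizes chosen so the full suite completes in seconds while
estimator noise stays well inside the asserted tolerances. All randomness
flows through `numpy.random.default_rng` seeded explicitly; identical
(parameters, seed) reproduce byte-identical schedules, sessions, logs and
reports.

## Known limitations

- Item prose is original to this package; content validity of the wording
  has not been (and cannot be) assessed against the unpublished original.
- α on branched scales conditions on full branch triggering, which selects
  symptomatic occasions and can overstate consistency relative to an
  imputation-based estimate.
- The compliance model's odds ratio applies per unit of the 1–7 latent
  severity, a different scale from an interview subscale total; only the
  direction and monotonicity of the effect are meaningful.
- The scheduler models whole minutes and ignores time zones and DST.
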