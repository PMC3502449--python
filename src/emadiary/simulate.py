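"""Synthetic respondents: latent symptom trajectories, responses, missingness.

The generator emulates the study conditions the engine is designed for: three
severity groups (acute, remitted, ultra-high-risk) of 12 participants each,
prompted 6 times a day for 7 days (42 occasions).  Each symptom construct
follows a stationary person-level AR(1) trajectory on the 1-7 continuum; item
responses are noisy analogue renderings of the latent state; completion of
each prompt is Bernoulli with a per-person probability from a logistic model
in which positive-symptom severity lowers completion (odds ratio below 1);
and paired interview ratings are noisy monotone transforms of the person's
latent mean, giving a known diary-interview concordance to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .item_bank import (
    DelusionSelection,
    ItemBank,
    analogue_to_likert,
    configure_delusions,
    load_default_bank,
)
from .psychometrics import (
    alpha_table,
    compute_instability_summaries,
    instability_table,
    reactivity_mean,
    validity_table,
)
from .scheduler import ScheduleConfig, WeekSchedule, make_week_schedule
from .scoring import ComplianceRule, completion_percent, score_entry_all, summarise_person
from .session_engine import REACTIVITY_ITEM_IDS, SessionEntry, administer_session, assign_set

__all__ = [
    "ScaleSimConfig",
    "SimParams",
    "SimOutput",
    "simulate_latent",
    "squash_latent",
    "render_response",
    "simulate_compliance",
    "simulate_interviews",
    "run_validity_study",
    "validity_recovery_experiment",
    "calibrate_interview_noise",
    "spearman_from_pearson",
]

GROUPS = ("acute", "remitted", "uhr")

#: Constructs informing the positive-symptom severity used by the compliance
#: model (the positive-subscale counterparts of the instrument).
POSITIVE_SCALES = (
    "delusions",
    "conceptual_disorganisation",
    "hallucinations",
    "excitement",
    "grandiosity",
    "suspiciousness",
    "hostility",
)


class ScaleSimConfig(BaseModel):
    """Latent-trajectory parameters for one symptom construct."""

    model_config = ConfigDict(frozen=True)

    base_mu: Mapping[str, float]  # group -> mean of the person-level latent mean
    tau: float = Field(default=0.8, ge=0)  # between-person SD of the latent mean
    phi: float = Field(default=0.5, ge=0, lt=1)  # AR(1) persistence
    sigma: float = Field(default=0.7, ge=0)  # innovation SD


def _default_scale_configs() -> dict[str, ScaleSimConfig]:
    """Study-condition defaults: acute > UHR >= remitted on positive constructs,
    persistence graded so beliefs are stable and social withdrawal is labile."""

    def cfg(acute: float, remitted: float, uhr: float, phi: float, tau: float = 0.8) -> ScaleSimConfig:
        return ScaleSimConfig(
            base_mu={"acute": acute, "remitted": remitted, "uhr": uhr}, phi=phi, tau=tau
        )

    return {
        # positive constructs
        "delusions": cfg(3.2, 1.8, 2.3, 0.85),
        "hallucinations": cfg(2.8, 1.6, 2.1, 0.55),
        "suspiciousness": cfg(2.9, 1.8, 2.4, 0.60),
        "grandiosity": cfg(2.4, 1.6, 1.8, 0.80),
        "conceptual_disorganisation": cfg(2.4, 1.7, 2.0, 0.35),
        "excitement": cfg(2.6, 2.0, 2.2, 0.30),
        "hostility": cfg(2.3, 1.7, 1.9, 0.40),
        # affective / general constructs (similar across groups)
        "anxiety": cfg(3.0, 2.5, 2.9, 0.40),
        "depression": cfg(3.0, 2.6, 2.9, 0.50),
        "hopelessness": cfg(2.8, 2.4, 2.7, 0.50),
        "guilt": cfg(2.4, 2.1, 2.3, 0.45),
        "somatic_concern": cfg(2.6, 2.0, 2.2, 0.50),
        "social_withdrawal": cfg(3.0, 2.6, 2.8, 0.20),
        # rarely endorsed in any group, mirroring its near-floor behaviour
        "guilty_ideas_of_reference": cfg(1.3, 1.15, 1.2, 0.50, tau=0.25),
    }


class SimParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_per_group: int = Field(default=12, ge=1)
    schedule: ScheduleConfig = ScheduleConfig()
    scale_configs: Mapping[str, ScaleSimConfig] = Field(default_factory=_default_scale_configs)
    sigma_item: float = Field(default=0.06, ge=0)  # analogue-fraction units
    sigma_int: float = Field(default=0.55, ge=0)  # interview-rating units
    compliance_beta0: float = 0.944  # logit of the expected completion rate at reference severity
    compliance_or: float = Field(default=0.68, gt=0)  # odds ratio per unit positive severity
    positive_reference: float = 2.5  # severity at which beta0 applies
    reactivity_mu: Mapping[str, float] = Field(
        default_factory=lambda: {"acute": 3.6, "remitted": 2.9, "uhr": 2.4}
    )
    reactivity_tau: float = Field(default=0.8, ge=0)
    delusion_threshold: float = 2.2  # latent mean above which beliefs tend to be configured
    seed: Optional[int] = None


@dataclass
class SimOutput:
    responses: pd.DataFrame  # long response log, one row per item response
    interviews: pd.DataFrame  # participant_id, occasion, item_code, rating
    truth: dict  # generating latent means and concordance per scale
    entries: dict[str, list[SessionEntry]]
    bank_views: dict[str, ItemBank]
    schedules: dict[str, WeekSchedule]
    groups: dict[str, str]


# ---------------------------------------------------------------------------
# Generative primitives


def simulate_latent(
    rng: np.random.Generator, mu: float, phi: float, sigma: float, n: int
) -> np.ndarray:
    """Stationary AR(1) series: x_1 ~ N(mu, sigma^2/(1-phi^2)),
    x_{t+1} = mu + phi (x_t - mu) + eps_t with eps_t ~ N(0, sigma^2)."""
    x = np.empty(n)
    if sigma == 0:
        x.fill(mu)
        return x
    x[0] = rng.normal(mu, sigma / math.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + eps[t - 1]
    return x


def squash_latent(latent: float | np.ndarray) -> float | np.ndarray:
    """Monotone map from the 1-7 latent continuum onto the analogue [0, 1] slider."""
    return np.clip((np.asarray(latent, dtype=float) - 1.0) / 6.0, 0.0, 1.0)


def render_response(latent: float, rng: np.random.Generator, sigma_item: float) -> float:
    """Analogue fraction for one item: squashed latent plus clamped item noise."""
    noise = rng.normal(0.0, sigma_item) if sigma_item > 0 else 0.0
    return float(np.clip(squash_latent(latent) + noise, 0.0, 1.0))


def simulate_compliance(
    rng: np.random.Generator,
    params: SimParams,
    positive_severity: float,
    n_alarms: Optional[int] = None,
) -> np.ndarray:
    """Independent Bernoulli completion flags for every scheduled alarm.

    Per-person probability: logistic(beta0 + ln(OR) * (severity - reference)),
    so an odds ratio below 1 makes more severe positive symptoms lower the
    completion probability monotonically.
    """
    n = params.schedule.n_alarms if n_alarms is None else n_alarms
    eta = params.compliance_beta0 + math.log(params.compliance_or) * (
        positive_severity - params.positive_reference
    )
    p = 1.0 / (1.0 + math.exp(-eta))
    return rng.random(n) < p


def _interview_rating(
    rng: np.random.Generator, latent_mean: float, code: str, sigma_int: float
) -> int:
    if code.startswith("CDS"):
        # Compress the 1-7 latent continuum onto the 1-4 interview range.
        raw = 1.0 + (latent_mean - 1.0) / 2.0 + rng.normal(0.0, sigma_int / 2.0)
        return int(np.clip(np.round(raw), 1, 4))
    raw = latent_mean + rng.normal(0.0, sigma_int)
    return int(np.clip(np.round(raw), 1, 7))


def simulate_interviews(
    rng: np.random.Generator,
    latent_means: Mapping[str, Mapping[str, float]],  # participant -> scale -> mu
    params: SimParams,
    bank: ItemBank,
    occasions: Sequence[str] = ("baseline", "followup"),
) -> pd.DataFrame:
    """Paired interview tables: noisy rounded transforms of the latent means."""
    rows = []
    code_by_scale = {s.scale_id: s.interview_map for s in bank.scales}
    for pid in sorted(latent_means):
        for occasion in occasions:
            for sid, mu in latent_means[pid].items():
                code = code_by_scale[sid]
                rating = _interview_rating(rng, mu, code, params.sigma_int)
                rows.append((pid, occasion, code, rating))
    return pd.DataFrame(rows, columns=["participant_id", "occasion", "item_code", "rating"])


# ---------------------------------------------------------------------------
# End-to-end study simulation


def _minutes_to_hhmm(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def _entries_to_log(
    entries: Mapping[str, Sequence[SessionEntry]],
    bank_views: Mapping[str, ItemBank],
    schedules: Mapping[str, WeekSchedule],
) -> pd.DataFrame:
    rows = []
    for pid in sorted(entries):
        view = bank_views[pid]
        scale_of = {it.item_id: s.scale_id for s in view.scales for it in s.items}
        for rid in REACTIVITY_ITEM_IDS:
            scale_of[rid] = "reactivity"
        alarms = schedules[pid].alarms
        for e in entries[pid]:
            answered = _minutes_to_hhmm(alarms[e.alarm_index - 1].time)
            if not e.completed:
                rows.append((pid, e.day, e.alarm_index, e.set, "", "", "", answered, "missed"))
                continue
            for iid, val in e.responses.items():
                rows.append(
                    (pid, e.day, e.alarm_index, e.set, iid, scale_of[iid], val, answered, "completed")
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "day",
            "alarm_index",
            "set",
            "item_id",
            "scale_id",
            "response_likert",
            "answered_at_hhmm",
            "status",
        ],
    )


def run_validity_study(
    params: SimParams | None = None,
    seed: int | None = None,
    bank: ItemBank | None = None,
) -> tuple[SimOutput, dict]:
    """Simulate a full cohort and run the complete analysis pipeline on it.

    Generates schedules, branching sessions, severity-dependent missingness
    and paired interviews; excludes non-compliant participants; and builds the
    validity, reliability, instability and compliance reports.  Fully
    reproducible from (params, seed).
    """
    params = params or SimParams()
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    bank = bank or load_default_bank()
    rng = np.random.default_rng(seed)

    n_alarms = params.schedule.n_alarms
    entries: dict[str, list[SessionEntry]] = {}
    bank_views: dict[str, ItemBank] = {}
    schedules: dict[str, WeekSchedule] = {}
    groups: dict[str, str] = {}
    latent_means: dict[str, dict[str, float]] = {}
    template_ids = [t.template_id for t in bank.delusion_templates]

    pid_counter = 0
    for group in GROUPS:
        for _ in range(params.n_per_group):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            groups[pid] = group

            mus = {
                sid: float(
                    np.clip(rng.normal(cfg.base_mu[group], cfg.tau), 1.0, 6.5)
                )
                for sid, cfg in params.scale_configs.items()
            }
            latent_means[pid] = mus

            # Personalised delusion configuration: more belief-laden latents
            # make one or two templates more likely to be entered at briefing.
            p_del = 1.0 / (1.0 + math.exp(-2.0 * (mus["delusions"] - params.delusion_threshold)))
            n_templates = 0
            if rng.random() < p_del:
                n_templates = 2 if rng.random() < 0.5 else 1
            chosen = tuple(rng.choice(template_ids, size=n_templates, replace=False)) if n_templates else ()
            selection = DelusionSelection(participant_id=pid, template_ids=chosen)
            view = configure_delusions(bank, selection)
            bank_views[pid] = view

            schedules[pid] = make_week_schedule(rng, params.schedule)

            series = {
                sid: simulate_latent(rng, mus[sid], cfg.phi, cfg.sigma, n_alarms)
                for sid, cfg in params.scale_configs.items()
            }
            reactivity_level = float(
                np.clip(rng.normal(params.reactivity_mu[group], params.reactivity_tau), 1.0, 7.0)
            )
            pos_mu = float(np.mean([mus[s] for s in POSITIVE_SCALES]))
            flags = simulate_compliance(rng, params, pos_mu)

            scale_of_item = {it.item_id: s.scale_id for s in view.scales for it in s.items}
            person_entries: list[SessionEntry] = []
            for alarm_idx in range(1, n_alarms + 1):
                set_no = assign_set(alarm_idx)
                day = (alarm_idx - 1) // params.schedule.prompts_per_day + 1
                first = (alarm_idx - 1) % params.schedule.prompts_per_day == 0
                if not flags[alarm_idx - 1]:
                    person_entries.append(
                        SessionEntry(pid, day, alarm_idx, set_no, {}, "missed", first)
                    )
                    continue
                t = alarm_idx - 1

                def responder(item_id: str) -> float:
                    if item_id in REACTIVITY_ITEM_IDS:
                        latent = reactivity_level
                    else:
                        latent = series[scale_of_item[item_id]][t]
                    return render_response(latent, rng, params.sigma_item)

                person_entries.append(
                    administer_session(
                        view,
                        set_no,
                        responder,
                        participant_id=pid,
                        day=day,
                        alarm_index=alarm_idx,
                        first_of_day=first,
                    )
                )
            entries[pid] = person_entries

    interviews = simulate_interviews(rng, latent_means, params, bank)

    truth = {
        "latent_means": latent_means,
        "groups": groups,
        "generating_concordance": {
            sid: {
                "pearson": cfg.tau / math.sqrt(cfg.tau**2 + params.sigma_int**2)
                if (cfg.tau or params.sigma_int)
                else 1.0,
                "spearman": spearman_from_pearson(
                    cfg.tau / math.sqrt(cfg.tau**2 + params.sigma_int**2)
                    if (cfg.tau or params.sigma_int)
                    else 1.0
                ),
            }
            for sid, cfg in params.scale_configs.items()
        },
    }
    output = SimOutput(
        responses=_entries_to_log(entries, bank_views, schedules),
        interviews=interviews,
        truth=truth,
        entries=entries,
        bank_views=bank_views,
        schedules=schedules,
        groups=groups,
    )
    reports = analyse_study(output, bank)
    return output, reports


def analyse_study(output: SimOutput, bank: ItemBank | None = None) -> dict:
    """Score, filter non-compliant participants, and build the report set."""
    bank = bank or load_default_bank()
    rule = ComplianceRule(n_possible=next(iter(output.schedules.values())).config.n_alarms)

    summaries = {
        pid: summarise_person(es, output.bank_views[pid], rule) for pid, es in output.entries.items()
    }
    compliant = {pid for pid, s in summaries.items() if s.compliant}
    n_entered = len(summaries)
    total_completed = sum(s.n_completed for s in summaries.values())

    kept_entries = {pid: output.entries[pid] for pid in sorted(compliant)}
    kept_views = {pid: output.bank_views[pid] for pid in sorted(compliant)}

    score_rows = []
    for pid in sorted(compliant):
        for e in kept_entries[pid]:
            for sid, value in score_entry_all(e, kept_views[pid]).items():
                score_rows.append((pid, e.day, e.alarm_index, sid, value))
    scores = pd.DataFrame(
        score_rows, columns=["participant_id", "day", "alarm_index", "scale_id", "value"]
    )

    mapping = {s.scale_id: s.interview_map for s in bank.scales}
    table2 = validity_table(
        [summaries[pid] for pid in sorted(compliant)], output.interviews, mapping
    )
    if kept_entries:
        alphas = alpha_table(kept_entries, kept_views)
    else:
        alphas = pd.DataFrame(columns=["scale_id", "alpha", "k", "n_rows"])
    table2 = table2.merge(alphas[["scale_id", "alpha"]], on="scale_id", how="left")

    delusion_pids = {
        pid for pid in compliant if len(output.bank_views[pid].scale("delusions").items) > 0
    }
    inst = compute_instability_summaries(scores) if not scores.empty else []
    table3 = instability_table(
        inst,
        delusion_participants=delusion_pids,
        scale_order=[s.scale_id for s in bank.scales],
    )

    # reactivity to the method, by severity group (magnitude only)
    reactivity_by_group: dict[str, list[float]] = {}
    for pid in sorted(compliant):
        r = reactivity_mean(kept_entries[pid])
        if r is not None:
            reactivity_by_group.setdefault(output.groups[pid], []).append(r)
    reactivity_summary = {
        group: {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                "n": len(vals)}
        for group, vals in sorted(reactivity_by_group.items())
    }

    compliance_summary = {
        "n_entered": n_entered,
        "n_compliant": len(compliant),
        "compliance_percent": completion_percent(len(compliant), n_entered) if n_entered else None,
        "threshold_count": rule.threshold_count,
        "n_possible_entries": rule.n_possible,
        "mean_entries_completed_compliant": (
            float(np.mean([summaries[p].n_completed for p in compliant])) if compliant else None
        ),
        "entry_completion_percent_overall": (
            completion_percent(total_completed, n_entered * rule.n_possible) if n_entered else None
        ),
    }
    return {
        "table2": table2,
        "table3": table3,
        "compliance": compliance_summary,
        "reactivity": reactivity_summary,
        "scores": scores,
        "person_summaries": summaries,
    }


def expected_compliance_fraction(
    params: SimParams | None = None, *, n_cohorts: int = 200, seed: int = 0
) -> float:
    """Model-implied fraction of participants meeting the compliance threshold.

    Averages, over simulated cohorts of latent means, the binomial tail
    probability that a person's completed-entry count reaches the threshold
    given their per-alarm completion probability from the logistic model.
    """
    from scipy import stats

    params = params or SimParams()
    rng = np.random.default_rng(seed)
    rule = ComplianceRule(n_possible=params.schedule.n_alarms)
    n = params.schedule.n_alarms
    probs = []
    for _ in range(n_cohorts):
        for group in GROUPS:
            for _ in range(params.n_per_group):
                mus = [
                    float(np.clip(rng.normal(cfg.base_mu[group], cfg.tau), 1.0, 6.5))
                    for sid, cfg in params.scale_configs.items()
                    if sid in POSITIVE_SCALES
                ]
                eta = params.compliance_beta0 + math.log(params.compliance_or) * (
                    float(np.mean(mus)) - params.positive_reference
                )
                p = 1.0 / (1.0 + math.exp(-eta))
                probs.append(float(stats.binom.sf(rule.threshold_count - 1, n, p)))
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# Concordance calibration and recovery


def spearman_from_pearson(r: float) -> float:
    """Population Spearman correlation of a bivariate normal with Pearson r."""
    return (6.0 / math.pi) * math.asin(r / 2.0)


def validity_recovery_experiment(
    *,
    sigma_int: float,
    n_participants: int = 36,
    n_replicates: int = 200,
    mu: float = 2.5,
    tau: float = 0.8,
    phi: float = 0.5,
    sigma: float = 0.7,
    sigma_item: float = 0.06,
    k_items: int = 4,
    n_occasions: int = 21,
    seed: int = 0,
) -> np.ndarray:
    """Recovered diary-interview Spearman rho, one value per simulated cohort.

    A fast vectorised rendering of the single-scale pipeline: person latent
    means -> AR(1) trajectories -> analogue item responses -> Likert -> scale
    and person means, correlated against rounded noisy interview ratings.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    rhos = np.empty(n_replicates)
    for rep in range(n_replicates):
        mus = np.clip(rng.normal(mu, tau, size=n_participants), 1.0, 6.5)
        # vectorised stationary AR(1): (participants x occasions)
        x = np.empty((n_participants, n_occasions))
        x[:, 0] = rng.normal(mus, sigma / math.sqrt(1 - phi * phi))
        for t in range(1, n_occasions):
            x[:, t] = mus + phi * (x[:, t - 1] - mus) + rng.normal(0, sigma, n_participants)
        frac = np.clip(
            squash_latent(x)[:, :, None] + rng.normal(0, sigma_item, (n_participants, n_occasions, k_items)),
            0.0,
            1.0,
        )
        likert = np.minimum(np.floor(frac * 7).astype(int) + 1, 7)
        diary_means = likert.mean(axis=(1, 2))
        interview = np.clip(np.round(mus + rng.normal(0, sigma_int, n_participants)), 1, 7)
        rhos[rep] = stats.spearmanr(diary_means, interview).statistic
    return rhos


def calibrate_interview_noise(
    target_rho: float,
    *,
    n_replicates: int = 40,
    seed: int = 0,
    lo: float = 1e-3,
    hi: float = 4.0,
    tol: float = 0.005,
    **experiment_kwargs,
) -> float:
    """Interview noise SD giving a target mean recovered Spearman rho.

    Bisection on ``sigma_int`` against the recovery experiment (the mean
    recovered rho is monotone decreasing in the interview noise).
    """
    if not 0 < target_rho < 1:
        raise ValueError("target_rho must lie in (0, 1)")

    def mean_rho(s: float) -> float:
        return float(
            np.mean(
                validity_recovery_experiment(
                    sigma_int=s, n_replicates=n_replicates, seed=seed, **experiment_kwargs
                )
            )
        )

    f_lo, f_hi = mean_rho(lo), mean_rho(hi)
    if not (f_hi < target_rho < f_lo):
        raise ValueError(
            f"target rho {target_rho} outside achievable range ({f_hi:.3f}, {f_lo:.3f})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_rho(mid) > target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
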