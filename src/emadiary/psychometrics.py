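"""Reliability, validity, instability and reactivity statistics.

Implements the analysis battery run on diary data: within-person instability
(mean squared successive difference and standard deviation over available
timepoints), internal consistency (Cronbach's alpha over pooled entries),
convergent validity (Spearman rank correlation between person-level diary
means and interview ratings), and the reactivity safety score, together with
the builders for the summary-table layouts the analyses are reported in.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .item_bank import ItemBank, ScaleDef
from .scoring import PersonSummary, score_entry_all
from .session_engine import REACTIVITY_ITEM_IDS, SessionEntry

__all__ = [
    "InstabilitySummary",
    "ReliabilityResult",
    "ValidityResult",
    "mssd",
    "within_person_sd",
    "cronbach_alpha",
    "spearman_rho",
    "compute_instability_summaries",
    "instability_table",
    "validity_table",
    "alpha_table",
    "reactivity_mean",
]

#: PANSS-style interview items are rated 1 (absent) to 7 (severe); the
#: depression-interview items used here are rated 1 to 4.
INTERVIEW_RANGES = {"PANSS": (1, 7), "CDS": (1, 4)}


@dataclass(frozen=True)
class InstabilitySummary:
    participant_id: str
    scale_id: str
    mssd: float
    sd: float
    n: int


@dataclass(frozen=True)
class ReliabilityResult:
    scale_id: str
    alpha: Optional[float]
    k: int
    n_rows: int


@dataclass(frozen=True)
class ValidityResult:
    scale_id: str
    rho: Optional[float]
    p: Optional[float]
    n: int
    flag: str = ""


# ---------------------------------------------------------------------------
# Core statistics


def mssd(series: Sequence[float]) -> Optional[float]:
    """Mean squared successive difference over available, time-ordered scores.

    Missing timepoints are simply dropped before differencing, so differences
    may span gaps (entries across days and non-sequential pairs included).
    Undefined (None) for fewer than two available scores.
    """
    x = np.asarray([v for v in series if v is not None and not np.isnan(v)], dtype=float)
    if x.size < 2:
        return None
    d = np.diff(x)
    return float(np.mean(d * d))


def within_person_sd(series: Sequence[float]) -> Optional[float]:
    """Sample standard deviation (n-1 denominator) over available scores."""
    x = np.asarray([v for v in series if v is not None and not np.isnan(v)], dtype=float)
    if x.size < 2:
        return None
    return float(np.std(x, ddof=1))


def cronbach_alpha(rows: np.ndarray | Sequence[Sequence[float]]) -> Optional[float]:
    """Cronbach's alpha over a (rows x items) score matrix, sample variances.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the row totals).
    Undefined (None) when the total-score variance is zero.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows and 2 item columns")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return None
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value over all orderings of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    *,
    method: str = "auto",
) -> tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation with average-rank ties.

    rho is the product-moment correlation of the rank vectors; the two-sided
    p-value uses the t-approximation with n-2 degrees of freedom, or an exact
    permutation distribution for small samples (``method="exact"``, the
    default resolution of ``"auto"`` below n = 10).  Undefined (None, None)
    when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    if method not in ("auto", "t", "exact"):
        raise ValueError(f"unknown method {method!r}")
    rho = float(stats.spearmanr(x, y).statistic)
    use_exact = method == "exact" or (method == "auto" and n < 10)
    if use_exact:
        return rho, float(_exact_spearman_p(x, y, rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# Table builders


def compute_instability_summaries(scores: pd.DataFrame) -> list[InstabilitySummary]:
    """Per-participant, per-scale MSSD and SD from a long score table.

    ``scores`` columns: participant_id, day, alarm_index, scale_id, value.
    Participants with fewer than two available timepoints on a scale are
    omitted (the metrics are undefined there).
    """
    out: list[InstabilitySummary] = []
    ordered = scores.sort_values(["participant_id", "scale_id", "alarm_index"])
    for (pid, sid), grp in ordered.groupby(["participant_id", "scale_id"], sort=True):
        series = grp["value"].tolist()
        m = mssd(series)
        s = within_person_sd(series)
        if m is None or s is None:
            continue
        out.append(InstabilitySummary(pid, sid, m, s, len(series)))
    return out


def instability_table(
    summaries: Iterable[InstabilitySummary],
    *,
    delusion_participants: Optional[set[str]] = None,
    scale_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Across-person mean (and SD) of the person-level MSSD and SD per scale.

    Delusion rows are restricted to participants who actually had delusion
    questions configured when ``delusion_participants`` is given.
    """
    rows = []
    for s in summaries:
        if (
            s.scale_id == "delusions"
            and delusion_participants is not None
            and s.participant_id not in delusion_participants
        ):
            continue
        rows.append((s.scale_id, s.mssd, s.sd))
    df = pd.DataFrame(rows, columns=["scale_id", "mssd", "sd"])
    if df.empty:
        return pd.DataFrame(
            columns=["scale_id", "mssd_mean", "mssd_sd", "sd_mean", "sd_sd", "n_participants"]
        )
    agg = df.groupby("scale_id").agg(
        mssd_mean=("mssd", "mean"),
        mssd_sd=("mssd", lambda v: v.std(ddof=1) if len(v) > 1 else float("nan")),
        sd_mean=("sd", "mean"),
        sd_sd=("sd", lambda v: v.std(ddof=1) if len(v) > 1 else float("nan")),
        n_participants=("mssd", "size"),
    )
    agg = agg.reset_index()
    if scale_order:
        order = {sid: i for i, sid in enumerate(scale_order)}
        agg = agg.sort_values("scale_id", key=lambda c: c.map(lambda v: order.get(v, len(order))))
    return agg.reset_index(drop=True)


def validity_table(
    summaries: Iterable[PersonSummary],
    interviews: pd.DataFrame,
    mapping: Mapping[str, str],
    *,
    occasion: str = "followup",
    min_endorsed: int = 3,
    method: str = "t",
) -> pd.DataFrame:
    """Diary-vs-interview convergent validity, one row per scale.

    ``interviews`` columns: participant_id, occasion, item_code, rating.
    Each scale's per-person diary means are correlated (Spearman) with its
    mapped interview item at the given occasion.  Scales endorsed (diary mean
    above the scale floor) by fewer than ``min_endorsed`` participants are
    excluded and flagged rather than analysed.  Defined rows are ordered by
    descending rho, mirroring the usual presentation "in order of strength".
    """
    if not mapping:
        raise ValueError("empty scale-to-interview mapping")
    summaries = list(summaries)
    iv = interviews[interviews["occasion"] == occasion]
    ratings: dict[str, dict[str, float]] = {}
    for code, grp in iv.groupby("item_code"):
        ratings[code] = dict(zip(grp["participant_id"], grp["rating"].astype(float)))

    results: list[ValidityResult] = []
    for scale_id, code in mapping.items():
        if code not in ratings:
            raise ValueError(f"no interview ratings for item code {code!r} (scale {scale_id!r})")
        pairs = [
            (s.scale_means[scale_id], ratings[code][s.participant_id])
            for s in summaries
            if scale_id in s.scale_means and s.participant_id in ratings[code]
        ]
        n = len(pairs)
        endorsed = sum(1 for d, _ in pairs if d > 1.0)
        if endorsed < min_endorsed:
            results.append(
                ValidityResult(scale_id, None, None, n, flag=f"endorsed by {endorsed} < {min_endorsed} participants")
            )
            continue
        if n < 4:
            results.append(ValidityResult(scale_id, None, None, n, flag="fewer than 4 pairs"))
            continue
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        rho, p = spearman_rho(x, y, method=method)
        if rho is None:
            results.append(ValidityResult(scale_id, None, None, n, flag="zero variance"))
        else:
            results.append(ValidityResult(scale_id, rho, p, n))

    defined = sorted((r for r in results if r.rho is not None), key=lambda r: -r.rho)
    flagged = [r for r in results if r.rho is None]
    return pd.DataFrame(
        [(r.scale_id, r.rho, r.p, r.n, r.flag) for r in defined + flagged],
        columns=["scale_id", "rho", "p", "n", "flag"],
    )


def _pooled_item_matrix(
    entries: Iterable[SessionEntry], scale: ScaleDef, bank_view: ItemBank
) -> np.ndarray:
    """Pooled (entries x items) matrix for one scale, complete rows only.

    For the delusions scale the matrix pools configured belief blocks by
    position (statement, preoccupation, distress, impact), so each block is
    one row: sub-items are parallel across templates.
    """
    rows: list[list[float]] = []
    if scale.scale_id == "delusions":
        for e in entries:
            if not e.completed or e.set != 2:
                continue
            block_ids = [it.item_id for it in bank_view.scale("delusions").items]
            for i in range(0, len(block_ids), 4):
                vals = [e.responses.get(iid) for iid in block_ids[i : i + 4]]
                if len(vals) == 4 and all(v is not None for v in vals):
                    rows.append([float(v) for v in vals])
        return np.asarray(rows, dtype=float)
    item_ids = [it.item_id for it in scale.items]
    for e in entries:
        if not e.completed or e.set != scale.set:
            continue
        vals = [e.responses.get(iid) for iid in item_ids]
        if all(v is not None for v in vals):
            rows.append([float(v) for v in vals])
    return np.asarray(rows, dtype=float)


def alpha_table(
    entries_by_participant: Mapping[str, Sequence[SessionEntry]],
    bank_views: Mapping[str, ItemBank],
) -> pd.DataFrame:
    """Cronbach's alpha per scale over pooled completed entries.

    Rows are entries pooled across participants and timepoints (listwise
    complete on the scale's items, so branched scales are assessed on the
    occasions where the full item set was triggered).
    """
    any_view = next(iter(bank_views.values()))
    rows = []
    for scale in any_view.scales:
        mats = []
        for pid, entries in entries_by_participant.items():
            view = bank_views[pid]
            sc = view.scale(scale.scale_id)
            m = _pooled_item_matrix(entries, sc, view)
            if m.size:
                mats.append(m)
        if not mats:
            rows.append((scale.scale_id, None, 0, 0))
            continue
        X = np.vstack(mats)
        k = X.shape[1]
        if k < 2 or X.shape[0] < 2:
            rows.append((scale.scale_id, None, k, X.shape[0]))
            continue
        rows.append((scale.scale_id, cronbach_alpha(X), k, X.shape[0]))
    return pd.DataFrame(rows, columns=["scale_id", "alpha", "k", "n_rows"])


def reactivity_mean(entries: Iterable[SessionEntry]) -> Optional[float]:
    """Mean of the two reactivity items over one participant's completed entries.

    The score is a magnitude: the items do not measure whether self-monitoring
    changed thoughts or mood for better or worse.
    """
    values: list[float] = []
    for e in entries:
        if not e.completed:
            continue
        for rid in REACTIVITY_ITEM_IDS:
            v = e.responses.get(rid)
            if v is not None:
                values.append(float(v))
    return sum(values) / len(values) if values else None
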