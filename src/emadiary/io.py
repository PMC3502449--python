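"""File formats: response logs, interview tables, schedules, report bundles.

CSV files are UTF-8, comma-separated with a header row and "." decimal; times
are HH:MM.  Undefined statistics are serialised as empty cells in CSV and as
null in JSON, never as 0.  Report CSVs round floats to 2 decimal places; the
JSON outputs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .item_bank import DelusionSelection, ItemBank, configure_delusions
from .scheduler import WeekSchedule
from .session_engine import REACTIVITY_ITEM_IDS, SessionEntry

__all__ = [
    "ResponseLogError",
    "read_response_log",
    "entries_from_log",
    "infer_bank_views",
    "write_schedule_csv",
    "write_reports",
    "read_interviews",
    "run_metadata",
]

LOG_COLUMNS = [
    "participant_id",
    "day",
    "alarm_index",
    "set",
    "item_id",
    "scale_id",
    "response_likert",
    "answered_at_hhmm",
    "status",
]


class ResponseLogError(ValueError):
    """Raised for malformed response-log files."""


def read_response_log(path: str | Path) -> pd.DataFrame:
    """Load and validate a response-log CSV (one row per item response)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str, "scale_id": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseLogError(f"response log missing columns: {missing}")
    completed = df[df["status"] == "completed"]
    bad = completed["response_likert"].astype(float)
    if ((bad < 1) | (bad > 7) | (bad != bad.round())).any():
        offenders = sorted(completed.loc[(bad < 1) | (bad > 7), "response_likert"].unique())
        raise ResponseLogError(f"illegal likert responses (must be integers 1..7): {offenders}")
    dup = completed.duplicated(subset=["participant_id", "day", "alarm_index", "item_id"])
    if dup.any():
        rows = completed.loc[dup, ["participant_id", "day", "alarm_index", "item_id"]]
        raise ResponseLogError(f"duplicate response rows:\n{rows.to_string(index=False)}")
    status_per_alarm = df.groupby(["participant_id", "day", "alarm_index"])["status"].nunique()
    if (status_per_alarm > 1).any():
        raise ResponseLogError("an alarm occasion mixes completed and missed rows")
    return df


def _hhmm_to_minutes(text: str) -> int | None:
    if not isinstance(text, str) or ":" not in text:
        return None
    h, m = text.split(":")
    return int(h) * 60 + int(m)


def entries_from_log(df: pd.DataFrame) -> dict[str, list[SessionEntry]]:
    """Reconstruct SessionEntry objects from a validated log frame."""
    out: dict[str, list[SessionEntry]] = {}
    for (pid, day, alarm), grp in df.groupby(["participant_id", "day", "alarm_index"], sort=True):
        status = grp["status"].iloc[0]
        set_no = int(grp["set"].iloc[0])
        if status == "completed":
            responses = {
                str(r.item_id): int(r.response_likert) for r in grp.itertuples(index=False)
            }
        else:
            responses = {}
        out.setdefault(str(pid), []).append(
            SessionEntry(
                participant_id=str(pid),
                day=int(day),
                alarm_index=int(alarm),
                set=set_no,
                responses=responses,
                status=status,
                answered_at=_hhmm_to_minutes(grp["answered_at_hhmm"].iloc[0]),
            )
        )
    for pid in out:
        out[pid].sort(key=lambda e: e.alarm_index)
    return out


def infer_bank_views(df: pd.DataFrame, bank: ItemBank) -> dict[str, ItemBank]:
    """Recover each participant's personalised bank from logged delusion items.

    Delusion item ids carry their template id as a ``<template>__<part>``
    prefix, so the per-participant selection can be reconstructed from the log.
    """
    views: dict[str, ItemBank] = {}
    delusion_rows = df[(df["scale_id"] == "delusions") & (df["status"] == "completed")]
    for pid in df["participant_id"].unique():
        ids = delusion_rows.loc[delusion_rows["participant_id"] == pid, "item_id"]
        templates = sorted({i.split("__")[0] for i in ids})
        selection = DelusionSelection(participant_id=str(pid), template_ids=tuple(templates))
        views[str(pid)] = configure_delusions(bank, selection)
    return views


def write_schedule_csv(
    schedules: Mapping[str, WeekSchedule], path: str | Path
) -> None:
    """Write alarm schedules: participant_id, day, alarm_index, time, expiry."""
    rows = []
    for pid in sorted(schedules):
        sched = schedules[pid]
        per_day = sched.config.prompts_per_day
        for i, alarm in enumerate(sched.alarms, start=1):
            rows.append(
                (
                    pid,
                    alarm.day_index,
                    (i - 1) % per_day + 1,
                    f"{alarm.time // 60:02d}:{alarm.time % 60:02d}",
                    f"{alarm.expiry // 60:02d}:{alarm.expiry % 60:02d}",
                )
            )
    pd.DataFrame(
        rows, columns=["participant_id", "day", "alarm_index", "time_hhmm", "expiry_hhmm"]
    ).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_reports(results: Mapping, out_dir: str | Path) -> dict[str, Path]:
    """Write table2.csv (sorted by descending rho), table3.csv, compliance.json.

    CSV floats are rounded to 2 dp; the JSON keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if "table2" in results:
        p = out / "table2.csv"
        results["table2"].to_csv(p, index=False, float_format="%.2f")
        paths["table2"] = p
    if "table3" in results:
        p = out / "table3.csv"
        results["table3"].to_csv(p, index=False, float_format="%.2f")
        paths["table3"] = p
    if "compliance" in results:
        p = out / "compliance.json"
        p.write_text(json.dumps(results["compliance"], indent=2, default=_json_default) + "\n")
        paths["compliance"] = p
    if "reactivity" in results:
        p = out / "reactivity.json"
        p.write_text(json.dumps(results["reactivity"], indent=2, default=_json_default) + "\n")
        paths["reactivity"] = p
    return paths


def read_interviews(path: str | Path) -> pd.DataFrame:
    """Load an interview table: participant_id, occasion, item_code, rating."""
    df = pd.read_csv(path, dtype={"participant_id": str, "occasion": str, "item_code": str})
    required = ["participant_id", "occasion", "item_code", "rating"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ResponseLogError(f"interview table missing columns: {missing}")
    rating = df["rating"].astype(float)
    limits = np.where(df["item_code"].str.startswith("CDS"), 4, 7)
    if ((rating < 1) | (rating > limits)).any():
        raise ResponseLogError("interview ratings outside their legal range")
    return df


def run_metadata(seed: int | None, config: Mapping | None = None) -> dict:
    """Reproducibility header: seed, canonical config hash, package version."""
    from . import __version__

    canonical = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "seed": seed,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "emadiary_version": __version__,
        "formats": {"csv": "utf-8, comma, header row, '.' decimal, HH:MM times"},
    }
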