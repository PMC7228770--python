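"""Trial classification from raw event streams and behavioral timing.

Button release time is the latency from the go cue to release of a start
button; movement time is the latency from release to target acquisition.
Outcomes are assigned by the first task rule violated in temporal order:
premature release (before the 200 ms post-go lock-out, or before the go cue
entirely), late release (after the 600 ms response window), reach timeout
(missing the 600 ms near / 1200 ms far deadline), and hold break (releasing
the target before 300 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import TaskConfig

__all__ = [
    "TrialRecord",
    "TimingSummary",
    "classify_trials",
    "records_to_frame",
    "compute_timing",
    "timing_summary",
    "percent_correct",
]

log = logging.getLogger(__name__)

OUTCOMES = ("correct", "premature", "late_release", "reach_timeout", "hold_break")


@dataclass
class TrialRecord:
    """One trial's condition, event timestamps (ms), and outcome."""

    trial_id: int
    distance: str = ""
    position: str = ""
    block: str = "main"
    fixation_onset: float = np.nan
    cue_on: float = np.nan
    cue_off: float = np.nan
    go: float = np.nan
    release: float = np.nan
    acquisition: float = np.nan
    hold_end: float = np.nan
    outcome: str = ""


def classify_trials(
    events: pd.DataFrame,
    config: TaskConfig,
    trial_info: pd.DataFrame | None = None,
) -> list[TrialRecord]:
    """Assign one outcome per trial from the raw sensor/LED event stream.

    ``events`` has columns (trial_id, event, time_ms). ``trial_info``
    optionally supplies condition columns (distance, position, block) keyed
    by trial_id; the far reach deadline is applied when distance == "far".
    Malformed trials (missing trial boundaries or cue) are excluded with a
    log entry, never silently dropped.
    """
    info = trial_info.set_index("trial_id") if trial_info is not None else None
    records: list[TrialRecord] = []
    for trial_id, grp in events.groupby("trial_id", sort=True):
        # ties broken by event-record order: keep the first occurrence
        t = grp.drop_duplicates("event").set_index("event")["time_ms"]
        if "trial_start" not in t.index or "trial_end" not in t.index:
            log.warning("trial %s excluded: missing boundary markers", trial_id)
            continue
        if "cue_on" not in t.index or "start_touch" not in t.index:
            log.warning("trial %s excluded: no fixation/cue events", trial_id)
            continue
        rec = TrialRecord(
            trial_id=int(trial_id),
            fixation_onset=t.get("start_touch", np.nan),
            cue_on=t.get("cue_on", np.nan),
            cue_off=t.get("cue_off", np.nan),
            go=t.get("go", np.nan),
            release=t.get("release", np.nan),
            acquisition=t.get("acquisition", np.nan),
            hold_end=t.get("hold_end", np.nan),
        )
        if info is not None and trial_id in info.index:
            row = info.loc[trial_id]
            rec.distance = row.get("distance", "")
            rec.position = row.get("position", "")
            rec.block = row.get("block", "main")
        rec.outcome = _classify_one(rec, config)
        records.append(rec)
    return records


def _classify_one(rec: TrialRecord, config: TaskConfig) -> str:
    go, release = rec.go, rec.release
    window_open = go + config.go_react_delay if not np.isnan(go) else np.nan
    if not np.isnan(release):
        if np.isnan(go) or release < window_open:
            return "premature"
        if release >= window_open + config.release_window:
            return "late_release"
    else:
        return "late_release"  # never released inside the window
    limit = config.reach_limit(rec.distance or "near")
    if np.isnan(rec.acquisition) or rec.acquisition - release > limit:
        return "reach_timeout"
    if np.isnan(rec.hold_end) or rec.hold_end - rec.acquisition < config.hold_duration:
        return "hold_break"
    return "correct"


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def compute_timing(trials: pd.DataFrame | list[TrialRecord]) -> pd.DataFrame:
    """Per-trial button release time and movement time (ms), correct trials.

    release_time = release - go; movement_time = acquisition - release.
    Trials with missing timestamps or non-positive latencies are excluded
    with a log entry.
    """
    df = records_to_frame(trials) if isinstance(trials, list) else trials
    df = df[df["outcome"] == "correct"].copy()
    rt = df["release"] - df["go"]
    mt = df["acquisition"] - df["release"]
    ok = rt.notna() & mt.notna() & (rt > 0) & (mt > 0)
    if (~ok).any():
        log.warning("%d trials excluded from timing (missing/non-positive)", int((~ok).sum()))
    out = df.loc[ok, ["trial_id", "distance", "position", "block"]].copy()
    out["release_time"] = rt[ok]
    out["movement_time"] = mt[ok]
    return out.reset_index(drop=True)


@dataclass
class TimingSummary:
    """Per-distance timing statistics and the near-vs-far Welch test."""

    groups: dict = field(default_factory=dict)  # distance -> {measure: (mean, sd, n)}
    tests: dict = field(default_factory=dict)  # measure -> (t, p)


def timing_summary(timing: pd.DataFrame) -> TimingSummary:
    """Mean/s.d./n per distance and a Welch two-sample t-test near vs far."""
    out = TimingSummary()
    for dist, grp in timing.groupby("distance"):
        out.groups[dist] = {
            m: (float(grp[m].mean()), float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0, len(grp))
            for m in ("release_time", "movement_time")
        }
    if {"near", "far"} <= set(out.groups):
        for m in ("release_time", "movement_time"):
            a = timing.loc[timing["distance"] == "near", m]
            b = timing.loc[timing["distance"] == "far", m]
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                out.tests[m] = (0.0, 1.0)  # identical constant groups
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                out.tests[m] = (float(t), float(p))
    return out


def percent_correct(trials: pd.DataFrame | list[TrialRecord]) -> float:
    """Fraction of initiated trials performed correctly."""
    df = records_to_frame(trials) if isinstance(trials, list) else trials
    return float((df["outcome"] == "correct").mean())
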