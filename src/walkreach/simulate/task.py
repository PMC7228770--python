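"""Synthetic task-event generator.

Produces a trial table and a raw event stream for the memory-guided
walk-and-reach task with configurable error-mode probabilities. All
timestamps are integer milliseconds on one session clock; identical seeds
give identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import DISTANCES, POSITIONS, CageGeometry, MovementTiming, TaskConfig, substream

__all__ = ["ERROR_MODES", "generate_task_trials"]

ERROR_MODES = ("premature", "late_release", "reach_timeout", "hold_break")

TRIAL_COLUMNS = [
    "trial_id",
    "distance",
    "position",
    "target_x",
    "target_y",
    "target_z",
    "block",
    "fixation_onset",
    "cue_on",
    "cue_off",
    "go",
    "release",
    "acquisition",
    "hold_end",
    "outcome",
]


def _uniform_ms(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Integer draw from the closed interval [lo, hi]."""
    return int(rng.integers(lo, hi + 1))


def generate_task_trials(
    config: TaskConfig,
    geometry: CageGeometry,
    n_trials: int,
    error_rates: dict[str, float] | None = None,
    seed: int = 0,
    movement: MovementTiming = MovementTiming(),
    block: str = "main",
    t_start: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_trials`` trials and return (trial table, event stream).

    ``error_rates`` maps error modes (:data:`ERROR_MODES`) to probabilities;
    the remainder is the correct-trial probability. Conditions are drawn
    uniformly over the 8 targets. Event rows are (trial_id, event, time_ms).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    error_rates = dict(error_rates or {})
    unknown = set(error_rates) - set(ERROR_MODES)
    if unknown:
        raise ValueError(f"unknown error modes: {sorted(unknown)}")
    probs = np.array([error_rates.get(m, 0.0) for m in ERROR_MODES], dtype=float)
    if (probs < 0).any() or probs.sum() > 1.0 + 1e-12:
        raise ValueError("error-mode probabilities must be >= 0 and sum to <= 1")

    rng = substream(seed, "task")
    outcomes = rng.choice(
        np.array(["correct", *ERROR_MODES]),
        size=n_trials,
        p=np.concatenate([[1.0 - probs.sum()], probs]),
    )
    conditions = rng.integers(0, 8, size=n_trials)  # uniform over 8 targets

    trials: list[dict] = []
    events: list[tuple[int, str, int]] = []
    t = int(t_start)
    for i in range(n_trials):
        distance = DISTANCES[conditions[i] // 4]
        position = POSITIONS[conditions[i] % 4]
        target = geometry.target(distance, position)
        outcome = str(outcomes[i])

        trial_start = t + _uniform_ms(rng, 500, 1500)
        fixation_onset = trial_start + _uniform_ms(rng, 100, 500)  # start-button touch
        cue_on = fixation_onset + _uniform_ms(rng, *config.fixation_duration_range)
        cue_off = cue_on + config.cue_duration
        go = cue_off + _uniform_ms(rng, *config.memory_duration_range)

        rec: dict = dict(
            trial_id=i,
            distance=distance,
            position=position,
            target_x=target[0],
            target_y=target[1],
            target_z=target[2],
            block=block,
            fixation_onset=fixation_onset,
            cue_on=cue_on,
            cue_off=cue_off,
            go=go,
            release=np.nan,
            acquisition=np.nan,
            hold_end=np.nan,
            outcome=outcome,
        )
        ev = [
            (i, "trial_start", trial_start),
            (i, "start_touch", fixation_onset),
            (i, "cue_on", cue_on),
            (i, "cue_off", cue_off),
        ]
        limit = config.reach_limit(distance)
        mean_dur = movement.near_mean if distance == "near" else movement.far_mean

        def draw_release() -> int:
            # reaction inside the valid window [go+delay, go+delay+window)
            return go + config.go_react_delay + _uniform_ms(rng, 0, config.release_window - 1)

        def draw_duration() -> int:
            d = rng.normal(mean_dur, movement.sd)
            return int(np.clip(round(d), 50, limit - 1))

        if outcome == "premature":
            # half the premature releases happen during the memory period
            # (before the go cue is ever shown), half inside the 200 ms
            # anticipation lock-out after the go cue
            if rng.random() < 0.5 and go - cue_off > 1:
                release = cue_off + _uniform_ms(rng, 0, go - cue_off - 1)
                rec["go"] = np.nan
                ev.append((i, "release", release))
            else:
                release = go + _uniform_ms(rng, 0, config.go_react_delay - 1)
                ev.append((i, "go", go))
                ev.append((i, "release", release))
            rec["release"] = release
            end = release + _uniform_ms(rng, 200, 600)
        elif outcome == "late_release":
            release = (
                go + config.go_react_delay + config.release_window + _uniform_ms(rng, 1, 400)
            )
            rec["release"] = release
            ev += [(i, "go", go), (i, "release", release)]
            end = release + _uniform_ms(rng, 200, 600)
        elif outcome == "reach_timeout":
            release = draw_release()
            rec["release"] = release
            ev += [(i, "go", go), (i, "release", release)]
            end = release + limit  # deadline passes without a target touch
        elif outcome == "hold_break":
            release = draw_release()
            acquisition = release + draw_duration()
            hold_end = acquisition + _uniform_ms(rng, 30, config.hold_duration - 1)
            rec.update(release=release, acquisition=acquisition, hold_end=hold_end)
            ev += [
                (i, "go", go),
                (i, "release", release),
                (i, "acquisition", acquisition),
                (i, "hold_end", hold_end),
            ]
            end = hold_end
        else:  # correct
            release = draw_release()
            acquisition = release + draw_duration()
            hold_end = acquisition + config.hold_duration
            rec.update(release=release, acquisition=acquisition, hold_end=hold_end)
            ev += [
                (i, "go", go),
                (i, "release", release),
                (i, "acquisition", acquisition),
                (i, "hold_end", hold_end),
                (i, "reward", hold_end),
            ]
            end = hold_end
        ev.append((i, "trial_end", end + _uniform_ms(rng, 100, 300)))
        events.extend(ev)
        trials.append(rec)
        t = ev[-1][2]

    trial_table = pd.DataFrame(trials, columns=TRIAL_COLUMNS)
    event_stream = pd.DataFrame(events, columns=["trial_id", "event", "time_ms"])
    return trial_table, event_stream
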