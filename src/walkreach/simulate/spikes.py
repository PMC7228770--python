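"""Direction-tuned inhomogeneous-Poisson spike generator.

Each unit has a baseline rate, multiplicative epoch gains (baseline / memory
/ movement), and an additive direction term of +/- depth/2 depending on
whether the trial's target is on the unit's preferred side. Rates are
piecewise constant over task epochs, so spike counts in any fixed window are
Poisson with the specified mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import substream

__all__ = ["TuningSpec", "generate_population_spikes", "build_population"]

log = logging.getLogger(__name__)

SPIKE_COLUMNS = ["unit", "area", "trial_id", "time_ms"]


@dataclass(frozen=True)
class TuningSpec:
    """Rate model of one unit (spikes/s)."""

    unit: str
    area: str = "M1"  # M1 | PMd | PRR
    baseline: float = 10.0
    gain_baseline: float = 1.0
    gain_memory: float = 1.0
    gain_movement: float = 1.0
    preference: str = "none"  # left | right | none
    depth_memory: float = 0.0
    depth_movement: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.depth_memory < 0 or self.depth_movement < 0:
            raise ValueError("rates and modulation depths must be >= 0")
        if self.preference not in ("left", "right", "none"):
            raise ValueError("preference must be left, right, or none")


def _epoch_windows(tr: pd.Series) -> list[tuple[str, float, float]]:
    """(epoch, t0, t1) windows in ms covering the trial, piecewise constant."""
    wins = [("baseline", tr["fixation_onset"] - 500.0, tr["cue_off"])]
    go = tr["go"] if not np.isnan(tr["go"]) else tr["cue_off"]
    wins.append(("memory", tr["cue_off"], go))
    rel = tr["release"] if not np.isnan(tr["release"]) else go
    wins.append(("baseline2", go, rel))
    if not np.isnan(tr["acquisition"]):
        wins.append(("movement", rel, tr["acquisition"]))
        end = tr["hold_end"] if not np.isnan(tr["hold_end"]) else tr["acquisition"]
        wins.append(("hold", tr["acquisition"], end + 500.0))
    return wins


def _rate(spec: TuningSpec, epoch: str, side: str) -> float:
    if epoch == "memory":
        gain, depth = spec.gain_memory, spec.depth_memory
    elif epoch == "movement":
        gain, depth = spec.gain_movement, spec.depth_movement
    else:
        gain, depth = spec.gain_baseline, 0.0
    rate = spec.baseline * gain
    if spec.preference != "none" and depth:
        rate += depth / 2.0 if side == spec.preference else -depth / 2.0
    if rate < 0:
        log.info("unit %s: negative rate clipped to 0 in epoch %s", spec.unit, epoch)
        rate = 0.0
    return rate


def generate_population_spikes(
    trials: pd.DataFrame,
    tuning: list[TuningSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate spike times (session-clock ms) for every unit and trial.

    Returns a tidy table (unit, area, trial_id, time_ms), sorted by time
    within unit and trial.
    """
    rng = substream(seed, "spikes")
    sides = np.where(trials["position"].str.contains("left"), "left", "right")
    rows_unit, rows_area, rows_trial, rows_time = [], [], [], []
    for spec in tuning:
        for (_, tr), side in zip(trials.iterrows(), sides):
            for epoch, t0, t1 in _epoch_windows(tr):
                dur_s = max(t1 - t0, 0.0) / 1000.0
                lam = _rate(spec, epoch, side) * dur_s
                if lam <= 0:
                    continue
                n = rng.poisson(lam)
                if n == 0:
                    continue
                times = np.sort(rng.uniform(t0, t1, size=n))
                rows_unit.append(np.full(n, spec.unit, object))
                rows_area.append(np.full(n, spec.area, object))
                rows_trial.append(np.full(n, tr["trial_id"], int))
                rows_time.append(times)
    if not rows_time:
        return pd.DataFrame(columns=SPIKE_COLUMNS)
    return pd.DataFrame(
        {
            "unit": np.concatenate(rows_unit),
            "area": np.concatenate(rows_area),
            "trial_id": np.concatenate(rows_trial),
            "time_ms": np.concatenate(rows_time),
        }
    )


def build_population(
    n_per_area: int = 16,
    baseline: float = 15.0,
    memory_depth_pmd_prr: float = 8.0,
    memory_depth_m1: float = 0.0,
    movement_depth: float = 8.0,
    memory_gain: float = 1.5,
    movement_gain: float = 2.0,
    seed: int = 0,
) -> list[TuningSpec]:
    """Standard synthetic population: direction tuning in the memory epoch in
    premotor (PMd) and parietal (PRR) units only, and in the movement epoch in
    all three areas. Preferences alternate left/right within each area."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    specs = []
    for area in ("M1", "PMd", "PRR"):
        mem_depth = memory_depth_m1 if area == "M1" else memory_depth_pmd_prr
        for i in range(n_per_area):
            specs.append(
                TuningSpec(
                    unit=f"{area}_{i:02d}",
                    area=area,
                    baseline=float(baseline * rng.uniform(0.7, 1.3)),
                    gain_memory=memory_gain,
                    gain_movement=movement_gain,
                    preference="left" if i % 2 == 0 else "right",
                    depth_memory=mem_depth,
                    depth_movement=movement_depth,
                )
            )
    return specs
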