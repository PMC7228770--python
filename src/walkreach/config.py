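"""Task, cage, and random-stream configuration.

Coordinate frame (mm): ``x`` is the target axis (left negative, right
positive), ``y`` the walk axis pointing from the start buttons toward the far
targets, ``z`` vertical (floor at 0). The start-button midpoint is the origin.

The defaults encode the study conditions of the memory-guided walk-and-reach
paradigm: a variable fixation period, a 400 ms target cue, a variable memory
period, a reaction window opening 200 ms after the go cue, and distance
dependent reach deadlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "MovementTiming",
    "CageGeometry",
    "POSITIONS",
    "DISTANCES",
    "BODY_PARTS",
    "substream",
]

#: canonical left-to-right target position labels
POSITIONS = ("outer-left", "mid-left", "mid-right", "outer-right")
DISTANCES = ("near", "far")
BODY_PARTS = ("wrist", "elbow", "shoulder", "headcap")

# fixed identifiers for named random substreams; appending new names never
# perturbs the draws of existing generators
_STREAMS = {
    "task": 0,
    "kinematics": 1,
    "cameras": 2,
    "spikes": 3,
    "broadband": 4,
    "dropout": 5,
    "stats": 6,
    "folds": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named random substream for a root seed.

    Each generator in the simulation owns one substream so that adding or
    reordering generators leaves every other stream untouched.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass(frozen=True)
class TaskConfig:
    """Timing rules of the memory-guided walk-and-reach task (ms)."""

    fixation_duration_range: tuple[int, int] = (400, 800)
    cue_duration: int = 400
    memory_duration_range: tuple[int, int] = (400, 2000)
    go_react_delay: int = 200
    release_window: int = 600
    reach_time_limit_near: int = 600
    reach_time_limit_far: int = 1200
    hold_duration: int = 300
    n_targets: int = 8

    def __post_init__(self) -> None:
        lo, hi = self.fixation_duration_range
        mlo, mhi = self.memory_duration_range
        if not (0 < lo <= hi):
            raise ValueError("fixation duration range must be positive and ordered")
        if not (0 <= mlo <= mhi):
            raise ValueError("memory duration range must be non-negative and ordered")
        for name in (
            "cue_duration",
            "go_react_delay",
            "release_window",
            "reach_time_limit_near",
            "reach_time_limit_far",
            "hold_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_targets != 8:
            raise ValueError("task uses 8 targets (2 distances x 4 positions)")

    def reach_limit(self, distance: str) -> int:
        return self.reach_time_limit_near if distance == "near" else self.reach_time_limit_far


@dataclass(frozen=True)
class MovementTiming:
    """Movement-duration model for generated trials (ms).

    Plausible-scale configuration constants for a fast near reach and a
    longer walk-and-reach; not measured quantities.
    """

    near_mean: float = 400.0
    far_mean: float = 900.0
    sd: float = 40.0


@dataclass(frozen=True)
class CageGeometry:
    """Cage layout: start buttons plus two rows of four targets.

    Near targets sit 100 mm along the walk axis and 600 mm above the start
    buttons at ~130 mm center-to-center spacing; far targets sit 1000 mm away
    at ~210 mm spacing. A removable passage with a 310 mm opening can
    constrain the walk path.
    """

    start_positions: np.ndarray = field(
        default_factory=lambda: np.array([[-80.0, 0.0, 0.0], [80.0, 0.0, 0.0]])
    )
    near_offset: tuple[float, float] = (100.0, 600.0)  # (walk, vertical) mm
    far_offset: tuple[float, float] = (1000.0, 600.0)
    near_spacing: float = 130.0
    far_spacing: float = 210.0
    passage_opening_width: float = 310.0
    # closed bounding box used by the cleaning pipeline, W x D x H 1320x740x750
    bbox_min: np.ndarray = field(
        default_factory=lambda: np.array([-370.0, -160.0, -50.0])
    )
    bbox_max: np.ndarray = field(
        default_factory=lambda: np.array([370.0, 1160.0, 700.0])
    )

    @property
    def near_targets(self) -> np.ndarray:
        """4x3 near-target centers, ordered left to right."""
        return self._row(*self.near_offset, self.near_spacing)

    @property
    def far_targets(self) -> np.ndarray:
        return self._row(*self.far_offset, self.far_spacing)

    @staticmethod
    def _row(walk: float, height: float, spacing: float) -> np.ndarray:
        xs = (np.arange(4) - 1.5) * spacing
        out = np.zeros((4, 3))
        out[:, 0] = xs
        out[:, 1] = walk
        out[:, 2] = height
        return out

    def target(self, distance: str, position: str) -> np.ndarray:
        row = self.near_targets if distance == "near" else self.far_targets
        return row[POSITIONS.index(position)]
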