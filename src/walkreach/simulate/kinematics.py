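"""Ground-truth kinematics generator.

The wrist follows a minimum-jerk path from its start button to the trial's
target between the release and acquisition events, sampled at 60 Hz. The
other body parts (elbow, shoulder, headcap) ride along as affine-offset
copies of the wrist path; on far trials their endpoint offsets keep them near
the body as it translates toward the far target row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import BODY_PARTS, CageGeometry, substream
from ..containers import Trajectory3D

__all__ = ["KinematicsParams", "minimum_jerk", "generate_kinematics"]

log = logging.getLogger(__name__)

# start / endpoint offsets of the passive body parts relative to the wrist
# path (mm); plausible resting-arm geometry, not measured values
_START_OFFSETS = {
    "wrist": (0.0, 0.0, 0.0),
    "elbow": (40.0, -60.0, 150.0),
    "shoulder": (70.0, -120.0, 380.0),
    "headcap": (90.0, -130.0, 560.0),
}
_END_OFFSETS = {
    "wrist": (0.0, 0.0, 0.0),
    "elbow": (20.0, -110.0, -80.0),
    "shoulder": (40.0, -230.0, -150.0),
    "headcap": (60.0, -210.0, -30.0),
}


@dataclass(frozen=True)
class KinematicsParams:
    """Noise and sampling settings for generated trajectories.

    Path noise is temporally smoothed (7-frame Hann kernel, renormalized to
    keep the per-frame marginal s.d.) because tracking jitter and postural
    sway are band-limited, not white at the 60 Hz frame rate.
    """

    fps: float = 60.0
    path_noise_sd: float = 3.0  # mm, isotropic per-frame jitter
    endpoint_sd: float = 5.0  # mm, trial-to-trial endpoint scatter
    start_index: int = 0  # which start button the tracked wrist rests on
    body_parts: tuple[str, ...] = BODY_PARTS


def smooth_noise(raw: np.ndarray) -> np.ndarray:
    """Band-limit frame noise with a unit-power 7-frame Hann kernel."""
    w = np.hanning(9)[1:-1]
    w = w / np.sqrt((w**2).sum())
    return np.column_stack(
        [np.convolve(raw[:, d], w, mode="same") for d in range(raw.shape[1])]
    )


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1]; peak speed at tau=0.5."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_kinematics(
    trials: pd.DataFrame,
    geometry: CageGeometry,
    params: KinematicsParams = KinematicsParams(),
    seed: int = 0,
) -> dict[int, dict[str, Trajectory3D]]:
    """Generate ground-truth trajectories for every trial with full timing.

    Returns ``{trial_id: {body_part: Trajectory3D}}``. Trials missing release
    or acquisition timestamps are skipped with a log entry. Frames cover
    fixation onset through hold end on the shared session clock (frame =
    round(t * fps / 1000)).
    """
    rng = substream(seed, "kinematics")
    out: dict[int, dict[str, Trajectory3D]] = {}
    for _, tr in trials.iterrows():
        if np.isnan(tr["release"]) or np.isnan(tr["acquisition"]):
            log.info("trial %s skipped: missing release/acquisition", tr["trial_id"])
            continue
        f0 = int(np.ceil(tr["fixation_onset"] * params.fps / 1000.0))
        f1 = int(np.floor(tr["hold_end"] * params.fps / 1000.0)) if not np.isnan(
            tr["hold_end"]
        ) else int(np.floor(tr["acquisition"] * params.fps / 1000.0))
        frames = np.arange(f0, f1 + 1)
        t_ms = frames / params.fps * 1000.0
        tau = (t_ms - tr["release"]) / (tr["acquisition"] - tr["release"])
        s = minimum_jerk(tau)

        start_w = geometry.start_positions[params.start_index]
        target = np.array([tr["target_x"], tr["target_y"], tr["target_z"]])
        endpoint = target + rng.normal(0.0, params.endpoint_sd, size=3)

        parts: dict[str, Trajectory3D] = {}
        for bp in params.body_parts:
            a = start_w + np.array(_START_OFFSETS[bp])
            b = endpoint + np.array(_END_OFFSETS[bp])
            path = a[None, :] + s[:, None] * (b - a)[None, :]
            if params.path_noise_sd > 0:
                path = path + smooth_noise(
                    rng.normal(0.0, params.path_noise_sd, size=path.shape)
                )
            parts[bp] = Trajectory3D.from_xyz(frames, path, fps=params.fps)
        out[int(tr["trial_id"])] = parts
    return out
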