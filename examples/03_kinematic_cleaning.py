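"""Reconstruct and clean 3D wrist trajectories from 4-camera 2D tracks.

Projects ground-truth minimum-jerk trajectories through calibrated pinhole
cameras with detection noise, misses (likelihood < 0.9), and displaced
outliers, then runs the cleaning chain: likelihood gate -> triangulation ->
50 px reprojection filter -> cage bounding box -> iterative speed-outlier
rejection -> shape-preserving cubic gap filling.
"""

import numpy as np

from walkreach import kinematics as km
from walkreach.config import CageGeometry, TaskConfig
from walkreach.simulate import (
    KinematicsParams,
    default_cameras,
    generate_kinematics,
    generate_task_trials,
    project_to_cameras,
)

geometry = CageGeometry()
trials, _ = generate_task_trials(TaskConfig(), geometry, 12, seed=3)
truth = generate_kinematics(trials, geometry, KinematicsParams(), seed=4)
cameras = default_cameras()

tid, parts = next(iter(truth.items()))
row = trials[trials["trial_id"] == tid].iloc[0]
tracks = project_to_cameras(
    parts, cameras, pixel_noise_sd=1.0, miss_rate=0.05, outlier_rate=0.05, seed=5
)


def movement_mask(frames):
    t = frames / 60.0 * 1000.0
    return (t >= row["release"]) & (t <= row["acquisition"])


traj = km.clean_pipeline(tracks, cameras, "wrist", movement_mask, geometry=geometry)
err = np.linalg.norm(traj.xyz[traj.valid] - parts["wrist"].xyz[traj.valid], axis=1)
print(f"trial {tid} ({row['distance']} {row['position']}):")
print(f"  valid fraction after cleaning: {traj.valid_fraction():.3f}")
print("  rejection breakdown:", {k: v for k, v in traj.reason_counts().items() if v})
print(f"  median 3D error vs ground truth: {np.median(err):.2f} mm")

# Contaminated detections are caught by the reprojection and speed filters;
# the surviving reconstruction tracks the true wrist path to a few mm.
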