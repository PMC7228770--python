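"""Pinhole-camera projection of 3D trajectories into per-camera 2D tracks.

Emulates markerless-tracking output: pixel coordinates with a likelihood per
detection, occasional low-likelihood misses, and rare high-likelihood
outliers displaced by >= 100 px. Ground-truth contamination flags are kept so
downstream cleaning stages can be scored exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import substream
from ..containers import CameraModel, Trajectory3D

__all__ = ["default_cameras", "look_at", "project_to_cameras"]

TRACK_COLUMNS = ["frame", "bodypart", "x", "y", "likelihood", "gt_flag"]


def look_at(center: np.ndarray, eye: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World->camera rotation and translation for a camera at ``eye`` looking
    at ``center`` with the world z axis kept roughly up in the image."""
    z = np.asarray(center, float) - np.asarray(eye, float)
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    t = -R @ np.asarray(eye, float)
    return R, t


def default_cameras(
    focal_px: float = 700.0, image_size: tuple[int, int] = (640, 480)
) -> list[CameraModel]:
    """Four calibrated VGA cameras viewing the cage from different angles."""
    w, h = image_size
    K = np.array([[focal_px, 0.0, w / 2], [0.0, focal_px, h / 2], [0.0, 0.0, 1.0]])
    center = np.array([0.0, 500.0, 350.0])
    eyes = [
        np.array([2100.0, 500.0, 800.0]),  # side view, target axis
        np.array([-2100.0, 500.0, 800.0]),
        np.array([800.0, -1500.0, 1000.0]),  # oblique front/back views
        np.array([-800.0, 2600.0, 1000.0]),
    ]
    cams = []
    for i, eye in enumerate(eyes):
        R, t = look_at(center, eye)
        cams.append(CameraModel(f"cam{i}", K, R, t, image_size))
    return cams


def project_to_cameras(
    trajectories: dict[str, Trajectory3D],
    cameras: list[CameraModel],
    pixel_noise_sd: float = 0.0,
    miss_rate: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Project body-part trajectories through each camera.

    Returns one DataFrame per camera with columns frame, bodypart, x, y,
    likelihood, gt_flag in {"ok", "miss", "outlier", "behind"}. Misses get a
    likelihood drawn below 0.9; outliers are displaced by 100-300 px but keep
    a high likelihood. Points behind a camera are emitted with likelihood 0.
    """
    if len(cameras) < 2:
        raise ValueError("at least two cameras are required for 3D reconstruction")
    rng = substream(seed, "cameras")
    out: dict[str, pd.DataFrame] = {}
    for cam in cameras:
        rows = []
        for bp, traj in trajectories.items():
            px, in_front = cam.project(traj.xyz)
            n = len(traj.frames)
            noise = rng.normal(0.0, pixel_noise_sd, size=(n, 2)) if pixel_noise_sd else 0.0
            px = px + noise
            u = rng.random(n)
            is_miss = u < miss_rate
            is_outlier = (~is_miss) & (u < miss_rate + outlier_rate)
            likelihood = rng.uniform(0.95, 1.0, size=n)
            likelihood[is_miss] = rng.uniform(0.0, 0.9, size=int(is_miss.sum()))
            # outliers: large displacement in a random direction, confident score
            ang = rng.uniform(0.0, 2 * np.pi, size=int(is_outlier.sum()))
            mag = rng.uniform(100.0, 300.0, size=int(is_outlier.sum()))
            px[is_outlier, 0] += mag * np.cos(ang)
            px[is_outlier, 1] += mag * np.sin(ang)
            flag = np.full(n, "ok", object)
            flag[is_miss] = "miss"
            flag[is_outlier] = "outlier"
            flag[~in_front] = "behind"
            likelihood[~in_front] = 0.0
            px[~in_front] = np.nan
            rows.append(
                pd.DataFrame(
                    {
                        "frame": traj.frames,
                        "bodypart": bp,
                        "x": px[:, 0],
                        "y": px[:, 1],
                        "likelihood": likelihood,
                        "gt_flag": flag,
                    }
                )
            )
        out[cam.name] = pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]
    return out
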