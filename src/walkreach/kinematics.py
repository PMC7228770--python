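"""3D trajectory reconstruction and cleaning from multi-camera 2D tracks.

The pipeline mirrors standard markerless motion-capture post-processing:
likelihood gating of 2D detections (>= 0.9 kept), least-squares triangulation
from at least two views, rejection of points with reprojection error above
50 px on any camera, a closed 1320 x 740 x 750 mm bounding box, iterative
speed-discontinuity rejection (removing the first and every second outlier
per pass until all inter-frame displacements are below threshold), and
shape-preserving cubic interpolation of interior gaps. Alignment, trial
averaging, trajectory variability, and the passage-control spread analysis
operate on the cleaned trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .config import CageGeometry
from .containers import CameraModel, Trajectory3D

__all__ = [
    "SpeedThresholds",
    "filter_likelihood",
    "triangulate",
    "triangulate_point",
    "filter_reprojection",
    "filter_bounding_box",
    "reject_speed_outliers",
    "interpolate_gaps",
    "clean_pipeline",
    "align_trials",
    "trial_average",
    "variability",
    "passage_spread",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeedThresholds:
    """Inter-frame displacement limits (mm/frame): (outside, during) movement."""

    wrist: tuple[float, float] = (12.0, 80.0)
    other: tuple[float, float] = (15.0, 40.0)

    def __post_init__(self) -> None:
        for pair in (self.wrist, self.other):
            if pair[1] < pair[0]:
                raise ValueError("movement threshold must be >= non-movement threshold")

    def for_part(self, bodypart: str) -> tuple[float, float]:
        return self.wrist if bodypart == "wrist" else self.other


# ---------------------------------------------------------------------------
# 2D gating and triangulation


def filter_likelihood(tracks: dict[str, pd.DataFrame], threshold: float = 0.9) -> dict[str, pd.DataFrame]:
    """Mark 2D detections with likelihood below ``threshold`` invalid.

    Boundary kept: likelihood == threshold survives. Returns copies with a
    boolean ``valid`` column (intersected with any existing one).
    """
    out = {}
    for cam, df in tracks.items():
        df = df.copy()
        base = df["valid"] if "valid" in df else pd.Series(True, index=df.index)
        df["valid"] = base & (df["likelihood"] >= threshold) & df["x"].notna()
        out[cam] = df
    return out


def triangulate_point(
    obs: dict[str, np.ndarray], cameras: dict[str, CameraModel]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Least-squares 3D point from >= 2 pixel observations.

    Linear DLT solution refined by nonlinear least squares on the stacked
    reprojection residuals. Returns (xyz, per-camera reprojection error in
    px) or None for degenerate geometry.
    """
    names = list(obs)
    if len(names) < 2:
        return None
    rows = []
    for name in names:
        P = cameras[name].projection
        u, v = obs[name]
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    A = np.vstack(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:  # parallel-ray / degenerate configuration
        return None
    X = vt[-1]
    if abs(X[3]) < 1e-15:
        return None
    x0 = X[:3] / X[3]

    def residuals(x: np.ndarray) -> np.ndarray:
        r = []
        for name in names:
            px, front = cameras[name].project(x)
            if not front[0]:
                r.extend([1e6, 1e6])
            else:
                r.extend(px[0] - obs[name])
        return np.asarray(r)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    res = sol.fun.reshape(-1, 2)
    per_cam = np.linalg.norm(res, axis=1)
    return sol.x, per_cam


def triangulate(
    tracks: dict[str, pd.DataFrame],
    cameras: list[CameraModel],
    bodypart: str,
    fps: float = 60.0,
) -> Trajectory3D:
    """Triangulate one body part frame-by-frame from valid 2D detections.

    Frames with fewer than two valid views are invalid with reason
    ``too_few_views``. Per-point reprojection errors (px, one per camera in
    input order; NaN where a camera did not contribute) are attached.
    """
    cam_by_name = {c.name: c for c in cameras}
    cam_order = [c.name for c in cameras]
    per_cam: dict[str, pd.DataFrame] = {}
    frames: set[int] = set()
    for name, df in tracks.items():
        sel = df[df["bodypart"] == bodypart]
        per_cam[name] = sel.set_index("frame")
        frames |= set(sel["frame"].tolist())
    frame_idx = np.array(sorted(frames), dtype=int)
    n = len(frame_idx)
    xyz = np.full((n, 3), np.nan)
    valid = np.zeros(n, bool)
    reason = np.full(n, "too_few_views", object)
    errs = np.full((n, len(cameras)), np.nan)
    for i, f in enumerate(frame_idx):
        obs = {}
        for name in cam_order:
            df = per_cam.get(name)
            if df is None or f not in df.index:
                continue
            row = df.loc[f]
            if bool(row["valid"]) and np.isfinite(row["x"]):
                obs[name] = np.array([row["x"], row["y"]])
        result = triangulate_point(obs, cam_by_name) if len(obs) >= 2 else None
        if result is None:
            continue
        xyz[i] = result[0]
        valid[i] = True
        reason[i] = "none"
        for j, name in enumerate(cam_order):
            if name in obs:
                errs[i, j] = result[1][list(obs).index(name)]
    traj = Trajectory3D(frame_idx, xyz, valid, reason, fps)
    traj.reproj_err = errs
    return traj


# ---------------------------------------------------------------------------
# outlier filters


def filter_reprojection(traj: Trajectory3D, threshold: float = 50.0) -> Trajectory3D:
    """Invalidate points whose reprojection error exceeds ``threshold`` px on
    at least one contributing camera."""
    out = traj.copy()
    if out.reproj_err is None:
        return out
    has_err = np.isfinite(out.reproj_err).any(axis=1)
    bad = np.zeros(len(out.frames), bool)
    bad[has_err] = np.nanmax(out.reproj_err[has_err], axis=1) > threshold
    out.reject(bad & out.valid, "reprojection")
    return out


def filter_bounding_box(traj: Trajectory3D, geometry: CageGeometry | None = None,
                        box: tuple[np.ndarray, np.ndarray] | None = None) -> Trajectory3D:
    """Invalidate points strictly outside the closed cage bounding box."""
    if box is None:
        geometry = geometry or CageGeometry()
        box = (geometry.bbox_min, geometry.bbox_max)
    lo, hi = box
    out = traj.copy()
    with np.errstate(invalid="ignore"):
        outside = ((out.xyz < lo) | (out.xyz > hi)).any(axis=1)
    out.reject(outside & out.valid, "bbox")
    return out


def reject_speed_outliers(
    traj: Trajectory3D,
    thresholds: tuple[float, float],
    movement_mask: np.ndarray,
) -> Trajectory3D:
    """Iteratively remove discontinuity outliers from a trajectory.

    Each pass computes Euclidean displacement rates between consecutive
    currently valid samples (distance divided by the frame gap, so the
    mm/frame thresholds apply across gaps left by earlier rejections); a
    rate exceeding the applicable threshold (the movement threshold when the
    later frame lies between release and acquisition, the non-movement
    threshold otherwise) flags its later sample. Only the 1st, 3rd, 5th, ...
    flagged samples are removed per pass (a single outlier produces two
    jumps), then the pass repeats until no displacement exceeds threshold.
    Terminates in at most n passes.
    """
    out = traj.copy()
    thr_still, thr_move = thresholds
    movement_mask = np.asarray(movement_mask, bool)
    while True:
        idx = np.where(out.valid)[0]
        if len(idx) < 2:
            return out
        gap = np.diff(out.frames[idx]).astype(float)
        gap[gap == 0] = 1.0
        disp = np.linalg.norm(np.diff(out.xyz[idx], axis=0), axis=1) / gap
        later = idx[1:]
        thr = np.where(movement_mask[later], thr_move, thr_still)
        flagged = later[disp > thr]
        if len(flagged) == 0:
            return out
        out.reject(flagged[::2], "speed")


def interpolate_gaps(traj: Trajectory3D) -> Trajectory3D:
    """Fill interior invalid samples by monotone (shape-preserving) cubic
    interpolation per coordinate; filled samples become valid with reason
    ``interpolated``. Leading/trailing gaps stay invalid."""
    out = traj.copy()
    idx = np.where(out.valid)[0]
    if len(idx) < 2:
        log.warning("trajectory has <2 valid points; nothing to interpolate")
        return out
    interior = np.where(~out.valid)[0]
    interior = interior[(interior > idx[0]) & (interior < idx[-1])]
    if len(interior) == 0:
        return out
    t = out.frames[idx].astype(float)
    for d in range(3):
        f = PchipInterpolator(t, out.xyz[idx, d])
        out.xyz[interior, d] = f(out.frames[interior].astype(float))
    out.valid[interior] = True
    out.reason[interior] = "interpolated"
    return out


def clean_pipeline(
    tracks: dict[str, pd.DataFrame],
    cameras: list[CameraModel],
    bodypart: str,
    movement_mask_fn,
    thresholds: SpeedThresholds = SpeedThresholds(),
    geometry: CageGeometry | None = None,
    likelihood: float = 0.9,
    reproj_px: float = 50.0,
    fps: float = 60.0,
    interpolate: bool = True,
) -> Trajectory3D:
    """Full cleaning chain: likelihood -> triangulation -> reprojection ->
    bounding box -> speed -> interpolation. ``movement_mask_fn(frames)``
    returns the per-frame movement flag."""
    gated = filter_likelihood(tracks, likelihood)
    traj = triangulate(gated, cameras, bodypart, fps=fps)
    traj = filter_reprojection(traj, reproj_px)
    traj = filter_bounding_box(traj, geometry=geometry)
    traj = reject_speed_outliers(traj, thresholds.for_part(bodypart), movement_mask_fn(traj.frames))
    if interpolate:
        traj = interpolate_gaps(traj)
    return traj


# ---------------------------------------------------------------------------
# alignment, averaging, variability, passage control


def align_trials(
    trials: list[tuple[Trajectory3D, float, float]],
    window_ms: tuple[float, float] = (100.0, 100.0),
    n_samples: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample trials onto a common normalized time base.

    Each item is (trajectory, release_ms, acquisition_ms). The window runs
    from ``release - pre`` to ``acquisition + post``; each trial is linearly
    interpolated onto ``n_samples`` evenly spaced points of that window.
    Returns (tensor of shape (n_kept, n_samples, 3), per-trial durations in
    ms). Trials with fewer than two valid frames in the window are excluded
    with a log entry.
    """
    pre, post = window_ms
    tensors, durations = [], []
    for traj, release, acquisition in trials:
        t0, t1 = release - pre, acquisition + post
        t = traj.times_ms
        sel = traj.valid & (t >= t0 - 1000.0 / traj.fps) & (t <= t1 + 1000.0 / traj.fps)
        if sel.sum() < 2:
            log.warning("trial excluded from alignment: <2 valid frames in window")
            continue
        ts = t[sel]
        grid = np.linspace(t0, t1, n_samples)
        cols = [np.interp(grid, ts, traj.xyz[sel, d]) for d in range(3)]
        tensors.append(np.column_stack(cols))
        durations.append(t1 - t0)
    if not tensors:
        return np.empty((0, n_samples, 3)), np.empty(0)
    return np.stack(tensors), np.asarray(durations)


def trial_average(aligned: np.ndarray) -> np.ndarray:
    """Pointwise mean trajectory over trials (n_samples x 3)."""
    if len(aligned) == 0:
        raise ValueError("need at least one trial")
    return aligned.mean(axis=0)


def variability(aligned: np.ndarray, mean: np.ndarray | None = None) -> pd.DataFrame:
    """Per-trial mean Euclidean deviation from the trial-averaged trajectory.

    Returns a frame with one row per trial (column ``deviation``, mm). The
    median and 0.75-quantile of that column are the summary statistics
    reported per body part and target distance.
    """
    if mean is None:
        mean = trial_average(aligned)
    dist = np.linalg.norm(aligned - mean[None], axis=2)  # (trials, samples)
    return pd.DataFrame({"deviation": dist.mean(axis=1)})


def deviation_summary(deviations: np.ndarray | pd.Series) -> tuple[float, float]:
    dev = np.asarray(deviations, float)
    return float(np.median(dev)), float(np.quantile(dev, 0.75))


def passage_spread(
    blocks: dict[str, list[Trajectory3D]],
    start_y: float = 0.0,
    plane_distance: float = 400.0,
    axis: int = 0,
) -> dict:
    """Spread of walk-and-reach crossings at a plane 400 mm from the start.

    For each trajectory the first crossing of the plane ``y = start_y +
    plane_distance`` is located by linear interpolation between the
    bracketing frames, and its coordinate along the target axis recorded.
    Returns per-block range and s.d. plus a two-sample Kolmogorov-Smirnov
    test between the two blocks. Trials never crossing are excluded with a
    log entry.
    """
    y_plane = start_y + plane_distance
    crossings: dict[str, np.ndarray] = {}
    for label, trajs in blocks.items():
        vals = []
        for traj in trajs:
            xyz = traj.xyz[traj.valid]
            if len(xyz) < 2:
                continue
            above = xyz[:, 1] >= y_plane
            if not above.any() or above[0]:
                log.warning("block %s: trajectory never crosses the plane; excluded", label)
                continue
            k = int(np.argmax(above))  # first frame beyond the plane
            y0, y1 = xyz[k - 1, 1], xyz[k, 1]
            w = 0.0 if y1 == y0 else (y_plane - y0) / (y1 - y0)
            vals.append(xyz[k - 1, axis] + w * (xyz[k, axis] - xyz[k - 1, axis]))
        crossings[label] = np.asarray(vals)
    out = {
        label: {
            "n": int(len(v)),
            "range": float(v.max() - v.min()) if len(v) else np.nan,
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "crossings": v,
        }
        for label, v in crossings.items()
    }
    labels = list(crossings)
    if len(labels) == 2 and all(len(crossings[l]) for l in labels):
        a, b = crossings[labels[0]], crossings[labels[1]]
        if np.array_equal(a, b):
            d, p = 0.0, 1.0
        else:
            ks = stats.ks_2samp(a, b)
            d, p = float(ks.statistic), float(ks.pvalue)
        out["ks"] = {"statistic": d, "p": p}
    return out
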