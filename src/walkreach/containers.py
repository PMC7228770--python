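"""In-memory containers shared by the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REASONS",
    "Trajectory3D",
    "CameraModel",
    "BroadbandBlock",
    "LossMask",
]

#: rejection provenance codes for 3D trajectory samples
REASONS = (
    "none",
    "low_likelihood",
    "too_few_views",
    "reprojection",
    "bbox",
    "speed",
    "interpolated",
)


@dataclass
class Trajectory3D:
    """Per-frame 3D positions (mm) of one body part at a fixed frame rate.

    ``valid`` marks usable samples; ``reason`` records why a sample was
    rejected (or ``"interpolated"`` for gap-filled samples, which are valid).
    ``reproj_err`` holds per-camera RMS reprojection error in pixels where a
    triangulation produced it.
    """

    frames: np.ndarray
    xyz: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    fps: float = 60.0
    reproj_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        n = len(self.frames)
        if not (self.xyz.shape == (n, 3) and len(self.valid) == n == len(self.reason)):
            raise ValueError("inconsistent trajectory array lengths")

    @classmethod
    def from_xyz(cls, frames: np.ndarray, xyz: np.ndarray, fps: float = 60.0) -> "Trajectory3D":
        n = len(frames)
        return cls(frames, xyz, np.ones(n, bool), np.full(n, "none", object), fps)

    @property
    def times_ms(self) -> np.ndarray:
        return self.frames / self.fps * 1000.0

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(
            self.frames.copy(),
            self.xyz.copy(),
            self.valid.copy(),
            self.reason.copy(),
            self.fps,
            None if self.reproj_err is None else self.reproj_err.copy(),
        )

    def reject(self, idx: np.ndarray, reason: str) -> None:
        """Invalidate samples, keeping the first recorded rejection reason."""
        idx = np.asarray(idx)
        fresh = idx[self.valid[idx]] if idx.dtype != bool else np.where(idx & self.valid)[0]
        self.valid[fresh] = False
        self.reason[fresh] = reason

    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self.valid) else float("nan")

    def reason_counts(self) -> dict[str, int]:
        return {r: int((self.reason == r).sum()) for r in REASONS}

    def to_frame(self, bodypart: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "bodypart": bodypart,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "valid": self.valid,
                "reason": self.reason,
            }
        )


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera: ``u ~ K (R X + t)`` with X in cage mm."""

    name: str
    intrinsic: np.ndarray  # 3x3, px
    rotation: np.ndarray  # 3x3 world->camera
    translation: np.ndarray  # 3-vector, camera frame
    image_size: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        K = np.asarray(self.intrinsic, float)
        R = np.asarray(self.rotation, float)
        if not np.allclose(K, np.triu(K)) or K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("intrinsic matrix must be upper-triangular with positive focals")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8:
            raise ValueError("rotation must be orthonormal")

    @property
    def projection(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        return np.asarray(self.intrinsic) @ np.hstack(
            [np.asarray(self.rotation), np.asarray(self.translation).reshape(3, 1)]
        )

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project Nx3 world points; returns (Nx2 pixels, in-front-of-camera mask)."""
        pts = np.atleast_2d(points)
        cam = pts @ np.asarray(self.rotation).T + np.asarray(self.translation)
        in_front = cam[:, 2] > 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            uvw = cam @ np.asarray(self.intrinsic).T
            px = uvw[:, :2] / uvw[:, 2:3]
        return px, in_front

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intrinsic": np.asarray(self.intrinsic).tolist(),
            "rotation": np.asarray(self.rotation).tolist(),
            "translation": np.asarray(self.translation).tolist(),
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            d["name"],
            np.array(d["intrinsic"], float),
            np.array(d["rotation"], float),
            np.array(d["translation"], float),
            tuple(d.get("image_size", (640, 480))),
        )


@dataclass
class BroadbandBlock:
    """Multi-channel integer-sampled wideband signal with headstage grouping."""

    data: np.ndarray  # (n_channels, n_samples) int16
    rate: float = 30000.0
    channel_names: list[str] = field(default_factory=list)
    headstage_map: dict[str, np.ndarray] = field(default_factory=dict)
    t_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if not self.headstage_map:
            self.headstage_map = {"hs0": np.arange(self.data.shape[0])}
        self.headstage_map = {k: np.asarray(v, int) for k, v in self.headstage_map.items()}

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_samples) / self.rate * 1000.0


@dataclass
class LossMask:
    """Sample-and-hold data-loss mask per headstage plus their union."""

    per_headstage: dict[str, np.ndarray]
    rate: float = 30000.0
    t_start_ms: float = 0.0

    @property
    def combined(self) -> np.ndarray:
        masks = list(self.per_headstage.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out

    def loss_fraction(self) -> float:
        return float(self.combined.mean())

    def trial_fractions(self, trials: pd.DataFrame) -> pd.Series:
        """Loss fraction per trial over its fixation-onset -> trial-end window."""
        comb = self.combined
        n = len(comb)
        out = {}
        for _, row in trials.iterrows():
            end = row["hold_end"]
            if np.isnan(end):
                end = max(
                    v for v in (row["go"], row["release"], row["acquisition"]) if not np.isnan(v)
                )
            i0 = int(np.clip((row["fixation_onset"] - self.t_start_ms) / 1000.0 * self.rate, 0, n))
            i1 = int(np.clip((end - self.t_start_ms) / 1000.0 * self.rate, 0, n))
            out[row["trial_id"]] = float(comb[i0:i1].mean()) if i1 > i0 else np.nan
        return pd.Series(out, name="loss_fraction")
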