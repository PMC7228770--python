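"""Readers and writers for the on-disk exchange formats.

Tables travel as CSV, camera calibrations as JSON, and broadband blocks as
interleaved little-endian int16 binary with a JSON sidecar describing rate,
channel names, and the headstage map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BroadbandBlock, CameraModel, LossMask, Trajectory3D

__all__ = [
    "write_table",
    "read_table",
    "write_tracks",
    "read_tracks",
    "write_calibration",
    "read_calibration",
    "write_broadband",
    "read_broadband",
    "write_loss_mask",
    "read_loss_mask",
    "write_trajectory",
    "read_trajectory",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(tracks: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_table(df, out_dir / f"tracks_{cam}.csv") for cam, df in tracks.items()]


def read_tracks(track_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = {}
    for path in sorted(Path(track_dir).glob("tracks_*.csv")):
        out[path.stem.removeprefix("tracks_")] = pd.read_csv(path)
    return out


def write_calibration(cameras: list[CameraModel], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([c.to_dict() for c in cameras], indent=2))
    return path


def read_calibration(path: str | Path) -> list[CameraModel]:
    return [CameraModel.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_broadband(block: BroadbandBlock, path: str | Path) -> tuple[Path, Path]:
    """Interleaved (sample-major) little-endian int16 plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(block.data.T.astype("<i2"))
    data.tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "rate": block.rate,
                "n_channels": block.n_channels,
                "n_samples": block.n_samples,
                "channel_names": list(block.channel_names),
                "headstage_map": {k: v.tolist() for k, v in block.headstage_map.items()},
                "t_start_ms": block.t_start_ms,
                "dtype": "<i2",
                "order": "sample-major",
            },
            indent=2,
        )
    )
    return path, sidecar


def read_broadband(path: str | Path) -> BroadbandBlock:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype="<i2")
    expected = meta["n_channels"] * meta["n_samples"]
    if len(raw) != expected:
        raise ValueError(f"binary length {len(raw)} != sidecar {expected}")
    data = raw.reshape(meta["n_samples"], meta["n_channels"]).T
    return BroadbandBlock(
        data,
        rate=meta["rate"],
        channel_names=meta["channel_names"],
        headstage_map={k: np.array(v) for k, v in meta["headstage_map"].items()},
        t_start_ms=meta.get("t_start_ms", 0.0),
    )


def write_loss_mask(mask: LossMask, path: str | Path) -> Path:
    df = pd.DataFrame({hs: m.astype(int) for hs, m in mask.per_headstage.items()})
    df.insert(0, "sample", np.arange(len(df)))
    return write_table(df, path)


def read_loss_mask(path: str | Path, rate: float = 30000.0) -> LossMask:
    df = pd.read_csv(path)
    return LossMask(
        {c: df[c].to_numpy(bool) for c in df.columns if c != "sample"}, rate=rate
    )


def write_trajectory(
    trajectories: dict[str, Trajectory3D], path: str | Path
) -> Path:
    df = pd.concat(
        [traj.to_frame(bp) for bp, traj in trajectories.items()], ignore_index=True
    )
    return write_table(df, path)


def read_trajectory(path: str | Path, fps: float = 60.0) -> dict[str, Trajectory3D]:
    df = pd.read_csv(path)
    out = {}
    for bp, grp in df.groupby("bodypart"):
        out[bp] = Trajectory3D(
            grp["frame"].to_numpy(),
            grp[["x", "y", "z"]].to_numpy(),
            grp["valid"].to_numpy(bool),
            grp["reason"].to_numpy(object),
            fps,
        )
    return out
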