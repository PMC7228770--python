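"""End-to-end orchestration: simulate -> behavior -> kinematics -> signal ->
decode, with a reproducibility manifest.

Every stage writes into its own subdirectory of the run's output directory;
the manifest records the configuration hash, per-stage wall-clock time, and
SHA-256 checksums of every output file, so a re-run with the same config and
seed can be verified byte-for-byte on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import io as wio
from . import kinematics as km
from . import signal as sg
from . import stats as st
from .config import CageGeometry, MovementTiming, TaskConfig
from .simulate import (
    DropoutSpec,
    KinematicsParams,
    build_population,
    default_cameras,
    generate_kinematics,
    generate_population_spikes,
    generate_task_trials,
    inject_data_loss,
    project_to_cameras,
    synthesize_broadband,
)

__all__ = ["RunConfig", "run_full_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; defaults follow the study protocol
    where it states a value."""

    seed: int = 0
    n_trials: int = 200
    error_rates: dict = field(default_factory=lambda: {"premature": 0.1, "hold_break": 0.05})
    n_units_per_area: int = 16
    # kinematics
    pixel_noise_sd: float = 1.0
    miss_rate: float = 0.03
    outlier_rate: float = 0.02
    align_samples: int = 100
    kinematics_trials: int = 40  # reconstruction is the slow stage; bounded
    # broadband stage (scaled-down demonstration of the signal-QC chain)
    broadband_channels: int = 64
    broadband_seconds: float = 10.0
    dropout_fraction: float = 0.03
    # statistics
    k_folds: int = 20
    n_perm_decoding: int = 500
    n_perm_modulation: int = 1000
    # stage switches
    run_kinematics: bool = True
    run_signal: bool = True
    run_decoding: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all enabled stages in dependency order; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "stages": {},
        "files": {},
    }
    task_cfg = TaskConfig()
    geometry = CageGeometry()

    def finish(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for f in files:
            manifest["files"][str(f.relative_to(out_dir))] = _sha256(f)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    sim = out_dir / "simulate"
    trials, events = generate_task_trials(
        task_cfg, geometry, config.n_trials, config.error_rates, seed=config.seed,
        movement=MovementTiming(),
    )
    files = [
        wio.write_table(trials, sim / "trials.csv"),
        wio.write_table(events, sim / "events.csv"),
    ]
    cameras = default_cameras()
    files.append(wio.write_calibration(cameras, sim / "calibration.json"))
    tuning = build_population(config.n_units_per_area, seed=config.seed)
    spikes = generate_population_spikes(trials, tuning, seed=config.seed)
    files.append(wio.write_table(spikes, sim / "spikes.csv"))
    finish("simulate", t0, files)

    # --- behavior -----------------------------------------------------
    t0 = time.perf_counter()
    beh = out_dir / "behavior"
    records = bh.classify_trials(events, task_cfg, trial_info=trials)
    rec_df = bh.records_to_frame(records)
    timing = bh.compute_timing(rec_df)
    summary = bh.timing_summary(timing)
    files = [
        wio.write_table(rec_df, beh / "trial_records.csv"),
        wio.write_table(timing, beh / "timing.csv"),
    ]
    beh_json = beh / "summary.json"
    beh_json.write_text(
        json.dumps(
            {
                "percent_correct": bh.percent_correct(rec_df),
                "groups": summary.groups,
                "tests": summary.tests,
            },
            indent=2,
        )
    )
    files.append(beh_json)
    finish("behavior", t0, files)

    correct = trials[trials["outcome"] == "correct"].reset_index(drop=True)

    # --- kinematics ---------------------------------------------------
    if config.run_kinematics:
        t0 = time.perf_counter()
        kin = out_dir / "kinematics"
        # reconstruct the wrist for a bounded number of trials
        subset = correct.head(config.kinematics_trials)
        truth = generate_kinematics(subset, geometry, KinematicsParams(), seed=config.seed)
        aligned_inputs = []
        dev_rows = []
        files = []
        for tid, parts in truth.items():
            tracks = project_to_cameras(
                parts,
                cameras,
                pixel_noise_sd=config.pixel_noise_sd,
                miss_rate=config.miss_rate,
                outlier_rate=config.outlier_rate,
                seed=config.seed + tid,
            )
            row = subset[subset["trial_id"] == tid].iloc[0]
            move = (row["release"], row["acquisition"])

            def mask_fn(frames: np.ndarray, move=move) -> np.ndarray:
                t = frames / 60.0 * 1000.0
                return (t >= move[0]) & (t <= move[1])

            traj = km.clean_pipeline(tracks, cameras, "wrist", mask_fn, geometry=geometry)
            aligned_inputs.append(
                (traj, row["release"], row["acquisition"], row["distance"], row["position"])
            )
        files.append(
            wio.write_trajectory(
                {"wrist": aligned_inputs[0][0]}, kin / "example_trajectory.csv"
            )
        )
        # per-target variability, pooled over positions within a distance
        for dist in ("near", "far"):
            for pos in sorted({p for *_, d, p in aligned_inputs if d == dist}):
                sel = [(t, r, a) for t, r, a, d, p in aligned_inputs if d == dist and p == pos]
                if len(sel) < 2:
                    continue
                tensor, _ = km.align_trials(sel, (100.0, 100.0), config.align_samples)
                dev = km.variability(tensor)
                dev["distance"] = dist
                dev["position"] = pos
                dev_rows.append(dev)
        if dev_rows:
            files.append(wio.write_table(pd.concat(dev_rows), kin / "wrist_deviation.csv"))
        finish("kinematics", t0, files)

    # --- signal -------------------------------------------------------
    if config.run_signal:
        t0 = time.perf_counter()
        sig = out_dir / "signal"
        dur_ms = config.broadband_seconds * 1000.0
        sub_spikes = spikes[spikes["time_ms"] < dur_ms]
        n_ch = config.broadband_channels
        hs_map = {
            "hs0": np.arange(n_ch // 2),
            "hs1": np.arange(n_ch // 2, n_ch),
        }
        from .simulate import common_signal

        block = synthesize_broadband(
            sub_spikes,
            n_channels=n_ch,
            duration_ms=dur_ms,
            common=common_signal(int(dur_ms / 1000.0 * 30000), seed=config.seed),
            headstage_map=hs_map,
            seed=config.seed,
        )
        lossy, truth_mask = inject_data_loss(
            block, DropoutSpec(config.dropout_fraction), seed=config.seed
        )
        detected = sg.detect_data_loss(lossy)
        files = list(wio.write_broadband(lossy, sig / "broadband.bin"))
        files.append(wio.write_loss_mask(detected, sig / "loss_mask.csv"))
        in_window = trials["fixation_onset"] < dur_ms
        fractions = detected.trial_fractions(trials[in_window])
        kept = sg.filter_trials_by_loss(trials[in_window], fractions)
        files.append(wio.write_table(kept, sig / "trials_kept.csv"))
        # condition one array (half of one headstage) and extract spikes
        arr = lossy.data[:8].astype(float)
        arr = np.vstack([sg.median_highpass(ch) for ch in arr])
        arr = np.vstack([sg.butterworth_lowpass(ch) for ch in arr])
        arr, report = sg.remove_common_noise_pca(arr)
        files.append(wio.write_table(report, sig / "common_noise_report.csv"))
        ev_rows = []
        for ch in range(arr.shape[0]):
            for e in sg.extract_spikes(arr[ch], channel=ch):
                ev_rows.append({"channel": e.channel, "time_s": e.time_s, "polarity": e.polarity})
        files.append(
            wio.write_table(pd.DataFrame(ev_rows, columns=["channel", "time_s", "polarity"]),
                            sig / "spike_events.csv")
        )
        u0 = spikes["unit"].iloc[0]
        t_spk = spikes.loc[spikes["unit"] == u0, "time_ms"].to_numpy() / 1000.0
        grid, rate = sg.spike_density(t_spk[t_spk < 20.0], 0.0, 20.0)
        files.append(
            wio.write_table(pd.DataFrame({"time_s": grid, "rate": rate}), sig / "sdf_example.csv")
        )
        finish("signal", t0, files)

    # --- decode -------------------------------------------------------
    if config.run_decoding:
        t0 = time.perf_counter()
        dec = out_dir / "decode"
        rates = st.window_firing_rates(spikes, correct)
        anova = st.anova_modulation(rates)
        files = [wio.write_table(anova, dec / "anova.csv")]
        results: dict = {}
        area_of = dict(zip(spikes["unit"], spikes["area"]))
        for dist in ("near", "far"):
            tr = correct[correct["distance"] == dist].reset_index(drop=True)
            if len(tr) < 2 * config.k_folds:
                continue
            labels = st.direction_labels(tr)
            mem = st.bin_firing_rates(spikes, tr, "cue_off", (-200.0, 700.0))
            mov = st.bin_firing_rates(spikes, tr, "acquisition", (-900.0, 300.0))
            for period, bins, window in (
                ("memory", mem, (100.0, 400.0)),
                ("movement", mov, (-300.0, 0.0)),
            ):
                feats = bins.bin_at(*window)
                for area in ("M1", "PMd", "PRR"):
                    cols = [i for i, u in enumerate(bins.units) if area_of[u] == area]
                    res = st.permutation_null_decoding(
                        feats[:, cols],
                        labels,
                        n_perm=config.n_perm_decoding,
                        k_folds=config.k_folds,
                        seed=config.seed,
                    )
                    res.p_corrected = st.bonferroni(res.p, 12)
                    mod = st.permutation_null_modulation(
                        feats[:, cols].T, labels, n_perm=config.n_perm_modulation,
                        seed=config.seed,
                    )
                    results[f"{dist}/{period}/{area}"] = {
                        "accuracy": res.accuracy,
                        "p": res.p,
                        "p_corrected": res.p_corrected,
                        "threshold": res.threshold,
                        "modulation": mod.accuracy,
                        "modulation_p": mod.p,
                        "modulation_p_corrected": st.bonferroni(mod.p, 12),
                    }
        dec.mkdir(parents=True, exist_ok=True)
        dec_json = dec / "decoding.json"
        dec_json.write_text(json.dumps(results, indent=2))
        files.append(dec_json)
        finish("decode", t0, files)
    else:
        manifest["stages"]["decode"] = {"skipped": True}

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema-check input files; returns a report (empty = no findings).

    Keys recognised: trials, events, tracks (directory), calibration,
    broadband. Column resolution is by name, so column order is free. At
    most the first five offending rows per violation are reported.
    """
    report: list[dict] = []

    def need_columns(df: pd.DataFrame, cols: set[str], path) -> bool:
        missing = cols - set(df.columns)
        if missing:
            report.append({"path": str(path), "error": f"missing columns {sorted(missing)}"})
            return False
        return True

    if "trials" in paths:
        df = pd.read_csv(paths["trials"])
        need_columns(df, {"trial_id", "distance", "position", "outcome"}, paths["trials"])
    if "events" in paths:
        df = pd.read_csv(paths["events"])
        if need_columns(df, {"trial_id", "event", "time_ms"}, paths["events"]):
            bad = df[~np.isfinite(pd.to_numeric(df["time_ms"], errors="coerce"))]
            if len(bad):
                report.append(
                    {
                        "path": str(paths["events"]),
                        "error": "non-numeric time_ms",
                        "rows": bad.head(5).index.tolist(),
                    }
                )
    if "tracks" in paths:
        for p in sorted(Path(paths["tracks"]).glob("tracks_*.csv")):
            df = pd.read_csv(p)
            need_columns(df, {"frame", "bodypart", "x", "y", "likelihood"}, p)
    if "calibration" in paths:
        try:
            wio.read_calibration(paths["calibration"])
        except Exception as exc:  # report-only contract
            report.append({"path": str(paths["calibration"]), "error": str(exc)})
    if "broadband" in paths:
        try:
            wio.read_broadband(paths["broadband"])
        except Exception as exc:
            report.append({"path": str(paths["broadband"]), "error": str(exc)})
    return report
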