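"""3D reconstruction and cleaning: triangulation, outlier filters,
interpolation, alignment, variability, and the passage-spread control."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import PchipInterpolator

from walkreach import kinematics as km
from walkreach.config import CageGeometry
from walkreach.containers import Trajectory3D
from walkreach.simulate import (
    KinematicsParams,
    generate_kinematics,
    generate_task_trials,
    project_to_cameras,
)


def _traj(xyz, frames=None, fps=60.0):
    xyz = np.asarray(xyz, float)
    frames = np.arange(len(xyz)) if frames is None else frames
    return Trajectory3D.from_xyz(frames, xyz, fps)


# ---------------------------------------------------------------------------
# likelihood gating


def test_likelihood_threshold_boundary_kept():
    df = pd.DataFrame(
        {"frame": [0, 1, 2], "bodypart": "wrist", "x": [1.0, 2.0, 3.0],
         "y": [1.0, 2.0, 3.0], "likelihood": [0.89, 0.90, 1.0]}
    )
    out = km.filter_likelihood({"cam0": df})["cam0"]
    assert out["valid"].tolist() == [False, True, True]


def test_likelihood_filter_removes_exactly_generator_misses(clean_session, geometry, cameras):
    trials, _ = clean_session
    truth = generate_kinematics(trials.head(3), geometry, KinematicsParams(), seed=8)
    parts = next(iter(truth.values()))
    tracks = project_to_cameras(parts, cameras, miss_rate=0.1, seed=9)
    gated = km.filter_likelihood(tracks)
    for cam, df in gated.items():
        assert ((df["gt_flag"] == "miss") == ~df["valid"]).all()


# ---------------------------------------------------------------------------
# triangulation


def _brute_force_point(obs, cams, center, span=1600.0, levels=6, grid=9):
    """Coarse-to-fine grid minimizer of the squared reprojection cost."""
    best = np.asarray(center, float)
    for _ in range(levels):
        ax = [np.linspace(best[d] - span, best[d] + span, grid) for d in range(3)]
        pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        cost = np.zeros(len(pts))
        for name, uv in obs.items():
            px, front = cams[name].project(pts)
            c = ((px - uv) ** 2).sum(axis=1)
            c[~front] = 1e12
            cost += c
        best = pts[np.argmin(cost)]
        span /= grid / 2.0
    return best


def test_noiseless_triangulation_recovers_point_exactly(cameras, rng):
    cams = {c.name: c for c in cameras}
    for _ in range(25):
        X = rng.uniform([-350, -100, 0], [350, 1100, 650])
        obs = {c.name: c.project(X)[0][0] for c in cameras}
        xyz, errs = km.triangulate_point(obs, cams)
        assert np.linalg.norm(xyz - X) < 1e-6
        assert errs.max() < 1e-6


def test_noisy_triangulation_matches_brute_force_minimizer(cameras, rng):
    cams = {c.name: c for c in cameras}
    for _ in range(10):
        X = rng.uniform([-300, 0, 50], [300, 1000, 600])
        obs = {c.name: c.project(X)[0][0] + rng.normal(0, 2, 2) for c in cameras}
        xyz, _ = km.triangulate_point(obs, cams)
        ref = _brute_force_point(obs, cams, center=[0, 500, 350])
        assert np.linalg.norm(xyz - ref) < 1.0


def test_single_view_yields_invalid_point(cameras):
    cams = {c.name: c for c in cameras}
    assert km.triangulate_point({"cam0": np.array([320.0, 240.0])}, cams) is None


def test_triangulate_projection_roundtrip_on_tracks(clean_session, geometry, cameras):
    trials, _ = clean_session
    truth = generate_kinematics(
        trials.head(2), geometry, KinematicsParams(path_noise_sd=0, endpoint_sd=0), seed=10
    )
    parts = next(iter(truth.values()))
    tracks = km.filter_likelihood(project_to_cameras(parts, cameras, seed=11))
    traj = km.triangulate(tracks, cameras, "wrist")
    assert traj.valid.all()
    assert np.allclose(traj.xyz, parts["wrist"].xyz, atol=1e-6)
    assert np.nanmax(traj.reproj_err) < 1e-6


# ---------------------------------------------------------------------------
# reprojection / bounding-box filters


def test_reprojection_filter_uses_max_over_cameras():
    traj = _traj(np.zeros((3, 3)))
    traj.reproj_err = np.array([[10.0, 51.0], [10.0, 49.0], [np.nan, np.nan]])
    out = km.filter_reprojection(traj, 50.0)
    assert out.valid.tolist() == [False, True, True]
    assert out.reason[0] == "reprojection"


def test_bbox_boundary_closed_and_strict_outside(geometry):
    corner = geometry.bbox_max.copy()
    outside = corner + np.array([1.0, 0.0, 0.0])
    traj = _traj([corner, outside, [0, 500, 300]])
    out = km.filter_bounding_box(traj, geometry)
    assert out.valid.tolist() == [True, False, True]
    assert out.reason[1] == "bbox"


def test_clean_synthetic_trajectories_have_zero_bbox_rejections(clean_session, geometry):
    trials, _ = clean_session
    truth = generate_kinematics(trials.head(5), geometry, KinematicsParams(), seed=12)
    for parts in truth.values():
        for traj in parts.values():
            out = km.filter_bounding_box(traj, geometry)
            assert out.valid.all()


# ---------------------------------------------------------------------------
# speed outliers


def test_single_teleport_removed_in_one_pass():
    xyz = np.zeros((20, 3))
    xyz[:, 0] = np.arange(20) * 5.0  # slow 5 mm/frame drift
    xyz[10] += np.array([0.0, 200.0, 0.0])  # teleported sample
    traj = _traj(xyz)
    out = km.reject_speed_outliers(traj, (12.0, 80.0), np.zeros(20, bool))
    assert not out.valid[10]
    assert out.valid.sum() == 19
    assert (out.reason == "speed").sum() == 1


def test_all_below_threshold_unchanged():
    xyz = np.cumsum(np.full((30, 3), 2.0), axis=0)
    traj = _traj(xyz)
    out = km.reject_speed_outliers(traj, (12.0, 80.0), np.zeros(30, bool))
    assert out.valid.all()


def test_movement_mask_switches_threshold():
    # 13 mm/frame steps: above the 12 mm resting limit, below the 80 mm
    # movement limit for the wrist
    xyz = np.zeros((10, 3))
    xyz[:, 0] = np.arange(10) * 13.0
    still = km.reject_speed_outliers(_traj(xyz), (12.0, 80.0), np.zeros(10, bool))
    moving = km.reject_speed_outliers(_traj(xyz), (12.0, 80.0), np.ones(10, bool))
    assert not still.valid.all()
    assert moving.valid.all()


def test_speed_iteration_terminates_on_random_walks(rng):
    for _ in range(5):
        xyz = np.cumsum(rng.normal(0, 20, (60, 3)), axis=0)
        out = km.reject_speed_outliers(_traj(xyz), (12.0, 80.0), np.zeros(60, bool))
        idx = np.where(out.valid)[0]
        if len(idx) >= 2:
            gap = np.diff(out.frames[idx]).astype(float)
            disp = np.linalg.norm(np.diff(out.xyz[idx], axis=0), axis=1) / gap
            assert (disp <= 12.0).all()


# ---------------------------------------------------------------------------
# interpolation


def test_gap_in_linear_segment_reproduced_exactly():
    xyz = np.column_stack([np.arange(20.0), 2 * np.arange(20.0), np.zeros(20)])
    traj = _traj(xyz)
    traj.reject(np.array([7, 8, 9]), "speed")
    traj.xyz[7:10] = np.nan
    out = km.interpolate_gaps(traj)
    assert out.valid.all()
    assert np.allclose(out.xyz[:, 0], np.arange(20.0), atol=1e-9)
    assert (out.reason[7:10] == "interpolated").all()


def test_no_gaps_identity():
    traj = _traj(np.random.default_rng(0).normal(size=(15, 3)))
    out = km.interpolate_gaps(traj)
    assert np.array_equal(out.xyz, traj.xyz)
    assert out.valid.all()


def test_interpolation_matches_reference_shape_preserving_cubic(rng):
    n = 200
    t = np.arange(n, dtype=float)
    xyz = np.column_stack([np.sin(t / 7.0), np.cos(t / 11.0), t / 50.0])
    traj = _traj(xyz)
    gaps = rng.choice(np.arange(1, n - 1), size=20, replace=False)
    traj.reject(gaps, "speed")
    out = km.interpolate_gaps(traj)
    keep = np.setdiff1d(np.arange(n), gaps)
    for d in range(3):
        ref = PchipInterpolator(t[keep], xyz[keep, d])(t[gaps])
        assert np.abs(out.xyz[gaps, d] - ref).max() < 1e-9


def test_leading_trailing_gaps_left_invalid():
    traj = _traj(np.ones((10, 3)))
    traj.reject(np.array([0, 1, 9]), "speed")
    out = km.interpolate_gaps(traj)
    assert not out.valid[[0, 1, 9]].any()


# ---------------------------------------------------------------------------
# filter properties


def test_filters_idempotent_and_counts_conserved(rng):
    xyz = np.cumsum(rng.normal(0, 10, (80, 3)), axis=0) + np.array([0, 500, 300])
    traj = _traj(xyz)
    traj.reproj_err = rng.uniform(0, 80, (80, 2))
    once = km.filter_reprojection(traj, 50.0)
    twice = km.filter_reprojection(once, 50.0)
    assert np.array_equal(once.valid, twice.valid)
    assert np.array_equal(once.reason, twice.reason)
    b_once = km.filter_bounding_box(once)
    b_twice = km.filter_bounding_box(b_once)
    assert np.array_equal(b_once.valid, b_twice.valid)
    s_once = km.reject_speed_outliers(b_once, (12.0, 80.0), np.zeros(80, bool))
    s_twice = km.reject_speed_outliers(s_once, (12.0, 80.0), np.zeros(80, bool))
    assert np.array_equal(s_once.valid, s_twice.valid)
    counts = s_once.reason_counts()
    assert counts["none"] == s_once.valid.sum()
    assert sum(counts.values()) == 80


# ---------------------------------------------------------------------------
# alignment, averaging, variability


def _linear_trial(duration_frames, start, stop, release_frame=10):
    n = duration_frames + 20
    tau = np.clip((np.arange(n) - release_frame) / duration_frames, 0, 1)
    xyz = np.asarray(start) + tau[:, None] * (np.asarray(stop) - np.asarray(start))
    traj = _traj(xyz)
    release_ms = release_frame / 60.0 * 1000.0
    acq_ms = (release_frame + duration_frames) / 60.0 * 1000.0
    return traj, release_ms, acq_ms


def test_alignment_invariant_to_duration():
    a = _linear_trial(24, [0, 0, 0], [100, 200, 300])
    b = _linear_trial(48, [0, 0, 0], [100, 200, 300])
    tensor, durations = km.align_trials([a, b], (0.0, 0.0), 50)
    assert np.allclose(tensor[0], tensor[1], atol=1e-9)
    assert durations[1] == pytest.approx(2 * durations[0])


def test_alignment_identity_when_grid_matches_frames():
    traj, release, acq = _linear_trial(24, [0, 0, 0], [100, 0, 0])
    tensor, _ = km.align_trials([(traj, release, acq)], (0.0, 0.0), 25)
    sel = (traj.times_ms >= release) & (traj.times_ms <= acq)
    assert np.allclose(tensor[0], traj.xyz[sel], atol=1e-9)


def test_trial_average_matches_loop_oracle(rng):
    tensor = rng.normal(size=(7, 30, 3))
    mean = km.trial_average(tensor)
    oracle = np.zeros((30, 3))
    for trial in tensor:
        oracle += trial
    oracle /= 7
    assert np.abs(mean - oracle).max() < 1e-12


def test_mirrored_pair_averages_to_midline():
    path = np.random.default_rng(1).normal(size=(20, 3))
    tensor = np.stack([path, -path])
    assert np.allclose(km.trial_average(tensor), 0.0)


def test_identical_trials_have_zero_deviation():
    path = np.random.default_rng(2).normal(size=(20, 3))
    tensor = np.stack([path] * 5)
    dev = km.variability(tensor)
    assert np.allclose(dev["deviation"], 0.0)


def test_symmetric_offset_pair_deviation_equals_offset():
    path = np.zeros((20, 3))
    tensor = np.stack([path + [5.0, 0, 0], path - [5.0, 0, 0]])
    dev = km.variability(tensor)
    assert np.allclose(dev["deviation"], 5.0)


def test_generator_variability_matches_monte_carlo_oracle(geometry, task_cfg):
    # 100 trials to a single target with 5 mm isotropic path noise
    sigma, n_trials, n_samples = 5.0, 100, 25
    trials, _ = generate_task_trials(task_cfg, geometry, 140, seed=21)
    one = trials[(trials.distance == "near") & (trials.position == "mid-left")]
    reps = int(np.ceil(n_trials / len(one)))
    one = pd.concat([one] * reps).head(n_trials).reset_index(drop=True)
    one["trial_id"] = np.arange(n_trials)
    truth = generate_kinematics(
        one, geometry, KinematicsParams(path_noise_sd=sigma, endpoint_sd=0.0), seed=22
    )
    items = []
    for tid, parts in truth.items():
        row = one[one.trial_id == tid].iloc[0]
        items.append((parts["wrist"], row["release"], row["acquisition"]))
    tensor, _ = km.align_trials(items, (0.0, 0.0), n_samples)
    observed = float(np.median(km.variability(tensor)["deviation"]))

    # Monte-Carlo oracle: same measurement chain written directly — Hann
    # band-limited Gaussian noise on 60 Hz frames, linear resampling onto
    # the aligned grid, per-trial time-averaged distance to the trial mean
    rng = np.random.default_rng(77)
    start = geometry.start_positions[0]
    target = geometry.target("near", "mid-left")
    w = np.hanning(9)[1:-1]
    w = w / np.sqrt((w**2).sum())
    meds = []
    for _ in range(60):
        sampled = np.empty((n_trials, n_samples, 3))
        for i in range(n_trials):
            dur = max(rng.normal(400.0, 40.0), 100.0)
            r = rng.uniform(0.0, 1000.0 / 60.0)
            ft = np.arange(-2, int(dur / 1000.0 * 60) + 3) / 60.0 * 1000.0
            tau = np.clip((ft - r) / dur, 0.0, 1.0)
            s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
            raw = rng.normal(0, sigma, (len(ft), 3))
            noise = np.column_stack(
                [np.convolve(raw[:, d], w, mode="same") for d in range(3)]
            )
            path = start + s[:, None] * (target - start) + noise
            grid = np.linspace(r, r + dur, n_samples)
            sampled[i] = np.column_stack(
                [np.interp(grid, ft, path[:, d]) for d in range(3)]
            )
        d = np.linalg.norm(sampled - sampled.mean(axis=0), axis=2).mean(axis=1)
        meds.append(np.median(d))
    oracle = float(np.mean(meds))
    assert abs(observed - oracle) < 0.10 * oracle


# ---------------------------------------------------------------------------
# passage spread


def _crossing_trajs(xs):
    out = []
    for x in xs:
        y = np.linspace(0.0, 1000.0, 40)
        xyz = np.column_stack([np.full_like(y, x), y, np.linspace(0, 600, 40)])
        out.append(_traj(xyz))
    return out


def test_identical_blocks_ks_null():
    xs = np.linspace(-100, 100, 30)
    res = km.passage_spread(
        {"passage": _crossing_trajs(xs), "open": _crossing_trajs(xs)}
    )
    assert res["ks"]["statistic"] == 0.0
    assert res["ks"]["p"] == pytest.approx(1.0)


def test_narrow_passage_detected_by_ks(rng):
    wide = _crossing_trajs(rng.uniform(-200, 200, 150))
    narrow = _crossing_trajs(rng.uniform(-50, 50, 150))
    res = km.passage_spread({"open": wide, "passage": narrow})
    assert res["ks"]["p"] < 0.01
    assert res["open"]["range"] > res["passage"]["range"]


def test_constant_crossings_have_zero_spread():
    res = km.passage_spread({"a": _crossing_trajs([10.0] * 5), "b": _crossing_trajs([10.0] * 5)})
    assert res["a"]["range"] == 0.0
    assert res["a"]["sd"] == 0.0


def test_non_crossing_trials_excluded():
    y = np.linspace(0.0, 300.0, 20)  # never reaches the 400 mm plane
    short = _traj(np.column_stack([np.zeros(20), y, y]))
    res = km.passage_spread({"a": [short] + _crossing_trajs([0.0, 5.0]), "b": _crossing_trajs([1.0, 2.0])})
    assert res["a"]["n"] == 2
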