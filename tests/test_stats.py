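"""Windowed rates, ANOVA screening, SVM decoding, permutation inference,
and the population modulation statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from walkreach import stats as st
from walkreach.simulate import TuningSpec, generate_population_spikes


@pytest.fixture(scope="module")
def correct_trials(clean_session):
    trials, _ = clean_session
    return trials[trials["outcome"] == "correct"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# windowed rates


def test_window_rate_arithmetic(correct_trials):
    tr = correct_trials.head(1)
    t0 = tr["cue_on"].iloc[0]
    spikes = pd.DataFrame(
        {"unit": "u0", "area": "M1", "trial_id": tr["trial_id"].iloc[0],
         "time_ms": t0 + np.array([10.0, 100.0, 200.0, 300.0, 499.0])}
    )
    rates = st.window_firing_rates(spikes, tr)
    after_cue = rates[(rates["alignment"] == "cue_on") & (rates["side"] == "after")]
    assert after_cue["rate"].iloc[0] == 10.0  # 5 spikes / 0.5 s
    before_cue = rates[(rates["alignment"] == "cue_on") & (rates["side"] == "before")]
    assert before_cue["rate"].iloc[0] == 0.0
    assert len(rates) == 8  # 2 sides x 4 alignments


def test_window_rates_eight_windows_per_trial(correct_trials):
    spec = TuningSpec(unit="u0", baseline=20.0)
    spikes = generate_population_spikes(correct_trials, [spec], seed=31)
    rates = st.window_firing_rates(spikes, correct_trials)
    counts = rates.groupby("trial_id").size()
    assert (counts == 8).all()
    base = rates[(rates["alignment"] == "cue_on") & (rates["side"] == "before")]
    se = base["rate"].std(ddof=1) / np.sqrt(len(base))
    assert abs(base["rate"].mean() - 20.0) < 3 * se


# ---------------------------------------------------------------------------
# ANOVA responsiveness


def _null_rates(trials, rng, effect=None):
    rows = []
    for _, tr in trials.iterrows():
        for window in [f"{s}_{a}" for s in ("before", "after") for a in st.ALIGNMENTS]:
            rate = rng.normal(20.0, 4.0)
            if effect == "distance" and tr["distance"] == "far":
                rate += 10.0
            if effect == "pos_x_time" and "left" in tr["position"] and window.startswith("after"):
                rate += 8.0
            rows.append(
                {"unit": "u0", "area": "M1", "trial_id": tr["trial_id"],
                 "distance": tr["distance"], "position": tr["position"],
                 "window": window, "rate": rate}
            )
    return pd.DataFrame(rows)


def test_injected_distance_effect_detected(correct_trials, rng):
    out = st.anova_modulation(_null_rates(correct_trials, rng, effect="distance"))
    assert out.loc[0, "p_C(distance)"] < 0.001
    assert bool(out.loc[0, "task_responsive"])


def test_position_interaction_flags_position_responsive(correct_trials, rng):
    hits = 0
    for i in range(5):
        r = np.random.default_rng(500 + i)
        out = st.anova_modulation(_null_rates(correct_trials, r, effect="pos_x_time"))
        assert bool(out.loc[0, "position_responsive"])
        hits += out.loc[0, "p_C(distance)"] < 0.05
    assert hits <= 2  # distance stays near its nominal null rate


def test_null_false_positive_rate_is_nominal_familywise(correct_trials):
    n_sims, flags = 60, 0
    for i in range(n_sims):
        r = np.random.default_rng(900 + i)
        out = st.anova_modulation(_null_rates(correct_trials, r))
        flags += int(out.loc[0, "task_responsive"])
    expected = 1.0 - 0.95**7
    se = np.sqrt(expected * (1 - expected) / n_sims)
    assert abs(flags / n_sims - expected) < 4 * se


def test_sparse_design_skipped(correct_trials, rng):
    rates = _null_rates(correct_trials.head(3), rng)
    out = st.anova_modulation(rates)
    assert out.loc[0, "skipped"] != ""


# ---------------------------------------------------------------------------
# binned features


def test_bin_rates_arithmetic_and_overlap(correct_trials):
    tr = correct_trials.head(1)
    t0 = tr["cue_off"].iloc[0]
    spikes = pd.DataFrame(
        {"unit": "u0", "area": "M1", "trial_id": tr["trial_id"].iloc[0],
         "time_ms": t0 + np.array([150.0, 250.0, 350.0])}
    )
    bins = st.bin_firing_rates(spikes, tr, "cue_off", (-200.0, 700.0))
    assert np.allclose(np.diff(bins.centers_ms), 100.0)
    assert bins.bin_at(100.0, 400.0)[0, 0] == 10.0  # 3 spikes / 0.3 s
    with pytest.raises(ValueError):
        bins.bin_at(95.0, 395.0)


# ---------------------------------------------------------------------------
# decoding


def test_separable_features_decode_perfectly(rng):
    y = np.array(["left"] * 30 + ["right"] * 30)
    X = np.where((y == "left")[:, None], 1.0, -1.0) + rng.normal(0, 0.05, (60, 4))
    acc, _ = st.decode_direction(X, y, k_folds=10, seed=0)
    assert acc == 1.0


def test_null_features_decode_at_chance(rng):
    y = np.array(["left", "right"] * 100)
    X = rng.standard_normal((200, 8))
    acc, _ = st.decode_direction(X, y, k_folds=20, seed=1)
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 200)


def test_accuracy_matches_bayes_oracle(rng):
    n, d = 400, 32
    y = np.array(["left"] * (n // 2) + ["right"] * (n // 2))
    mu = np.full(d, 0.5)
    X = rng.standard_normal((n, d)) + np.where((y == "left")[:, None], mu, -mu)
    acc, _ = st.decode_direction(X, y, k_folds=20, seed=2)
    # Monte-Carlo Bayes rate of the generating model (known optimal rule)
    Xt = rng.standard_normal((20000, d)) + np.concatenate(
        [np.tile(mu, (10000, 1)), np.tile(-mu, (10000, 1))]
    )
    yt = np.array([1] * 10000 + [-1] * 10000)
    bayes = np.mean(np.sign(Xt @ mu) == yt)
    assert abs(acc - bayes) < 0.05


def test_decoding_invariant_to_channel_permutation_and_affine(rng):
    y = np.array(["left", "right"] * 25)
    X = rng.standard_normal((50, 6)) + np.where((y == "left")[:, None], 0.4, -0.4)
    folds = st.make_folds(y, 10, seed=3)
    acc, _ = st.decode_direction(X, y, folds=folds)
    perm = rng.permutation(6)
    acc_perm, _ = st.decode_direction(X[:, perm], y, folds=folds)
    scale = rng.uniform(0.5, 3.0, 6)
    offset = rng.normal(0, 5, 6)
    acc_affine, _ = st.decode_direction(X * scale + offset, y, folds=folds)
    assert acc == pytest.approx(acc_perm, abs=1e-12)
    assert acc == pytest.approx(acc_affine, abs=1e-9)


def test_folds_deterministic_and_stratified():
    y = np.array(["left"] * 40 + ["right"] * 40)
    a = st.make_folds(y, 20, seed=4)
    b = st.make_folds(y, 20, seed=4)
    assert all(np.array_equal(x, z) for x, z in zip(a, b))
    for fold in a:
        labels = y[fold]
        assert (labels == "left").sum() == (labels == "right").sum() == 2


def test_folds_reduced_when_class_too_small(caplog):
    y = np.array(["left"] * 5 + ["right"] * 40)
    folds = st.make_folds(y, 20, seed=5)
    assert len(folds) == 5


def test_permutation_p_value_definitions(rng):
    y = np.array(["left", "right"] * 20)
    X = rng.standard_normal((40, 4)) + np.where((y == "left")[:, None], 2.0, -2.0)
    res = st.permutation_null_decoding(X, y, n_perm=50, k_folds=5, seed=6)
    assert res.p == 0.0  # observed above every null sample
    assert res.accuracy > res.threshold
    null = np.arange(100.0)
    assert float(np.mean(null > np.median(null))) == pytest.approx(0.5, abs=0.01)


def test_permutation_requires_positive_n(rng):
    y = np.array(["left", "right"] * 10)
    with pytest.raises(ValueError):
        st.permutation_null_decoding(rng.standard_normal((20, 2)), y, n_perm=0)


# ---------------------------------------------------------------------------
# modulation statistic


def test_modulation_trivial_values():
    y = np.array(["left", "left", "right", "right"])
    rates = np.array([[10.0, 10.0, 6.0, 6.0], [3.0, 3.0, 9.0, 9.0]])
    assert st.firing_rate_modulation(rates, y) == pytest.approx(5.0)  # (4 + 6) / 2
    same = np.ones((3, 4))
    assert st.firing_rate_modulation(same, y) == 0.0


def test_modulation_converges_to_folded_normal_oracle(rng):
    depth, sigma, n_trials, n_units = 4.0, 6.0, 400, 200
    y = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials // 2))
    shift = np.where(y == "left", depth / 2.0, -depth / 2.0)
    rates = rng.normal(20.0, sigma, (n_units, n_trials)) + shift
    obs = st.firing_rate_modulation(rates, y)
    # analytic folded-normal mean of the left-right difference estimator
    sd = np.sqrt(sigma**2 * (2.0 / (n_trials // 2)))
    oracle = sd * np.sqrt(2 / np.pi) * np.exp(-(depth**2) / (2 * sd**2)) + depth * (
        1 - 2 * sps.norm.cdf(-depth / sd)
    )
    se = sd / np.sqrt(n_units)  # conservative spread over units
    assert abs(obs - oracle) < 2 * se + 0.02 * oracle


def test_modulation_permutation_strong_tuning_and_determinism(rng):
    y = np.array(["left", "right"] * 30)
    rates = rng.normal(15.0, 2.0, (10, 60)) + np.where(y == "left", 5.0, -5.0)
    a = st.permutation_null_modulation(rates, y, n_perm=200, seed=7)
    b = st.permutation_null_modulation(rates, y, n_perm=200, seed=7)
    assert a.p == 0.0
    assert np.array_equal(a.null, b.null)


# ---------------------------------------------------------------------------
# Bonferroni


@pytest.mark.parametrize("p,m,expected", [(0.01, 12, 0.12), (0.2, 12, 1.0), (0.3, 1, 0.3)])
def test_bonferroni_examples(p, m, expected):
    assert st.bonferroni(p, m) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True)
@given(hst.floats(0, 1), hst.integers(1, 20), hst.integers(1, 20))
def test_bonferroni_composition(p, a, b):
    double = st.bonferroni(st.bonferroni(p, a), b)
    single = st.bonferroni(p, a * b)
    if p * a <= 1.0:
        assert double == pytest.approx(single)
    else:
        assert double == 1.0 and single == 1.0


# ---------------------------------------------------------------------------
# passage comparison


def _mod_stat(data):
    rates, labels = data
    return st.firing_rate_modulation(rates, labels)


def test_passage_unbalanced_blocks_show_no_size_artifact(rng):
    ps = []
    for i in range(30):
        r = np.random.default_rng(2000 + i)
        y_a = np.array(["left", "right"] * 40)
        y_b = np.array(["left", "right"] * 15)
        shift_a = np.where(y_a == "left", 3.0, -3.0)
        shift_b = np.where(y_b == "left", 3.0, -3.0)
        a = r.normal(20, 4, (12, 80)) + shift_a
        b = r.normal(20, 4, (12, 30)) + shift_b
        res = st.compare_passage(_mod_stat, (a, y_a), (b, y_b), n_perm=100, seed=i)
        ps.append(res.p)
    assert 0.3 <= float(np.median(ps)) <= 0.8


def test_passage_effect_power_grows_with_depth(rng):
    y = np.array(["left", "right"] * 30)
    base = rng.normal(20, 3, (10, 60))
    ps = []
    for depth in (0.0, 3.0, 8.0):
        a = base + np.where(y == "left", depth, -depth)
        b = rng.normal(20, 3, (10, 60))
        res = st.compare_passage(_mod_stat, (a, y), (b, y), n_perm=200, seed=9)
        ps.append(res.p)
    assert ps[2] < 0.05
    assert ps[2] <= ps[1] <= ps[0] + 0.2


def test_passage_empty_block_rejected(rng):
    y = np.array(["left", "right"] * 5)
    with pytest.raises(ValueError):
        st.compare_passage(_mod_stat, (rng.normal(size=(3, 10)), y), (np.empty((3, 0)), np.array([])))
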