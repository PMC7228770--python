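"""Windowed firing rates, ANOVA responsiveness, SVM direction decoding, and
permutation inference for the walk-and-reach population analyses.

Conventions: firing rates are spike counts in half-open windows divided by
window length. Direction labels group the two left positions against the two
right positions. Cross-validation folds are stratified by class, fixed once
per analysis run, and reused across all time bins and permutation
surrogates. Permutation p-values are the fraction of the null distribution
strictly above the observed value (one-tailed) or above it in absolute value
(two-tailed); no +1 smoothing, so p = 0 is attainable. Bonferroni correction
multiplies raw p-values by the number of tests and caps at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.svm import SVC

from .config import substream

__all__ = [
    "direction_labels",
    "window_firing_rates",
    "anova_modulation",
    "bin_firing_rates",
    "FeatureBins",
    "make_folds",
    "decode_direction",
    "permutation_null_decoding",
    "DecodingResult",
    "firing_rate_modulation",
    "permutation_null_modulation",
    "bonferroni",
    "compare_passage",
]

log = logging.getLogger(__name__)

ALIGNMENTS = ("cue_on", "go", "release", "acquisition")


def direction_labels(trials: pd.DataFrame) -> np.ndarray:
    """left/right category per trial: outer-left and mid-left vs the rest."""
    return np.where(trials["position"].str.contains("left"), "left", "right")


# ---------------------------------------------------------------------------
# windowed rates and ANOVA screening


def _count_in_windows(
    spikes: pd.DataFrame, trials: pd.DataFrame, starts: pd.Series, width_ms: float
) -> pd.DataFrame:
    """Spike counts per (unit, trial) in per-trial half-open windows."""
    units = sorted(spikes["unit"].unique())
    t0 = trials["trial_id"].map(starts.to_dict()) if isinstance(starts, pd.Series) else starts
    lookup = dict(zip(trials["trial_id"], t0))
    s = spikes[["unit", "trial_id", "time_ms"]].copy()
    s["t0"] = s["trial_id"].map(lookup)
    inside = (s["time_ms"] >= s["t0"]) & (s["time_ms"] < s["t0"] + width_ms)
    counts = (
        s[inside].groupby(["unit", "trial_id"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=units, columns=trials["trial_id"], fill_value=0)
    return counts


def window_firing_rates(
    spikes: pd.DataFrame, trials: pd.DataFrame, window_ms: float = 500.0
) -> pd.DataFrame:
    """Firing rates in 500 ms windows before and after each alignment event.

    For every trial and unit, eight windows are formed: [a-500, a) and
    [a, a+500) for each alignment in (cue_on, go, release, acquisition).
    Trials missing an alignment timestamp are omitted for that alignment with
    a log entry. Returns a tidy table with columns unit, area, trial_id,
    alignment, side, rate, distance, position, block.
    """
    area_of = dict(zip(spikes["unit"], spikes["area"])) if "area" in spikes else {}
    frames = []
    for alignment in ALIGNMENTS:
        anchor = trials[alignment]
        ok = anchor.notna()
        if (~ok).any():
            log.info("%d trials lack %s; windows omitted", int((~ok).sum()), alignment)
        sub = trials[ok]
        for side, t0 in (("before", sub[alignment] - window_ms), ("after", sub[alignment])):
            counts = _count_in_windows(spikes, sub, pd.Series(t0.values, index=sub.index), window_ms)
            tidy = counts.stack().rename("count").reset_index()
            tidy.columns = ["unit", "trial_id", "count"]
            tidy["rate"] = tidy["count"] / (window_ms / 1000.0)
            tidy["alignment"] = alignment
            tidy["side"] = side
            frames.append(tidy.drop(columns="count"))
    out = pd.concat(frames, ignore_index=True)
    meta = trials.set_index("trial_id")[["distance", "position", "block"]]
    out = out.join(meta, on="trial_id")
    out["area"] = out["unit"].map(area_of).fillna("")
    out["window"] = out["side"] + "_" + out["alignment"]
    return out


def anova_modulation(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-unit 3-way fixed-effects ANOVA: distance (2) x position (4) x
    time window (8), all interactions, Type II sums of squares.

    A unit is ``task_responsive`` if any of the seven effects is significant
    at ``alpha`` and ``position_responsive`` if the position main effect or
    any interaction involving position is. Units with empty design cells are
    skipped with a reason.
    """
    results = []
    terms = [
        "C(distance)",
        "C(position)",
        "C(window)",
        "C(distance):C(position)",
        "C(distance):C(window)",
        "C(position):C(window)",
        "C(distance):C(position):C(window)",
    ]
    position_terms = [t for t in terms if "position" in t]
    for unit, df in rates.groupby("unit"):
        cells = df.groupby(["distance", "position", "window"], observed=True).size()
        if len(cells) < 2 * 4 * 8 or (cells < 2).any():
            results.append({"unit": unit, "skipped": "empty or singleton design cells"})
            continue
        model = smf.ols("rate ~ C(distance) * C(position) * C(window)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        pvals = {t: float(table.loc[t, "PR(>F)"]) for t in terms}
        row = {"unit": unit, "skipped": ""}
        row.update({f"p_{t}": p for t, p in pvals.items()})
        row["task_responsive"] = any(p < alpha for p in pvals.values())
        row["position_responsive"] = any(pvals[t] < alpha for t in position_terms)
        if "area" in df:
            row["area"] = df["area"].iloc[0]
        results.append(row)
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# binned features for decoding


@dataclass
class FeatureBins:
    """Per-bin firing-rate feature tensors on an alignment-relative timeline."""

    features: np.ndarray  # (n_bins, n_trials, n_units) spikes/s
    centers_ms: np.ndarray  # bin centers relative to the alignment event
    alignment: str
    units: list[str]
    trial_ids: np.ndarray

    def bin_at(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Features of the bin whose extent matches [start, stop) (ms)."""
        center = (start_ms + stop_ms) / 2.0
        i = int(np.argmin(np.abs(self.centers_ms - center)))
        if abs(self.centers_ms[i] - center) > 1e-6:
            raise ValueError(f"no bin centered at {center} ms")
        return self.features[i]


def bin_firing_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    alignment: str,
    span_ms: tuple[float, float],
    bin_ms: float = 300.0,
    step_ms: float = 100.0,
) -> FeatureBins:
    """Overlapping firing-rate bins (300 ms wide, 100 ms steps) along an
    alignment-relative timeline.

    ``span_ms`` gives the start of the first bin and the end of the last bin
    relative to the alignment event. The designated test bins of the study
    are 100-400 ms after cue offset (memory) and 300-0 ms before target
    acquisition (movement).
    """
    ok = trials[alignment].notna()
    sub = trials[ok].reset_index(drop=True)
    units = sorted(spikes["unit"].unique())
    starts = np.arange(span_ms[0], span_ms[1] - bin_ms + 0.5 * step_ms, step_ms)
    feats = np.zeros((len(starts), len(sub), len(units)))
    anchor = dict(zip(sub["trial_id"], sub[alignment]))
    s = spikes[spikes["trial_id"].isin(anchor)].copy()
    s["rel"] = s["time_ms"] - s["trial_id"].map(anchor)
    unit_idx = {u: j for j, u in enumerate(units)}
    trial_idx = {t: i for i, t in enumerate(sub["trial_id"])}
    ui = s["unit"].map(unit_idx).to_numpy()
    ti = s["trial_id"].map(trial_idx).to_numpy()
    rel = s["rel"].to_numpy()
    for b, b0 in enumerate(starts):
        inside = (rel >= b0) & (rel < b0 + bin_ms)
        np.add.at(feats[b], (ti[inside], ui[inside]), 1.0)
    feats /= bin_ms / 1000.0
    return FeatureBins(
        features=feats,
        centers_ms=starts + bin_ms / 2.0,
        alignment=alignment,
        units=units,
        trial_ids=sub["trial_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# decoding


def make_folds(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Class-stratified fold assignment, fixed for the whole analysis run.

    If a class has fewer than ``k`` members, k is reduced with a warning.
    Returns a list of test-index arrays.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    k_eff = min(k, counts.min())
    if k_eff < k:
        log.warning("reducing folds from %d to %d (smallest class)", k, k_eff)
    rng = substream(seed, "folds")
    folds: list[list[int]] = [[] for _ in range(k_eff)]
    for c in classes:
        idx = np.where(labels == c)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k_eff].append(j)
    return [np.sort(np.array(f)) for f in folds]


def _fold_accuracy(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], C: float) -> float:
    n = len(y)
    accs = []
    all_idx = np.arange(n)
    for test in folds:
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        if len(np.unique(y[train])) < 2:
            log.warning("fold skipped: one class absent in training split")
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train] - mu) / sd, y[train])
        accs.append(float(np.mean(clf.predict((X[test] - mu) / sd) == y[test])))
    return float(np.mean(accs))


def decode_direction(
    features: np.ndarray,
    labels: np.ndarray,
    k_folds: int = 20,
    C: float = 1.0,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Fold-mean accuracy of a linear SVM (C = 1, per-channel z-scoring fit
    on the training folds only). Returns (accuracy, folds) so the same folds
    can be reused across time bins and surrogates."""
    y = np.asarray(labels)
    if folds is None:
        folds = make_folds(y, k_folds, seed=seed)
    return _fold_accuracy(np.asarray(features, float), y, folds, C), folds


@dataclass
class DecodingResult:
    """Observed accuracy, permutation null, threshold, and p-values."""

    accuracy: float
    null: np.ndarray
    threshold: float
    p: float
    p_corrected: float = np.nan
    folds: list[np.ndarray] = field(default_factory=list)


def permutation_null_decoding(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 500,
    k_folds: int = 20,
    C: float = 1.0,
    seed: int = 0,
    alpha: float = 0.05,
    folds: list[np.ndarray] | None = None,
) -> DecodingResult:
    """One-tailed permutation test of decoding accuracy above chance.

    Each surrogate permutes the trial-to-direction assignment and recomputes
    the full cross-validated accuracy with the observed fold assignment. The
    permutation is applied to the feature rows rather than the label vector:
    the two are the same relabeling null, but permuting the rows keeps every
    surrogate's folds stratified exactly like the observed ones, so the null
    is exchangeable with the observed statistic (permuting the labels alone
    de-stratifies the surrogate folds and biases the null low). p = (# null
    > observed) / n_perm; the significance threshold is the (1 - alpha) null
    quantile.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if folds is None:
        folds = make_folds(y, k_folds, seed=seed)
    obs = _fold_accuracy(X, y, folds, C)
    rng = substream(seed, "stats")
    null = np.array(
        [_fold_accuracy(X[rng.permutation(len(y))], y, folds, C) for _ in range(n_perm)]
    )
    return DecodingResult(
        accuracy=obs,
        null=null,
        threshold=float(np.quantile(null, 1.0 - alpha)),
        p=float(np.mean(null > obs)),
        folds=folds,
    )


# ---------------------------------------------------------------------------
# population firing-rate modulation


def firing_rate_modulation(rates: np.ndarray, labels: np.ndarray) -> float:
    """Population statistic: mean over units of |mean rate(left) - mean
    rate(right)| for a (units x trials) rate matrix."""
    y = np.asarray(labels)
    left = rates[:, y == "left"]
    right = rates[:, y == "right"]
    if left.shape[1] == 0 or right.shape[1] == 0:
        raise ValueError("both directions must be present")
    return float(np.mean(np.abs(left.mean(axis=1) - right.mean(axis=1))))


def permutation_null_modulation(
    rates: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DecodingResult:
    """One-tailed permutation test of the population modulation statistic.

    Surrogates permute the shared trial direction labels (all units recorded
    simultaneously see the same permutation). p = fraction of null above the
    observed statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    R = np.asarray(rates, float)
    y = np.asarray(labels)
    obs = firing_rate_modulation(R, y)
    rng = substream(seed, "stats")
    is_left = (y == "left").astype(float)
    n_left = is_left.sum()
    n_right = len(y) - n_left
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(is_left)
        mean_l = R @ perm / n_left
        mean_r = R @ (1.0 - perm) / n_right
        null[i] = np.mean(np.abs(mean_l - mean_r))
    return DecodingResult(
        accuracy=obs,
        null=null,
        threshold=float(np.quantile(null, 1.0 - alpha)),
        p=float(np.mean(null > obs)),
    )


def bonferroni(p: float, multiplier: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * multiplier)."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    return min(1.0, p * multiplier)


# ---------------------------------------------------------------------------
# passage control


def compare_passage(
    stat_fn,
    data_with: tuple,
    data_without: tuple,
    n_perm: int = 500,
    seed: int = 0,
) -> DecodingResult:
    """Two-tailed permutation test for a block effect (passage vs none).

    ``stat_fn(data)`` maps a per-trial dataset tuple (features-or-rates,
    labels) to a scalar statistic (decoding accuracy or population
    modulation). The observed value is stat(with) - stat(without); surrogates
    permute the block assignment over the pooled trials keeping block sizes.
    p is the fraction of the null at least as extreme in absolute value.
    """
    Xw, yw = data_with
    Xo, yo = data_without
    n_w, n_o = len(yw), len(yo)
    if n_w == 0 or n_o == 0:
        raise ValueError("both blocks must be non-empty")
    # trials stack along the first axis for features, second for rate matrices
    trial_axis = 0 if Xw.shape[0] == n_w else 1
    X = np.concatenate([Xw, Xo], axis=trial_axis)
    y = np.concatenate([yw, yo])
    obs = stat_fn((Xw, yw)) - stat_fn((Xo, yo))
    rng = substream(seed, "stats")
    null = np.empty(n_perm)
    idx = np.arange(n_w + n_o)
    for i in range(n_perm):
        perm = rng.permutation(idx)
        a, b = perm[:n_w], perm[n_w:]
        take = (lambda s: X[s]) if trial_axis == 0 else (lambda s: X[:, s])
        null[i] = stat_fn((take(a), y[a])) - stat_fn((take(b), y[b]))
    return DecodingResult(
        accuracy=obs,
        null=null,
        threshold=float(np.quantile(np.abs(null), 0.95)),
        p=float(np.mean(np.abs(null) >= abs(obs))),
    )
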