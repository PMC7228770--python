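"""Wireless data-loss detection, broadband conditioning, spike extraction,
and spike-density estimation.

Conditioning chain: sliding-window median high-pass (91 samples), zero-phase
second-order Butterworth low-pass at 5 kHz, and per-array PCA common-noise
removal. Spikes are threshold crossings on the conditioned signal (multi-unit
by construction); spike-density functions convolve spike trains with a
unit-integral Gaussian kernel (sigma 50 ms) sampled at 200 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .containers import BroadbandBlock, LossMask

__all__ = [
    "detect_data_loss",
    "filter_trials_by_loss",
    "median_highpass",
    "butterworth_lowpass",
    "remove_common_noise_pca",
    "SpikeEvent",
    "extract_spikes",
    "spike_density",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# wireless data loss


def _unchanged_runs(check: np.ndarray, min_run: int) -> np.ndarray:
    """Mask samples lying in maximal runs of >= min_run consecutive samples
    whose value (on every check channel) repeats the previous sample."""
    n = check.shape[1]
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    unchanged = (np.diff(check, axis=1) == 0).all(axis=0)  # position t <-> sample t vs t-1
    # run-length encode the unchanged positions
    padded = np.concatenate([[False], unchanged, [False]])
    starts = np.where(~padded[:-1] & padded[1:])[0]
    ends = np.where(padded[:-1] & ~padded[1:])[0]
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s + 1 : e + 1] = True  # position t refers to sample index t+? (diff offset)
    return mask


def detect_data_loss(
    block: BroadbandBlock, n_check_channels: int = 32, min_run: int = 4
) -> LossMask:
    """Detect sample-and-hold dropouts per headstage.

    A sample is loss-flagged iff it belongs to a maximal run of at least
    ``min_run`` consecutive samples over which none of the first
    ``n_check_channels`` of the headstage changes value relative to its
    predecessor. The combined mask is the union over headstages: the
    192-channel record counts as lost whenever even one headstage lost data.
    """
    masks = {}
    for hs, channels in block.headstage_map.items():
        if len(channels) < n_check_channels:
            raise ValueError(f"headstage {hs} has fewer than {n_check_channels} channels")
        check = block.data[channels[:n_check_channels]]
        masks[hs] = _unchanged_runs(check, min_run)
    return LossMask(masks, rate=block.rate, t_start_ms=block.t_start_ms)


def filter_trials_by_loss(
    trials: pd.DataFrame,
    fractions: pd.Series,
    max_fraction: float = 0.05,
) -> pd.DataFrame:
    """Keep trials whose data-loss fraction is strictly smaller than 5%."""
    frac = trials["trial_id"].map(fractions)
    keep = frac < max_fraction
    return trials[keep.fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# conditioning


def median_highpass(signal: np.ndarray, window: int = 91) -> np.ndarray:
    """Subtract a centered sliding-window median (windows truncate at edges)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = np.asarray(signal, dtype=float)
    n = len(x)
    half = window // 2
    med = np.empty(n)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        med[half : n - half] = np.median(sw, axis=1)
    for i in range(min(half, n)):
        med[i] = np.median(x[: i + half + 1])
    for i in range(max(n - half, 0), n):
        med[i] = np.median(x[i - half :])
    return x - med


def butterworth_lowpass(
    signal: np.ndarray, cutoff: float = 5000.0, order: int = 2, rate: float = 30000.0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    The two passes square the magnitude response, so a sinusoid at the cutoff
    is attenuated to |H|^2 = 1/2 in amplitude. Reflective padding of three
    filter orders is used at the edges.
    """
    if cutoff >= rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff, fs=rate)
    return filtfilt(b, a, np.asarray(signal, float), padtype="even", padlen=3 * order)


def remove_common_noise_pca(
    array_block: np.ndarray,
    var_share: float = 0.30,
    loading_uniformity: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove common-signal principal components from one array's channels.

    Components are computed across channels (channels as variables). A
    component is classified "common" when its variance share exceeds
    ``var_share`` and its channel-loading uniformity min|l|/max|l| exceeds
    ``loading_uniformity`` — a broadly, evenly loaded component is shared
    noise rather than a single channel's spikes. Classified components are
    zeroed before back-projection. Returns (denoised block, report) where the
    report lists every component's variance share, uniformity, and removal
    flag.
    """
    X = np.asarray(array_block, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two channels")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    # economy SVD: columns of U are channel-space components
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    shares = var / total if total > 0 else var
    nonnull = s > 1e-12 * (s[0] if len(s) else 1.0)
    uniform = np.zeros(len(s))
    absU = np.abs(U)
    with np.errstate(invalid="ignore", divide="ignore"):
        uniform[nonnull] = absU[:, nonnull].min(axis=0) / absU[:, nonnull].max(axis=0)
    remove = nonnull & (shares > var_share) & (uniform > loading_uniformity)
    report = pd.DataFrame(
        {
            "component": np.arange(len(s)),
            "variance_share": shares,
            "loading_uniformity": uniform,
            "removed": remove,
        }
    )
    if remove.any():
        keep = ~remove
        Xc = U[:, keep] @ (U[:, keep].T @ Xc)
    return Xc + mean, report


# ---------------------------------------------------------------------------
# spikes


@dataclass
class SpikeEvent:
    """One threshold-crossing event with its waveform snippet."""

    channel: int
    sample: int
    time_s: float
    polarity: str
    waveform: np.ndarray


def extract_spikes(
    signal: np.ndarray,
    k: float = 4.0,
    polarity: str = "neg",
    snippet: tuple[int, int] = (12, 20),
    deadtime: int = 30,
    rate: float = 30000.0,
    channel: int = 0,
) -> list[SpikeEvent]:
    """Extract threshold-crossing events from one conditioned channel.

    The threshold is ``k`` times the robust noise s.d. (median absolute
    deviation / 0.6745). A crossing opens an event at the extremum within
    ``deadtime`` samples; crossings closer than ``deadtime`` to the previous
    extremum are merged into it. Waveform snippets are cut around the
    extremum; events whose snippet would leave the signal are dropped.
    """
    x = np.asarray(signal, dtype=float)
    med = np.median(x)
    sigma = np.median(np.abs(x - med)) / 0.6745
    if sigma <= 0:
        return []
    pre, post = snippet
    events: list[SpikeEvent] = []

    def scan(sign: float, label: str) -> None:
        # sign=+1 scans negative deflections, sign=-1 positive ones
        y = sign * (x - med)
        over = y < -k * sigma  # crossings on the signed trace
        idx = np.where(over)[0]
        i = 0
        while i < len(idx):
            start = idx[i]
            stop = min(start + deadtime, len(x))
            ext = start + int(np.argmin(y[start:stop]))
            # merge crossings within the dead time
            j = i
            while j + 1 < len(idx) and idx[j + 1] <= ext + deadtime:
                j += 1
            if ext - pre >= 0 and ext + post <= len(x):
                events.append(
                    SpikeEvent(
                        channel=channel,
                        sample=ext,
                        time_s=ext / rate,
                        polarity=label,
                        waveform=x[ext - pre : ext + post].copy(),
                    )
                )
            i = j + 1

    if polarity in ("neg", "both"):
        scan(1.0, "neg")
    if polarity in ("pos", "both"):
        scan(-1.0, "pos")
    events.sort(key=lambda e: e.sample)
    return events


def spike_density(
    spike_times_s: np.ndarray,
    t_start_s: float,
    t_stop_s: float,
    sigma_ms: float = 50.0,
    out_rate: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-density function: unit-integral Gaussian kernel on a 200 Hz grid.

    rate(t) = sum over spikes of N(t - t_spike; sigma); the integral of the
    density over a wide window equals the spike count. Returns (time grid in
    s, rate in spikes/s).
    """
    if sigma_ms <= 0:
        raise ValueError("sigma must be > 0")
    sigma = sigma_ms / 1000.0
    grid = np.arange(t_start_s, t_stop_s + 0.5 / out_rate, 1.0 / out_rate)
    times = np.asarray(spike_times_s, dtype=float)
    rate = np.zeros(len(grid))
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for chunk in np.array_split(times, max(1, len(times) // 512)):
        if len(chunk) == 0:
            continue
        d = grid[:, None] - chunk[None, :]
        rate += norm * np.exp(-0.5 * (d / sigma) ** 2).sum(axis=1)
    return grid, rate
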