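"""Broadband (30 ksps) signal synthesis and wireless-dropout injection.

Spikes insert biphasic templates on their channels; independent Gaussian
noise is added per channel and a common signal (line-frequency sinusoid plus
band-limited Gaussian) identically to all channels of an array. Output is
quantized to int16 samples (1 LSB = 0.25 uV equivalent, fixed).

Wireless data loss is emulated per headstage as sample-and-hold: during a
loss segment every channel of the headstage repeats its last value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import substream
from ..containers import BroadbandBlock, LossMask

__all__ = [
    "DropoutSpec",
    "biphasic_template",
    "common_signal",
    "synthesize_broadband",
    "inject_data_loss",
]


@dataclass(frozen=True)
class DropoutSpec:
    """Expected per-headstage loss fraction and geometric segment lengths."""

    loss_fraction: float = 0.03
    mean_segment: float = 600.0  # samples; >= 4 keeps segments detectable

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss fraction must be in [0, 1)")
        if self.mean_segment < 4:
            raise ValueError("mean segment length must be >= 4 samples")


def biphasic_template(
    amplitude: float = 120.0, rate: float = 30000.0, duration_ms: float = 1.2
) -> np.ndarray:
    """Biphasic extracellular spike shape in integer LSBs (negative-leading)."""
    n = int(round(duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate * 1000.0
    wave = -np.exp(-(((t - 0.3) / 0.12) ** 2)) + 0.45 * np.exp(-(((t - 0.65) / 0.2) ** 2))
    return amplitude * wave / np.abs(wave).max()  # peak-normalized, negative-leading


def common_signal(
    n_samples: int,
    rate: float = 30000.0,
    line_freq: float = 50.0,
    line_amp: float = 30.0,
    band_amp: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Line-frequency sinusoid plus low-pass-filtered Gaussian process."""
    from scipy.signal import butter, filtfilt

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 811]))
    t = np.arange(n_samples) / rate
    sig = line_amp * np.sin(2 * np.pi * line_freq * t)
    if band_amp > 0:
        b, a = butter(2, 500.0, fs=rate)
        noise = filtfilt(b, a, rng.standard_normal(n_samples))
        sd = noise.std()
        if sd > 0:
            sig = sig + band_amp * noise / sd
    return sig


def synthesize_broadband(
    spikes: pd.DataFrame,
    n_channels: int,
    duration_ms: float,
    templates: dict[str, np.ndarray] | np.ndarray | None = None,
    channel_of_unit: dict[str, int] | None = None,
    noise_sd: float = 10.0,
    common: np.ndarray | None = None,
    rate: float = 30000.0,
    t_start_ms: float = 0.0,
    headstage_map: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> BroadbandBlock:
    """Render spike times into a quantized multi-channel broadband block.

    ``spikes`` is the tidy (unit, time_ms) table of the spike generator;
    units map one-to-one onto channels unless ``channel_of_unit`` is given.
    ``common`` is added identically to every channel.
    """
    n_samples = int(round(duration_ms / 1000.0 * rate))
    rng = substream(seed, "broadband")
    data = (
        rng.normal(0.0, noise_sd, size=(n_channels, n_samples)) if noise_sd > 0
        else np.zeros((n_channels, n_samples))
    )
    if common is not None:
        if len(common) != n_samples:
            raise ValueError("common signal length must match the block")
        data += common[None, :]

    if templates is None:
        templates = biphasic_template(rate=rate)
    units = list(dict.fromkeys(spikes["unit"])) if len(spikes) else []
    if channel_of_unit is None:
        channel_of_unit = {u: i % n_channels for i, u in enumerate(units)}
    for u in units:
        tpl = templates[u] if isinstance(templates, dict) else templates
        if len(tpl) > n_samples:
            raise ValueError("template longer than block")
        ch = channel_of_unit[u]
        times = spikes.loc[spikes["unit"] == u, "time_ms"].to_numpy()
        idx = np.round((times - t_start_ms) / 1000.0 * rate).astype(int)
        for i0 in idx:
            if i0 < 0 or i0 + len(tpl) > n_samples:
                continue
            data[ch, i0 : i0 + len(tpl)] += tpl
    q = np.clip(np.round(data), -32768, 32767).astype(np.int16)
    return BroadbandBlock(q, rate=rate, t_start_ms=t_start_ms, headstage_map=headstage_map or {})


def inject_data_loss(
    block: BroadbandBlock,
    spec: DropoutSpec | dict[str, DropoutSpec],
    seed: int = 0,
) -> tuple[BroadbandBlock, LossMask]:
    """Inject sample-and-hold dropouts per headstage; return block + mask.

    Loss segments start as a Bernoulli process tuned to the target loss
    fraction and have geometric lengths (mean ``mean_segment``, minimum 4
    samples). Within a segment every channel of the headstage repeats its
    value from the last pre-segment sample.
    """
    rng = substream(seed, "dropout")
    n = block.n_samples
    data = block.data.copy()
    masks: dict[str, np.ndarray] = {}
    for hs, channels in block.headstage_map.items():
        s = spec[hs] if isinstance(spec, dict) else spec
        mask = np.zeros(n, dtype=bool)
        if s.loss_fraction > 0:
            p_start = s.loss_fraction / s.mean_segment
            t = 1  # hold needs a pre-segment sample to repeat
            while t < n:
                if rng.random() < p_start:
                    length = max(4, int(rng.geometric(1.0 / s.mean_segment)))
                    end = min(t + length, n)
                    mask[t:end] = True
                    data[np.ix_(channels, np.arange(t, end))] = data[channels, t - 1][:, None]
                    t = end + 1  # ensure a changing sample separates segments
                else:
                    t += 1
        masks[hs] = mask
    out = BroadbandBlock(
        data,
        rate=block.rate,
        channel_names=list(block.channel_names),
        headstage_map={k: v.copy() for k, v in block.headstage_map.items()},
        t_start_ms=block.t_start_ms,
    )
    return out, LossMask(masks, rate=block.rate, t_start_ms=block.t_start_ms)
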