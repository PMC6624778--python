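"""Synthetic oddball speller sessions with known ground truth.

The simulator emulates a copy-spelling session: per trial (letter), ``k_a``
random 12-permutations of row/column flashes at the standard cadence
(0.125 s flash + 0.125 s rest), on top of per-channel background noise.
After every flash of the attended letter's row or column, a positive
unimodal deflection — a half-sine of 400 ms span peaking ``p300_latency_s``
(with uniform jitter) after onset — is added to the responsive channels.
Background noise is 1/f-shaped ("pink") Gaussian by default, since resting
EEG is low-frequency dominated and pink noise stresses the 10 Hz lowpass
realistically; white noise is available via ``noise_color``.

At the defaults (5 uV deflection on 28.1 uV background) the amplitude/SD
ratio sits at the ~-15 dB regime typical of single-epoch evoked responses.
Deflections of consecutive target flashes (onset asynchrony 0.25 s < span
0.4 s) overlap and are summed linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .eeg_io import DEFAULT_CHANNELS, EEGSession, StimulusEvent
from .speller import SpellerMatrix


@dataclass
class SimParams:
    """Generative settings of one simulated session."""

    word: str = "WATER"
    n_channels: int = 8
    fs: float = 256.0
    k_a: int = 10
    flash_s: float = 0.125
    isi_s: float = 0.125
    p300_amp_uV: float = 5.0
    p300_latency_s: float = 0.3
    p300_span_s: float = 0.4
    latency_jitter_s: float = 0.02
    noise_sd_uV: float = 28.1
    noise_color: str = "pink"  # "pink" or "white"
    responsive_channels: Optional[Sequence[str]] = None  # None -> all
    inter_trial_s: float = 2.0
    channel_labels: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self):
        if self.flash_s + self.isi_s <= 0:
            raise ValueError("flash_s + isi_s must be positive")
        if self.p300_amp_uV < 0:
            raise ValueError("p300_amp_uV must be nonnegative")
        if self.channel_labels is None:
            base = list(DEFAULT_CHANNELS)
            while len(base) < self.n_channels:
                base.append(f"ch{len(base)}")
            self.channel_labels = base[: self.n_channels]


def snr_db(params: SimParams) -> float:
    """Deflection amplitude over background standard deviation, in dB:
    ``20 log10(p300_amp_uV / noise_sd_uV)``."""
    if params.noise_sd_uV <= 0:
        raise ValueError("noise_sd_uV must be positive")
    with np.errstate(divide="ignore"):
        return float(20.0 * np.log10(params.p300_amp_uV / params.noise_sd_uV))


def _pink_noise(rng: np.random.Generator, n: int, channels: int) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise, column per channel."""
    white = rng.standard_normal((n, channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale[:, None], n=n, axis=0)
    shaped -= shaped.mean(axis=0)
    sd = shaped.std(axis=0)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_session(params: SimParams,
                     matrix: SpellerMatrix | None = None) -> EEGSession:
    """Generate a copy-spelling session for ``params.word``.

    Every event carries ``is_target``; ``meta["target_word"]`` records the
    ground truth.  Identical parameters (including ``seed``) reproduce the
    session bit for bit.
    """
    matrix = matrix or SpellerMatrix()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    soa = params.flash_s + params.isi_s

    target_locs = [matrix.locate(ch) for ch in params.word]  # raises if absent

    events: list[StimulusEvent] = []
    t = 0.0
    for trial0, (row_l, col_l) in enumerate(target_locs):
        for seq in range(1, params.k_a + 1):
            perm = rng.permutation(12) + 1
            for loc in perm:
                onset = int(round(t * fs))
                events.append(StimulusEvent(onset, int(loc), seq, trial0 + 1,
                                            bool(loc in (row_l, col_l))))
                t += soa
        t += params.inter_trial_s
    n = int(round(t * fs))

    C = params.n_channels
    if params.noise_color == "pink":
        samples = _pink_noise(rng, n, C) * params.noise_sd_uV
    elif params.noise_color == "white":
        samples = rng.standard_normal((n, C)) * params.noise_sd_uV
    else:
        raise ValueError(f"unknown noise_color {params.noise_color!r}")

    labels = list(params.channel_labels)
    if params.responsive_channels is None:
        responsive = list(range(C))
    else:
        responsive = [labels.index(ch) for ch in params.responsive_channels]

    span = params.p300_span_s
    span_n = int(round(span * fs))
    bump_t = np.arange(span_n) / fs
    bump = np.sin(np.pi * bump_t / span)  # positive half-sine, unit peak
    for ev in events:
        if not ev.is_target or params.p300_amp_uV == 0:
            continue
        jitter = rng.uniform(-params.latency_jitter_s, params.latency_jitter_s) \
            if params.latency_jitter_s > 0 else 0.0
        peak = ev.sample_index / fs + params.p300_latency_s + jitter
        start = int(round((peak - span / 2) * fs))
        lo, hi = max(0, start), min(n, start + span_n)
        if hi <= lo:
            continue
        seg = params.p300_amp_uV * bump[lo - start:hi - start]
        for c in responsive:
            samples[lo:hi, c] += seg

    session = EEGSession(samples, fs, labels, events,
                         meta={"target_word": params.word})
    return session.validate()
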