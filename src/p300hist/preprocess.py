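"""Signal enhancement, artifact rejection, segmentation and averaging.

The enhancement chain runs, in order: mains notch, 4th-order 10 Hz lowpass
Butterworth, FIR anti-alias decimation (order 30) down to the target rate
(16 Hz by default).  Filtering is causal (forward-only), as an online
speller would run it.  Artifact rejection then drops every intensification
sequence whose epochs stray beyond +-artifact_uV on any channel, and the
surviving epochs are stacked per location and ensemble-averaged:

    x_l(n, c) = (1 / k_a') * sum_i S_i_l(n, c)

with k_a' the number of surviving sequences.  Averaging of time-locked
epochs cancels background activity that is not phase-locked to the flash,
raising the evoked-response SNR roughly by sqrt(k_a').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .eeg_io import EEGSession, RunConfig, StimulusEvent
from .errors import InvalidRateError, NoSequencesError


@dataclass
class TrialSegments:
    """Stacked epochs of one trial.

    ``segments[i, l - 1]`` is the ``[n_max x C]`` epoch of surviving sequence
    ``i`` (0-based, time order) at location ``l``.
    """

    trial_id: int
    segments: np.ndarray  # (k_a_effective, 12, n_max, C)
    k_a_effective: int
    n_max: int

    def __post_init__(self):
        k, twelve, n, _ = self.segments.shape
        assert twelve == 12 and k == self.k_a_effective and n == self.n_max
        assert self.k_a_effective >= 1


@dataclass
class AveragedTrial:
    """Per-location ensemble averages ``x[l - 1, n, c]`` of one trial."""

    trial_id: int
    x: np.ndarray  # (12, n_max, C)

    def __post_init__(self):
        assert self.x.shape[0] == 12
        if not np.all(np.isfinite(self.x)):
            raise ValueError(f"trial {self.trial_id}: non-finite averaged signal")


def enhance_signal(session: EEGSession, cfg: RunConfig) -> EEGSession:
    """Notch, lowpass and decimate a session down to ``cfg.target_fs``.

    Event sample indices are rescaled by the rate ratio, rounding toward the
    floor.  Deterministic: identical input gives bit-identical output.
    """
    fs, target = session.fs, cfg.target_fs
    if fs < 2 * target:
        raise InvalidRateError(
            f"sampling rate {fs} Hz below twice the target rate {target} Hz"
        )
    x = np.asarray(session.samples, dtype=float)

    if cfg.notch_hz and cfg.notch_hz < fs / 2:
        b, a = signal.iirnotch(cfg.notch_hz, Q=30.0, fs=fs)
        x = signal.lfilter(b, a, x, axis=0)
    sos = signal.butter(4, 10.0, btype="low", fs=fs, output="sos")
    x = signal.sosfilt(sos, x, axis=0)

    ratio = Fraction(target / fs).limit_denominator(10_000)
    if ratio.numerator == 1:
        # integer decimation with a causal order-30 FIR anti-alias filter
        x = signal.decimate(x, ratio.denominator, n=30, ftype="fir",
                            axis=0, zero_phase=False)
    else:
        # non-integer ratio (e.g. 250 -> 16 Hz): rational polyphase resampling
        x = signal.resample_poly(x, ratio.numerator, ratio.denominator, axis=0)

    scale = target / fs
    events = [
        StimulusEvent(int(np.floor(ev.sample_index * scale)), ev.location,
                      ev.sequence_index, ev.trial_id, ev.is_target)
        for ev in session.events
    ]
    return EEGSession(x, target, list(session.channel_labels), events,
                      dict(session.meta))


def reject_artifacts(session: EEGSession, cfg: RunConfig) -> EEGSession:
    """Drop every intensification sequence whose epochs exceed the threshold.

    A sequence is removed when any sample of any channel within any of its
    12 epochs ``[onset, onset + n_max)`` deviates strictly beyond
    ``+-cfg.artifact_uV``.  Samples are untouched; only the event list
    shrinks.  Trials losing *all* sequences are recorded in
    ``meta["flagged_trials"]`` and refused downstream.
    """
    n_max = int(round(session.fs * cfg.t_max))
    thr = cfg.artifact_uV
    kept: list[StimulusEvent] = []
    rejected: list[tuple[int, int]] = []
    groups: dict[tuple[int, int], list[StimulusEvent]] = {}
    for ev in session.events:
        groups.setdefault((ev.trial_id, ev.sequence_index), []).append(ev)
    for (trial, seq), evs in groups.items():
        bad = False
        for ev in evs:
            stop = min(ev.sample_index + n_max, session.n_samples)
            window = session.samples[ev.sample_index:stop]
            if window.size and np.max(np.abs(window)) > thr:
                bad = True
                break
        if bad:
            rejected.append((trial, seq))
        else:
            kept.extend(evs)
    trials_before = {ev.trial_id for ev in session.events}
    trials_after = {ev.trial_id for ev in kept}
    flagged = sorted(trials_before - trials_after)
    if flagged:
        warnings.warn(f"trials {flagged} lost all sequences to artifact "
                      "rejection and cannot be averaged")
    meta = dict(session.meta)
    meta["flagged_trials"] = flagged
    meta["rejected_sequences"] = sorted(rejected)
    return EEGSession(session.samples, session.fs, list(session.channel_labels),
                      sorted(kept, key=lambda e: e.sample_index), meta)


def segment_trials(session: EEGSession, cfg: RunConfig,
                   on_empty: str = "raise") -> list[TrialSegments]:
    """Cut half-open epochs ``[onset, onset + n_max)`` per trial and sequence.

    Epochs are rearranged by location so rows map to l in 1..6 and columns
    to 7..12, regardless of the (random) flash order.  Sequences whose
    epochs run past the recording end are dropped.  A trial with no
    surviving sequence raises :class:`NoSequencesError` (``on_empty="raise"``)
    or is skipped and listed in the returned trials' absence
    (``on_empty="skip"``).
    """
    if on_empty not in ("raise", "skip"):
        raise ValueError("on_empty must be 'raise' or 'skip'")
    n_max = int(round(session.fs * cfg.t_max))
    C = session.n_channels
    out: list[TrialSegments] = []
    flagged = set(session.meta.get("flagged_trials", []))
    by_trial = session.events_by_trial()
    for trial_id in sorted(set(by_trial) | flagged):
        seqs: dict[int, list[StimulusEvent]] = {}
        for ev in by_trial.get(trial_id, []):
            seqs.setdefault(ev.sequence_index, []).append(ev)
        stacks = []
        for seq_idx in sorted(seqs):
            evs = seqs[seq_idx]
            if len(evs) != 12:
                raise NoSequencesError(
                    f"trial {trial_id}, sequence {seq_idx}: incomplete "
                    f"sequence of {len(evs)} events"
                )
            if max(ev.sample_index for ev in evs) + n_max > session.n_samples:
                continue  # window runs past the recording end
            block = np.empty((12, n_max, C))
            for ev in evs:
                block[ev.location - 1] = session.samples[
                    ev.sample_index:ev.sample_index + n_max
                ]
            stacks.append(block)
        if not stacks:
            if on_empty == "raise":
                raise NoSequencesError(
                    f"trial {trial_id}: no surviving intensification sequence"
                )
            continue
        out.append(TrialSegments(trial_id, np.stack(stacks), len(stacks), n_max))
    return out


def ensemble_average(trial: TrialSegments) -> AveragedTrial:
    """Point-to-point mean over the surviving sequences (per location)."""
    return AveragedTrial(trial.trial_id, trial.segments.mean(axis=0))


def preprocess_session(session: EEGSession, cfg: RunConfig,
                       on_empty: str = "raise") -> list[TrialSegments]:
    """Full front end: enhance, reject artifacts, segment."""
    enhanced = enhance_signal(session, cfg)
    cleaned = reject_artifacts(enhanced, cfg)
    return segment_trials(cleaned, cfg, on_empty=on_empty)
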