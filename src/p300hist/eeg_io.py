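"""Session data model and columnar CSV input/output.

A session is a multichannel EEG recording in microvolts plus a stimulation
log.  The stimulation log records which of the 12 locations of a 6x6 speller
matrix (rows are locations 1-6, columns 7-12) flashed at which sample.  The
12 flashes of one random permutation form one *intensification sequence*;
``k_a`` sequences form one *trial* (the attempt to spell one letter).

The native on-disk format is a plain CSV with one row per sample::

    Time,<ch_1>,...,<ch_C>,StimCode,Trial,IsTarget

``StimCode`` is 0 except at flash onsets where it holds the location (1-12);
``Trial`` carries the trial id at onset rows; ``IsTarget`` is 1/0 at onset
rows when the target is known (copy spelling) and empty otherwise.  Sample
indices are 0-based everywhere in this package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, SessionValidationError, UnsupportedFormatError

_RESERVED_COLUMNS = ("Time", "StimCode", "Trial", "IsTarget")

#: electrode labels of the reference 8-channel centro-parieto-occipital montage
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")


@dataclass(frozen=True)
class StimulusEvent:
    """One row/column flash onset.

    ``location`` is 1-6 for matrix rows and 7-12 for matrix columns.
    ``sequence_index`` (1-based) numbers the intensification sequence within
    the trial; ``is_target`` is known only in copy-spelling sessions.
    """

    sample_index: int
    location: int
    sequence_index: int
    trial_id: int
    is_target: Optional[bool] = None


@dataclass
class EEGSession:
    """A multichannel recording (microvolts) plus its stimulation log."""

    samples: np.ndarray  # shape (n_samples, C), float64, microvolts
    fs: float  # sampling frequency in Hz
    channel_labels: list[str]
    events: list[StimulusEvent]
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def validate(self) -> "EEGSession":
        """Check structural invariants; raise :class:`SessionValidationError`."""
        if self.samples.ndim != 2:
            raise SessionValidationError("samples must be a 2-D array")
        if self.n_channels < 1:
            raise SessionValidationError("need at least one channel")
        if not self.fs > 0:
            raise SessionValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise SessionValidationError("channel labels must be unique")
        if len(self.channel_labels) != self.n_channels:
            raise SessionValidationError("one label per channel is required")
        for ev in self.events:
            if not 0 <= ev.sample_index < self.n_samples:
                raise SessionValidationError(
                    f"event at sample {ev.sample_index} outside recording of "
                    f"{self.n_samples} samples"
                )
            if not 1 <= ev.location <= 12:
                raise SessionValidationError(f"location {ev.location} outside 1..12")
        _check_sequences(self.events)
        return self

    def events_by_trial(self) -> dict[int, list[StimulusEvent]]:
        """Events grouped per trial, each group sorted by sample index."""
        out: dict[int, list[StimulusEvent]] = {}
        for ev in sorted(self.events, key=lambda e: e.sample_index):
            out.setdefault(ev.trial_id, []).append(ev)
        return out


def _check_sequences(events: list[StimulusEvent]) -> None:
    groups: dict[tuple[int, int], list[int]] = {}
    for ev in events:
        groups.setdefault((ev.trial_id, ev.sequence_index), []).append(ev.location)
    for (trial, seq), locs in groups.items():
        if sorted(locs) != list(range(1, 13)):
            raise SessionValidationError(
                f"trial {trial}, sequence {seq}: locations {sorted(locs)} are "
                "not a permutation of 1..12"
            )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters of the decoding pipeline.

    gamma : image scale; one plotted sample every ``gamma`` pixel columns and
        one pixel per ``1/gamma`` microvolt-standardized unit vertically.
    s : patch scale of the descriptor; the patch spans ``12 s`` pixels.
    k : neighbor count of the k-NBNN decision rule.
    k_a : intensification sequences per trial.
    t_max : epoch length in seconds from flash onset.
    target_fs : decimated sampling rate in Hz.
    artifact_uV : per-sequence rejection threshold on absolute amplitude.
    notch_hz : mains frequency removed before lowpass filtering.
    metric : ``"cosine"`` (default) or ``"sqeuclidean"`` template distance.
    norm : descriptor normalization, ``"max"`` (default) or ``"l2"``.
    """

    gamma: int = 4
    s: int = 3
    k: int = 7
    k_a: int = 10
    t_max: float = 1.0
    target_fs: float = 16.0
    artifact_uV: float = 70.0
    notch_hz: float = 50.0
    metric: str = "cosine"
    norm: str = "max"
    seed: int = 0

    @property
    def n_max(self) -> int:
        """Epoch length in samples at the decimated rate."""
        return int(round(self.target_fs * self.t_max))

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key=value`` configuration file."""
        values = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise FormatError(f"{path}:{lineno}: unknown configuration key {key!r}")
            values[key] = casts[types[key]](val)
        return cls(**values)

    def to_file(self, path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV reader / writer
# ---------------------------------------------------------------------------

def read_session_csv(path) -> EEGSession:
    """Read a session CSV written by :func:`write_session_csv` (or by an
    OpenVibe-style export following the same column convention).

    A stimulus event is the *first* sample of a run of equal nonzero
    ``StimCode`` values: codes held for the whole flash duration collapse to
    a single onset.  Sequence indices are recovered by chunking each trial's
    onsets, in time order, into groups of 12, each of which must be a
    permutation of 1..12.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    for col in ("Time", "StimCode", "Trial"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    channels = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if not channels:
        raise FormatError(f"{path}: no channel columns found")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the rate")

    t = df["Time"].to_numpy(dtype=float)
    fs = round((len(t) - 1) / (t[-1] - t[0]), 6)
    samples = df[channels].to_numpy(dtype=float)
    codes = df["StimCode"].to_numpy(dtype=int)
    trials = df["Trial"].to_numpy(dtype=int)
    if "IsTarget" in df.columns:
        targets = df["IsTarget"].to_numpy(dtype=float)
    else:
        targets = np.full(len(df), np.nan)

    onsets = np.flatnonzero((codes != 0) & (np.diff(codes, prepend=0) != 0))
    events = _events_from_onsets(onsets, codes, trials, targets)
    return EEGSession(samples, fs, list(channels), events).validate()


def _events_from_onsets(onsets, codes, trials, targets) -> list[StimulusEvent]:
    """Assign sequence indices by chunking each trial's onsets into 12s."""
    per_trial: dict[int, list[int]] = {}
    for idx in onsets:
        per_trial.setdefault(int(trials[idx]), []).append(int(idx))
    events = []
    for trial_id, idxs in per_trial.items():
        if len(idxs) % 12 != 0:
            raise SessionValidationError(
                f"trial {trial_id}: {len(idxs)} flash onsets do not form "
                "complete 12-location sequences"
            )
        for seq0 in range(len(idxs) // 12):
            chunk = idxs[12 * seq0 : 12 * (seq0 + 1)]
            locs = [int(codes[i]) for i in chunk]
            if sorted(locs) != list(range(1, 13)):
                raise SessionValidationError(
                    f"trial {trial_id}, sequence {seq0 + 1}: locations {locs} "
                    "are not a permutation of 1..12"
                )
            for i in chunk:
                is_t = None if np.isnan(targets[i]) else bool(targets[i])
                events.append(
                    StimulusEvent(int(i), int(codes[i]), seq0 + 1, trial_id, is_t)
                )
    return sorted(events, key=lambda e: e.sample_index)


def write_session_csv(session: EEGSession, path) -> None:
    """Write a session to CSV with lossless event recovery.

    Amplitudes are serialized with the shortest round-trip decimal
    representation (well above 6 significant digits), so a write/read cycle
    reproduces samples exactly and a second write is byte-identical.
    """
    session.validate()
    n = session.n_samples
    stim = np.zeros(n, dtype=int)
    trial = np.zeros(n, dtype=int)
    is_target = np.full(n, "", dtype=object)
    for ev in session.events:
        stim[ev.sample_index] = ev.location
        trial[ev.sample_index] = ev.trial_id
        if ev.is_target is not None:
            is_target[ev.sample_index] = int(ev.is_target)

    df = pd.DataFrame({"Time": np.arange(n) / session.fs})
    for c, label in enumerate(session.channel_labels):
        df[label] = session.samples[:, c]
    df["StimCode"] = stim
    df["Trial"] = trial
    df["IsTarget"] = is_target
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# optional adapter for the public ALS speller recordings (.mat)
# ---------------------------------------------------------------------------

def read_bnci_mat(path) -> EEGSession:
    """Best-effort adapter for the BNCI-Horizon 008-2014 ``.mat`` recordings
    (8 channels at 256 Hz with per-sample flash and target markers).

    The adapter is optional: nothing in the pipeline requires it, and any
    file it cannot interpret raises :class:`UnsupportedFormatError` rather
    than crashing.
    """
    path = Path(path)
    if path.suffix.lower() != ".mat":
        raise UnsupportedFormatError(f"{path}: not a .mat file")
    from scipy.io import loadmat

    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise UnsupportedFormatError(f"{path}: cannot load .mat file: {exc}") from exc

    data = mat.get("data")
    if data is None:
        raise UnsupportedFormatError(f"{path}: no 'data' variable found")
    runs = np.atleast_1d(data)
    try:
        return _assemble_bnci_runs(runs)
    except UnsupportedFormatError:
        raise
    except Exception as exc:
        raise UnsupportedFormatError(f"{path}: unknown 008-2014 layout: {exc}") from exc


def _assemble_bnci_runs(runs) -> EEGSession:
    all_samples = []
    events: list[StimulusEvent] = []
    fs = None
    labels = None
    offset = 0
    trial_base = 0
    for run in runs:
        X = np.asarray(getattr(run, "X"), dtype=float)
        if X.ndim != 2:
            raise UnsupportedFormatError("run.X is not a matrix")
        if X.shape[0] < X.shape[1]:  # channels x samples -> samples x channels
            X = X.T
        fs = float(getattr(run, "fs", 256.0))
        raw_labels = getattr(run, "channels", None)
        if raw_labels is not None:
            labels = [str(c).strip() for c in np.atleast_1d(raw_labels)]
        else:
            labels = list(DEFAULT_CHANNELS[: X.shape[1]])
        stim = np.asarray(getattr(run, "y_stim"), dtype=float).ravel().astype(int)
        target = np.asarray(getattr(run, "y"), dtype=float).ravel()
        onsets = np.flatnonzero((stim != 0) & (np.diff(stim, prepend=0) != 0))
        trial_starts = np.atleast_1d(np.asarray(getattr(run, "trial"))).astype(int)
        trial_of = np.searchsorted(trial_starts, onsets, side="right")  # 1-based
        trials = np.zeros(len(stim), dtype=int)
        for idx, tr in zip(onsets, trial_of):
            trials[idx] = trial_base + int(tr)
        events.extend(
            _events_from_onsets(onsets + offset,
                                _shift_codes(stim, offset, len(stim)),
                                _shift_codes(trials, offset, len(stim)),
                                _shift_codes(target, offset, len(stim), fill=np.nan))
        )
        all_samples.append(X)
        offset += X.shape[0]
        trial_base += len(trial_starts)
    samples = np.vstack(all_samples)
    return EEGSession(samples, fs, labels, events).validate()


def _shift_codes(arr, offset, n, fill=0):
    """Place ``arr`` at ``offset`` in a longer zero/NaN array so that global
    sample indices can be used uniformly."""
    out = np.full(offset + n, fill, dtype=float if fill is np.nan else np.asarray(arr).dtype)
    out[offset:] = arr
    return out


def sessions_equal(a: EEGSession, b: EEGSession, tol_uV: float = 1e-6) -> bool:
    """True when two sessions agree in rate, labels, amplitudes (to ``tol_uV``)
    and have identical event lists."""
    return (
        abs(a.fs - b.fs) < 1e-6
        and a.channel_labels == b.channel_labels
        and a.samples.shape == b.samples.shape
        and np.allclose(a.samples, b.samples, atol=tol_uV, rtol=0.0)
        and sorted(a.events, key=lambda e: e.sample_index)
        == sorted(b.events, key=lambda e: e.sample_index)
    )
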