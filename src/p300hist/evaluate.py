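"""Offline speller evaluation: character recognition rate and k_a curves.

The character recognition rate (CRR) is the percentage of correctly decoded
letters over *all* test trials: a trial whose pipeline failed (for example,
every sequence rejected) counts as an error, so the CRR reflects usable
performance; the failure count is reported separately.  The information
transfer rate is reported informationally with the standard Wolpaw formula
for an N=36 selection.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .eeg_io import EEGSession, RunConfig
from .errors import CalibrationError
from .preprocess import enhance_signal, ensemble_average, reject_artifacts, \
    segment_trials
from .speller import LetterPrediction, SpellerMatrix, TemplateSet, calibrate, \
    decode_trials

SCHEMA_VERSION = 1


@dataclass
class EvaluationReport:
    """Results of one offline calibrate-then-decode run."""

    calib_crr_per_channel: dict[str, float]
    bpc: str
    test_crr: float
    n_test_trials: int
    n_failed_trials: int
    rejected_sequences_calib: int
    rejected_sequences_test: int
    itr_bits_per_selection: float
    config: dict
    ka_curve: Optional[dict[int, float]] = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["ka_curve"] is not None:
            d["ka_curve"] = {str(k): v for k, v in d["ka_curve"].items()}
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def wolpaw_itr(p: float, n_classes: int = 36) -> float:
    """Wolpaw information transfer rate in bits per selection."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    bits = np.log2(n_classes)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n_classes - 1))
    return float(max(0.0, bits))


def target_letters(session: EEGSession, matrix: SpellerMatrix) -> dict[int, str]:
    """Ground-truth letter per trial, from the ``is_target`` event flags."""
    letters: dict[int, str] = {}
    for trial_id, evs in session.events_by_trial().items():
        rows = {ev.location for ev in evs if ev.is_target and ev.location <= 6}
        cols = {ev.location for ev in evs if ev.is_target and ev.location >= 7}
        if len(rows) == 1 and len(cols) == 1:
            letters[trial_id] = matrix.letter(rows.pop(), cols.pop())
    return letters


def crr_percent(preds: list[LetterPrediction], truth: dict[int, str]) -> float:
    """Percentage of correct letters over all trials with known truth."""
    if not truth:
        raise ValueError("no trials with known target letters")
    by_trial = {p.trial_id: p for p in preds}
    correct = sum(
        1 for tid, letter in truth.items()
        if tid in by_trial and by_trial[tid].letter == letter
    )
    return 100.0 * correct / len(truth)


def calibrate_session(session: EEGSession, matrix: SpellerMatrix,
                      cfg: RunConfig,
                      targets: Optional[dict[int, str]] = None
                      ) -> tuple[TemplateSet, int]:
    """Preprocess and calibrate on a copy-spelling session.

    Returns the template set and the number of artifact-rejected sequences.
    """
    enhanced = enhance_signal(session, cfg)
    cleaned = reject_artifacts(enhanced, cfg)
    tsegs = segment_trials(cleaned, cfg, on_empty="skip")
    truth = targets if targets is not None else target_letters(session, matrix)
    usable = [ts for ts in tsegs if ts.trial_id in truth]
    if len(usable) < 2:
        raise CalibrationError(
            "calibration requires at least 2 trials with known targets"
        )
    trials = [ensemble_average(ts) for ts in usable]
    tset = calibrate(trials, [truth[ts.trial_id] for ts in usable], matrix,
                     cfg, channel_labels=list(session.channel_labels))
    return tset, len(cleaned.meta.get("rejected_sequences", []))


def evaluate(calib_session: EEGSession, test_session: EEGSession,
             matrix: SpellerMatrix, cfg: RunConfig,
             ka_sweep: bool = False) -> EvaluationReport:
    """Calibrate on one session, decode another, and report CRR.

    With ``ka_sweep`` the test trials are re-decoded using only the first
    ``k_a_used`` sequences for every ``k_a_used`` in 1..k_a, tracing the
    performance-versus-averaging curve.
    """
    tset, rej_calib = calibrate_session(calib_session, matrix, cfg)

    enhanced = enhance_signal(test_session, cfg)
    cleaned = reject_artifacts(enhanced, cfg)
    tsegs = segment_trials(cleaned, cfg, on_empty="skip")
    truth = target_letters(test_session, matrix)
    if not truth:
        raise ValueError("test session has no trials with known targets")

    preds = decode_trials(tsegs, tset, matrix, cfg, k_a_used=None)
    test_crr = crr_percent(preds, truth)
    n_failed = len(truth) - sum(
        1 for p in preds if p.error is None and p.trial_id in truth
    )

    ka_curve = None
    if ka_sweep:
        ka_curve = {}
        for ka in range(1, cfg.k_a + 1):
            ka_preds = decode_trials(tsegs, tset, matrix, cfg, k_a_used=ka)
            ka_curve[ka] = crr_percent(ka_preds, truth)

    return EvaluationReport(
        calib_crr_per_channel=tset.calib_crr,
        bpc=tset.bpc_label,
        test_crr=test_crr,
        n_test_trials=len(truth),
        n_failed_trials=n_failed,
        rejected_sequences_calib=rej_calib,
        rejected_sequences_test=len(cleaned.meta.get("rejected_sequences", [])),
        itr_bits_per_selection=wolpaw_itr(test_crr / 100.0),
        config=dataclasses.asdict(cfg),
        ka_curve=ka_curve,
    )
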