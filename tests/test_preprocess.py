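"""Filtering chain, artifact rejection, segmentation and averaging."""

import numpy as np
import pytest

from conftest import toy_session
from oracles import naive_mean
from p300hist import (EEGSession, RunConfig, TrialSegments, enhance_signal,
                      ensemble_average, reject_artifacts, segment_trials)
from p300hist.errors import InvalidRateError, NoSequencesError


def _plain(n, fs=256.0, channels=1, value=0.0):
    return EEGSession(np.full((n, channels), float(value)), fs,
                      [f"ch{c}" for c in range(channels)], [])


class TestEnhance:
    def test_zero_input_gives_zero_output_at_target_rate(self, cfg):
        out = enhance_signal(_plain(256), cfg)
        assert out.fs == 16.0
        assert out.n_samples == 16
        assert np.all(out.samples == 0.0)

    def test_dc_level_preserved_after_settling(self, cfg):
        out = enhance_signal(_plain(256, value=5.0), cfg)
        assert out.samples[-4:, 0] == pytest.approx(5.0, rel=0.02)

    def test_20hz_tone_strongly_attenuated(self, cfg):
        t = np.arange(1024) / 256.0
        session = EEGSession(np.sin(2 * np.pi * 20.0 * t)[:, None], 256.0,
                             ["Cz"], [])
        out = enhance_signal(session, cfg)
        steady = out.samples[16:, 0]  # skip the causal-filter transient
        assert steady.std() < 0.05 * session.samples[:, 0].std()

    def test_rate_below_twice_target_rejected(self, cfg):
        with pytest.raises(InvalidRateError):
            enhance_signal(_plain(100, fs=20.0), cfg)

    def test_rational_resampling_reaches_16hz(self, cfg):
        out = enhance_signal(_plain(2500, fs=250.0), cfg)
        assert out.fs == 16.0
        assert out.n_samples == 160

    def test_deterministic(self, cfg):
        rng = np.random.default_rng(0)
        session = EEGSession(rng.normal(size=(512, 2)), 256.0, ["a", "b"], [])
        a = enhance_signal(session, cfg)
        b = enhance_signal(session, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_event_indices_rescaled_with_floor(self, cfg):
        session = toy_session(fs=256.0, soa=64, gap=256, n_max=256,
                              noise_sd=0.1)
        out = enhance_signal(session, cfg)
        for before, after in zip(session.events, out.events):
            assert after.sample_index == int(np.floor(before.sample_index / 16))


class TestRejectArtifacts:
    def test_below_threshold_keeps_everything(self, cfg):
        session = toy_session(k_a=2)
        session.samples[:] = 69.9
        out = reject_artifacts(session, cfg)
        assert out.events == session.events
        assert out.meta["rejected_sequences"] == []

    def test_single_spike_removes_exactly_its_sequence(self, cfg):
        """One +71 uV sample inside sequence 2 removes that sequence's 12
        events and nothing else (threshold +-70 uV)."""
        session = toy_session(k_a=3, noise_sd=0.1)
        seq2 = [ev for ev in session.events if ev.sequence_index == 2]
        session.samples[seq2[5].sample_index + 3, 0] = 71.0
        out = reject_artifacts(session, cfg)
        assert out.meta["rejected_sequences"] == [(1, 2)]
        assert {ev.sequence_index for ev in out.events} == {1, 3}
        assert len(out.events) == 24

    def test_zero_threshold_removes_all_nonzero_sequences(self, cfg):
        session = toy_session(k_a=2, noise_sd=1.0)
        out = reject_artifacts(session, cfg.replace(artifact_uV=0.0))
        assert out.events == []

    def test_fully_rejected_trial_is_flagged(self, cfg):
        session = toy_session(n_trials=2, k_a=1, noise_sd=0.1)
        for ev in session.events:
            if ev.trial_id == 2:
                session.samples[ev.sample_index] = 200.0
        with pytest.warns(UserWarning, match=r"trials \[2\]"):
            out = reject_artifacts(session, cfg)
        assert out.meta["flagged_trials"] == [2]
        with pytest.raises(NoSequencesError, match="trial 2"):
            segment_trials(out, cfg)


class TestSegment:
    def test_half_open_window_arithmetic(self, cfg):
        session = toy_session(k_a=1, noise_sd=1.0)
        first = session.events[0]
        segs = segment_trials(session, cfg)
        got = segs[0].segments[0, first.location - 1]
        expected = session.samples[first.sample_index:first.sample_index + 16]
        assert np.array_equal(got, expected)

    def test_ten_sequences_give_120_segments(self, cfg):
        session = toy_session(k_a=10, gap=32)
        segs = segment_trials(session, cfg)
        assert segs[0].segments.shape == (10, 12, 16, 1)
        assert segs[0].k_a_effective == 10

    def test_flash_order_within_sequence_is_irrelevant(self, cfg):
        base = np.arange(1, 13)
        shuffled = np.random.default_rng(1).permutation(12) + 1
        a = toy_session(orders=[[base]], noise_sd=1.0,
                        rng=np.random.default_rng(9))
        b = toy_session(orders=[[shuffled]], noise_sd=1.0,
                        rng=np.random.default_rng(9))
        # align: location l in session b flashed at a different time; epochs
        # must still be indexed by location, not by flash order
        seg_a = segment_trials(a, cfg)[0]
        seg_b = segment_trials(b, cfg)[0]
        for l0 in range(12):
            loc = l0 + 1
            ev_a = next(e for e in a.events if e.location == loc)
            ev_b = next(e for e in b.events if e.location == loc)
            assert np.array_equal(
                seg_a.segments[0, l0],
                a.samples[ev_a.sample_index:ev_a.sample_index + 16])
            assert np.array_equal(
                seg_b.segments[0, l0],
                b.samples[ev_b.sample_index:ev_b.sample_index + 16])

    def test_window_past_end_drops_sequence(self, cfg):
        session = toy_session(k_a=2, gap=0, n_max=8)  # second seq truncated
        session.samples = session.samples[:session.events[-1].sample_index + 8]
        segs = segment_trials(session, cfg)
        assert segs[0].k_a_effective == 1


class TestEnsembleAverage:
    def test_identical_segments_average_to_themselves(self):
        seg = np.random.default_rng(0).normal(size=(1, 12, 16, 2))
        stack = np.repeat(seg, 5, axis=0)
        avg = ensemble_average(TrialSegments(1, stack, 5, 16))
        assert np.allclose(avg.x, seg[0])

    def test_two_point_average(self):
        stack = np.zeros((2, 12, 16, 1))
        stack[1] = 2.0
        avg = ensemble_average(TrialSegments(1, stack, 2, 16))
        assert np.all(avg.x == 1.0)

    def test_matches_naive_mean_loop(self):
        segments = np.random.default_rng(2).normal(size=(4, 12, 5, 2))
        avg = ensemble_average(TrialSegments(1, segments, 4, 5))
        assert np.allclose(avg.x, naive_mean(segments), atol=1e-12)

    def test_variance_shrinks_like_one_over_ka(self):
        """Averaging k_a i.i.d. noise epochs divides sample variance by
        about k_a (ratio within [0.6, 1.4]/k_a over 200 replicates)."""
        rng = np.random.default_rng(7)
        k_a, n = 10, 64
        ratios = []
        for _ in range(17):  # 17 trials x 12 locations >= 200 replicates
            stack = rng.normal(size=(k_a, 12, n, 1))
            avg = ensemble_average(TrialSegments(1, stack, k_a, n))
            ratios.extend(avg.x[:, :, 0].var(axis=1, ddof=1)
                          / stack[:, :, :, 0].var(axis=(0, 2), ddof=1))
        mean_ratio = np.mean(ratios)
        assert 0.6 / k_a < mean_ratio < 1.4 / k_a
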