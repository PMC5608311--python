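"""VAD, GLR change detection, speaker clustering, roles and DER."""

import numpy as np
import pytest

from dyadvox.corpus import AudioSignal, SpeechSegment, Turn
from dyadvox import preprocess as pp
from dyadvox.synthetic import SimConfig, render_audio

RATE = 16000


def tone(f0, dur, amp=0.4):
    t = np.arange(int(dur * RATE)) / RATE
    return amp * np.sin(2 * np.pi * f0 * t)


class TestVAD:
    def test_pure_silence_empty(self):
        assert pp.detect_voice(AudioSignal(np.zeros(RATE), RATE)) == []

    def test_tone_silence_tone_two_segments(self):
        x = np.concatenate([tone(220, 1.0), np.zeros(RATE), tone(220, 1.0)])
        segs = pp.detect_voice(AudioSignal(x, RATE))
        assert len(segs) == 2
        truth = [(0.0, 1.0), (2.0, 3.0)]
        for seg, (s, e) in zip(segs, truth):
            assert abs(seg.start - s) <= 0.05
            assert abs(seg.end - e) <= 0.05

    def test_constant_white_noise_deterministic(self):
        rng = np.random.default_rng(0)
        x = 0.2 * rng.standard_normal(2 * RATE)
        a = pp.detect_voice(AudioSignal(x, RATE))
        b = pp.detect_voice(AudioSignal(x, RATE))
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    def test_translation_equivariance(self):
        """Padding with leading silence shifts detections by the pad length."""
        x = np.concatenate([tone(200, 0.8), np.zeros(RATE // 2), tone(200, 0.8)])
        base = pp.detect_voice(AudioSignal(np.concatenate([np.zeros(RATE), x]), RATE))
        shifted = pp.detect_voice(
            AudioSignal(np.concatenate([np.zeros(2 * RATE), x]), RATE))
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert abs((b.start - a.start) - 1.0) < 0.05
            assert abs((b.end - a.end) - 1.0) < 0.05


class TestGLR:
    def test_identical_windows_statistic_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((100, 15))
        assert abs(pp.glr_statistic(a, a.copy())) < 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((80, 15)), rng.standard_normal((90, 15))
        assert pp.glr_statistic(a, b) == pytest.approx(pp.glr_statistic(b, a))

    def test_null_false_alarm_rate(self):
        """Stationary Gaussian features rarely trigger at default threshold."""
        rng = np.random.default_rng(3)
        alarms = 0
        for _ in range(100):
            X = rng.standard_normal((1000, 15))
            if pp.glr_change_points(X):
                alarms += 1
        assert alarms <= 5

    def test_single_change_detected_and_localized(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((500, 15)),
                       rng.standard_normal((500, 15)) + 5.0])
        pts = pp.glr_change_points(X)
        assert len(pts) == 1
        assert abs(pts[0] - 5.0) <= 0.25

    def test_short_region_no_change_points(self):
        rng = np.random.default_rng(5)
        assert pp.glr_change_points(rng.standard_normal((150, 15))) == []


class TestClustering:
    def _segments(self, n, dur=1.0):
        return [SpeechSegment(i * dur, (i + 1) * dur) for i in range(n)]

    def test_two_gaussians_high_purity(self):
        rng = np.random.default_rng(6)
        hits = total = 0
        for _ in range(10):
            labels = [i % 2 for i in range(12)]
            feats = [rng.standard_normal((60, 15)) + 4.0 * l for l in labels]
            ids = pp.cluster_speakers(self._segments(12), feats)
            agree = sum(a == b for a, b in zip(ids, labels))
            hits += max(agree, 12 - agree)
            total += 12
        assert hits / total >= 0.9

    def test_two_segments_forced_split(self):
        rng = np.random.default_rng(7)
        ids = pp.cluster_speakers(self._segments(2),
                                  [rng.standard_normal((50, 15)) for _ in range(2)])
        assert sorted(ids) == [0, 1]

    def test_duplicated_segments_deterministic(self):
        rng = np.random.default_rng(8)
        block = rng.standard_normal((50, 15))
        far = rng.standard_normal((50, 15)) + 8.0
        feats = [block, block.copy(), block.copy(), far]
        ids = pp.cluster_speakers(self._segments(4), feats)
        assert ids[:3] == [0, 0, 0] and ids[3] == 1

    def test_single_segment_error(self):
        with pytest.raises(pp.DiarizationError):
            pp.cluster_speakers(self._segments(1), [np.zeros((50, 15))])


class TestRoles:
    def _setup(self, pitches):
        segs = [SpeechSegment(0.0, 1.0), SpeechSegment(1.0, 2.0)]
        times = np.arange(0.005, 2.0, 0.01)
        pitch = np.where(times < 1.0, pitches[0], pitches[1]).astype(float)
        return segs, [0, 1], pitch, times

    def test_higher_pitch_is_wife(self):
        segs, ids, pitch, times = self._setup((120.0, 210.0))
        res = pp.assign_roles(segs, ids, pitch, times)
        assert res.cluster_stats["H"]["mean_pitch"] == pytest.approx(120.0)
        assert res.cluster_stats["W"]["mean_pitch"] == pytest.approx(210.0)
        assert [t.role for t in res.turns] == ["H", "W"]

    def test_equal_pitch_tie_break(self):
        segs, ids, pitch, times = self._setup((150.0, 150.0))
        res = pp.assign_roles(segs, ids, pitch, times)
        assert [t.role for t in res.turns] == ["H", "W"]

    def test_unvoiced_cluster_errors(self):
        segs, ids, pitch, times = self._setup((120.0, 210.0))
        pitch[times >= 1.0] = np.nan
        with pytest.raises(pp.DiarizationError):
            pp.assign_roles(segs, ids, pitch, times)


class TestDER:
    def test_identity_zero(self):
        ref = [Turn("H", 0.0, 4.0), Turn("W", 4.0, 8.0)]
        assert pp.diarization_error_rate(ref, ref) == 0.0

    def test_role_swap_invariance(self):
        ref = [Turn("H", 0.0, 4.0), Turn("W", 4.0, 8.0)]
        hyp = [Turn("W", 0.0, 4.0), Turn("H", 4.0, 8.0)]
        assert pp.diarization_error_rate(hyp, ref) == 0.0

    def test_hand_built_quarter_error(self):
        """8 s of reference speech with 2 s attributed to the wrong speaker."""
        ref = [Turn("H", 0.0, 4.0), Turn("W", 4.0, 8.0)]
        hyp = [Turn("H", 0.0, 6.0), Turn("W", 6.0, 8.0)]
        assert pp.diarization_error_rate(hyp, ref) == pytest.approx(0.25)

    def test_empty_reference_errors(self):
        with pytest.raises(pp.DiarizationError):
            pp.diarization_error_rate([], [])


class TestEndToEnd:
    def test_rendered_dialogue_roles_recovered(self):
        """Rendered 110/210 Hz alternating turns diarize with correct roles."""
        n_ok = 0
        for seed in range(5):
            turns = []
            t = 0.3
            rng = np.random.default_rng(100 + seed)
            for i in range(8):
                dur = rng.uniform(0.8, 1.4)
                turns.append(Turn("HW"[i % 2], round(t, 3), round(t + dur, 3)))
                t += dur + rng.uniform(0.3, 0.6)
            audio, refs = render_audio(turns, SimConfig(), seed=seed)
            res = pp.diarize(audio)
            der = pp.diarization_error_rate(res.turns, turns)
            if der < 0.3 and res.cluster_stats["W"]["mean_pitch"] > \
                    res.cluster_stats["H"]["mean_pitch"]:
                n_ok += 1
        assert n_ok >= 4
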