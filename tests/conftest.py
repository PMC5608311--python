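import numpy as np
import pytest

from dyadvox.corpus import FrameTrack, Interaction, OutcomeSample, Corpus, Turn
from dyadvox.frame_features import FEATURE_NAMES


def make_track(values: np.ndarray, hop: float = 0.010,
               t0: float = 0.0) -> FrameTrack:
    """Wrap a (frames x 74) matrix as a FrameTrack on a uniform grid."""
    values = np.asarray(values, dtype=float)
    times = t0 + (np.arange(len(values)) + 0.5) * hop
    return FrameTrack(values=values, times=times,
                      voiced=np.ones(len(values), dtype=bool),
                      feature_names=FEATURE_NAMES, hop=hop)


def constant_track(value: float, n_frames: int = 100, **kw) -> FrameTrack:
    return make_track(np.full((n_frames, len(FEATURE_NAMES)), value), **kw)


def make_interaction(couple="c000", timepoint="pre", topic="husband_chosen",
                     tracks=None, turns=None) -> Interaction:
    return Interaction(couple_id=couple, timepoint=timepoint, topic=topic,
                       tracks=tracks or {}, turns=turns or [])


def make_sample(tracks_builder, couple="c000", rating=4, horizon="26wk"):
    """Outcome sample whose 8 (timepoint, topic, role) tracks come from a
    callback tracks_builder(timepoint, topic, role) -> FrameTrack."""
    def session(timepoint):
        out = {}
        for topic in ("husband_chosen", "wife_chosen"):
            tracks = {role: tracks_builder(timepoint, topic, role)
                      for role in ("H", "W")}
            turns = []
            t = 0.0
            for i in range(4):
                role = "HW"[i % 2]
                turns.append(Turn(role=role, start=t, end=t + 0.25))
                t += 0.25
            out[topic] = make_interaction(couple, timepoint, topic, tracks, turns)
        return out
    return OutcomeSample(couple_id=couple, pre=session("pre"),
                         post=session(horizon), rating=rating, horizon=horizon)


@pytest.fixture(scope="session")
def small_corpus():
    """16-sample synthetic feature corpus shared by read-only tests."""
    from dyadvox.synthetic import SimConfig, simulate_feature_corpus
    cfg = SimConfig(n_couples=10, seed=7, turns_per_interaction=(8, 12),
                    turn_dur=(0.6, 1.2))
    corpus, truth, ratings = simulate_feature_corpus(cfg)
    return corpus, truth, ratings
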