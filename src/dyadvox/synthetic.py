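"""Seeded generator of synthetic dyadic-therapy corpora.

The clinical corpus this pipeline was designed around is not
distributable, so the generator emits corpora with the statistical
structure the analysis assumes: couples with a 4-level outcome class
(imbalanced 12/26/34/67), pre- and post-therapy sessions of two topic
interactions each, alternating husband/wife turns, 74-dim frame tracks
at a 10 ms hop, multi-annotator 1-9 behavioral-code ratings, and an
optional schematic audio rendering (harmonic complexes at each
speaker's f0) for exercising VAD, diarization and pitch tracking.

Class-conditioned effects, all scaled by ``effect_size`` and graded
across the four classes, mirror the direction of the strongest
associations the analysis is meant to recover:

* recovered couples have a rising within-turn pitch contour (positive
  mean pitch delta), larger turn-to-turn loudness variability
  (positive loudness-SD association) and lower jitter;
* post-therapy sessions shift loudness and intensity upward for
  recovering couples, so long-term quarter deltas are informative;
* behavioral codes shift toward the positive pole for recovering
  couples (and the negative pole for declining ones).

Within-speaker turn dynamics follow an AR(1) drift with a
cross-speaker coupling term, so short-term HH/WW/HW deltas are
non-trivial.  With ``effect_size = 0`` every channel is exchangeable
across classes (the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import (AudioSignal, Corpus, Interaction, OutcomeSample,
                     SpeechSegment, Turn, HORIZONS, TOPICS, ROLES)
from . import frame_features as ff
from .code_features import CODE_NAMES


class SimulationError(ValueError):
    pass


# class-conditioned effect multiplier per rating: graded from -1
# (deteriorated) to +1 (recovered)
def _class_multiplier(rating: int) -> float:
    return (rating - 2.5) / 1.5


# behavioral-code polarity: +1 codes rise with recovery, -1 codes fall
_POSITIVE_CODES = {
    "global_positive_affect", "use_of_humor", "affection", "satisfaction",
    "emotional_support", "instrumental_support", "acceptance_of_other",
    "negotiates", "makes_agreements", "offers_solutions",
}
_NEGATIVE_CODES = {
    "global_negative_affect", "sadness", "anger_frustration",
    "belligerence_domineering", "contempt_disgust", "tension_anxiety",
    "defensiveness", "blame", "pressures_for_change", "withdraws", "avoidance",
}
CODE_POLARITY = {
    c: (1.0 if c in _POSITIVE_CODES else -1.0 if c in _NEGATIVE_CODES else 0.0)
    for c in CODE_NAMES
}

N_BASE = len(ff.BASE_NAMES)
_IDX = {name: i for i, name in enumerate(ff.BASE_NAMES)}

# per-channel baselines and scales (37 base features); the named
# channels get physically plausible values, the rest generic latents
def _baselines(base_f0: dict[str, float]) -> dict[str, np.ndarray]:
    out = {}
    for role in ROLES:
        b = np.zeros(N_BASE)
        b[_IDX["pitch"]] = base_f0[role]
        b[_IDX["intensity"]] = -25.0
        b[_IDX["loudness"]] = 10.0
        b[_IDX["jitter"]] = 0.012
        b[_IDX["shimmer"]] = 0.05
        b[_IDX["hnr"]] = 15.0
        out[role] = b
    return out


_SCALES = np.ones(N_BASE)
_SCALES[_IDX["pitch"]] = 6.0
_SCALES[_IDX["intensity"]] = 1.5
_SCALES[_IDX["loudness"]] = 0.5
_SCALES[_IDX["jitter"]] = 0.002
_SCALES[_IDX["shimmer"]] = 0.01
_SCALES[_IDX["hnr"]] = 1.5


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    The class mix matches the 12/26/34/67 outcome counts; 110/210 Hz
    husband/wife baseline pitch; interactions of 20-30 alternating
    turns of 1-3 s (shorter than the clinical 10 minutes, same
    structure).
    """

    n_couples: int = 88
    class_probs: tuple[float, ...] = (12 / 139, 26 / 139, 34 / 139, 67 / 139)
    both_horizons_prob: float = 53 / 88
    turns_per_interaction: tuple[int, int] = (20, 30)
    turn_dur: tuple[float, float] = (1.0, 3.0)
    gap_dur: tuple[float, float] = (0.2, 0.8)
    base_f0: dict[str, float] = field(default_factory=lambda: {"H": 110.0, "W": 210.0})
    effect_size: float = 1.0
    noise_sd: float = 1.0        # frame noise in per-channel scale units
    drift_sd: float = 0.5        # turn-level AR(1) innovation, scale units
    ar_coef: float = 0.6
    coupling: float = 0.3        # cross-speaker entrainment term
    hop: float = 0.010
    n_annotators: tuple[int, int] = (2, 4)
    code_cell_sd: float = 2.0    # latent per-cell behavior spread
    code_noise_sd: float = 1.2   # annotator disagreement around the cell
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise SimulationError("class_probs must be a probability 4-vector")
        if len(self.class_probs) != 4:
            raise SimulationError("class_probs must have 4 entries")
        for lo, hi in (self.turns_per_interaction, self.turn_dur, self.gap_dur):
            if lo <= 0 or hi < lo:
                raise SimulationError("ranges must be positive and ordered")


@dataclass
class GroundTruth:
    """Latent state of an emitted corpus, for oracle-style tests."""

    rating_of_couple: dict[str, int]
    horizons_of_couple: dict[str, tuple[str, ...]]
    turns: dict[tuple[str, str, str], list[Turn]]          # (couple, timepoint, topic)
    turn_means: dict[tuple[str, str, str], np.ndarray]     # (n_turns, 37)
    base_f0: dict[str, float]


# ---------------------------------------------------------------------------
# interaction-level generation
# ---------------------------------------------------------------------------

def _simulate_interaction(couple: str, timepoint: str, topic: str, rating: int,
                          cfg: SimConfig, rng: np.random.Generator
                          ) -> tuple[Interaction, list[Turn], np.ndarray]:
    m = _class_multiplier(rating) * cfg.effect_size
    baselines = _baselines(cfg.base_f0)
    is_post = timepoint != "pre"

    n_turns = int(rng.integers(cfg.turns_per_interaction[0],
                               cfg.turns_per_interaction[1] + 1))
    roles = [ROLES[i % 2] for i in range(n_turns)]
    durs = rng.uniform(*cfg.turn_dur, size=n_turns)
    gaps = rng.uniform(*cfg.gap_dur, size=n_turns)
    turns: list[Turn] = []
    t = gaps[0]
    for role, dur, gap in zip(roles, durs, gaps):
        turns.append(Turn(role=role, start=round(t, 3), end=round(t + dur, 3)))
        t += dur + gap

    # turn-level deviations: AR(1) within speaker + cross-speaker coupling
    dev = np.zeros((n_turns, N_BASE))
    last_of: dict[str, np.ndarray | None] = {"H": None, "W": None}
    drift_scale = cfg.drift_sd * _SCALES
    loud = _IDX["loudness"]
    for i, role in enumerate(roles):
        other = "W" if role == "H" else "H"
        innov = rng.normal(0.0, drift_scale)
        # loudness turn-to-turn variability grows with recovery
        innov[loud] *= max(0.1, 1.0 + 0.5 * m)
        d = innov
        if last_of[role] is not None:
            d = d + cfg.ar_coef * last_of[role]
        if last_of[other] is not None:
            d = d + cfg.coupling * last_of[other]
        dev[i] = d
        last_of[role] = d

    turn_means = np.vstack([baselines[r] for r in roles]) + dev
    # class-level mean shifts
    turn_means[:, _IDX["jitter"]] = np.clip(
        turn_means[:, _IDX["jitter"]] - 0.003 * m, 1e-4, None)
    if is_post:
        turn_means[:, loud] += 0.4 * m
        turn_means[:, _IDX["intensity"]] += 0.8 * m

    pitch_slope = 15.0 * m  # Hz/s rising contour for recovering couples

    tracks: dict[str, object] = {}
    for role in ROLES:
        frame_times, frame_vals = [], []
        for i, turn in enumerate(turns):
            if turn.role != role:
                continue
            n_f = max(3, int(np.floor(turn.duration / cfg.hop)))
            tt = turn.start + (np.arange(n_f) + 0.5) * cfg.hop
            vals = (turn_means[i][None, :]
                    + rng.normal(0.0, cfg.noise_sd * _SCALES, size=(n_f, N_BASE)))
            vals[:, _IDX["pitch"]] += pitch_slope * (tt - tt.mean())
            vals[:, _IDX["pitch"]] = np.clip(vals[:, _IDX["pitch"]], 40.0, None)
            vals[:, _IDX["jitter"]] = np.clip(vals[:, _IDX["jitter"]], 1e-4, None)
            frame_times.append(tt)
            frame_vals.append(vals)
        times = np.concatenate(frame_times)
        base = np.vstack(frame_vals)
        track = ff.append_derivatives(base, times, np.ones(len(times), dtype=bool),
                                      hop=cfg.hop)
        tracks[role] = track

    inter = Interaction(couple_id=couple, timepoint=timepoint, topic=topic,
                        turns=turns, tracks=tracks)
    return inter, turns, turn_means


def _simulate_codes(inter: Interaction, rating: int, cfg: SimConfig,
                    rng: np.random.Generator) -> list[tuple]:
    m = _class_multiplier(rating) * cfg.effect_size
    iid = f"{inter.couple_id}:{inter.timepoint}:{inter.topic}"
    n_ann = int(rng.integers(cfg.n_annotators[0], cfg.n_annotators[1] + 1))
    centers = 5.0 + 0.8 * m * np.asarray([CODE_POLARITY[c] for c in CODE_NAMES])
    rows = []
    for spouse in ROLES:
        # latent behavior per cell, shared by annotators (drives agreement)
        cell = centers + rng.normal(0.0, cfg.code_cell_sd, size=len(CODE_NAMES))
        draws = np.clip(np.round(
            cell[:, None] + rng.normal(0.0, cfg.code_noise_sd,
                                       size=(len(CODE_NAMES), n_ann))), 1, 9)
        for ci, code in enumerate(CODE_NAMES):
            for a in range(n_ann):
                rows.append((iid, spouse, code, f"ann{a + 1}", int(draws[ci, a])))
    return rows


# ---------------------------------------------------------------------------
# corpus-level generation
# ---------------------------------------------------------------------------

def _couple_plan(cfg: SimConfig, rng: np.random.Generator
                 ) -> list[tuple[str, int, tuple[str, ...]]]:
    plans = []
    for i in range(cfg.n_couples):
        couple = f"c{i:03d}"
        rating = int(rng.choice([1, 2, 3, 4], p=cfg.class_probs))
        if rng.uniform() < cfg.both_horizons_prob:
            horizons: tuple[str, ...] = HORIZONS
        else:
            horizons = (HORIZONS[int(rng.integers(0, 2))],)
        plans.append((couple, rating, horizons))
    return plans


def simulate_feature_corpus(cfg: SimConfig | None = None,
                            with_codes: bool = True
                            ) -> tuple[Corpus, GroundTruth, pd.DataFrame]:
    """Full in-memory corpus with frame tracks, plus ground truth and
    the long-format behavioral-code rating table."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth({}, {}, {}, {}, dict(cfg.base_f0))
    samples: list[OutcomeSample] = []
    code_rows: list[tuple] = []
    for couple, rating, horizons in _couple_plan(cfg, rng):
        truth.rating_of_couple[couple] = rating
        truth.horizons_of_couple[couple] = horizons
        sessions: dict[str, dict[str, Interaction]] = {}
        for timepoint in ("pre",) + horizons:
            sessions[timepoint] = {}
            for topic in TOPICS:
                inter, turns, means = _simulate_interaction(
                    couple, timepoint, topic, rating, cfg, rng)
                sessions[timepoint][topic] = inter
                truth.turns[(couple, timepoint, topic)] = turns
                truth.turn_means[(couple, timepoint, topic)] = means
                if with_codes:
                    code_rows.extend(_simulate_codes(inter, rating, cfg, rng))
        for horizon in horizons:
            samples.append(OutcomeSample(
                couple_id=couple, pre=sessions["pre"], post=sessions[horizon],
                rating=rating, horizon=horizon))
    ratings = pd.DataFrame(
        code_rows, columns=["interaction_id", "spouse", "code", "annotator", "rating"])
    corpus = Corpus(samples=samples, metadata={"generator": "dyadvox.synthetic",
                                               "seed": cfg.seed,
                                               "effect_size": cfg.effect_size})
    return corpus, truth, ratings


def simulate_feature_table(cfg: SimConfig | None = None,
                           set_ids: tuple[str, ...] = ("static",),
                           ) -> tuple[Corpus, dict[str, pd.DataFrame], GroundTruth]:
    """Memory-light simulation: assemble feature vectors couple by couple
    and drop the frame tracks afterwards.

    Returns a corpus whose interactions keep turns but not tracks, one
    samples x features table per requested set id, and the ground truth.
    """
    from . import functionals as fx
    from . import code_features as cf

    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    need_codes = any(s in ("codes", "all") for s in set_ids)
    truth = GroundTruth({}, {}, {}, {}, dict(cfg.base_f0))
    samples: list[OutcomeSample] = []
    tables: dict[str, list[np.ndarray]] = {s: [] for s in set_ids}
    names: dict[str, tuple[str, ...]] = {}
    index: list[str] = []

    for couple, rating, horizons in _couple_plan(cfg, rng):
        truth.rating_of_couple[couple] = rating
        truth.horizons_of_couple[couple] = horizons
        sessions: dict[str, dict[str, Interaction]] = {}
        code_rows: list[tuple] = []
        for timepoint in ("pre",) + horizons:
            sessions[timepoint] = {}
            for topic in TOPICS:
                inter, turns, means = _simulate_interaction(
                    couple, timepoint, topic, rating, cfg, rng)
                sessions[timepoint][topic] = inter
                truth.turns[(couple, timepoint, topic)] = turns
                truth.turn_means[(couple, timepoint, topic)] = means
                code_rows.extend(_simulate_codes(inter, rating, cfg, rng))
        averaged = (cf.average_annotators(pd.DataFrame(
            code_rows, columns=["interaction_id", "spouse", "code",
                                "annotator", "rating"]))
            if need_codes else None)
        for horizon in horizons:
            sample = OutcomeSample(
                couple_id=couple, pre=sessions["pre"], post=sessions[horizon],
                rating=rating, horizon=horizon)
            codes = (cf.code_feature_vector(sample, averaged)
                     if averaged is not None else None)
            for set_id in set_ids:
                vec = fx.assemble_feature_vector(sample, set_id, codes)
                if set_id not in names:
                    names[set_id] = vec.names
                tables[set_id].append(vec.values)
            samples.append(sample)
            index.append(sample.sample_id)
        for tp_sessions in sessions.values():
            for inter in tp_sessions.values():
                inter.tracks = {}
    frames = {
        s: pd.DataFrame(np.vstack(tables[s]), index=index, columns=list(names[s]))
        for s in set_ids
    }
    corpus = Corpus(samples=samples, metadata={"generator": "dyadvox.synthetic",
                                               "seed": cfg.seed,
                                               "effect_size": cfg.effect_size})
    return corpus, frames, truth


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------

def render_audio(turns: list[Turn], cfg: SimConfig | None = None,
                 rate: int = 16000, n_harmonics: int = 8,
                 amplitude: float = 0.3, seed: int | None = None
                 ) -> tuple[AudioSignal, list[SpeechSegment]]:
    """Render a turn plan as amplitude-modulated harmonic complexes.

    Each turn becomes a band-limited sawtooth-like tone at the role's
    baseline f0 (with a slow random vibrato), shaped by an attack/decay
    envelope; inter-turn gaps are silence.  Returns the 16 kHz mono
    signal plus the reference speech segments.  Deliberately schematic:
    it exercises VAD, GLR segmentation, clustering and pitch tracking,
    not speech realism.
    """
    cfg = cfg or SimConfig()
    for a, b in zip(turns, turns[1:]):
        if b.start < a.end:
            raise SimulationError("overlapping turn plan cannot be rendered")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    total = (max(t.end for t in turns) + 0.3) if turns else 0.3
    x = np.zeros(int(np.ceil(total * rate)))
    refs: list[SpeechSegment] = []
    for turn in turns:
        f0 = cfg.base_f0[turn.role]
        n = int(round(turn.duration * rate))
        t = np.arange(n) / rate
        vibrato = 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(3, 6) * t
                                      + rng.uniform(0, 2 * np.pi))
        phase = 2 * np.pi * np.cumsum(f0 * vibrato) / rate
        tone = np.zeros(n)
        for k in range(1, n_harmonics + 1):
            if k * f0 < rate / 2:
                tone += np.sin(k * phase) / k
        env = np.minimum(1.0, np.minimum(t, turn.duration - t) / 0.05)
        start = int(round(turn.start * rate))
        seg = amplitude * env * tone / 1.5
        x[start : start + n] += seg[: len(x) - start]
        refs.append(SpeechSegment(turn.start, turn.end, turn.role))
    return AudioSignal(samples=x, rate=rate), refs
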