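"""Pre-processing: voice activity detection, speaker-change detection,
two-speaker agglomerative clustering and husband/wife role assignment.

The recordings are single-channel far-field audio of exactly two
speakers of different sexes, so diarization reduces to: find speech,
cut it at likely speaker changes (generalized likelihood ratio, GLR,
on MFCC frames), agglomerate the pieces into two clusters, and label
the higher-mean-pitch cluster as the wife.

VAD here is a deliberately simple energy + spectral-flatness detector:
a frame is speech when its energy clears an adaptive noise-floor
threshold and its spectral flatness is below a cap.  It fills the same
interface a trained detector would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft

from .corpus import AudioSignal, SpeechSegment, Turn
from . import frame_features as ff

logger = logging.getLogger("dyadvox")


class DiarizationError(ValueError):
    pass


@dataclass
class VADConfig:
    frame: float = 0.025
    hop: float = 0.010
    margin_db: float = 10.0       # speech must clear noise floor by this much
    floor_percentile: float = 10.0
    abs_silence_db: float = -55.0
    flatness_max: float = 0.5     # geometric/arithmetic spectral flatness cap
    min_gap: float = 0.2          # merge speech runs separated by less
    min_dur: float = 0.2          # drop shorter speech runs


@dataclass
class GLRConfig:
    window: float = 1.0           # seconds per side
    hop: float = 0.1
    n_mfcc: int = 15
    # frozen from a synthetic stationary-Gaussian null calibration at a
    # 5% per-track false-alarm rate (15-dim, 100-frame windows, 10 s tracks:
    # null 95th percentile of the max statistic ~105)
    threshold: float = 110.0
    reg: float = 1e-6


@dataclass
class TurnConfig:
    merge_gap: float = 0.3        # same-role segments closer than this merge
    min_turn: float = 0.2         # shorter turns are discarded


@dataclass
class PreprocessConfig:
    vad: VADConfig = field(default_factory=VADConfig)
    glr: GLRConfig = field(default_factory=GLRConfig)
    turns: TurnConfig = field(default_factory=TurnConfig)


@dataclass
class DiarizationResult:
    """Two-role turn segmentation plus per-cluster summary statistics."""

    turns: list[Turn]
    cluster_stats: dict[str, dict[str, float]]  # role -> {mean_pitch, speech_time}


# ---------------------------------------------------------------------------
# Voice activity detection
# ---------------------------------------------------------------------------

def detect_voice(audio: AudioSignal, cfg: VADConfig | None = None) -> list[SpeechSegment]:
    """Energy + spectral-flatness VAD; returns merged speech segments.

    The energy threshold adapts to the recording: noise floor at the
    configured percentile of frame energy plus a margin.  All-silent
    input returns an empty list.
    """
    cfg = cfg or VADConfig()
    fcfg = ff.FeatureConfig(hop=cfg.hop, window=cfg.frame)
    frames, times = ff.frame_signal(audio.samples, audio.rate, fcfg)
    if frames.shape[0] == 0:
        return []
    energy_db = 10.0 * np.log10(np.mean(frames**2, axis=1) + 1e-12)
    windowed = frames * np.hamming(frames.shape[1])
    power = np.abs(rfft(windowed, axis=1)) ** 2 + 1e-20
    flatness = np.exp(np.mean(np.log(power), axis=1)) / np.mean(power, axis=1)

    floor = np.percentile(energy_db, cfg.floor_percentile)
    threshold = max(floor + cfg.margin_db, cfg.abs_silence_db)
    speech = (energy_db > threshold) & (flatness < cfg.flatness_max)

    segments = _runs_to_segments(speech, times, cfg.frame)
    segments = merge_close_segments(segments, cfg.min_gap)
    segments = [s for s in segments if s.duration >= cfg.min_dur]
    return segments


def _runs_to_segments(mask: np.ndarray, times: np.ndarray, frame: float) -> list[SpeechSegment]:
    """Contiguous True runs of a frame mask -> time segments (frame extents)."""
    segments: list[SpeechSegment] = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return segments
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for a, b in zip(starts, ends):
        start = max(0.0, times[a] - frame / 2)
        end = times[b] + frame / 2
        if end > start:
            segments.append(SpeechSegment(start=start, end=end))
    return segments


def merge_close_segments(segments: list[SpeechSegment], gap: float) -> list[SpeechSegment]:
    if not segments:
        return []
    merged = [segments[0]]
    for seg in segments[1:]:
        if seg.start - merged[-1].end < gap and seg.label == merged[-1].label:
            merged[-1] = SpeechSegment(merged[-1].start, max(merged[-1].end, seg.end),
                                       merged[-1].label)
        else:
            merged.append(seg)
    return merged


# ---------------------------------------------------------------------------
# Generalized likelihood ratio change detection
# ---------------------------------------------------------------------------

def _gaussian_loglik_term(x: np.ndarray, reg: float) -> float:
    """n/2 * logdet of the ML covariance of rows of x (the GLR building block)."""
    n, d = x.shape
    cov = np.cov(x, rowvar=False, bias=True) + reg * np.eye(d)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return float("inf")
    return 0.5 * n * logdet


def glr_statistic(a: np.ndarray, b: np.ndarray, reg: float = 1e-6) -> float:
    """GLR between two frame blocks under full-covariance Gaussians.

    R = L(merged) - L(a) - L(b) in 0.5*n*logdet terms; symmetric in a
    and b, ~0 for identical windows, large for distinct speakers.
    """
    both = np.vstack([a, b])
    return (_gaussian_loglik_term(both, reg)
            - _gaussian_loglik_term(a, reg)
            - _gaussian_loglik_term(b, reg))


def glr_change_points(features: np.ndarray, cfg: GLRConfig | None = None,
                      frame_hop: float = 0.010) -> list[float]:
    """Candidate speaker-change times within one speech region.

    Slides two adjacent windows over the MFCC block and reports local
    maxima of the GLR that exceed the threshold.  Regions shorter than
    two windows yield no change points.
    """
    cfg = cfg or GLRConfig()
    X = np.asarray(features, dtype=float)[:, : cfg.n_mfcc]
    L = int(round(cfg.window / frame_hop))
    hop = max(1, int(round(cfg.hop / frame_hop)))
    T = X.shape[0]
    if T < 2 * L:
        return []
    centers = np.arange(L, T - L + 1, hop)
    stats = np.array([
        glr_statistic(X[c - L : c], X[c : c + L], cfg.reg) for c in centers
    ])
    times: list[float] = []
    for i, c in enumerate(centers):
        if stats[i] <= cfg.threshold:
            continue
        lo, hi = max(0, i - 1), min(len(stats), i + 2)
        if stats[i] >= np.max(stats[lo:hi]):
            times.append(float(c * frame_hop))
    return times


def split_at_changes(segment: SpeechSegment, change_times: list[float],
                     min_piece: float = 0.2) -> list[SpeechSegment]:
    """Cut a speech segment at change times, dropping slivers."""
    bounds = [segment.start]
    for t in sorted(change_times):
        if t - bounds[-1] >= min_piece and segment.end - t >= min_piece:
            bounds.append(t)
    bounds.append(segment.end)
    return [SpeechSegment(a, b, segment.label) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# Agglomerative two-speaker clustering
# ---------------------------------------------------------------------------

def cluster_speakers(segments: list[SpeechSegment],
                     segment_features: list[np.ndarray],
                     reg: float = 1e-6) -> list[int]:
    """Merge speaker-homogeneous segments down to 2 clusters by GLR distance.

    Greedy agglomeration: repeatedly merge the cluster pair with the
    smallest GLR (pooling their frames), breaking ties by earliest
    segment index, until two clusters remain.  Returns a cluster id
    (0 or 1) per input segment; id 0 is the cluster containing the
    earliest segment.
    """
    if len(segments) < 2:
        raise DiarizationError("need at least 2 segments to form 2 clusters")
    if len(segments) != len(segment_features):
        raise DiarizationError("segments and features must align")
    clusters: list[list[int]] = [[i] for i in range(len(segments))]
    frames: list[np.ndarray] = [np.asarray(f, dtype=float) for f in segment_features]

    def dist(i: int, j: int) -> float:
        a, b = frames[i], frames[j]
        if len(a) < 3 or len(b) < 3:
            return 0.0  # too short to distinguish: merge early
        return glr_statistic(a, b, reg)

    while len(clusters) > 2:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(i, j)
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        frames[i] = np.vstack([frames[i], frames[j]])
        del clusters[j], frames[j]

    assignment = np.zeros(len(segments), dtype=int)
    # cluster 0 = the one holding the earliest segment
    first_of = [min(c) for c in clusters]
    order = np.argsort(first_of)
    for new_id, ci in enumerate(order):
        for seg_idx in clusters[ci]:
            assignment[seg_idx] = new_id
    return assignment.tolist()


# ---------------------------------------------------------------------------
# Role assignment and turn construction
# ---------------------------------------------------------------------------

def build_turns(segments: list[SpeechSegment], roles: list[str],
                cfg: TurnConfig | None = None) -> list[Turn]:
    """Merge adjacent same-role segments into turns; drop short turns."""
    cfg = cfg or TurnConfig()
    labelled = sorted(
        (SpeechSegment(s.start, s.end, r) for s, r in zip(segments, roles)),
        key=lambda s: s.start,
    )
    merged = merge_close_segments(labelled, cfg.merge_gap)
    return [Turn(role=s.label, start=s.start, end=s.end)
            for s in merged if s.duration >= cfg.min_turn]


def assign_roles(segments: list[SpeechSegment], cluster_ids: list[int],
                 pitch: np.ndarray, frame_times: np.ndarray,
                 turn_cfg: TurnConfig | None = None) -> DiarizationResult:
    """Label the higher-mean-pitch cluster as wife (W), the other husband (H).

    Mean pitch per cluster is taken over voiced frames inside the
    cluster's segments.  Equal means tie-break to the earlier cluster
    as husband (logged).  A cluster with no voiced frames is an error.
    """
    ids = np.asarray(cluster_ids)
    mean_pitch: dict[int, float] = {}
    for cid in (0, 1):
        sel = np.zeros(len(frame_times), dtype=bool)
        for seg, sid in zip(segments, ids):
            if sid == cid:
                sel |= (frame_times >= seg.start) & (frame_times < seg.end)
        vals = pitch[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise DiarizationError(
                f"cluster {cid} has no voiced frames; cannot assign roles"
            )
        mean_pitch[cid] = float(np.mean(vals))
    if mean_pitch[0] == mean_pitch[1]:
        logger.warning("equal cluster mean pitches; tie-break: first cluster -> H")
        role_of = {0: "H", 1: "W"}
    elif mean_pitch[0] < mean_pitch[1]:
        role_of = {0: "H", 1: "W"}
    else:
        role_of = {0: "W", 1: "H"}
    roles = [role_of[int(c)] for c in ids]
    turns = build_turns(segments, roles, turn_cfg)
    stats = {
        role_of[c]: {
            "mean_pitch": mean_pitch[c],
            "speech_time": float(sum(s.duration for s, i in zip(segments, ids) if i == c)),
        }
        for c in (0, 1)
    }
    return DiarizationResult(turns=turns, cluster_stats=stats)


def diarize(audio: AudioSignal, cfg: PreprocessConfig | None = None) -> DiarizationResult:
    """Full pipeline: VAD -> GLR segmentation -> 2-cluster -> roles -> turns."""
    cfg = cfg or PreprocessConfig()
    speech = detect_voice(audio, cfg.vad)
    if not speech:
        raise DiarizationError("no speech detected")
    fcfg = ff.FeatureConfig()
    spectral = ff.extract_spectral(audio, fcfg)
    _, times = ff.frame_signal(audio.samples, audio.rate, fcfg)
    pitch, _, _ = ff._autocorr_pitch(audio.samples, audio.rate, times, fcfg)

    pieces: list[SpeechSegment] = []
    for seg in speech:
        sel = (times >= seg.start) & (times < seg.end)
        changes = glr_change_points(spectral[sel], cfg.glr)
        changes = [seg.start + t for t in changes]
        pieces.extend(split_at_changes(seg, changes))
    if len(pieces) < 2:
        raise DiarizationError("fewer than 2 speech pieces; cannot cluster")
    feats = []
    for seg in pieces:
        sel = (times >= seg.start) & (times < seg.end)
        feats.append(spectral[sel, : cfg.glr.n_mfcc])
    ids = cluster_speakers(pieces, feats, cfg.glr.reg)
    return assign_roles(pieces, ids, pitch, times, cfg.turns)


# ---------------------------------------------------------------------------
# Diarization error rate
# ---------------------------------------------------------------------------

def diarization_error_rate(hyp: list[Turn], ref: list[Turn],
                           grid: float = 0.001) -> float:
    """(miss + false alarm + confusion time) / reference speech time.

    Scored on a fine time grid with the role mapping chosen to minimize
    the error (permutation-optimal over the two roles).
    """
    if not ref:
        raise DiarizationError("empty reference; DER undefined")
    end = max(t.end for t in ref + hyp if t is not None)
    n = int(np.ceil(end / grid))

    def paint(turns: list[Turn]) -> np.ndarray:
        arr = np.zeros(n, dtype=np.int8)  # 0 none, 1 H, 2 W
        code = {"H": 1, "W": 2}
        for t in turns:
            arr[int(round(t.start / grid)) : int(round(t.end / grid))] = code[t.role]
        return arr

    r, h = paint(ref), paint(hyp)
    ref_speech = np.count_nonzero(r)
    if ref_speech == 0:
        raise DiarizationError("reference has zero speech time")
    errors = []
    for mapping in ({1: 1, 2: 2}, {1: 2, 2: 1}):
        hm = np.select([h == 1, h == 2], [mapping[1], mapping[2]], default=0)
        miss = np.count_nonzero((r > 0) & (hm == 0))
        fa = np.count_nonzero((r == 0) & (hm > 0))
        conf = np.count_nonzero((r > 0) & (hm > 0) & (r != hm))
        errors.append(miss + fa + conf)
    return float(min(errors)) / float(ref_speech)
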