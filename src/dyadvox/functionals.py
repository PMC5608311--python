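"""Session-pair feature assembly.

Three feature representations summarise the 74 frame-level descriptors
for one outcome sample (two pre-therapy and two post-therapy
interactions):

* **static functionals** — 6 order statistics (mean, median, SD, min,
  max, IQR) of each feature per speaker per interaction:
  74 x 6 x (2 timepoints x 2 topics x 2 speakers) = 3552 values.
* **short-term dynamic functionals** — means per speaker turn, then
  differences between adjacent turns within a speaker (HH, WW) and
  from a husband turn to the immediately following wife turn (HW); the
  wife-to-husband direction is omitted as it is the HW sequence with
  the sign reversed.  The same 6 statistics are applied to each delta
  sequence per feature per interaction.
* **long-term dynamic functionals** — after removing silence each
  session is z-normalized per feature, its speech frames split into
  four equal-count quarters, and per-quarter per-spouse means of the
  post-therapy session are subtracted from the pre-therapy ones
  quarter by quarter: 74 x 4 x 2 = 592 values per topic.

All statistics are missing-aware (NaN entries are ignored; an empty
sequence yields NaN).  Vector element order is canonical and stable:
timepoint-major, then topic, speaker, feature, statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Interaction, OutcomeSample, Corpus, Turn, FrameTrack, TOPICS, ROLES

logger = logging.getLogger("dyadvox")

STAT_NAMES = ("mean", "median", "std", "min", "max", "iqr")
DELTA_TYPES = ("HH", "HW", "WW")
FEATURE_SETS = ("codes", "static", "dynamic", "acoustic_all", "all")
N_QUARTERS = 4


class FeatureAssemblyError(ValueError):
    pass


@dataclass
class TurnMeanSeries:
    """Per-turn missing-aware feature means, ordered by time."""

    roles: np.ndarray            # (n_turns,) of 'H'/'W'
    starts: np.ndarray
    means: np.ndarray            # (n_turns, n_features)
    feature_names: tuple[str, ...]


@dataclass
class FeatureVector:
    """Named, ordered feature assembly for one outcome sample."""

    names: tuple[str, ...]
    values: np.ndarray
    set_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise FeatureAssemblyError("names/values length mismatch")

    @property
    def dimension(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _stats(x: np.ndarray) -> np.ndarray:
    """The 6-statistic set along axis 0, NaN-aware; empty/all-NaN -> NaN.

    SD uses the population convention (a single observation has SD 0).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_feat = x.shape[1]
    out = np.full((len(STAT_NAMES), n_feat), np.nan)
    counts = np.sum(np.isfinite(x), axis=0)
    any_data = counts > 0
    if not np.any(any_data):
        return out
    if np.all(counts == x.shape[0]):  # fully observed: cheap exact path
        out[0] = np.mean(x, axis=0)
        q25, q50, q75 = np.percentile(x, [25, 50, 75], axis=0)
        out[1] = q50
        out[2] = np.std(x, axis=0, ddof=0)
        out[3] = np.min(x, axis=0)
        out[4] = np.max(x, axis=0)
        out[5] = q75 - q25
        return out
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out[0] = np.nanmean(x, axis=0)
        out[1] = np.nanmedian(x, axis=0)
        out[2] = np.nanstd(x, axis=0, ddof=0)
        out[3] = np.nanmin(x, axis=0)
        out[4] = np.nanmax(x, axis=0)
        out[5] = np.nanpercentile(x, 75, axis=0) - np.nanpercentile(x, 25, axis=0)
    out[:, ~any_data] = np.nan
    return out


# ---------------------------------------------------------------------------
# turn-level series and deltas
# ---------------------------------------------------------------------------

def turn_means(track: FrameTrack, turns: list[Turn], min_frames: int = 3) -> TurnMeanSeries:
    """Missing-aware per-turn means of every feature.

    Turns covering fewer than ``min_frames`` frames of the track are
    dropped (logged).
    """
    roles, starts, rows = [], [], []
    for turn in sorted(turns, key=lambda t: t.start):
        sel = (track.times >= turn.start) & (track.times < turn.end)
        if np.count_nonzero(sel) < min_frames:
            logger.debug("dropping turn %s@%.2fs: %d frames",
                         turn.role, turn.start, int(np.count_nonzero(sel)))
            continue
        block = track.values[sel]
        if np.all(np.isfinite(block)):
            rows.append(block.mean(axis=0))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append(np.nanmean(block, axis=0))
        roles.append(turn.role)
        starts.append(turn.start)
    if rows:
        means = np.vstack(rows)
    else:
        means = np.empty((0, len(track.feature_names)))
    return TurnMeanSeries(
        roles=np.asarray(roles, dtype=object),
        starts=np.asarray(starts, dtype=float),
        means=means,
        feature_names=track.feature_names,
    )


def merge_turn_series(a: TurnMeanSeries, b: TurnMeanSeries) -> TurnMeanSeries:
    """Interleave two per-speaker series into one time-ordered series."""
    if a.feature_names != b.feature_names:
        raise FeatureAssemblyError("cannot merge series with different features")
    starts = np.concatenate([a.starts, b.starts])
    order = np.argsort(starts, kind="stable")
    return TurnMeanSeries(
        roles=np.concatenate([a.roles, b.roles])[order],
        starts=starts[order],
        means=np.vstack([a.means, b.means])[order] if len(order) else a.means,
        feature_names=a.feature_names,
    )


def turn_deltas(series: TurnMeanSeries) -> dict[str, np.ndarray]:
    """Adjacent-turn difference sequences HH, HW, WW (later minus earlier).

    HH/WW difference consecutive turns of that speaker (intervening
    other-speaker turns are skipped); HW is the wife-turn mean minus
    the immediately preceding husband-turn mean at each H->W adjacency.
    """
    n_feat = series.means.shape[1] if series.means.ndim == 2 else 0
    empty = np.empty((0, n_feat))
    out = {d: empty for d in DELTA_TYPES}
    if len(series.roles) < 2:
        return out
    h_idx = np.flatnonzero(series.roles == "H")
    w_idx = np.flatnonzero(series.roles == "W")
    if len(h_idx) >= 2:
        out["HH"] = np.diff(series.means[h_idx], axis=0)
    if len(w_idx) >= 2:
        out["WW"] = np.diff(series.means[w_idx], axis=0)
    hw = [
        series.means[i + 1] - series.means[i]
        for i in range(len(series.roles) - 1)
        if series.roles[i] == "H" and series.roles[i + 1] == "W"
    ]
    if hw:
        out["HW"] = np.vstack(hw)
    return out


def short_term_functionals(
    deltas: dict[str, np.ndarray], feature_names: tuple[str, ...]
) -> dict[str, float]:
    """The 6-statistic set applied to each HH/HW/WW delta sequence per feature."""
    frag: dict[str, float] = {}
    for dtype in DELTA_TYPES:
        seq = deltas.get(dtype)
        stats = (_stats(seq) if seq is not None and len(seq)
                 else np.full((len(STAT_NAMES), len(feature_names)), np.nan))
        for fi, feat in enumerate(feature_names):
            for si, stat in enumerate(STAT_NAMES):
                frag[f"{dtype}.{feat}.{stat}"] = float(stats[si, fi])
    return frag


# ---------------------------------------------------------------------------
# static functionals
# ---------------------------------------------------------------------------

def static_functionals(track: FrameTrack) -> dict[str, float]:
    """6 statistics x 74 features for one speaker in one interaction."""
    stats = _stats(track.values)
    frag: dict[str, float] = {}
    for fi, feat in enumerate(track.feature_names):
        for si, stat in enumerate(STAT_NAMES):
            frag[f"{feat}.{stat}"] = float(stats[si, fi])
    return frag


# ---------------------------------------------------------------------------
# long-term functionals
# ---------------------------------------------------------------------------

def _session_quarter_means(interaction: Interaction) -> dict[str, np.ndarray]:
    """Per-quarter per-spouse means of session-z-normalized features.

    Frames of both spouses are pooled (time-ordered) for the
    normalization statistics and the equal-count quarter split; a
    feature with zero SD in the session normalizes to 0 by rule.
    Returns role -> (4, n_features), NaN where a spouse has no frames
    in a quarter.
    """
    tracks = [(role, interaction.tracks[role]) for role in ROLES
              if role in interaction.tracks]
    if not tracks:
        raise FeatureAssemblyError(
            f"interaction {interaction.couple_id}/{interaction.timepoint} has no tracks"
        )
    n_feat = len(tracks[0][1].feature_names)
    times = np.concatenate([t.times for _, t in tracks])
    values = np.vstack([t.values for _, t in tracks])
    roles = np.concatenate([np.full(t.n_frames, r, dtype=object) for r, t in tracks])
    order = np.argsort(times, kind="stable")
    values, roles = values[order], roles[order]

    if np.all(np.isfinite(values)):
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(values, axis=0)
            sd = np.nanstd(values, axis=0, ddof=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    z = values - mu
    nz = sd > 0
    z[:, nz] /= sd[nz]
    z[:, ~nz] = 0.0  # degenerate features normalize to 0, not inf
    z[~np.isfinite(values)] = np.nan

    n = len(z)
    bounds = np.round(np.linspace(0, n, N_QUARTERS + 1)).astype(int)
    out = {role: np.full((N_QUARTERS, n_feat), np.nan) for role in ROLES}
    for q in range(N_QUARTERS):
        sl = slice(bounds[q], bounds[q + 1])
        for role in ROLES:
            sel = roles[sl] == role
            if np.any(sel):
                block = z[sl][sel]
                if np.all(np.isfinite(block)):
                    out[role][q] = block.mean(axis=0)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        out[role][q] = np.nanmean(block, axis=0)
    return out


def long_term_functionals(pre: Interaction, post: Interaction) -> dict[str, float]:
    """Post-minus-pre per-quarter per-spouse normalized means (592 values)."""
    if pre.topic != post.topic or pre.couple_id != post.couple_id:
        raise FeatureAssemblyError("long-term deltas need same-couple same-topic sessions")
    qm_pre = _session_quarter_means(pre)
    qm_post = _session_quarter_means(post)
    names = next(iter(pre.tracks.values())).feature_names
    frag: dict[str, float] = {}
    for q in range(N_QUARTERS):
        for role in ROLES:
            delta = qm_post[role][q] - qm_pre[role][q]
            for fi, feat in enumerate(names):
                frag[f"q{q + 1}.{role}.{feat}"] = float(delta[fi])
    return frag


# ---------------------------------------------------------------------------
# per-sample assembly
# ---------------------------------------------------------------------------

def _sample_static(sample: OutcomeSample) -> dict[str, float]:
    frag: dict[str, float] = {}
    for tp_name, sessions in (("pre", sample.pre), ("post", sample.post)):
        for topic in TOPICS:
            inter = sessions[topic]
            for role in ROLES:
                if role not in inter.tracks:
                    raise FeatureAssemblyError(
                        f"missing {role} track in {inter.couple_id}/{inter.timepoint}"
                    )
                for name, val in static_functionals(inter.tracks[role]).items():
                    frag[f"static.{tp_name}.{topic}.{role}.{name}"] = val
    return frag


def _sample_short_term(sample: OutcomeSample) -> dict[str, float]:
    frag: dict[str, float] = {}
    for tp_name, sessions in (("pre", sample.pre), ("post", sample.post)):
        for topic in TOPICS:
            inter = sessions[topic]
            series = [
                turn_means(inter.tracks[role],
                           [t for t in inter.turns if t.role == role])
                for role in ROLES if role in inter.tracks
            ]
            merged = series[0]
            for s in series[1:]:
                merged = merge_turn_series(merged, s)
            deltas = turn_deltas(merged)
            for name, val in short_term_functionals(deltas, merged.feature_names).items():
                frag[f"short.{tp_name}.{topic}.{name}"] = val
    return frag


def _sample_long_term(sample: OutcomeSample) -> dict[str, float]:
    frag: dict[str, float] = {}
    for topic in TOPICS:
        for name, val in long_term_functionals(sample.pre[topic], sample.post[topic]).items():
            frag[f"long.{topic}.{name}"] = val
    return frag


def assemble_feature_vector(
    sample: OutcomeSample,
    set_id: str,
    code_features: dict[str, float] | None = None,
) -> FeatureVector:
    """Canonical named feature vector for one outcome sample.

    set_id: 'codes' (behavioral-code features, 264 under defaults),
    'static' (3552), 'dynamic' (short-term + long-term),
    'acoustic_all' (static + dynamic), 'all' (acoustic_all + codes).
    Code features must be supplied (see code_features module) for the
    'codes' and 'all' sets.
    """
    if set_id not in FEATURE_SETS:
        raise FeatureAssemblyError(f"unknown feature set {set_id!r}; use {FEATURE_SETS}")
    frag: dict[str, float] = {}
    if set_id in ("static", "acoustic_all", "all"):
        frag.update(_sample_static(sample))
    if set_id in ("dynamic", "acoustic_all", "all"):
        frag.update(_sample_short_term(sample))
        frag.update(_sample_long_term(sample))
    if set_id in ("codes", "all"):
        if code_features is None:
            raise FeatureAssemblyError(f"set {set_id!r} requires code features")
        frag.update(code_features)
    names = tuple(frag.keys())
    values = np.asarray(list(frag.values()), dtype=float)
    n_missing = int(np.sum(~np.isfinite(values)))
    if n_missing:
        logger.debug("sample %s: %.1f%% missing entries in %s vector",
                     sample.sample_id, 100.0 * n_missing / len(values), set_id)
    return FeatureVector(names=names, values=values, set_id=set_id)


def build_feature_table(
    corpus: Corpus,
    set_id: str,
    code_features_by_sample: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Samples x named-features matrix for a whole corpus (index: sample id)."""
    rows, index, names = [], [], None
    for sample in corpus.samples:
        cf = (code_features_by_sample or {}).get(sample.sample_id)
        vec = assemble_feature_vector(sample, set_id, cf)
        if names is None:
            names = vec.names
        elif vec.names != names:
            raise FeatureAssemblyError("inconsistent feature names across samples")
        rows.append(vec.values)
        index.append(sample.sample_id)
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(names or ()))


def write_feature_table(table: pd.DataFrame, path, registry_path=None) -> None:
    """Write the feature matrix as CSV plus a sidecar column-order registry."""
    table.to_csv(path, index_label="sample_id")
    if registry_path is not None:
        with open(registry_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(table.columns) + "\n")
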