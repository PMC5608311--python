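"""Behavioral-code features and inter-annotator agreement.

Each 10-minute interaction is rated per spouse on 33 behavioral codes
(20 from the Social Support Interaction Rating System, 13 from the
Couples Interaction Rating System) on a 1-9 scale by multiple
annotators.  The mean across annotators is the reference rating; the
per-sample feature vector stacks 33 codes x 2 spouses x 2 topics x 2
timepoints = 264 values.

Agreement is quantified with Krippendorff's alpha under the interval
metric (ratings are quasi-continuous), missing-tolerant, both pooled
over all codes and averaged per code.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .corpus import OutcomeSample, TOPICS, ROLES

logger = logging.getLogger("dyadvox")

SSIRS_CODES = (
    "global_positive_affect", "global_negative_affect", "use_of_humor",
    "influence_of_humor", "sadness", "anger_frustration",
    "belligerence_domineering", "contempt_disgust", "tension_anxiety",
    "defensiveness", "affection", "satisfaction", "solicits_suggestions",
    "instrumental_support", "emotional_support", "submissive_or_dominant",
    "topic_relationship_issue", "topic_personal_issue",
    "discussion_about_husband", "discussion_about_wife",
)
CIRS_CODES = (
    "acceptance_of_other", "blame", "responsibility_for_self",
    "solicits_partner_perspective", "states_external_origins", "discussion",
    "defines_problem", "offers_solutions", "negotiates", "makes_agreements",
    "pressures_for_change", "withdraws", "avoidance",
)
CODE_NAMES: tuple[str, ...] = SSIRS_CODES + CIRS_CODES  # 33 codes

RATING_COLUMNS = ("interaction_id", "spouse", "code", "annotator", "rating")


class CodeError(ValueError):
    pass


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format rating table (1-9 scale, known codes)."""
    missing = set(RATING_COLUMNS) - set(ratings.columns)
    if missing:
        raise CodeError(f"rating table missing columns: {sorted(missing)}")
    vals = ratings["rating"].to_numpy(dtype=float)
    if np.any((vals < 1) | (vals > 9)):
        raise CodeError("ratings must lie in [1, 9]")
    unknown = set(ratings["code"]) - set(CODE_NAMES)
    if unknown:
        raise CodeError(f"unknown behavioral codes: {sorted(unknown)[:5]}")
    return ratings


def average_annotators(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean rating per (interaction, spouse, code) across annotators."""
    validate_ratings(ratings)
    return (
        ratings.groupby(["interaction_id", "spouse", "code"], sort=True)["rating"]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Krippendorff's alpha (interval metric)
# ---------------------------------------------------------------------------

def _alpha_from_matrix(m: np.ndarray) -> float:
    """Interval-metric alpha from an items x coders matrix with NaN gaps.

    alpha = 1 - D_o / D_e where D_o averages squared differences within
    units (each unit weighted by its pairable values) and D_e over all
    pairable values regardless of unit.
    """
    m = np.asarray(m, dtype=float)
    counts = np.sum(np.isfinite(m), axis=1)
    usable = counts >= 2
    if not np.any(usable):
        raise CodeError("no unit has two or more ratings; alpha undefined")
    n_pairable = int(counts[usable].sum())
    do_sum = 0.0
    for row, mu in zip(m[usable], counts[usable]):
        vals = row[np.isfinite(row)]
        diffs = vals[:, None] - vals[None, :]
        do_sum += np.sum(diffs**2) / (mu - 1)
    d_o = do_sum / n_pairable
    pooled = m[usable][np.isfinite(m[usable])]
    if len(np.unique(pooled)) < 2:
        raise CodeError("all pairable ratings identical; alpha undefined")
    diffs = pooled[:, None] - pooled[None, :]
    d_e = np.sum(diffs**2) / (n_pairable * (n_pairable - 1))
    return float(1.0 - d_o / d_e)


def _pivot(ratings: pd.DataFrame) -> np.ndarray:
    wide = ratings.pivot_table(
        index=["interaction_id", "spouse", "code"],
        columns="annotator", values="rating", aggfunc="mean",
    )
    return wide.to_numpy(dtype=float)


def krippendorff_alpha(ratings: pd.DataFrame, per_code_average: bool = False) -> float:
    """Interval-metric Krippendorff alpha of a long-format rating table.

    With ``per_code_average`` the alpha is computed separately per code
    (units = interaction x spouse) and averaged over codes that have
    co-rated items; otherwise all (interaction, spouse, code) cells are
    pooled as units.
    """
    validate_ratings(ratings)
    if not per_code_average:
        return _alpha_from_matrix(_pivot(ratings))
    alphas = []
    for _, sub in ratings.groupby("code", sort=True):
        try:
            alphas.append(_alpha_from_matrix(_pivot(sub)))
        except CodeError:
            continue
    if not alphas:
        raise CodeError("no code has co-rated items; alpha undefined")
    return float(np.mean(alphas))


# ---------------------------------------------------------------------------
# per-sample code feature vector
# ---------------------------------------------------------------------------

def interaction_id(couple_id: str, timepoint: str, topic: str) -> str:
    return f"{couple_id}:{timepoint}:{topic}"


def code_feature_vector(
    sample: OutcomeSample, averaged: pd.DataFrame
) -> dict[str, float]:
    """264-value fragment: 33 codes x 2 spouses x 2 topics x 2 timepoints.

    ``averaged`` is the output of :func:`average_annotators`.  Missing
    cells become NaN (logged); canonical order is timepoint-major, then
    topic, spouse, code.
    """
    lookup = {
        (r.interaction_id, r.spouse, r.code): float(r.rating)
        for r in averaged.itertuples()
    }
    frag: dict[str, float] = {}
    n_missing = 0
    for tp_name, sessions in (("pre", sample.pre), ("post", sample.post)):
        for topic in TOPICS:
            inter = sessions[topic]
            iid = interaction_id(inter.couple_id, inter.timepoint, topic)
            for spouse in ROLES:
                for code in CODE_NAMES:
                    val = lookup.get((iid, spouse, code), np.nan)
                    if not np.isfinite(val):
                        n_missing += 1
                    frag[f"codes.{tp_name}.{topic}.{spouse}.{code}"] = val
    if n_missing:
        logger.debug("sample %s: %d/%d code cells missing",
                     sample.sample_id, n_missing, len(frag))
    return frag


def code_features_by_sample(
    samples, averaged: pd.DataFrame
) -> dict[str, dict[str, float]]:
    return {s.sample_id: code_feature_vector(s, averaged) for s in samples}
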