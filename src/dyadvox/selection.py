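"""Feature relevance: Pearson correlation ranking and mutual-information
maximisation (MIM) selection.

For correlation analysis the 4-level outcome is binarized into
recovery (rating 4) vs no recovery (ratings 1-3); each feature gets a
Pearson r against the binary label with a two-tailed t-test p-value.

MIM scores every feature X_k by the plug-in mutual information
I(X_k; Y) in bits after equal-frequency discretization, and selection
keeps the top-k features (k chosen by inner cross-validation on the
training split only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("dyadvox")


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    method: str = "mim"                    # 'mim' or 'pearson'
    bins: int = 10                         # equal-frequency bins for MI
    # candidate selected fractions of the feature dimension
    k_fractions: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)

    def k_grid(self, dim: int) -> list[int]:
        ks = sorted({max(1, min(dim, int(round(f * dim)))) for f in self.k_fractions})
        if not ks:
            raise SelectionError("empty k grid")
        return ks


# ---------------------------------------------------------------------------
# outcome binarization and correlation
# ---------------------------------------------------------------------------

def binarize_outcome(ratings) -> np.ndarray:
    """Map outcome ratings to recovery labels: 4 -> 1, {1,2,3} -> 0."""
    r = np.asarray(ratings, dtype=int)
    if np.any((r < 1) | (r > 4)):
        raise SelectionError("outcome ratings must lie in 1..4")
    return (r == 4).astype(int)


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-tailed p-value (t-transform, n-2 df).

    Zero-variance x yields (nan, nan) with a log entry rather than an
    error, so vectorized reports can skip degenerate features.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise SelectionError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.debug("zero-variance input to correlation; returning NaN")
        return float("nan"), float("nan")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_report(
    X: pd.DataFrame, ratings, functional_sep: str = "."
) -> pd.DataFrame:
    """Per-feature Pearson r and p against the binarized outcome.

    Returns a frame (feature, r, p, abs_r) sorted by |r| descending.
    """
    y = binarize_outcome(ratings)
    rows = []
    for col in X.columns:
        try:
            r, p = pearson_with_test(X[col].to_numpy(), y)
        except SelectionError:
            continue
        if np.isfinite(r):
            rows.append((col, r, p, abs(r)))
    rep = pd.DataFrame(rows, columns=["feature", "r", "p", "abs_r"])
    return rep.sort_values("abs_r", ascending=False, kind="stable").reset_index(drop=True)


def top_functional_per_feature(report: pd.DataFrame, base_names) -> pd.DataFrame:
    """For each base acoustic feature keep its max-|r| functional."""
    rows = []
    for base in base_names:
        sub = report[report["feature"].str.contains(f".{base}.", regex=False)
                     | report["feature"].str.endswith(f".{base}")]
        if len(sub):
            rows.append(sub.iloc[0])
    if not rows:
        return report.iloc[0:0]
    return (pd.DataFrame(rows)
            .sort_values("abs_r", ascending=False, kind="stable")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# mutual information maximisation
# ---------------------------------------------------------------------------

def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize a column into (at most) ``bins`` equal-frequency bins."""
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information_bits(xd: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI in bits between two discrete label vectors."""
    xs, xi = np.unique(xd, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mim_scores(X: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    """I(X_k; Y) in bits per column after equal-frequency binning.

    Constant columns score 0; NaNs are assigned to a dedicated bin so
    missingness itself can carry (training-split) information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("need at least 2 classes for MI scores")
    scores = np.zeros(X.shape[1])
    for k in range(X.shape[1]):
        col = X[:, k]
        finite = np.isfinite(col)
        if not np.any(finite) or np.nanstd(col) == 0:
            continue
        xd = np.full(len(col), -1, dtype=int)
        xd[finite] = equal_frequency_bins(col[finite], bins)
        scores[k] = max(0.0, mutual_information_bits(xd, y))
    return scores


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest scores; ties go to the lower index."""
    scores = np.asarray(scores, dtype=float)
    if k > len(scores):
        raise SelectionError(f"k={k} exceeds dimension {len(scores)}")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


def choose_k_by_cv(X, y, k_grid, evaluate, seed: int = 0) -> int:
    """Pick k from a grid by an inner-CV evaluation callback.

    ``evaluate(X_sel, y, seed) -> accuracy`` is supplied by the caller
    (the classifier module) so selection stays classifier-agnostic.
    Ties prefer the smaller k.
    """
    if not len(k_grid):
        raise SelectionError("empty k grid")
    scores = mim_scores(X, y)
    best_k, best_acc = None, -np.inf
    for k in sorted(k_grid):
        idx = select_top_k(scores, k)
        acc = evaluate(np.asarray(X, dtype=float)[:, idx], y, seed)
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return int(best_k)


def selection_report(scores: np.ndarray, names, k: int) -> pd.DataFrame:
    selected = np.zeros(len(scores), dtype=bool)
    selected[select_top_k(scores, k)] = True
    rank = sps.rankdata(-scores, method="ordinal")
    return pd.DataFrame({
        "feature": list(names), "score": scores, "rank": rank.astype(int),
        "selected": selected,
    }).sort_values("rank", kind="stable").reset_index(drop=True)
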