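"""Evaluation metrics and statistical comparisons.

Fold-wise accuracy and macro-averaged F1 summaries, majority-class
chance rates, exact paired comparison of two feature sets (two-tailed
binomial test on discordant out-of-fold predictions, i.e. exact
McNemar), and Clopper-Pearson intervals for the discordance-direction
proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score

from .corpus import Corpus
from .classify import CVResult, ExperimentSpec, EXPERIMENTS

logger = logging.getLogger("dyadvox")


class EvaluationError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """Exact paired comparison of two classifiers on shared samples."""

    p: float
    n_discordant: int
    n_favoring_a: int
    ci: tuple[float, float]      # 95% CI for the proportion favoring A


# ---------------------------------------------------------------------------
# fold summaries
# ---------------------------------------------------------------------------

def accuracy_summary(result: CVResult) -> tuple[float, float]:
    """(mean %, SD %) of per-fold accuracies."""
    accs = [f.accuracy for f in result.folds if len(f.test_ids)]
    if not accs:
        raise EvaluationError("no non-empty folds")
    accs = np.asarray(accs) * 100.0
    return float(np.mean(accs)), float(np.std(accs, ddof=0))


def f_summary(result: CVResult) -> tuple[float, float]:
    """(mean, SD) of per-fold macro-averaged F1 scores."""
    fs = []
    for fold in result.folds:
        if not len(fold.test_ids):
            logger.info("fold %d has no test samples; excluded", fold.fold)
            continue
        fs.append(f1_score(fold.y_true, fold.y_pred, average="macro",
                           zero_division=0))
    if not fs:
        raise EvaluationError("no non-empty folds")
    fs = np.asarray(fs)
    return float(np.mean(fs)), float(np.std(fs, ddof=0))


def chance_rate(corpus: Corpus, spec: ExperimentSpec | int) -> float:
    """Majority-class rate (%) on the experiment's sample domain, 1 decimal."""
    spec = EXPERIMENTS[spec] if isinstance(spec, int) else spec
    ratings = [s.rating for s in corpus.samples if spec.in_domain(s)]
    if not ratings:
        raise EvaluationError(f"no samples in experiment {spec.id} domain")
    labels = spec.labels(ratings)
    _, counts = np.unique(labels, return_counts=True)
    return round(100.0 * counts.max() / len(labels), 1)


# ---------------------------------------------------------------------------
# paired exact comparison
# ---------------------------------------------------------------------------

def compare_feature_sets(res_a: CVResult, res_b: CVResult,
                         level: float = 0.95) -> ComparisonResult:
    """Exact McNemar on pooled out-of-fold predictions.

    Among samples where exactly one system is correct, the count
    favoring A is tested against Binomial(n, 1/2), two-tailed; the CI
    is the Clopper-Pearson interval for the proportion favoring A.
    """
    a = res_a.pooled.set_index("sample_id")
    b = res_b.pooled.set_index("sample_id")
    if set(a.index) != set(b.index):
        raise EvaluationError("results cover different sample domains")
    b = b.loc[a.index]
    if not np.array_equal(a["y_true"].to_numpy(), b["y_true"].to_numpy()):
        raise EvaluationError("results disagree on true labels")
    correct_a = a["y_pred"].to_numpy() == a["y_true"].to_numpy()
    correct_b = b["y_pred"].to_numpy() == b["y_true"].to_numpy()
    discordant = correct_a != correct_b
    n = int(np.sum(discordant))
    k = int(np.sum(correct_a & discordant))
    if n == 0:
        logger.info("no discordant samples; comparison degenerate")
        return ComparisonResult(p=1.0, n_discordant=0, n_favoring_a=0,
                                ci=(0.0, 1.0))
    p = float(sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return ComparisonResult(p=p, n_discordant=n, n_favoring_a=k,
                            ci=clopper_pearson(k, n, level))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if not (0 <= k <= n) or n < 1:
        raise EvaluationError(f"invalid successes/trials: k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lower, upper)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def summarize_results(results: dict[tuple[str, int], CVResult],
                      corpus: Corpus) -> pd.DataFrame:
    """Feature-set x experiment table of accuracy and F summaries.

    Percentages to 1 decimal, F-scores to 2, plus the chance row.
    """
    rows = []
    experiments = sorted({e for _, e in results})
    chance = {"feature_set": "chance", "dim": None}
    for e in experiments:
        chance[f"expt{e}_acc_mean"] = chance_rate(corpus, e)
    rows.append(chance)
    for fset in sorted({f for f, _ in results}):
        row: dict = {"feature_set": fset}
        for e in experiments:
            res = results.get((fset, e))
            if res is None:
                continue
            am, asd = accuracy_summary(res)
            fm, fsd = f_summary(res)
            row[f"expt{e}_acc_mean"] = round(am, 1)
            row[f"expt{e}_acc_sd"] = round(asd, 1)
            row[f"expt{e}_f_mean"] = round(fm, 2)
            row[f"expt{e}_f_sd"] = round(fsd, 2)
        rows.append(row)
    return pd.DataFrame(rows)
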