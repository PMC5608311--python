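"""Outcome-prediction experiments: couple-grouped 10-fold cross-validated
RBF-SVM classification with per-fold normalization, feature selection
and grid search.

Three experiments share one machinery:

* Experiment 1 — recovery (rating 4) vs no recovery (1-3), all samples;
* Experiment 2 — ratings 1 vs 2 vs 3 on the non-recovered subset;
* Experiment 3 — all four ratings.

The two outcome samples of one couple (26-week and 2-year horizons)
always share a fold, so no couple appears in both a training and a
test split.  Every fitted statistic — median imputation, z-score
normalization, MIM selection, the (C, gamma) grid search — is computed
on the training split only; each fold records which sample ids its
statistics touched so leakage is checkable after the fact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .corpus import Corpus, OutcomeSample
from .selection import SelectionConfig, mim_scores, select_top_k, SelectionError

logger = logging.getLogger("dyadvox")


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentSpec:
    """Label map and sample domain of one classification experiment."""

    id: int
    name: str
    domain_ratings: tuple[int, ...]
    label_map: dict[int, int] = field(hash=False)

    def labels(self, ratings) -> np.ndarray:
        out = []
        for r in np.asarray(ratings, dtype=int):
            if r not in self.label_map:
                raise ExperimentError(f"rating {r} outside experiment {self.id} domain")
            out.append(self.label_map[r])
        return np.asarray(out, dtype=int)

    def in_domain(self, sample: OutcomeSample) -> bool:
        return sample.rating in self.domain_ratings


EXPERIMENTS: dict[int, ExperimentSpec] = {
    1: ExperimentSpec(1, "recovery_vs_not", (1, 2, 3, 4),
                      {1: 0, 2: 0, 3: 0, 4: 1}),
    2: ExperimentSpec(2, "nonrecovered_levels", (1, 2, 3),
                      {1: 1, 2: 2, 3: 3}),
    3: ExperimentSpec(3, "all_four_ratings", (1, 2, 3, 4),
                      {1: 1, 2: 2, 3: 3, 4: 4}),
}


@dataclass
class ClassifierConfig:
    # default grid contains the reported optimum (C=1000, gamma=0.001)
    C_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    gamma_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    inner_folds: int = 5
    n_folds: int = 10

    def __post_init__(self) -> None:
        self.C_grid = tuple(sorted(set(self.C_grid)))
        self.gamma_grid = tuple(sorted(set(self.gamma_grid)))
        if not self.C_grid or not self.gamma_grid:
            raise ExperimentError("empty SVM parameter grid")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ExperimentError("C and gamma must be positive")


@dataclass
class FoldResult:
    fold: int
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    chosen_k: int
    chosen_C: float
    chosen_gamma: float
    # sample ids each fitted statistic touched (leakage audit trail)
    stat_sample_ids: dict[str, set[str]] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


@dataclass
class CVResult:
    experiment: int
    feature_set: str
    folds: list[FoldResult]

    @property
    def pooled(self) -> pd.DataFrame:
        """Out-of-fold predictions, one row per sample."""
        frames = [
            pd.DataFrame({"sample_id": f.test_ids, "y_true": f.y_true,
                          "y_pred": f.y_pred, "fold": f.fold})
            for f in self.folds
        ]
        return pd.concat(frames, ignore_index=True).sort_values("sample_id")

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.asarray([f.accuracy for f in self.folds])


# ---------------------------------------------------------------------------
# grouped folds
# ---------------------------------------------------------------------------

def make_grouped_folds(samples: list[OutcomeSample], labels: np.ndarray,
                       n_folds: int = 10, seed: int = 0,
                       max_redraws: int = 100) -> np.ndarray:
    """Fold id per sample with both samples of a couple kept together.

    Couples are shuffled and dealt round-robin, balancing fold sizes to
    within one couple.  Assignments are re-drawn (bounded) until every
    class is present in every training split.
    """
    couples: list[str] = []
    for s in samples:
        if s.couple_id not in couples:
            couples.append(s.couple_id)
    if n_folds > len(couples):
        raise ExperimentError(f"{n_folds} folds but only {len(couples)} couples")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws):
        order = rng.permutation(len(couples))
        fold_of_couple = {couples[ci]: int(i % n_folds) for i, ci in enumerate(order)}
        folds = np.asarray([fold_of_couple[s.couple_id] for s in samples])
        ok = all(
            np.all(np.isin(classes, labels[folds != f])) for f in range(n_folds)
        )
        if ok:
            if attempt:
                logger.debug("grouped folds: %d redraws for class coverage", attempt)
            return folds
    raise ExperimentError(
        "could not stratify: some class missing from a training split after "
        f"{max_redraws} redraws"
    )


# ---------------------------------------------------------------------------
# per-fold fitted transforms
# ---------------------------------------------------------------------------

def median_impute(train_X: np.ndarray, test_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaNs by the training-split median per feature."""
    train_X = np.array(train_X, dtype=float)
    test_X = np.array(test_X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(train_X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    for X in (train_X, test_X):
        nan_r, nan_c = np.nonzero(~np.isfinite(X))
        X[nan_r, nan_c] = med[nan_c]
    return train_X, test_X


def normalize_fit_apply(train_X: np.ndarray, test_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score both splits using training-split mean/SD per feature.

    Zero-SD (constant) training features map to 0 in both splits.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] == 0:
        raise ExperimentError("empty training split")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    nz = sd > 0
    def apply(X: np.ndarray) -> np.ndarray:
        Z = np.zeros_like(X)
        Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
        return Z
    return apply(train_X), apply(test_X)


# ---------------------------------------------------------------------------
# one-against-all RBF SVM
# ---------------------------------------------------------------------------

class OneVsAllSVM:
    """One binary RBF SVC per class; prediction by margin argmax.

    Decision ties resolve to the lowest class label.
    """

    def __init__(self, C: float, gamma: float) -> None:
        self.C, self.gamma = C, gamma
        self.classes_: np.ndarray | None = None
        self._machines: list[SVC] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsAllSVM":
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ExperimentError("need at least 2 classes to train")
        self._machines = []
        for c in self.classes_:
            m = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
            m.fit(X, (y == c).astype(int))
            self._machines.append(m)
        return self

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_function(X) for m in self._machines])

    def predict(self, X: np.ndarray) -> np.ndarray:
        margins = self.decision_matrix(X)
        # argmax returns the first (lowest-class) index on exact ties
        return self.classes_[np.argmax(margins, axis=1)]


def _inner_fold_ids(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified-ish inner folds; falls back to 3 folds if degenerate."""
    rng = np.random.default_rng(seed)
    for folds in (n_folds, 3):
        assign = np.zeros(len(y), dtype=int)
        ok = True
        for c in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == c))
            assign[idx] = np.arange(len(idx)) % folds
        for f in range(folds):
            if len(np.unique(y[assign != f])) < 2 or np.sum(assign == f) == 0:
                ok = False
                break
        if ok:
            return assign
        logger.debug("inner CV degenerate at %d folds; falling back", folds)
    raise ExperimentError("cannot build inner CV folds: a class is too small")


def inner_cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                      n_folds: int, seed: int) -> float:
    assign = _inner_fold_ids(y, n_folds, seed)
    correct = 0
    for f in np.unique(assign):
        tr, te = assign != f, assign == f
        Xtr, Xte = normalize_fit_apply(X[tr], X[te])
        model = OneVsAllSVM(C, gamma).fit(Xtr, y[tr])
        correct += int(np.sum(model.predict(Xte) == y[te]))
    return correct / len(y)


def grid_search_svm(train_X: np.ndarray, train_y: np.ndarray,
                    cfg: ClassifierConfig | None = None,
                    seed: int = 0) -> tuple[float, float]:
    """(C*, gamma*) maximizing inner-CV accuracy; ties -> smallest C then gamma."""
    cfg = cfg or ClassifierConfig()
    if len(np.unique(train_y)) < 2:
        raise ExperimentError("grid search needs at least 2 classes")
    best = None
    for C in cfg.C_grid:
        for gamma in cfg.gamma_grid:
            acc = inner_cv_accuracy(train_X, train_y, C, gamma,
                                    cfg.inner_folds, seed)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def run_experiment(
    corpus: Corpus,
    feature_table: pd.DataFrame,
    spec: ExperimentSpec | int,
    seed: int = 0,
    sel_cfg: SelectionConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    feature_set: str = "unspecified",
) -> CVResult:
    """Couple-grouped outer CV with per-fold impute/normalize/select/search.

    ``feature_table`` is a samples x features frame indexed by sample
    id (see functionals.build_feature_table).  All randomness derives
    from ``seed``.
    """
    spec = EXPERIMENTS[spec] if isinstance(spec, int) else spec
    sel_cfg = sel_cfg or SelectionConfig()
    clf_cfg = clf_cfg or ClassifierConfig()

    samples = [s for s in corpus.samples if spec.in_domain(s)]
    if not samples:
        raise ExperimentError(f"no samples in experiment {spec.id} domain")
    ids = [s.sample_id for s in samples]
    missing = [i for i in ids if i not in feature_table.index]
    if missing:
        raise ExperimentError(f"feature table lacks samples: {missing[:5]}")
    X_all = feature_table.loc[ids].to_numpy(dtype=float)
    y_all = spec.labels([s.rating for s in samples])

    folds = make_grouped_folds(samples, y_all, clf_cfg.n_folds, seed)
    results: list[FoldResult] = []
    for f in range(clf_cfg.n_folds):
        tr, te = folds != f, folds == f
        if not np.any(te):
            logger.info("fold %d empty; skipped", f)
            continue
        train_ids = {ids[i] for i in np.flatnonzero(tr)}
        Xtr_raw, Xte_raw = X_all[tr], X_all[te]
        ytr, yte = y_all[tr], y_all[te]

        Xtr, Xte = median_impute(Xtr_raw, Xte_raw)

        scores = mim_scores(Xtr, ytr, sel_cfg.bins)
        k_grid = sel_cfg.k_grid(Xtr.shape[1])
        if len(k_grid) > 1:
            k = _choose_k(Xtr, ytr, scores, k_grid, clf_cfg, seed + f)
        else:
            k = k_grid[0]
        sel = select_top_k(scores, k)
        Xtr_sel, Xte_sel = Xtr[:, sel], Xte[:, sel]

        C, gamma = grid_search_svm(Xtr_sel, ytr, clf_cfg, seed + f)
        Ztr, Zte = normalize_fit_apply(Xtr_sel, Xte_sel)
        model = OneVsAllSVM(C, gamma).fit(Ztr, ytr)
        y_pred = model.predict(Zte)
        results.append(FoldResult(
            fold=f,
            test_ids=[ids[i] for i in np.flatnonzero(te)],
            y_true=yte, y_pred=y_pred, chosen_k=k, chosen_C=C, chosen_gamma=gamma,
            stat_sample_ids={
                "imputation": set(train_ids),
                "selection": set(train_ids),
                "normalization": set(train_ids),
                "grid_search": set(train_ids),
            },
        ))
    return CVResult(experiment=spec.id, feature_set=feature_set, folds=results)


def _choose_k(Xtr, ytr, scores, k_grid, clf_cfg: ClassifierConfig, seed: int) -> int:
    """k* by inner-CV accuracy at the reference operating point (C=1000,
    gamma=0.001); the full (C, gamma) search then runs on the selected set."""
    best_k, best_acc = k_grid[0], -np.inf
    for k in sorted(k_grid):
        idx = select_top_k(scores, k)
        try:
            acc = inner_cv_accuracy(Xtr[:, idx], ytr, 1000.0, 1e-3,
                                    clf_cfg.inner_folds, seed)
        except ExperimentError:
            continue
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return best_k
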