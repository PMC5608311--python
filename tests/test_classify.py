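"""Grouped folds, per-fold transforms, SVM search, experiment runs."""

import numpy as np
import pandas as pd
import pytest

from dyadvox import classify as cl
from dyadvox.corpus import Corpus, Interaction, OutcomeSample
from dyadvox.selection import SelectionConfig
from dyadvox.synthetic import SimConfig, simulate_feature_table

SMALL_SEL = SelectionConfig(k_fractions=(0.02, 0.05))
SMALL_CLF = cl.ClassifierConfig(C_grid=(10.0, 1000.0), gamma_grid=(1e-3, 1e-2),
                                n_folds=5, inner_folds=3)


def sample_stub(couple, rating, horizon):
    pre = {t: Interaction(couple, "pre", t) for t in ("husband_chosen", "wife_chosen")}
    post = {t: Interaction(couple, horizon, t) for t in ("husband_chosen", "wife_chosen")}
    return OutcomeSample(couple, pre, post, rating, horizon)


def stub_samples(n_couples, both=True):
    samples = []
    for i in range(n_couples):
        rating = [1, 2, 3, 4][i % 4]
        samples.append(sample_stub(f"c{i}", rating, "26wk"))
        if both:
            samples.append(sample_stub(f"c{i}", rating, "2yr"))
    return samples


class TestGroupedFolds:
    def test_couple_samples_share_fold(self):
        samples = stub_samples(20)
        labels = np.asarray([s.rating for s in samples])
        folds = cl.make_grouped_folds(samples, labels, n_folds=10, seed=0)
        by_couple = {}
        for s, f in zip(samples, folds):
            by_couple.setdefault(s.couple_id, set()).add(int(f))
        assert all(len(v) == 1 for v in by_couple.values())

    def test_ten_couples_ten_folds(self):
        samples = stub_samples(10, both=False)
        labels = np.asarray([s.rating for s in samples])
        folds = cl.make_grouped_folds(samples, labels, n_folds=10, seed=1)
        assert sorted(folds.tolist()) == list(range(10))

    def test_seeded_reproducibility(self):
        samples = stub_samples(15)
        labels = np.asarray([s.rating for s in samples])
        runs = [cl.make_grouped_folds(samples, labels, 5, seed=42)
                for _ in range(5)]
        for r in runs[1:]:
            np.testing.assert_array_equal(runs[0], r)

    def test_fold_sizes_balanced(self):
        samples = stub_samples(23, both=False)
        labels = np.asarray([s.rating for s in samples])
        folds = cl.make_grouped_folds(samples, labels, 5, seed=2)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_every_training_split_sees_every_class(self):
        samples = stub_samples(12)
        labels = np.asarray([s.rating for s in samples])
        folds = cl.make_grouped_folds(samples, labels, 6, seed=3)
        for f in range(6):
            assert set(labels[folds != f]) == {1, 2, 3, 4}


class TestTransforms:
    def test_normalize_arithmetic(self):
        tr = np.array([[2.0], [4.0]])
        te = np.array([[3.0]])
        ztr, zte = cl.normalize_fit_apply(tr, te)
        assert ztr[:, 0].tolist() == [-1.0, 1.0]
        assert zte[0, 0] == 0.0

    def test_constant_column_maps_to_zero(self):
        tr = np.full((5, 1), 7.0)
        te = np.array([[9.0]])
        ztr, zte = cl.normalize_fit_apply(tr, te)
        assert np.all(ztr == 0.0) and np.all(zte == 0.0)

    def test_round_trip_identity_on_train(self):
        rng = np.random.default_rng(0)
        tr = rng.standard_normal((20, 4))
        ztr, _ = cl.normalize_fit_apply(tr, tr)
        mu, sd = tr.mean(0), tr.std(0)
        np.testing.assert_allclose(ztr * sd + mu, tr, atol=1e-12)

    def test_median_impute_uses_train_only(self):
        tr = np.array([[1.0], [3.0], [np.nan]])
        te = np.array([[np.nan]])
        itr, ite = cl.median_impute(tr, te)
        assert itr[2, 0] == 2.0 and ite[0, 0] == 2.0


class TestGridSearch:
    def test_default_grid_contains_reported_optimum(self):
        cfg = cl.ClassifierConfig()
        assert 1000.0 in cfg.C_grid and 1e-3 in cfg.gamma_grid

    def test_duplicated_grid_deduplicated(self):
        cfg = cl.ClassifierConfig(C_grid=(1.0, 1.0, 10.0), gamma_grid=(0.1, 0.1))
        assert cfg.C_grid == (1.0, 10.0) and cfg.gamma_grid == (0.1,)

    def test_separable_blobs_high_inner_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((30, 2)) + 6.0])
        y = np.repeat([0, 1], 30)
        C, gamma = cl.grid_search_svm(X, y, SMALL_CLF, seed=0)
        acc = cl.inner_cv_accuracy(X, y, C, gamma, 3, 0)
        assert acc >= 0.95

    def test_one_vs_all_tie_goes_to_lowest_class(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 2))
        y = np.repeat([1, 2, 3], 10)
        model = cl.OneVsAllSVM(1.0, 0.5).fit(X, y)
        preds = model.predict(X)
        assert set(preds) <= {1, 2, 3}


@pytest.fixture(scope="module")
def effect_corpus():
    cfg = SimConfig(n_couples=24, seed=5, effect_size=2.0,
                    turns_per_interaction=(10, 14), turn_dur=(0.6, 1.2))
    corpus, tables, _ = simulate_feature_table(cfg, set_ids=("static",))
    return corpus, tables["static"]


class TestRunExperiment:
    def test_every_sample_predicted_once(self, effect_corpus):
        corpus, table = effect_corpus
        res = cl.run_experiment(corpus, table, 1, seed=3,
                                sel_cfg=SMALL_SEL, clf_cfg=SMALL_CLF)
        pooled = res.pooled
        domain = [s.sample_id for s in corpus.samples]
        assert sorted(pooled["sample_id"]) == sorted(domain)
        assert pooled["sample_id"].is_unique

    def test_no_leakage_instrumentation(self, effect_corpus):
        corpus, table = effect_corpus
        res = cl.run_experiment(corpus, table, 1, seed=3,
                                sel_cfg=SMALL_SEL, clf_cfg=SMALL_CLF)
        for fold in res.folds:
            test_ids = set(fold.test_ids)
            for stat, touched in fold.stat_sample_ids.items():
                assert not (touched & test_ids), f"{stat} touched test samples"

    def test_experiment2_domain_is_experiment1_negative_class(self, effect_corpus):
        corpus, table = effect_corpus
        neg = {s.sample_id for s in corpus.samples if s.rating in (1, 2, 3)}
        spec2 = cl.EXPERIMENTS[2]
        dom2 = {s.sample_id for s in corpus.samples if spec2.in_domain(s)}
        assert dom2 == neg

    def test_perfectly_coded_dummy_feature_found(self, effect_corpus):
        """Selection must find a leak-by-construction class-coded column."""
        corpus, table = effect_corpus
        spec = cl.EXPERIMENTS[1]
        y = {s.sample_id: spec.label_map[s.rating] for s in corpus.samples}
        leaked = table.copy()
        leaked["dummy"] = [float(y[i]) for i in leaked.index]
        res = cl.run_experiment(corpus, leaked, 1, seed=3,
                                sel_cfg=SMALL_SEL, clf_cfg=SMALL_CLF)
        assert all(f.accuracy == 1.0 for f in res.folds)

    def test_effect_recovery_beats_chance(self, effect_corpus):
        from dyadvox.evaluate import accuracy_summary, chance_rate
        corpus, table = effect_corpus
        res = cl.run_experiment(corpus, table, 1, seed=3,
                                sel_cfg=SMALL_SEL, clf_cfg=SMALL_CLF)
        mean_acc, _ = accuracy_summary(res)
        assert mean_acc >= chance_rate(corpus, 1) + 15.0

    def test_unknown_feature_set_or_missing_samples(self, effect_corpus):
        corpus, table = effect_corpus
        with pytest.raises(cl.ExperimentError, match="lacks samples"):
            cl.run_experiment(corpus, table.iloc[:3], 1, seed=0,
                              sel_cfg=SMALL_SEL, clf_cfg=SMALL_CLF)
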