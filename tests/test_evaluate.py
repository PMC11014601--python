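"""Splitting, oversampling, metrics, model training, repeated CV, tuning."""

import numpy as np
import pandas as pd
import pytest

from pathpairs import (
    FeatureMatrix,
    ModelSpec,
    PathwayCatalog,
    SplitSpec,
    compute_metrics,
    cross_join,
    oversample_positives,
    run_cv,
    stratified_split,
    train_model,
    tune,
)
from pathpairs.evaluate import OVERALL
from pathpairs.exceptions import (
    ConfigError,
    DegenerateTrainingSetError,
    StratificationError,
    UnsupportedOperationError,
)


def labeled_dataset(n_metab=50, seed=0, member_fraction=0.2, n_path=2):
    """A small pair dataset with controllable label balance."""
    rng = np.random.default_rng(seed)
    metab = FeatureMatrix(
        [f"m{i}" for i in range(n_metab)],
        [f"f{j}" for j in range(5)],
        rng.random((n_metab, 5)),
    )
    pathway = FeatureMatrix(
        [f"P{i}" for i in range(n_path)],
        [f"g{j}" for j in range(3)],
        rng.random((n_path, 3)),
    )
    members = {
        f"P{p}": [f"m{i}" for i in
                  rng.choice(n_metab, max(2, int(member_fraction * n_metab)),
                             replace=False)]
        for p in range(n_path)
    }
    return cross_join(metab, pathway, PathwayCatalog.from_dict(members))


# ------------------------------------------------------------------ splitting

class TestStratifiedSplit:
    def test_test_size_and_per_stratum_positive_count(self):
        ds = labeled_dataset(n_metab=50, member_fraction=0.1, n_path=2)
        # 100 entries, 10 positive, label-stratified 20% test
        assert ds.n_entries == 100 and int(ds.labels.sum()) == 10
        tr, te = stratified_split(ds, SplitSpec(0.2, "label", seed=4))
        assert te.n_entries == 20
        assert int(te.labels.sum()) == 2
        assert tr.n_entries == 80 and int(tr.labels.sum()) == 8

    def test_disjoint_and_covering(self):
        ds = labeled_dataset(seed=1)
        tr, te = stratified_split(ds, SplitSpec(0.25, "pathway_label", seed=0))
        joint = np.concatenate([tr.entry_indices, te.entry_indices])
        assert len(joint) == ds.n_entries
        assert len(np.unique(joint)) == ds.n_entries

    def test_same_seed_reproduces_split(self):
        ds = labeled_dataset(seed=2)
        a = stratified_split(ds, SplitSpec(0.2, "pathway_label", seed=9))
        b = stratified_split(ds, SplitSpec(0.2, "pathway_label", seed=9))
        np.testing.assert_array_equal(a[1].entry_indices, b[1].entry_indices)

    def test_different_seeds_differ(self):
        ds = labeled_dataset(n_metab=100, seed=2)
        a = stratified_split(ds, SplitSpec(0.2, "pathway_label", seed=1))
        b = stratified_split(ds, SplitSpec(0.2, "pathway_label", seed=2))
        assert not np.array_equal(a[1].entry_indices, b[1].entry_indices)

    def test_pathway_label_strata_cover_every_pathway(self):
        ds = labeled_dataset(n_metab=80, n_path=3, seed=5)
        _, te = stratified_split(ds, SplitSpec(0.15, "pathway_label", seed=0))
        assert set(te.pathway_positions()) == {0, 1, 2}

    def test_singleton_stratum_raises(self):
        # one positive entry total -> (pathway, label=1) stratum of size 1
        metab = FeatureMatrix(["m0", "m1", "m2"], ["f0"], np.ones((3, 1)))
        pathway = FeatureMatrix(["P0"], ["g0"], np.ones((1, 1)))
        ds = cross_join(metab, pathway,
                        PathwayCatalog.from_dict({"P0": ["m0"]}))
        with pytest.raises(StratificationError):
            stratified_split(ds, SplitSpec(0.3, "pathway_label", seed=0))

    def test_metabolite_grouped_mode_keeps_groups_intact(self):
        ds = labeled_dataset(n_metab=60, seed=3)
        tr, te = stratified_split(ds, SplitSpec(0.2, "metabolite_grouped", 0))
        assert not set(tr.metabolite_positions()) & set(te.metabolite_positions())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SplitSpec(0.0)
        with pytest.raises(ConfigError):
            SplitSpec(1.0)


# --------------------------------------------------------------- oversampling

class TestOversampling:
    def _balance(self, n_pos, n_neg):
        rng = np.random.default_rng(0)
        n_metab = n_pos + n_neg
        metab = FeatureMatrix(
            [f"m{i}" for i in range(n_metab)], ["f0"],
            rng.random((n_metab, 1)),
        )
        pathway = FeatureMatrix(["P0"], ["g0"], np.ones((1, 1)))
        catalog = PathwayCatalog.from_dict(
            {"P0": [f"m{i}" for i in range(n_pos)]}
        )
        return cross_join(metab, pathway, catalog)

    def test_exact_half_when_ratio_divides(self):
        out = oversample_positives(self._balance(10, 90))
        y = out.labels
        assert int(y.sum()) == 90 and len(y) == 180
        assert y.mean() == pytest.approx(0.5)

    def test_duplication_factor_is_maximal(self):
        out = oversample_positives(self._balance(10, 95))
        y = out.labels
        assert int(y.sum()) == 90  # k = 9
        assert y.mean() == pytest.approx(90 / 185)
        # one more duplication round would exceed one half
        assert (100) / (100 + 95) > 0.5

    def test_balanced_input_unchanged(self):
        ds = self._balance(10, 10)
        out = oversample_positives(ds)
        assert out.n_entries == ds.n_entries
        np.testing.assert_array_equal(np.sort(out.entry_indices),
                                      np.sort(ds.entry_indices))

    def test_single_class_raises(self):
        ds = self._balance(5, 5)
        pos_only = ds.subset(np.flatnonzero(ds.labels == 1))
        with pytest.raises(DegenerateTrainingSetError):
            oversample_positives(pos_only)

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 10), (7, 100), (11, 53),
                                             (20, 21)])
    def test_proportion_bound_and_maximality(self, n_pos, n_neg):
        out = oversample_positives(self._balance(n_pos, n_neg))
        y = out.labels
        k = int(y.sum()) // n_pos
        assert y.mean() <= 0.5
        assert ((k + 1) * n_pos) / ((k + 1) * n_pos + n_neg) > 0.5


# -------------------------------------------------------------------- metrics

class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert m.accuracy == 1.0 and m.mcc == 1.0 and m.f1 == 1.0

    def test_uninformative_confusion_gives_zero_mcc(self):
        m = compute_metrics([1, 0, 1, 0], [1, 1, 0, 0])
        assert m.mcc == pytest.approx(0.0)

    def test_closed_form_example(self):
        # TP=3, FP=1, FN=2, TN=4
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = compute_metrics(y_true, y_pred)
        assert m.mcc == pytest.approx(10 / np.sqrt(600))
        assert m.f1 == pytest.approx(2 / 3)

    def test_zero_denominator_conventions(self):
        # no predicted positives -> precision 0; no true positives -> recall 0
        m = compute_metrics([0, 0, 1], [0, 0, 0])
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert m.mcc == 0.0  # (TP+FP) factor is zero

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_confusion_enumeration(self, seed):
        """Oracle: explicitly enumerate the confusion cells of random
        50-element vectors and evaluate every metric from first principles."""
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        cells = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for t, p in zip(y_true, y_pred):
            cells[{(1, 1): "tp", (0, 1): "fp",
                   (1, 0): "fn", (0, 0): "tn"}[(t, p)]] += 1
        tp, fp, fn, tn = cells["tp"], cells["fp"], cells["fn"], cells["tn"]
        m = compute_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx((tp + tn) / 50)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert m.precision == pytest.approx(prec)
        assert m.recall == pytest.approx(rec)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert m.f1 == pytest.approx(f1)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
        assert m.mcc == pytest.approx(mcc)


# ------------------------------------------------------------ model training

def separable_toy():
    """20 pair entries whose label is a threshold on one metabolite feature."""
    values = np.zeros((20, 2))
    values[:, 0] = np.arange(20)
    values[:10, 1] = 5.0
    metab = FeatureMatrix([f"m{i}" for i in range(20)], ["f0", "f1"], values)
    pathway = FeatureMatrix(["P0"], ["g0"], np.ones((1, 1)))
    catalog = PathwayCatalog.from_dict({"P0": [f"m{i}" for i in range(10)]})
    return cross_join(metab, pathway, catalog)


class TestTrainModel:
    @pytest.mark.parametrize("backend,hp", [
        ("gbt", {}),
        ("mlp", {"hidden_layer_sizes": (16,), "max_iter": 500,
                 "learning_rate_init": 0.01}),
    ])
    def test_backends_fit_separable_toy(self, backend, hp):
        ds = separable_toy()
        clf = train_model(ModelSpec(backend, hp, seed=0), ds)
        X, y = ds.materialize()
        assert compute_metrics(y, clf.predict(X)).accuracy == 1.0

    def test_single_class_training_raises(self):
        ds = separable_toy()
        neg = ds.subset(np.flatnonzero(ds.labels == 0))
        with pytest.raises(DegenerateTrainingSetError):
            train_model(ModelSpec("gbt", {}, 0), neg)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("svm")


# ------------------------------------------------------------------- run_cv

class TestRunCV:
    def test_bookkeeping_three_iterations(self, small_pair_dataset):
        res = run_cv(small_pair_dataset, ModelSpec("gbt", {}, 0),
                     SplitSpec(seed=0), 3)
        recs = res.records
        overall = recs[recs.pathway_id == OVERALL]
        assert sorted(overall.iteration) == [1, 2, 3]
        n_path = small_pair_dataset.pathway.n_rows
        for pid in small_pair_dataset.catalog.pathway_ids:
            assert (recs.pathway_id == pid).sum() == 3
        assert len(recs) == 3 * (n_path + 1)

    def test_per_pathway_confusions_partition_overall(self, small_pair_dataset):
        res = run_cv(small_pair_dataset, ModelSpec("gbt", {}, 0),
                     SplitSpec(seed=1), 2)
        recs = res.records
        for it in (1, 2):
            sub = recs[recs.iteration == it]
            ov = sub[sub.pathway_id == OVERALL].iloc[0]
            per = sub[sub.pathway_id != OVERALL]
            for cell in ("tp", "fp", "fn", "tn"):
                assert per[cell].sum() == ov[cell]

    def test_test_sets_contain_no_duplicates(self, small_pair_dataset):
        """Test purity: oversampling must never leak into test indices."""
        for it in range(1, 4):
            tr, te = stratified_split(
                small_pair_dataset, SplitSpec(0.15, "pathway_label", it)
            )
            tr_os = oversample_positives(tr)
            assert len(np.unique(te.entry_indices)) == te.n_entries
            assert not set(te.entry_indices) & set(tr_os.entry_indices)

    def test_deterministic_under_seed(self, small_pair_dataset):
        a = run_cv(small_pair_dataset, ModelSpec("gbt", {}, 5),
                   SplitSpec(seed=5), 2)
        b = run_cv(small_pair_dataset, ModelSpec("gbt", {}, 5),
                   SplitSpec(seed=5), 2)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_importance_collection_rejected_for_mlp(self, small_pair_dataset):
        with pytest.raises(UnsupportedOperationError):
            run_cv(small_pair_dataset, ModelSpec("mlp", {}, 0),
                   SplitSpec(seed=0), 1, collect_importance=True)


# --------------------------------------------------------------------- tuning

class TestTune:
    def test_single_trial_is_best(self, small_pair_dataset):
        space = {"n_estimators": {"type": "int", "low": 20, "high": 30}}
        res = tune(small_pair_dataset, "gbt", space, n_trials=1,
                   max_cv_iterations=2, seed=0)
        assert res.best_trial == 0
        assert not res.trials.pruned.iloc[0]

    def test_deterministic_under_seed(self, small_pair_dataset):
        space = {"max_depth": {"type": "int", "low": 2, "high": 5}}
        kwargs = dict(n_trials=3, max_cv_iterations=2, seed=7)
        a = tune(small_pair_dataset, "gbt", space, **kwargs)
        b = tune(small_pair_dataset, "gbt", space, **kwargs)
        assert a.best_trial == b.best_trial
        assert a.best_median_mcc == b.best_median_mcc
        pd.testing.assert_frame_equal(
            a.trials.drop(columns="hyperparameters"),
            b.trials.drop(columns="hyperparameters"),
        )

    def test_capacity_constrained_trial_cannot_win_on_separable_data(self):
        """A depth-1, 2-tree model vs. an unconstrained one on data where the
        unconstrained model can fit exactly: the larger model's median MCC
        must be at least as high."""
        rng = np.random.default_rng(0)
        n = 120
        values = rng.random((n, 4))
        metab = FeatureMatrix([f"m{i}" for i in range(n)],
                              [f"f{j}" for j in range(4)], values)
        pathway = FeatureMatrix(["P0"], ["g0"], np.ones((1, 1)))
        members = [f"m{i}" for i in range(n) if values[i, 0] > 0.6]
        ds = cross_join(metab, pathway,
                        PathwayCatalog.from_dict({"P0": members}))
        from pathpairs.evaluate import SplitSpec as SS
        big, small = {}, {"n_estimators": 2, "max_depth": 1,
                          "learning_rate": 0.1}
        medians = {}
        for name, hp in (("big", big), ("small", small)):
            mccs = []
            for it in range(3):
                tr, te = stratified_split(ds, SS(0.2, "label", it))
                tr = oversample_positives(tr)
                clf = train_model(ModelSpec("gbt", hp, it), tr)
                X, y = te.materialize()
                mccs.append(compute_metrics(y, clf.predict(X)).mcc)
            medians[name] = np.median(mccs)
        assert medians["big"] >= medians["small"]

    def test_empty_search_space_rejected(self, small_pair_dataset):
        with pytest.raises(ConfigError):
            tune(small_pair_dataset, "gbt", {}, n_trials=1)

    def test_pruning_can_trigger_and_best_is_unpruned(self, small_pair_dataset):
        space = {"max_depth": {"type": "int", "low": 1, "high": 8}}
        res = tune(small_pair_dataset, "gbt", space, n_trials=8,
                   max_cv_iterations=3, seed=1,
                   n_startup_trials=2, n_warmup_steps=2)
        best_row = res.trials[res.trials.trial == res.best_trial].iloc[0]
        assert not best_row.pruned
        # pruned trials stopped early
        for r in res.trials.itertuples(index=False):
            if r.pruned:
                assert r.n_iterations < 3
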