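import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribotex.datasets import SpeciesDataset
from ribotex.evaluation import (
    ConfusionCounts,
    MetricsRecord,
    adjusted_r2,
    aggregate,
    auc,
    confusion,
    evaluate_model_cv,
    family_differences,
    kfold_split,
    metrics,
    permutation_importance,
    reliability_tests,
)
from ribotex.model_zoo import TrainingConfig, make_eml, make_sml, train


class TestConfusionAndMetrics:
    def test_hand_counted_example(self):
        truth = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        c = confusion(truth, pred)
        assert (c.TP, c.FN, c.FP, c.TN) == (2, 1, 1, 6)
        m = metrics(c)
        assert m["eta"] == pytest.approx(0.8)
        assert m["R"] == pytest.approx(2 / 3)
        assert m["P"] == pytest.approx(2 / 3)
        assert m["F"] == pytest.approx(2 / 3)

    def test_perfect_and_inverted(self):
        y = [1, 1, 0, 0]
        assert confusion(y, y).FP == 0 and confusion(y, y).FN == 0
        inv = confusion(y, [0, 0, 1, 1])
        assert inv.TP == 0 and inv.TN == 0

    def test_degenerate_denominators_warn(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m["eta"] == 1.0 and m["R"] == m["P"] == m["F"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    @pytest.mark.parametrize("seed", range(5))
    def test_identities_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        tp, tn, fp, fn = rng.integers(1, 50, 4)
        c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
        m = metrics(c)
        assert m["eta"] == pytest.approx((tp + tn) / c.total, abs=1e-12)
        assert m["F"] == pytest.approx(2 * m["P"] * m["R"] / (m["P"] + m["R"]),
                                       abs=1e-12)


class TestAuc:
    def test_perfect_and_reversed(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0
        assert auc([1, 1, 0, 0], [0.2, 0.3, 0.8, 0.9]) == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_normalized_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 40)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        s = rng.normal(size=40)
        u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert auc(y, s) == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))


def make_ds(n0=40, n1=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n0, 3)), rng.normal(2, 1, (n1, 3))])
    y = np.array([0] * n0 + [1] * n1)
    prov = np.array([f"r{i}" for i in range(n0 + n1)], dtype=object)
    return SpeciesDataset("toy", X, y, "pairwise", ("a", "b"), prov)


class TestKfold:
    def test_folds_partition_rows(self):
        ds = make_ds()
        splits = kfold_split(ds, 10, seed=0)
        assert len(splits) == 10
        tests = [set(te) for _, te in splits]
        assert set().union(*tests) == set(range(ds.n_samples))
        assert sum(len(t) for t in tests) == ds.n_samples  # pairwise disjoint

    def test_stratification_within_one_sample(self):
        ds = make_ds(n0=40, n1=60)
        for _, te in kfold_split(ds, 5, seed=1):
            pos = ds.labels[te].sum()
            assert abs(pos - 12) <= 1

    def test_seeded_determinism_and_class_size_guard(self):
        ds = make_ds()
        a = kfold_split(ds, 4, seed=7)
        b = kfold_split(ds, 4, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)
        tiny = make_ds(n0=3, n1=60)
        with pytest.raises(ValueError, match="< K"):
            kfold_split(tiny, 5, seed=0)


class TestAggregate:
    @staticmethod
    def recs(model, dataset, etas, alphas):
        return [MetricsRecord(model=model, dataset=dataset, K=10, fold=i,
                              eta=e, R=e, P=e, F=e, alpha=a)
                for i, (e, a) in enumerate(zip(etas, alphas))]

    def test_simple_means(self):
        records = (self.recs("m1", "d1", [0.8], [0.8])
                   + self.recs("m1", "d2", [0.9], [0.9]))
        rep = aggregate(records)
        assert rep.per_model.loc["m1", "eta"] == pytest.approx(0.85)
        assert rep.system["eta"] == pytest.approx(0.85)

    def test_system_mean_equals_mean_of_dataset_means(self):
        rng = np.random.default_rng(0)
        records = []
        for m in ["m1", "m2", "m3"]:
            for d in ["d1", "d2"]:
                v = rng.uniform(0.5, 1.0, 4)
                records += self.recs(m, d, v, v)
        rep = aggregate(records)
        assert rep.system["eta"] == pytest.approx(rep.per_dataset["eta"].mean())
        assert rep.system["eta"] == pytest.approx(rep.per_model["eta"].mean())

    def test_incomplete_grid_names_missing_cells(self):
        records = (self.recs("m1", "d1", [0.8], [0.8])
                   + self.recs("m2", "d2", [0.9], [0.9]))
        with pytest.raises(ValueError, match="missing cells"):
            aggregate(records)

    def test_family_difference_rounds_before_differencing(self):
        # means 88.712 and 90.878 print as 88.71 / 90.88 -> difference 2.17
        a = [88.712]
        b = [90.878]
        assert family_differences(a, b, "percent") == pytest.approx(2.17)
        assert family_differences([0.89642], [0.92038], "auc") == pytest.approx(2.40)


class TestReliability:
    def test_identical_groups_no_effect(self):
        acc = {"m1": [0.8, 0.8, 0.8], "m2": [0.8, 0.8, 0.8]}
        out = reliability_tests(acc)
        assert out["anova_p"] == pytest.approx(1.0)
        assert out["Z_two_tailed"] == {"m1": 0.0, "m2": 0.0}
        assert not out["anova_pass"]

    def test_disjoint_ranges_significant(self):
        rng = np.random.default_rng(0)
        acc = {"lo": rng.uniform(0.60, 0.65, 10), "hi": rng.uniform(0.90, 0.95, 10)}
        out = reliability_tests(acc)
        assert out["anova_p"] < 0.01 and out["anova_pass"]
        # cross-check against the textbook one-way ANOVA statistic
        f_ref, p_ref = stats.f_oneway(acc["lo"], acc["hi"])
        assert out["anova_F"] == pytest.approx(f_ref)
        assert out["anova_p"] == pytest.approx(p_ref)
        assert out["Z_two_tailed"]["hi"] > 0 > out["Z_two_tailed"]["lo"]

    def test_perfect_probabilistic_predictor_r2(self):
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        assert adjusted_r2(y, y) == pytest.approx(1.0)

    def test_input_guards(self):
        with pytest.raises(ValueError):
            reliability_tests({"only": [0.8, 0.9, 0.7]})
        with pytest.raises(ValueError):
            reliability_tests({"a": [0.8, 0.9], "b": [0.7, 0.6]})


class TestCrossValidationRuns:
    def test_per_fold_records_and_leakage_guard(self):
        ds = make_ds(n0=40, n1=80, seed=3)
        records = evaluate_model_cv(make_sml("LR"), ds, K=4, seed=0)
        assert len(records) == 4
        assert all(0 <= r.eta <= 1 and 0 <= r.alpha <= 1 for r in records)
        # synthetic provenance never reaches a test fold: test rows are drawn
        # from the original dataset, which carries no synthetic flags
        assert not any(str(p).startswith("synthetic:") for p in ds.provenance)

    def test_corpus_wide_prep_route_runs(self):
        ds = make_ds(n0=40, n1=80, seed=4)
        records = evaluate_model_cv(make_sml("NB"), ds, K=2, seed=0,
                                    corpus_wide_prep=True)
        assert len(records) == 2


class TestPermutationImportance:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 300
        X = rng.normal(size=(n, 5))
        y = (X[:, 3] > 0).astype(int)
        ds = SpeciesDataset("t", X, y, "pairwise", ("a", "b"),
                            np.array([f"r{i}" for i in range(n)], dtype=object))
        model = train(make_sml("DT"), ds)
        imp = permutation_importance(model, X, y, seed=0,
                                     feature_names=list("abcde"))
        assert imp.iloc[0]["feature"] == "d"
        # pure-noise columns contribute ~nothing
        assert np.all(imp["importance"].iloc[1:] < 0.1)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        ds = SpeciesDataset("t", X, y, "pairwise", ("a", "b"),
                            np.array([f"r{i}" for i in range(100)], dtype=object))
        model = train(make_sml("RF"), ds)
        a = permutation_importance(model, X, y, seed=5)
        b = permutation_importance(model, X, y, seed=5)
        pd.testing.assert_frame_equal(a, b)
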