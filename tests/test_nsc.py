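import numpy as np
import pandas as pd
import pytest

from triadscan import (ExpressionMatrix, NSCClassifier, evaluate_predictions,
                       median_ratio_size_factors, prepare_counts,
                       split_train_test)


def _frame(arr, prefix_g="g", prefix_s="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix_g}{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix_s}{j}" for j in range(arr.shape[1])])


class TestSizeFactors:
    def test_identical_columns_give_one(self):
        df = _frame(np.tile([[4.0], [10.0], [7.0]], (1, 5)))
        np.testing.assert_allclose(median_ratio_size_factors(df), 1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(50)
        df = _frame(rng.integers(1, 500, (60, 6)))
        got = median_ratio_size_factors(df)
        log_gm = np.log(df.to_numpy()).mean(axis=1)
        for j, s in enumerate(df.columns):
            expected = np.exp(np.median(np.log(df[s].to_numpy()) - log_gm))
            assert got[s] == pytest.approx(expected)

    def test_matches_pydeseq2(self):
        """Cross-check against the DESeq2 reference implementation."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(51)
        counts = rng.integers(1, 800, (80, 8))
        df = _frame(counts)
        meta = pd.DataFrame({"condition": ["a", "b"] * 4},
                            index=df.columns)
        dds = DeseqDataSet(counts=df.T, metadata=meta, design="~condition",
                           quiet=True)
        dds.fit_size_factors()
        ours = median_ratio_size_factors(df).to_numpy()
        np.testing.assert_allclose(ours, dds.obs["size_factors"].to_numpy(),
                                   rtol=1e-6)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(52)
        df = _frame(rng.integers(1, 100, (30, 4)))
        base = median_ratio_size_factors(df)
        shuffled = df.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(base, median_ratio_size_factors(shuffled))


class TestPrepareCounts:
    def test_transform_formula(self):
        counts = ExpressionMatrix(_frame(np.tile([[9.0], [19.0]], (1, 3))),
                                  "counts")
        X, sf, w = prepare_counts(counts)
        np.testing.assert_allclose(sf, 1.0)
        np.testing.assert_allclose(X.iloc[0], np.log2(10 + 0.5))
        assert w is None

    def test_all_zero_sample_rejected(self):
        df = _frame([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="s1"):
            prepare_counts(ExpressionMatrix(df, "counts"))

    def test_voom_weights_shape(self):
        rng = np.random.default_rng(53)
        counts = ExpressionMatrix(_frame(rng.integers(0, 200, (50, 6))), "counts")
        X, _, w = prepare_counts(counts, voom_weights=True)
        assert w.shape == X.shape
        assert (w > 0).all()


class TestSplit:
    def test_18_samples_stratified(self):
        samples = [f"s{i}" for i in range(18)]
        labels = ["N"] * 9 + ["S"] * 9
        train, test = split_train_test(samples, labels, 0.6, seed=0)
        assert len(train) == 10  # floor(0.6 * 18) with stratification
        assert len(test) == 8
        train_labels = [labels[samples.index(s)] for s in train]
        assert train_labels.count("N") == 5 and train_labels.count("S") == 5

    def test_same_seed_same_partition(self):
        samples = [f"s{i}" for i in range(20)]
        labels = ["a", "b"] * 10
        assert split_train_test(samples, labels, seed=4) \
            == split_train_test(samples, labels, seed=4)

    def test_fraction_one_empty_test(self):
        train, test = split_train_test(["a", "b", "c", "d"],
                                       ["x", "x", "y", "y"], 1.0)
        assert test == []

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(["a", "b", "c"], ["x", "x", "y"])


def _independent_nearest_centroid(X_train, y_train, X_new):
    """Plain nearest centroid with pooled standardisation (oracle)."""
    classes = sorted(set(y_train))
    n, k = len(y_train), len(classes)
    means = {c: X_train[[i for i, yy in enumerate(y_train) if yy == c]].mean(axis=0)
             for c in classes}
    ss = sum(((X_train[[i for i, yy in enumerate(y_train) if yy == c]]
               - means[c]) ** 2).sum(axis=0) for c in classes)
    s = np.sqrt(ss / (n - k))
    s0 = np.median(s)
    priors = {c: y_train.count(c) / n for c in classes}
    preds = []
    for x in X_new:
        scores = [(((x - means[c]) / (s + s0)) ** 2).sum() - 2 * np.log(priors[c])
                  for c in classes]
        preds.append(classes[int(np.argmin(scores))])
    return preds


class TestNSC:
    def _toy(self):
        """6 samples x 5 genes; gene g0 separates the classes by ~10 sd."""
        rng = np.random.default_rng(60)
        X = rng.normal(10, 1, (5, 6))
        X[0, :3] += 10.0
        labels = ["hi", "hi", "hi", "lo", "lo", "lo"]
        return _frame(X), labels

    def test_delta_zero_equals_plain_nearest_centroid(self):
        rng = np.random.default_rng(61)
        X = _frame(rng.normal(0, 1, (20, 8)))
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        fit = NSCClassifier(X, labels).fit(delta=0.0)
        X_new = rng.normal(0, 1, (5, 20))
        got = list(fit.predict(_frame(X_new.T, prefix_s="t")))
        oracle = _independent_nearest_centroid(X.to_numpy().T, labels, X_new)
        assert got == oracle

    def test_delta_zero_selects_everything(self):
        X, labels = self._toy()
        fit = NSCClassifier(X, labels).fit(delta=0.0)
        assert len(fit.selected_features()) == 5

    def test_full_shrinkage_predicts_priors(self):
        rng = np.random.default_rng(62)
        X = _frame(rng.normal(0, 1, (10, 6)))
        labels = ["a"] * 4 + ["b"] * 2
        fit = NSCClassifier(X, labels).fit(delta=1e9)
        assert len(fit.selected_features()) == 0
        assert (fit.predict(X) == "a").all()  # majority class

    def test_toy_shrinkage_table(self):
        """d_ik from the explicit formulas; one gene survives mid shrinkage."""
        X, labels = self._toy()
        fit = NSCClassifier(X, labels).fit(delta=0.0)
        arr = X.to_numpy().T
        overall = arr.mean(axis=0)
        d_oracle = np.empty((2, 5))
        s2 = np.zeros(5)
        for ci, c in enumerate(("hi", "lo")):
            sub = arr[[i for i, l in enumerate(labels) if l == c]]
            s2 += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        s = np.sqrt(s2 / (6 - 2))
        s0 = np.median(s)
        for ci, c in enumerate(("hi", "lo")):
            sub = arr[[i for i, l in enumerate(labels) if l == c]]
            mk = np.sqrt(1 / 3 - 1 / 6)
            d_oracle[ci] = (sub.mean(axis=0) - overall) / (mk * (s + s0))
        np.testing.assert_allclose(fit.stats["d"], d_oracle, rtol=1e-10)
        # pick a delta between the separated gene and the rest
        strengths = np.abs(d_oracle).max(axis=0)
        lo, hi = np.sort(strengths)[-2], np.sort(strengths)[-1]
        assert hi > 2 * lo  # the planted gene stands clear
        mid_fit = NSCClassifier(X, labels).fit(delta=(lo + hi) / 2)
        assert list(mid_fit.selected_features()["gene_id"]) == ["g0"]

    def test_selection_monotone_in_delta(self):
        rng = np.random.default_rng(63)
        X = _frame(rng.normal(0, 2, (30, 10)))
        labels = ["a"] * 5 + ["b"] * 5
        clf = NSCClassifier(X, labels)
        sizes = [len(clf.fit(delta=d).selected_features())
                 for d in np.linspace(0, 3, 12)]
        assert sizes == sorted(sizes, reverse=True)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(64)
        X = _frame(rng.normal(0, 1, (15, 6)))
        X.iloc[3] += np.array([3, 3, 3, 0, 0, 0])
        labels = ["a"] * 3 + ["b"] * 3
        fit1 = NSCClassifier(X, labels).fit(delta=1.0)
        shuffled = X.sample(frac=1, random_state=2)
        fit2 = NSCClassifier(shuffled, labels).fit(delta=1.0)
        assert list(fit1.predict(X)) == list(fit2.predict(shuffled))
        assert set(fit1.selected_features()["gene_id"]) \
            == set(fit2.selected_features()["gene_id"])

    def test_library_size_invariance(self):
        """A common library-size factor is absorbed by the size factors."""
        rng = np.random.default_rng(65)
        counts = rng.integers(1, 300, (40, 8)).astype(float)
        labels = ["a"] * 4 + ["b"] * 4
        X1, _, _ = prepare_counts(ExpressionMatrix(_frame(counts), "counts"))
        X2, _, _ = prepare_counts(ExpressionMatrix(_frame(counts * 3), "counts"))
        f1 = NSCClassifier(X1, labels).fit(delta=0.5)
        f2 = NSCClassifier(X2, labels).fit(delta=0.5)
        assert list(f1.predict(X1)) == list(f2.predict(X2))


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate_predictions(["N", "S", "N", "S"], ["N", "S", "N", "S"], "S")
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_all_predicted_reference(self):
        m = evaluate_predictions(["N", "N", "S", "S"], ["S"] * 4, "S")
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_matches_hand_tally(self):
        rng = np.random.default_rng(66)
        true = list(rng.choice(["N", "S"], 10))
        pred = list(rng.choice(["N", "S"], 10))
        m = evaluate_predictions(true, pred, "S")
        tp = sum(t == p == "N" for t, p in zip(true, pred))
        tn = sum(t == p == "S" for t, p in zip(true, pred))
        fp = sum(t == "S" and p == "N" for t, p in zip(true, pred))
        fn = sum(t == "N" and p == "S" for t, p in zip(true, pred))
        assert m.accuracy == pytest.approx((tp + tn) / 10)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.confusion.to_numpy().sum() == 10

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            evaluate_predictions(["a"], ["a"], "zz")
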