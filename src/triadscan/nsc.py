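"""Nearest-shrunken-centroid classification of RNA-seq samples.

The classifier follows the canonical NSC recipe: standardized
class-vs-overall centroid differences

    d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

are soft-thresholded, d'_ik = sign(d_ik) (|d_ik| - delta)_+, shrunken
centroids are reconstructed as xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik,
and a sample is assigned to the class minimising

    sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log pi_k.

Counts enter as log2 of (count + 1) after DESeq-style median-ratio
normalisation (with an optional voom-style precision-weight variant).
The shrinkage threshold delta is chosen by repeated stratified K-fold
cross-validation; genes with a nonzero shrunken difference in any class
are the selected biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .io import ExpressionMatrix

__all__ = [
    "median_ratio_size_factors",
    "prepare_counts",
    "split_train_test",
    "NSCClassifier",
    "NSCResults",
    "ClassificationMetrics",
    "evaluate_predictions",
]


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-ratio size factors (genes x samples input).

    The reference is the per-gene geometric mean across samples; genes with
    any zero count are excluded from the reference.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; cannot form reference")
    log_arr = np.log(arr[positive])
    log_gm = log_arr.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_arr - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _voom_weights(log_mat: np.ndarray) -> np.ndarray:
    """Precision weights from a lowess fit of sqrt(per-gene sd) vs mean."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mean = log_mat.mean(axis=1)
    sd = log_mat.std(axis=1, ddof=1)
    fit = lowess(np.sqrt(sd), mean, frac=0.5, return_sorted=True)
    pred_quarter_sd = np.interp(mean, fit[:, 0], fit[:, 1])  # sqrt(sd) scale
    w = 1.0 / np.maximum(pred_quarter_sd, 1e-6) ** 4         # 1/variance
    return np.repeat(w[:, None], log_mat.shape[1], axis=1)


def prepare_counts(counts: ExpressionMatrix, pseudocount: float = 1.0,
                   voom_weights: bool = False
                   ) -> tuple[pd.DataFrame, pd.Series, np.ndarray | None]:
    """Counts -> log2 median-ratio-normalised matrix (genes x samples).

    Adds ``pseudocount`` to every count, computes median-ratio size
    factors on the offset counts, divides, and returns
    ``log2(normalised + 0.5)`` plus optional voom-style precision weights.
    """
    if counts.unit != "counts":
        raise ValueError(f"prepare_counts expects counts, got {counts.unit!r}")
    if (counts.values.sum(axis=0) == 0).any():
        bad = counts.values.columns[counts.values.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    offset = counts.values + pseudocount
    sf = median_ratio_size_factors(offset)
    normalised = offset / sf
    log_mat = np.log2(normalised + 0.5)
    weights = _voom_weights(log_mat.to_numpy()) if voom_weights else None
    return log_mat, sf, weights


def split_train_test(samples, labels, fraction_train: float = 0.6,
                     seed: int | None = 0) -> tuple[list, list]:
    """Deterministic stratified split preserving class proportions."""
    samples = list(samples)
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError(f"class {counts.idxmin()!r} has fewer than 2 samples")
    if fraction_train >= 1.0:
        return samples, []   # empty test set; caller is expected to notice
    train, test = train_test_split(samples, train_size=fraction_train,
                                   stratify=labels, random_state=seed,
                                   shuffle=True)
    return list(train), list(test)


@dataclass
class ClassificationMetrics:
    """Accuracy / sensitivity / specificity with the reference class negative."""
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame  # rows true, columns predicted


def evaluate_predictions(true_labels, predicted, reference: str
                         ) -> ClassificationMetrics:
    """Confusion matrix and derived metrics; ``reference`` is the negative class."""
    true_s = pd.Series(list(true_labels), name="true")
    pred_s = pd.Series(list(predicted), name="predicted")
    classes = sorted(set(true_s) | set(pred_s))
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} absent from labels")
    cm = pd.crosstab(true_s, pred_s).reindex(index=classes, columns=classes,
                                             fill_value=0)
    pos = true_s != reference
    tp = int(((true_s == pred_s) & pos).sum())
    tn = int(((true_s == pred_s) & ~pos).sum())
    fn = int(pos.sum()) - tp
    fp = int((~pos).sum()) - tn
    acc = (tp + tn) / len(true_s)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassificationMetrics(accuracy=acc, sensitivity=sens,
                                 specificity=spec, confusion=cm)


# ---------------------------------------------------------------------------


def _nsc_statistics(X: np.ndarray, y: np.ndarray, classes: np.ndarray,
                    priors: np.ndarray | None = None):
    """Centroids, pooled s_i, s0, m_k and unshrunken d_ik.

    X is samples x genes; returns dict of arrays (genes-major).
    """
    n, p = X.shape
    k = len(classes)
    overall = X.mean(axis=0)
    centroids = np.empty((k, p))
    nk = np.empty(k)
    ss = np.zeros(p)
    for i, c in enumerate(classes):
        sub = X[y == c]
        nk[i] = len(sub)
        centroids[i] = sub.mean(axis=0)
        ss += ((sub - centroids[i]) ** 2).sum(axis=0)
    s = np.sqrt(ss / max(n - k, 1))
    s0 = np.median(s)
    mk = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 0.0))
    denom = mk[:, None] * (s + s0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (centroids - overall) / denom, 0.0)
    if priors is None:
        priors = nk / n
    return {"overall": overall, "centroids": centroids, "nk": nk, "s": s,
            "s0": s0, "mk": mk, "d": d, "priors": priors}


def _shrink(stats: dict, delta: float) -> np.ndarray:
    d = stats["d"]
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _predict_scores(stats: dict, d_shrunk: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Discriminant scores (samples x classes); lower is better."""
    shrunk_centroids = stats["overall"][None, :] + \
        stats["mk"][:, None] * (stats["s"] + stats["s0"])[None, :] * d_shrunk
    denom = (stats["s"] + stats["s0"]) ** 2
    scores = np.empty((X.shape[0], d_shrunk.shape[0]))
    for i in range(d_shrunk.shape[0]):
        diff = X - shrunk_centroids[i][None, :]
        scores[:, i] = (diff * diff / denom[None, :]).sum(axis=1)
    scores -= 2.0 * np.log(stats["priors"])[None, :]
    return scores


class NSCClassifier:
    """Nearest shrunken centroids on a log-transformed expression matrix.

    Parameters
    ----------
    X : DataFrame, genes x samples (as produced by :func:`prepare_counts`).
    labels : per-sample class labels aligned with ``X``'s columns.
    """

    def __init__(self, X: pd.DataFrame, labels):
        self.X = X
        self.labels = pd.Series(list(labels), index=X.columns, name="label")
        self.classes = np.array(sorted(self.labels.unique()))
        if len(self.classes) < 2:
            raise ValueError("need at least two classes")

    def fit(self, delta: float | None = None, n_delta: int = 30,
            cv_folds: int = 5, cv_repeats: int = 2,
            seed: int | None = 0) -> "NSCResults":
        """Fit; when ``delta`` is None choose it by repeated stratified CV.

        The grid spans 0 .. max|d_ik| in ``n_delta`` steps; accuracy ties
        break toward the largest delta (fewest genes).
        """
        Xs = self.X.to_numpy(dtype=float).T   # samples x genes
        y = self.labels.to_numpy()
        stats = _nsc_statistics(Xs, y, self.classes)
        dmax = float(np.abs(stats["d"]).max())
        cv_table = None
        if delta is None:
            grid = np.linspace(0.0, dmax, n_delta)
            cv_table = self._cross_validate(Xs, y, grid, cv_folds, cv_repeats, seed)
            best = cv_table["mean_accuracy"].max()
            delta = float(cv_table.loc[
                cv_table["mean_accuracy"] >= best - 1e-12, "delta"].max())
        d_shrunk = _shrink(stats, delta)
        return NSCResults(model=self, stats=stats, delta=float(delta),
                          d_shrunk=d_shrunk, cv_table=cv_table)

    def _cross_validate(self, Xs, y, grid, folds, repeats, seed) -> pd.DataFrame:
        min_class = pd.Series(y).value_counts().min()
        folds = int(min(folds, min_class))  # degrade gracefully on tiny classes
        if folds < 2:
            raise ValueError("cross-validation needs every class twice")
        splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                           random_state=seed)
        correct = np.zeros(len(grid))
        total = np.zeros(len(grid))
        n_genes = np.zeros(len(grid))
        n_folds = 0
        for train_idx, test_idx in splitter.split(Xs, y):
            st = _nsc_statistics(Xs[train_idx], y[train_idx], self.classes)
            n_folds += 1
            for gi, delta in enumerate(grid):
                ds = _shrink(st, delta)
                scores = _predict_scores(st, ds, Xs[test_idx])
                pred = self.classes[np.argmin(scores, axis=1)]
                correct[gi] += (pred == y[test_idx]).sum()
                total[gi] += len(test_idx)
                n_genes[gi] += (np.abs(ds) > 0).any(axis=0).sum()
        return pd.DataFrame({
            "delta": grid,
            "mean_accuracy": correct / total,
            "mean_n_genes": n_genes / n_folds,
        })


@dataclass
class NSCResults:
    """Fitted NSC model: shrunken centroids, CV path and selection."""
    model: NSCClassifier
    stats: dict
    delta: float
    d_shrunk: np.ndarray
    cv_table: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.model.X.index

    @property
    def shrunken_centroids(self) -> pd.DataFrame:
        sc = self.stats["overall"][None, :] + \
            self.stats["mk"][:, None] * \
            (self.stats["s"] + self.stats["s0"])[None, :] * self.d_shrunk
        return pd.DataFrame(sc.T, index=self.gene_ids, columns=self.model.classes)

    def selected_features(self) -> pd.DataFrame:
        """Genes with a nonzero shrunken difference, ranked by max |d'_ik|."""
        score = np.abs(self.d_shrunk).max(axis=0)
        keep = score > 0
        out = pd.DataFrame({"gene_id": self.gene_ids[keep],
                            "score": score[keep]})
        return out.sort_values("score", ascending=False,
                               kind="stable").reset_index(drop=True)

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        """Classify new samples (genes x samples, same gene order)."""
        if not X_new.index.equals(self.gene_ids):
            X_new = X_new.reindex(self.gene_ids)
            if X_new.isna().any().any():
                raise ValueError("X_new is missing model genes")
        scores = _predict_scores(self.stats, self.d_shrunk,
                                 X_new.to_numpy(dtype=float).T)
        return pd.Series(self.model.classes[np.argmin(scores, axis=1)],
                         index=X_new.columns, name="predicted")

    def evaluate(self, X_test: pd.DataFrame, labels_test,
                 reference: str) -> ClassificationMetrics:
        pred = self.predict(X_test)
        return evaluate_predictions(list(labels_test), list(pred), reference)

    def summary(self) -> str:
        sel = self.selected_features()
        lines = [
            "Nearest shrunken centroids",
            f"classes: {', '.join(map(str, self.model.classes))} "
            f"(priors {np.round(self.stats['priors'], 3).tolist()})",
            f"samples: {self.model.X.shape[1]}  genes: {self.model.X.shape[0]}",
            f"delta = {self.delta:.4g}  s0 = {self.stats['s0']:.4g}",
            f"selected genes: {len(sel)}",
        ]
        if self.cv_table is not None:
            best = self.cv_table.loc[self.cv_table["delta"] == self.delta]
            if len(best):
                lines.append(
                    f"CV accuracy at delta: {best['mean_accuracy'].iloc[0]:.3f}")
        if len(sel):
            top = ", ".join(sel["gene_id"].head(5))
            lines.append(f"top genes: {top}")
        return "\n".join(lines)
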