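"""Participant-wise leave-one-out evaluation of feature subsets.

Each fold trains on all participants but one and tests on the held-out
participant's windows, so subject identity never leaks between train and
test.  Accuracy is the window-level correct fraction per fold, in percent.
Per-fold feature standardisation is fitted on the training folds only.

Subset-vs-all-features comparisons use an exact two-sided paired sign test
on the per-fold accuracies (ties dropped), with Benjamini-Hochberg
correction across the comparisons of a population family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .preprocessing import LevelDataset

CLASSIFIERS = ("naive_bayes", "linear_svm", "decision_tree")


class GaussianNaiveBayes:
    """Closed-form Gaussian naive Bayes (per-class means/variances, priors)."""

    var_floor = 1e-9

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.log_prior_ = np.log(counts / len(y))
        self.theta_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.vstack([X[y == c].var(axis=0) for c in self.classes_])
        self.var_ += self.var_floor + 1e-9 * self.var_.max()
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        ll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            z = (X - self.theta_[k]) ** 2 / self.var_[k]
            ll[:, k] = self.log_prior_[k] - 0.5 * np.sum(
                np.log(2 * np.pi * self.var_[k]) + z, axis=1
            )
        return self.classes_[np.argmax(ll, axis=1)]


class _MajorityClass:
    """Predicts the most frequent training class (baseline instrument)."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=object)


def make_classifier(tag: str, seed: int = 0):
    if tag == "naive_bayes":
        return GaussianNaiveBayes()
    if tag == "linear_svm":
        return LinearSVC(C=1.0, random_state=seed, max_iter=5000)
    if tag == "decision_tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if tag == "majority":
        return _MajorityClass()
    raise ValueError(f"unknown classifier tag: {tag!r}")


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def fit_predict(classifier: str, X_train, y_train, X_test, seed: int = 0):
    """Train one classifier and predict the test windows.

    Features are standardised with training-fold statistics.  A train fold
    with a single class predicts that class for everything.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.size == 0:
        raise ValueError("empty training set")
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature columns mismatch")
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        return np.full(len(X_test), y_train[0], dtype=object)
    Xtr, Xte = _standardize(X_train, X_test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LinearSVC convergence on tiny folds
        model = make_classifier(classifier, seed=seed).fit(Xtr, y_train)
        return np.asarray(model.predict(Xte))


@dataclass
class CVResult:
    """Per-participant LOOCV accuracies and pooled confusion table."""

    level: int
    classifier: str
    feature_set: str
    accuracies: dict            # participant -> accuracy (%)
    confusion: pd.DataFrame     # pooled rows=true, cols=predicted
    classes: list
    population: str | None = None

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([self.accuracies[p] for p in sorted(self.accuracies)])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def loocv_by_participant(
    dataset: LevelDataset,
    classifier: str,
    subset=None,
    seed: int = 0,
    participants=None,
    selector=None,
) -> CVResult:
    """Leave-one-participant-out cross-validation on one level dataset.

    ``subset`` is a FeatureSubset (or None for all features).  If
    ``selector`` is given (a callable ``(X, y) -> column indices``), feature
    selection is re-run inside each training fold instead — the
    leakage-free pipeline mode.  Participants listed in ``participants`` but
    absent from the level are skipped with a warning.
    """
    X = dataset.X.to_numpy(dtype=float)
    y = dataset.y
    groups = dataset.groups
    present = sorted(set(groups))
    if len(present) < 2:
        raise ValueError("LOOCV needs at least 2 participants")
    folds = sorted(set(participants)) if participants is not None else present
    cols = None
    if subset is not None:
        cols = np.asarray(subset.indices, dtype=int)
        if cols.size and (cols.min() < 0 or cols.max() >= X.shape[1]):
            raise ValueError("subset indices out of range")
    classes = sorted(set(y))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    accuracies = {}
    for p in folds:
        test_m = groups == p
        if not test_m.any():
            warnings.warn(f"participant {p!r} has no occurrences at level "
                          f"{dataset.level}; fold skipped")
            continue
        train_m = ~test_m
        Xtr, ytr = X[train_m], y[train_m]
        Xte, yte = X[test_m], y[test_m]
        if selector is not None:
            fold_cols = np.asarray(selector(Xtr, ytr), dtype=int)
        else:
            fold_cols = cols
        if fold_cols is not None:
            Xtr, Xte = Xtr[:, fold_cols], Xte[:, fold_cols]
        pred = fit_predict(classifier, Xtr, ytr, Xte, seed=seed)
        accuracies[p] = float((pred == yte).mean() * 100.0)
        for true_c, pred_c in zip(yte, pred):
            if pred_c not in conf.columns:
                conf[pred_c] = 0
            conf.loc[true_c, pred_c] += 1
    name = "all" if (subset is None and selector is None) else (
        getattr(subset, "method", None) or "per_fold_selection")
    return CVResult(
        level=dataset.level,
        classifier=classifier,
        feature_set=name,
        accuracies=accuracies,
        confusion=conf,
        classes=classes,
    )


@dataclass
class SignTestResult:
    """Exact paired sign test between two per-fold accuracy vectors."""

    n_pos: int
    n_neg: int
    n_ties: int
    p: float
    adjusted_p: float | None = None
    significant: bool | None = None
    all_ties: bool = False


def paired_sign_test(acc_a, acc_b, tie_tol: float = 1e-12) -> SignTestResult:
    """Two-sided exact sign test on paired fold accuracies (a vs b).

    Differences smaller than ``tie_tol`` in magnitude are ties and are
    dropped; with all pairs tied the p-value is 1 (flagged).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be equal-length, non-empty")
    d = a - b
    n_pos = int(np.sum(d > tie_tol))
    n_neg = int(np.sum(d < -tie_tol))
    n_ties = int(a.size - n_pos - n_neg)
    if n_pos + n_neg == 0:
        return SignTestResult(0, 0, n_ties, 1.0, all_ties=True)
    p = binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue
    return SignTestResult(n_pos, n_neg, n_ties, float(p))


def benjamini_hochberg(pvals, q: float = 0.05):
    """BH step-up FDR control: (reject flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([])
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, adjusted


# ---------------------------------------------------------------------------
# report shapes


def accuracy_table(cv_results: list, comparisons: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accuracy report: population x classifier x feature set by level.

    One row per (population, classifier, feature_set); one column per level
    holding the mean fold accuracy, with significance flags merged in from
    ``comparisons`` when given.
    """
    if not cv_results:
        return pd.DataFrame(
            columns=["population", "classifier", "feature_set", "level",
                     "mean_accuracy", "adjusted_p", "significant"]
        )
    rows = [
        {
            "population": r.population,
            "classifier": r.classifier,
            "feature_set": r.feature_set,
            "level": r.level,
            "mean_accuracy": r.mean_accuracy,
        }
        for r in cv_results
    ]
    table = pd.DataFrame(rows)
    if comparisons is not None and len(comparisons):
        table = table.merge(
            comparisons[
                ["population", "classifier", "feature_set", "level",
                 "p", "adjusted_p", "significant"]
            ],
            how="left",
            on=["population", "classifier", "feature_set", "level"],
        )
    return table


def confusion_frame(result: CVResult) -> pd.DataFrame:
    """Pooled confusion table with totals (rows = true classes)."""
    conf = result.confusion.copy()
    conf["total"] = conf.sum(axis=1)
    return conf


def write_reports(outdir, accuracy: pd.DataFrame, confusions: dict,
                  common: dict) -> None:
    """Write accuracy, confusion, and common-feature tables as CSV files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    accuracy.to_csv(os.path.join(outdir, "accuracy_table.csv"), index=False)
    for key, conf in confusions.items():
        conf.to_csv(os.path.join(outdir, f"confusion_{key}.csv"))
    for method, table in common.items():
        table.to_csv(os.path.join(outdir, f"common_features_{method}.csv"),
                     index=False)
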