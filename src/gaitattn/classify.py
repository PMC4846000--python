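"""Run-wise cross-validated multi-class decoding of the attention tasks.

Five classifiers are evaluated: an RBF-kernel SVM (C=512, kernel width
0.002), Gaussian naive Bayes, least-squares LDA, 30-nearest-neighbors and
a single decision tree.  Validation is 8-fold with each run serving as
one test fold, so no epoch of a test run ever reaches the training set.
Success rates are percentages of correctly labeled test epochs; group
averages pool the individual fold values rather than session means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import BandFeatures

CLASSIFIER_KINDS = ("svm_rbf", "naive_bayes", "lda", "knn", "decision_tree")

#: short display names matching the result tables
KIND_ABBREV = {
    "svm_rbf": "SVM",
    "naive_bayes": "NB",
    "lda": "LDA",
    "knn": "KNN",
    "decision_tree": "DTL",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus its (fixed, non-searched) hyperparameters."""

    kind: str
    svm_C: float = 512.0
    svm_gamma: float = 0.002  # RBF kernel width
    knn_k: int = 30
    tree_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.svm_C <= 0 or self.svm_gamma <= 0 or self.knn_k < 1:
            raise ValueError("hyperparameters must be positive")

    def build(self):
        if self.kind == "svm_rbf":
            return SVC(kernel="rbf", C=self.svm_C, gamma=self.svm_gamma)
        if self.kind == "naive_bayes":
            return GaussianNB()
        if self.kind == "lda":
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k,
                                        metric="euclidean")
        return DecisionTreeClassifier(random_state=self.tree_seed)


def default_specs() -> tuple[ClassifierSpec, ...]:
    return tuple(ClassifierSpec(kind) for kind in CLASSIFIER_KINDS)


@dataclass
class CVResult:
    """Per-fold success rates (% correct) for one band/classifier/session."""

    fold_rates: np.ndarray  # (n_folds,), percent
    band: str
    kind: str
    subject_group: str = "healthy"
    session_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.fold_rates < 0) or np.any(self.fold_rates > 100):
            raise ValueError("success rates must lie in [0, 100]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_rates))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_rates, ddof=1))


def runwise_folds(
    features: BandFeatures,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train, test) index split per run; fold i tests on run i."""
    runs = np.unique(features.runs)
    if runs.size < 2:
        raise ValueError("need at least 2 runs for run-wise folding")
    folds = []
    for run in runs:
        test = np.flatnonzero(features.runs == run)
        train = np.flatnonzero(features.runs != run)
        folds.append((train, test))
    return folds


def evaluate(
    features: BandFeatures,
    spec: ClassifierSpec,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    subject_group: str = "healthy",
    session_id: str = "",
) -> CVResult:
    """Cross-validated success rates for one classifier on one band."""
    if folds is None:
        folds = runwise_folds(features)
    x = np.asarray(features.values, dtype=np.float64)
    y = np.asarray(features.labels)
    rates = []
    for train, test in folds:
        if np.unique(y[train]).size < 2:
            raise ValueError("training fold has fewer than 2 classes")
        if spec.kind == "knn" and spec.knn_k > train.size:
            raise ValueError(
                f"k={spec.knn_k} exceeds training size {train.size}"
            )
        model = spec.build()
        model.fit(x[train], y[train])
        predicted = model.predict(x[test])
        rates.append(100.0 * np.mean(predicted == y[test]))
    return CVResult(
        fold_rates=np.array(rates),
        band=features.band,
        kind=spec.kind,
        subject_group=subject_group,
        session_id=session_id,
    )


def run_matrix(
    sessions: Iterable[tuple[str, str, dict[str, BandFeatures]]],
    specs: Sequence[ClassifierSpec] | None = None,
    bands: Sequence[str] = ("gamma_low", "gamma_high"),
) -> list[CVResult]:
    """Evaluate every (band, classifier, session) combination.

    ``sessions`` yields (session_id, subject_group, band -> features).
    """
    specs = tuple(specs) if specs is not None else default_specs()
    results = []
    for session_id, group, by_band in sessions:
        for band in bands:
            features = by_band[band]
            folds = runwise_folds(features)
            for spec in specs:
                results.append(
                    evaluate(features, spec, folds,
                             subject_group=group, session_id=session_id)
                )
    return results


def pooled_fold_rates(
    results: Iterable[CVResult],
    band: str | None = None,
    kind: str | None = None,
    subject_group: str | None = None,
) -> np.ndarray:
    """All single-fold values matching the given filters, pooled."""
    rates = [
        r.fold_rates
        for r in results
        if (band is None or r.band == band)
        and (kind is None or r.kind == kind)
        and (subject_group is None or r.subject_group == subject_group)
    ]
    if not rates:
        return np.array([])
    return np.concatenate(rates)


def results_table(results: Sequence[CVResult]) -> pd.DataFrame:
    """Success-rate table: one row per (band, session), one column per
    classifier, entries "mean±sd", plus pooled group averages."""
    rows = []
    for r in results:
        rows.append(
            {
                "band": r.band,
                "session": r.session_id,
                "group": r.subject_group,
                "classifier": KIND_ABBREV[r.kind],
                "cell": f"{r.mean:.2f}±{r.std:.2f}",
            }
        )
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index=["band", "group", "session"],
        columns="classifier",
        values="cell",
        aggfunc="first",
    )
    avg_rows = {}
    for band in sorted({r.band for r in results}):
        for group in sorted({r.subject_group for r in results}):
            cells = {}
            for kind in CLASSIFIER_KINDS:
                pooled = pooled_fold_rates(results, band, kind, group)
                if pooled.size:
                    cells[KIND_ABBREV[kind]] = (
                        f"{pooled.mean():.2f}±{pooled.std(ddof=1):.2f}"
                    )
            if cells:
                avg_rows[(band, group, "Avg")] = cells
    avg = pd.DataFrame.from_dict(avg_rows, orient="index")
    avg.index = pd.MultiIndex.from_tuples(avg.index,
                                          names=table.index.names)
    return pd.concat([table, avg]).sort_index()
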