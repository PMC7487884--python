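"""Classifier training and evaluation for drug-target pair scoring.

Positives are known drug-protein interactions; an equal-sized negative
set is drawn uniformly (without replacement) from the unlabelled part of
the drug x protein grid before cross-validation.  Evaluation is
stratified k-fold (default 5) with the full metric suite -- accuracy,
specificity, sensitivity, precision, Matthews correlation, ROC AUC and
area under the precision-recall curve -- reported per fold and as
mean +/- population standard deviation over folds.

Classifier hyperparameters are frozen in :data:`CLASSIFIER_DEFAULTS`
(scikit-learn-era defaults, e.g. 100 trees for the random forest) so
results do not drift with library versions.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold

from .errors import CapacityError, ConfigError, StratificationError

#: Frozen hyperparameters for the five supported classifier families.
#: Everything not listed here is the library default; seeds are injected
#: at fit time for the stochastic learners.
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "logistic": {"max_iter": 1000},
    "knn": {"n_neighbors": 5},
    "naive_bayes": {},
    "decision_tree": {},
    "random_forest": {"n_estimators": 100, "n_jobs": 1},
}

DEFAULT_THRESHOLD = 0.5


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the five supported families with frozen defaults."""
    if name == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(random_state=seed, **CLASSIFIER_DEFAULTS[name])
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(**CLASSIFIER_DEFAULTS[name])
    if name == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB(**CLASSIFIER_DEFAULTS[name])
    if name == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed, **CLASSIFIER_DEFAULTS[name])
    if name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, **CLASSIFIER_DEFAULTS[name])
    raise ConfigError(
        f"unknown classifier {name!r}; valid names: {sorted(CLASSIFIER_DEFAULTS)}"
    )


# ---------------------------------------------------------------------------
# negative sampling and folds
# ---------------------------------------------------------------------------


def sample_negative_pairs(
    positives: Iterable[tuple[str, str]],
    drugs: Iterable[str],
    proteins: Iterable[str],
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Equal-sized negative set, uniform without replacement.

    Candidates are all drug x protein pairs not in ``positives``; the
    result is disjoint from the positives and deterministic per seed.
    """
    positives = list(positives)
    pos_set = set(positives)
    drugs = sorted(set(drugs))
    proteins = sorted(set(proteins))
    candidates = [
        (d, p) for d in drugs for p in proteins if (d, p) not in pos_set
    ]
    n = len(positives)
    if len(candidates) < n:
        raise CapacityError(
            f"need {n} negative pairs but only {len(candidates)} "
            "non-interacting pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample; class-balanced partition."""
    labels = np.asarray(labels, dtype=int)
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise StratificationError(
                f"class {cls} has {(labels == cls).sum()} members, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def fold_hash(assignment: np.ndarray) -> str:
    """Stable digest of a fold assignment, for cross-grid consistency checks."""
    return hashlib.sha256(np.asarray(assignment, dtype=np.int64).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

METRIC_NAMES = ("acc", "spec", "prec", "mcc", "sen", "auc", "aupr")


@dataclass
class MetricSet:
    """Threshold metrics at 0.5 plus ROC AUC and average-precision AUPR.

    All values are proportions in [0, 1] (MCC in [-1, 1]); use
    :meth:`as_percent` for the conventional percentage display.
    """

    acc: float
    spec: float
    prec: float
    mcc: float
    sen: float
    auc: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_percent(self) -> dict[str, float]:
        out = {k: 100.0 * v for k, v in self.as_dict().items()}
        out["aupr"] = self.aupr  # conventionally printed as a fraction
        return out


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricSet:
    """Full metric suite from labels and classifier scores.

    Thresholded metrics use ``score >= threshold``; AUC is the trapezoidal
    area under the ROC curve (equal to the Mann-Whitney U statistic over
    n_pos * n_neg); AUPR is step-wise average precision, which avoids the
    optimistic bias of trapezoidal PR interpolation.  A zero MCC
    denominator (constant predictions) yields MCC = 0 with a warning.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ConfigError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ConfigError("both classes must be present (AUC undefined otherwise)")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero (constant predictions); MCC set to 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    auc = float(roc_auc_score(y, s))
    aupr = float(average_precision_score(y, s))
    return MetricSet(acc, spec, prec, float(mcc), sen, auc, aupr)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-fold metrics plus mean and population sd, in fold order."""

    fold_metrics: list[MetricSet]
    fold_assignment: np.ndarray
    seed: int
    classifier: str

    @property
    def k(self) -> int:
        return len(self.fold_metrics)

    @property
    def mean(self) -> MetricSet:
        return MetricSet(
            **{
                m: float(np.mean([getattr(f, m) for f in self.fold_metrics]))
                for m in METRIC_NAMES
            }
        )

    @property
    def sd(self) -> MetricSet:
        return MetricSet(
            **{
                m: float(np.std([getattr(f, m) for f in self.fold_metrics]))
                for m in METRIC_NAMES
            }
        )

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.fold_metrics):
            rows.append({"fold": str(i), **(m.as_percent() if percent else m.as_dict())})
        mean = self.mean.as_percent() if percent else self.mean.as_dict()
        sd = self.sd.as_percent() if percent else self.sd.as_dict()
        rows.append(
            {"fold": "average", **{k: mean[k] for k in mean}}
        )
        rows.append({"fold": "sd", **{k: sd[k] for k in sd}})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, percent: bool = True) -> None:
        self.to_frame(percent).to_csv(path, index=False)


def _fit_and_score(clf, X, y, train_idx, test_idx) -> np.ndarray:
    clf.fit(X[train_idx], y[train_idx])
    proba = clf.predict_proba(X[test_idx])
    pos_col = list(clf.classes_).index(1)
    return proba[:, pos_col]


def cross_validate(
    features,
    k: int = 5,
    classifier_name: str = "random_forest",
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier family.

    ``features`` is a :class:`~linedti.features.FeatureMatrix` (or any
    object with ``X`` and ``y``).  Passing a precomputed ``folds``
    assignment lets several runs share identical splits.
    """
    if classifier_name not in CLASSIFIER_DEFAULTS:
        raise ConfigError(
            f"unknown classifier {classifier_name!r}; valid names: "
            f"{sorted(CLASSIFIER_DEFAULTS)}"
        )
    X = np.asarray(features.X, dtype=float)
    y = np.asarray(features.y, dtype=int)
    if folds is None:
        folds = stratified_kfold(y, k=k, seed=seed)
    folds = np.asarray(folds)
    metrics = []
    for fold in range(int(folds.max()) + 1):
        test_idx = np.nonzero(folds == fold)[0]
        train_idx = np.nonzero(folds != fold)[0]
        clf = make_classifier(classifier_name, seed=seed)
        scores = _fit_and_score(clf, X, y, train_idx, test_idx)
        metrics.append(compute_metrics(y[test_idx], scores))
    return CVReport(metrics, folds, seed, classifier_name)


def cv_curves(features, k: int = 5, classifier_name: str = "random_forest", seed: int = 0):
    """Pooled out-of-fold ROC and PR curve points as two DataFrames."""
    X = np.asarray(features.X, dtype=float)
    y = np.asarray(features.y, dtype=int)
    folds = stratified_kfold(y, k=k, seed=seed)
    oof = np.zeros(len(y))
    for fold in range(k):
        test_idx = np.nonzero(folds == fold)[0]
        train_idx = np.nonzero(folds != fold)[0]
        clf = make_classifier(classifier_name, seed=seed)
        oof[test_idx] = _fit_and_score(clf, X, y, train_idx, test_idx)
    fpr, tpr, roc_thr = roc_curve(y, oof)
    prec, rec, _ = precision_recall_curve(y, oof)
    roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr})
    pr_df = pd.DataFrame({"recall": rec, "precision": prec})
    return roc_df, pr_df


# ---------------------------------------------------------------------------
# comparison experiments
# ---------------------------------------------------------------------------

FEATURE_MODES = ("attribute", "behavior", "both")


@dataclass
class ExperimentGrid:
    """One CVReport per cell, all sharing fold assignments and seed."""

    axis: str  # 'feature_mode' or 'classifier'
    cells: dict[str, CVReport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        hashes = {fold_hash(r.fold_assignment) for r in self.cells.values()}
        if len(hashes) > 1:
            raise ConfigError("grid cells must share one fold assignment")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, report in self.cells.items():
            mean, sd = report.mean.as_percent(), report.sd.as_percent()
            row: dict[str, str] = {self.axis: name}
            for m in METRIC_NAMES:
                prec = 4 if m == "aupr" else 2
                row[m] = f"{mean[m]:.{prec}f} +/- {sd[m]:.{prec}f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_classifier_comparison(
    features,
    seed: int = 0,
    k: int = 5,
    classifiers: Sequence[str] = tuple(CLASSIFIER_DEFAULTS),
) -> ExperimentGrid:
    """Five-family comparison on one feature matrix with identical folds."""
    folds = stratified_kfold(np.asarray(features.y, dtype=int), k=k, seed=seed)
    cells = {
        name: cross_validate(features, k=k, classifier_name=name, seed=seed, folds=folds)
        for name in classifiers
    }
    return ExperimentGrid("classifier", cells)


def run_feature_ablation(
    graph,
    sequences: Mapping[str, str],
    structures: Mapping[str, object],
    pairs: Sequence[tuple[str, str, int]],
    seed: int = 0,
    k: int = 5,
    line_config=None,
    classifier_name: str = "random_forest",
) -> ExperimentGrid:
    """Attribute-only vs behaviour-only vs combined features, shared folds.

    Single-mode cells use 64-dim node vectors (128-dim pairs); the
    combined cell uses 128-dim node vectors (256-dim pairs).  Behaviour
    vectors come from one embedding of ``graph`` shared by all cells.
    """
    from .pipeline import attribute_vector_map, behavior_vector_map, node_vector_map
    from .features import assemble_pair_matrix

    attr = attribute_vector_map(sequences, structures)
    names = {n for d, p, _ in pairs for n in (d, p)}
    behav = behavior_vector_map(graph, line_config=line_config, names=names)
    labels = np.asarray([lab for _, _, lab in pairs], dtype=int)
    folds = stratified_kfold(labels, k=k, seed=seed)
    cells = {}
    for mode in FEATURE_MODES:
        vectors = node_vector_map(attr, behav, mode=mode, names=names)
        matrix = assemble_pair_matrix(pairs, vectors)
        cells[mode] = cross_validate(
            matrix, k=k, classifier_name=classifier_name, seed=seed, folds=folds
        )
    return ExperimentGrid("feature_mode", cells)
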