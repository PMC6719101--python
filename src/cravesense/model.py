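"""Fisher-score feature selection, classifiers, and cross-session evaluation.

Trials are labeled by design: stimulation = high craving (1), wash-off = low
craving (0).  Per training set, the Fisher score

    F_j = (mu_j1 - mu_j0)^2 / (s_j1^2 + s_j0^2)

ranks the 14 candidates; the RBF-kernel SVM uses the top two features and the
other classifiers (kNN, CDNN, LDA, random forest) the single best one —
feature dimension is kept small because a session contributes only 36 trials.

Evaluation reproduces a four-condition protocol on each subject's third
session: (1) stratified 6-fold cross-validation within day 3 (30 train / 6
test per fold, feature selection refit per fold), (2) train on day 1,
(3) train on day 2, (4) train on days 1+2 pooled — conditions 2-4 always test
on all 36 day-3 trials.  Missing feature values are imputed with training-set
means and features are z-scored with training-set statistics, so no test-set
information reaches the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import FEATURE_NAMES, STIMULATION, SubjectStudy, ValidationError
from .features import FeatureConfig, features_table
from .preprocess import PreprocessConfig

__all__ = [
    "CLASSIFIER_NAMES",
    "CONDITIONS",
    "ClassifierSpec",
    "EvaluationResult",
    "CDNNClassifier",
    "fisher_score",
    "select_features",
    "train_classifier",
    "SubjectFeatures",
    "subject_features",
    "evaluate_subject",
    "evaluate_cohort",
]

CLASSIFIER_NAMES = ("svm_rbf", "knn", "cdnn", "lda", "random_forest")
CONDITIONS = ("cross_validation", "tr_day1", "tr_day2", "tr_day1_day2")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier plus its fixed hyper-parameters.

    Defaults: SVM with RBF kernel, C = 1, gamma = 1/(number of input
    features); kNN with k = 17; CDNN with k = size of the training set;
    LDA; random forest with 100 trees.  The SVM consumes the two
    highest-Fisher-score features, every other classifier the single best.
    """

    name: str
    knn_k: int = 17
    svm_c: float = 1.0
    rf_trees: int = 100
    seed: int = 0
    standardize: bool = True
    n_selected_features: int | None = None  # None -> 2 for svm_rbf else 1

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValidationError(f"unknown classifier {self.name!r}")
        if self.knn_k < 1 or self.svm_c <= 0:
            raise ValidationError("ClassifierSpec: need knn_k >= 1 and svm_c > 0")
        if self.n_selected_features not in (None, 1, 2):
            raise ValidationError("n_selected_features must be 1 or 2")

    @property
    def k_features(self) -> int:
        if self.n_selected_features is not None:
            return self.n_selected_features
        return 2 if self.name == "svm_rbf" else 1


@dataclass
class EvaluationResult:
    subject_id: str
    classifier: str
    condition: str
    accuracy: float                      # percent of day-3 trials correct
    n_train: int
    n_test: int
    selected_features: list[tuple[str, ...]]  # per training set (per fold for CV)
    fold_accuracies: list[float] = field(default_factory=list)
    fold_sizes: list[tuple[int, int]] = field(default_factory=list)  # (train, test)


# ---------------------------------------------------------------------------
# Fisher score and selection
# ---------------------------------------------------------------------------

_EPS_VAR = 1e-12


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-class Fisher score per feature column, NaN-aware.

    Missing entries are excluded feature-wise.  If both class variances
    vanish but the means differ, the denominator is replaced by a small
    epsilon so the perfectly separating feature ranks on top; if the means
    are also equal (or a class has no observations) the score is 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"fisher_score requires exactly 2 classes, got {classes.size}")
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        ok = np.isfinite(col)
        stats = []
        for c in classes:
            v = col[ok & (y == c)]
            if v.size < 1:
                stats = None
                break
            stats.append((np.mean(v), np.var(v, ddof=1) if v.size > 1 else 0.0))
        if stats is None:
            continue
        (m0, s0), (m1, s1) = stats
        num = (m1 - m0) ** 2
        den = s0 + s1
        if num == 0.0:
            scores[j] = 0.0
        else:
            scores[j] = num / max(den, _EPS_VAR)
    return scores


def select_features(scores: np.ndarray, k: int) -> list[int]:
    """Indices of the top-``k`` scores, ties broken by lower feature number."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= scores.size:
        raise ValidationError(f"select_features: k={k} out of range")
    order = np.lexsort((np.arange(scores.size), -scores))  # stable: index ascends on ties
    return [int(i) for i in order[:k]]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class CDNNClassifier:
    """Centroid-displacement-based k-nearest-neighbour classifier.

    For a query x, take its k nearest training points (Euclidean; here
    k = n_train).  For each class c present among them with member set S_c,
    the displacement is ||centroid(S_c) - centroid(S_c u {x})||; predict the
    class whose local centroid moves least.  Ties resolve by majority among
    the neighbours, then by lower class label.
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        self.k_ = self.X_.shape[0] if self.k is None else min(self.k, self.X_.shape[0])
        if self.k_ < 1:
            raise ValidationError("CDNN requires at least one training point")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=self.y_.dtype)
        for i, x in enumerate(X):
            d = np.linalg.norm(self.X_ - x, axis=1)
            nn = np.argsort(d, kind="stable")[: self.k_]
            yn = self.y_[nn]
            disp, counts = {}, {}
            for c in self.classes_:
                members = self.X_[nn][yn == c]
                if members.shape[0] == 0:
                    continue
                g = members.mean(axis=0)
                g_aug = np.vstack([members, x]).mean(axis=0)
                disp[c] = float(np.linalg.norm(g - g_aug))
                counts[c] = members.shape[0]
            best = min(disp.values())
            tied = sorted(c for c, v in disp.items() if v == best)
            if len(tied) > 1:
                maxcount = max(counts[c] for c in tied)
                tied = sorted(c for c in tied if counts[c] == maxcount)
            out[i] = tied[0]
        return out


def train_classifier(spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray):
    """Fit the classifier named by ``spec`` on an already-selected,
    already-standardized training matrix."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    n = X_train.shape[0]
    if spec.name == "svm_rbf":
        clf = SVC(C=spec.svm_c, kernel="rbf", gamma="auto")  # gamma = 1/n_features
    elif spec.name == "knn":
        if spec.knn_k > n:
            raise ValidationError(f"kNN: k={spec.knn_k} exceeds n_train={n}")
        clf = KNeighborsClassifier(n_neighbors=spec.knn_k)
    elif spec.name == "cdnn":
        clf = CDNNClassifier(k=None)  # k = n_train by definition
    elif spec.name == "lda":
        clf = LinearDiscriminantAnalysis()
    elif spec.name == "random_forest":
        clf = RandomForestClassifier(n_estimators=spec.rf_trees,
                                     random_state=spec.seed)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValidationError(spec.name)
    return clf.fit(X_train, y_train)


# ---------------------------------------------------------------------------
# per-training-set fit: impute -> select -> standardize -> train
# ---------------------------------------------------------------------------

@dataclass
class _FittedModel:
    clf: object
    selected: list[int]
    col_means: np.ndarray   # imputation means of the selected columns
    mu: np.ndarray
    sd: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float)[:, self.selected].copy()
        for j in range(Z.shape[1]):
            bad = ~np.isfinite(Z[:, j])
            Z[bad, j] = self.col_means[j]
        Z = (Z - self.mu) / self.sd
        return self.clf.predict(Z)


def _fit_on(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> _FittedModel:
    scores = fisher_score(X, y)
    selected = select_features(scores, spec.k_features)
    Z = np.asarray(X, dtype=float)[:, selected].copy()
    col_means = np.empty(Z.shape[1])
    for j in range(Z.shape[1]):
        col = Z[:, j]
        ok = np.isfinite(col)
        col_means[j] = np.mean(col[ok]) if ok.any() else 0.0
        col[~ok] = col_means[j]
    if spec.standardize:
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu = np.zeros(Z.shape[1])
        sd = np.ones(Z.shape[1])
    Zs = (Z - mu) / sd
    clf = train_classifier(spec, Zs, y)
    return _FittedModel(clf=clf, selected=selected, col_means=col_means, mu=mu, sd=sd)


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class SubjectFeatures:
    """Per-session feature matrices (36 x 14) and labels for one subject."""

    subject_id: str
    X: dict[str, np.ndarray]   # session_id -> (36, 14)
    y: dict[str, np.ndarray]   # session_id -> (36,) in {0, 1}

    @classmethod
    def from_table(cls, table: pd.DataFrame, subject_id: str) -> "SubjectFeatures":
        sub = table[table.subject_id == subject_id]
        X, y = {}, {}
        for sid, grp in sub.groupby("session_id"):
            grp = grp.sort_values("trial_index")
            X[sid] = grp[list(FEATURE_NAMES)].to_numpy(dtype=float)
            y[sid] = (grp["kind"] == STIMULATION).to_numpy(dtype=int)
        return cls(subject_id=subject_id, X=X, y=y)


def subject_features(study: SubjectStudy,
                     feature_config: FeatureConfig = FeatureConfig(),
                     preprocess_config: PreprocessConfig = PreprocessConfig(),
                     ) -> SubjectFeatures:
    """Run preprocessing + feature extraction for a study."""
    table = features_table(study, feature_config, preprocess_config)
    return SubjectFeatures.from_table(table, study.subject_id)


def _feature_names(selected: Sequence[int]) -> tuple[str, ...]:
    return tuple(FEATURE_NAMES[i] for i in selected)


def evaluate_subject(feats: SubjectFeatures | SubjectStudy,
                     spec: ClassifierSpec, *, cv_seed: int = 0,
                     ) -> list[EvaluationResult]:
    """The four evaluation conditions on one subject's day-3 session."""
    if isinstance(feats, SubjectStudy):
        feats = subject_features(feats)
    X3, y3 = feats.X["day3"], feats.y["day3"]
    results = []

    # condition 1: stratified 6-fold CV within day 3
    skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=cv_seed)
    fold_acc, fold_sizes, fold_sel = [], [], []
    for tr_idx, te_idx in skf.split(X3, y3):
        model = _fit_on(spec, X3[tr_idx], y3[tr_idx])
        pred = model.predict(X3[te_idx])
        fold_acc.append(100.0 * float(np.mean(pred == y3[te_idx])))
        fold_sizes.append((len(tr_idx), len(te_idx)))
        fold_sel.append(_feature_names(model.selected))
    results.append(EvaluationResult(
        subject_id=feats.subject_id, classifier=spec.name,
        condition="cross_validation", accuracy=float(np.mean(fold_acc)),
        n_train=fold_sizes[0][0], n_test=len(y3),
        selected_features=fold_sel, fold_accuracies=fold_acc,
        fold_sizes=fold_sizes))

    # conditions 2-4: train on earlier day(s), test on all 36 day-3 trials
    train_sets = {
        "tr_day1": (feats.X["day1"], feats.y["day1"]),
        "tr_day2": (feats.X["day2"], feats.y["day2"]),
        "tr_day1_day2": (np.vstack([feats.X["day1"], feats.X["day2"]]),
                         np.concatenate([feats.y["day1"], feats.y["day2"]])),
    }
    for cond, (Xt, yt) in train_sets.items():
        model = _fit_on(spec, Xt, yt)
        pred = model.predict(X3)
        acc = 100.0 * float(np.mean(pred == y3))
        results.append(EvaluationResult(
            subject_id=feats.subject_id, classifier=spec.name, condition=cond,
            accuracy=acc, n_train=Xt.shape[0], n_test=len(y3),
            selected_features=[_feature_names(model.selected)]))
    return results


def evaluate_cohort(cohort: Sequence[SubjectFeatures | SubjectStudy],
                    specs: Sequence[ClassifierSpec] | None = None,
                    *, cv_seed: int = 0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every subject under every classifier.

    Returns ``(per_subject, summary)``: the long per-subject accuracy table
    and the classifier x condition table of across-subject medians and
    interquartile ranges.
    """
    if specs is None:
        specs = [ClassifierSpec(name) for name in CLASSIFIER_NAMES]
    rows = []
    for feats in cohort:
        if isinstance(feats, SubjectStudy):
            feats = subject_features(feats)
        for spec in specs:
            for res in evaluate_subject(feats, spec, cv_seed=cv_seed):
                rows.append({"subject_id": res.subject_id,
                             "classifier": res.classifier,
                             "condition": res.condition,
                             "accuracy": res.accuracy})
    per_subject = pd.DataFrame(rows)
    summary = (per_subject
               .groupby(["classifier", "condition"])["accuracy"]
               .agg(median="median",
                    iqr=lambda a: float(np.percentile(a, 75) - np.percentile(a, 25)))
               .reset_index())
    return per_subject, summary
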