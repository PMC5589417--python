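"""Temporal-generalization decoding of categorical and circular labels.

Linear max-margin decoders are fitted independently at every time sample of
an epoch array and evaluated at every other time sample, yielding a
train-time x test-time generalization matrix.  Categorical labels
(e.g. seen/unseen visibility) use a linear SVM scored by ROC AUC of its
decision values; circular labels (stimulus/response angle) use a pair of
linear support-vector regressions predicting sine and cosine, recombined
through the arctangent, scored as ``pi/2 - mean |angular error|``.

All preprocessing (ANOVA feature selection, z-scoring, class weighting) is
fitted strictly on the training fold of a stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVR

from .network import wrap_angle

__all__ = [
    "FoldPlan",
    "GeneralizationMatrix",
    "anova_select",
    "fit_categorical",
    "score_auc",
    "fit_angle",
    "angular_accuracy",
    "temporal_generalization",
    "cross_generalize",
]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified cross-validation assignment of trials to test folds."""

    assignments: np.ndarray   # (n_trials,) fold index of each trial's test fold
    k: int
    stratified: bool = True
    seed: int | None = None

    @classmethod
    def build(cls, labels, k: int, seed: int | None = 0) -> "FoldPlan":
        labels = np.asarray(labels)
        # stratify over the discrete label values (for circular labels the
        # 20 positions act as strata)
        _, strata = np.unique(labels, return_inverse=True)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        assignments = np.empty(len(labels), dtype=int)
        for fold, (_, test_idx) in enumerate(skf.split(labels, strata)):
            assignments[test_idx] = fold
        return cls(assignments=assignments, k=k, seed=seed)

    def splits(self):
        for fold in range(self.k):
            test = self.assignments == fold
            yield ~test, test


@dataclass
class GeneralizationMatrix:
    """Decoder scores for every (train-time, test-time) pair."""

    scores: np.ndarray        # (n_train_times, n_test_times)
    metric: str               # "auc" or "angular_accuracy"
    train_times: np.ndarray
    test_times: np.ndarray

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.scores)

    def mean_diagonal(self) -> float:
        return float(self.diagonal.mean())


def anova_select(train_features: np.ndarray, labels,
                 fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of the top ``fraction`` of features by one-way ANOVA F.

    Ties broken by feature index (stable); features with undefined F
    (e.g. constant across trials) rank last.  Must be fitted on training
    data only.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    X = np.asarray(train_features, dtype=float)
    labels = np.asarray(labels)
    n, n_feat = X.shape
    groups = [X[labels == g] for g in np.unique(labels)]
    grand = X.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F = np.where(np.isfinite(F), F, -np.inf)
    n_keep = max(1, int(np.ceil(fraction * n_feat)))
    order = np.argsort(-F, kind="stable")
    mask = np.zeros(n_feat, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


class _Scaler:
    """Train-fold z-scoring; zero-variance features pass through."""

    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X):
        return (X - self.mean_) / self.scale_


def fit_categorical(train: np.ndarray, labels, class_weighting: bool = True,
                    C: float = 1.0):
    """Linear SVM on (already preprocessed) training features.

    Returns a fitted estimator whose ``decision_function`` gives the signed
    distance to the separating hyperplane.  Inverse-class-frequency
    weighting counteracts class imbalance.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("categorical decoder requires exactly two classes")
    clf = SVC(kernel="linear", C=C,
              class_weight="balanced" if class_weighting else None)
    clf.fit(np.asarray(train, dtype=float), labels)
    return clf


def score_auc(decision_values: np.ndarray, labels) -> float:
    """Area under the ROC curve of decision values across test trials.

    The positive class is the larger label in sorted order (matching the
    orientation of the SVM decision function); ties in the decision values
    are handled by the midrank convention.
    """
    _, y = np.unique(np.asarray(labels), return_inverse=True)
    return float(roc_auc_score(y, np.asarray(decision_values)))


class AnglePredictor:
    """Paired sin/cos support-vector regressions with arctangent readout."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, theta):
        theta = np.asarray(theta, dtype=float)
        if np.allclose(theta, theta[0]):
            raise ValueError("degenerate training set: all angles equal")
        X = np.asarray(X, dtype=float)
        kw = dict(C=self.C, loss="squared_epsilon_insensitive", dual=False,
                  max_iter=10000, random_state=0)
        self._sin = LinearSVR(**kw).fit(X, np.sin(theta))
        self._cos = LinearSVR(**kw).fit(X, np.cos(theta))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.arctan2(self._sin.predict(X), self._cos.predict(X))


def fit_angle(train: np.ndarray, theta_labels, C: float = 1.0) -> AnglePredictor:
    """Fit the circular decoder (two linear SVRs + atan2 recombination)."""
    return AnglePredictor(C=C).fit(train, theta_labels)


def angular_accuracy(pred_angles, true_angles) -> float:
    """Accuracy score ``pi/2 - mean |wrapped angular error|``.

    Ranges over [-pi/2, pi/2]; chance (uniformly random predictions) is 0,
    perfect prediction pi/2, systematically antipodal prediction -pi/2.
    """
    pred = np.asarray(pred_angles, dtype=float)
    true = np.asarray(true_angles, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.pi / 2 - np.mean(np.abs(wrap_angle(pred - true))))


class _TimePointPipeline:
    """Feature selection + scaling + decoder, fitted at one train time."""

    def __init__(self, metric: str, select_fraction: float, C: float):
        self.metric = metric
        self.select_fraction = select_fraction
        self.C = C

    def fit(self, X, labels):
        self.mask_ = anova_select(X, labels, self.select_fraction)
        Xs = X[:, self.mask_]
        self.scaler_ = _Scaler().fit(Xs)
        Z = self.scaler_.transform(Xs)
        if self.metric == "auc":
            self.est_ = fit_categorical(Z, labels, C=self.C)
        elif self.metric == "angular_accuracy":
            self.est_ = fit_angle(Z, labels, C=self.C)
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        return self

    def predict(self, X):
        Z = self.scaler_.transform(X[:, self.mask_])
        if self.metric == "auc":
            return self.est_.decision_function(Z)
        return self.est_.predict(Z)


def _default_folds(metric: str) -> int:
    return 5 if metric == "auc" else 2


def temporal_generalization(epochs, labels, metric: str = "auc",
                            fold_plan: FoldPlan | None = None,
                            seed: int | None = 0,
                            select_fraction: float = 0.5,
                            C: float = 1.0,
                            diagonal_only: bool = False
                            ) -> GeneralizationMatrix:
    """Cross-validated decoding at each time sample, tested at all others.

    ``epochs`` is an :class:`~silentwm.circstats.EpochSet` (or any object
    with ``data`` (trials x channels x time) and ``times``).  Within each
    stratified fold, a full pipeline is fitted per train-time on the
    training trials and applied to the held-out trials at every test time;
    scores are then computed across all trials (each held out exactly once).
    """
    X = np.asarray(epochs.data, dtype=float)
    times = np.asarray(epochs.times)
    labels = np.asarray(labels)
    n_trials, n_channels, n_times = X.shape
    if fold_plan is None:
        fold_plan = FoldPlan.build(labels, _default_folds(metric), seed)
    preds = np.full((n_times, n_times, n_trials), np.nan)
    for train_mask, test_mask in fold_plan.splits():
        for it in range(n_times):
            pipe = _TimePointPipeline(metric, select_fraction, C)
            pipe.fit(X[train_mask, :, it], labels[train_mask])
            test_times = [it] if diagonal_only else range(n_times)
            for jt in test_times:
                preds[it, jt, test_mask] = pipe.predict(X[test_mask, :, jt])
    scores = np.full((n_times, n_times), np.nan)
    cells = ((it, it) for it in range(n_times)) if diagonal_only else \
        ((it, jt) for it in range(n_times) for jt in range(n_times))
    for it, jt in cells:
        if metric == "auc":
            scores[it, jt] = score_auc(preds[it, jt], labels)
        else:
            scores[it, jt] = angular_accuracy(preds[it, jt], labels)
    return GeneralizationMatrix(scores=scores, metric=metric,
                                train_times=times, test_times=times)


def cross_generalize(train_epochs, train_labels, test_epochs, test_labels,
                     metric: str = "auc", seed: int | None = 0,
                     select_fraction: float = 0.5, C: float = 1.0
                     ) -> GeneralizationMatrix:
    """Train on one condition, test on an independent one.

    Decoders from each cross-validation training split of the training set
    are applied to the *entire* test set; their predictions are averaged
    before scoring.  Label semantics (e.g. training on visibility, testing
    on accuracy) are the caller's responsibility.
    """
    Xtr = np.asarray(train_epochs.data, dtype=float)
    Xte = np.asarray(test_epochs.data, dtype=float)
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("feature (channel) dimension mismatch")
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    n_times_tr = Xtr.shape[2]
    n_times_te = Xte.shape[2]
    plan = FoldPlan.build(train_labels, _default_folds(metric), seed)
    # decision values average arithmetically; predicted angles average as
    # unit vectors (circular mean)
    dtype = complex if metric == "angular_accuracy" else float
    acc = np.zeros((n_times_tr, n_times_te, Xte.shape[0]), dtype=dtype)
    for train_mask, _ in plan.splits():
        for it in range(n_times_tr):
            pipe = _TimePointPipeline(metric, select_fraction, C)
            pipe.fit(Xtr[train_mask, :, it], train_labels[train_mask])
            for jt in range(n_times_te):
                pred = pipe.predict(Xte[:, :, jt])
                acc[it, jt] += np.exp(1j * pred) if dtype is complex else pred
    acc /= plan.k
    scores = np.empty((n_times_tr, n_times_te))
    for it in range(n_times_tr):
        for jt in range(n_times_te):
            if metric == "auc":
                scores[it, jt] = score_auc(acc[it, jt].real, test_labels)
            else:
                scores[it, jt] = angular_accuracy(np.angle(acc[it, jt]),
                                                  test_labels)
    return GeneralizationMatrix(scores=scores, metric=metric,
                                train_times=np.asarray(train_epochs.times),
                                test_times=np.asarray(test_epochs.times))
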