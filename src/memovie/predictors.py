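"""Content-based prediction of single-trial memorability.

Three families of predictors:

* a cross-validated multivariate linear regression of group-level
  accuracy (fraction of subjects correct per shot) on the content
  vector;
* a linear support-vector classifier predicting correct/incorrect shot
  labels (per subject or the across-subject majority), with balanced
  class subsampling so chance is 50%, ten-fold cross-validation,
  per-property ablation, and a label-shuffle null distribution;
* two behaviour-only upper bounds — predicting a subject from the
  majority of the other subjects, and predicting repeat presentations
  from the first presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .consistency import mode_labels, repeat_pairs, _first_presentations
from .errors import ConfigurationError, DataIntegrityError

#: Minimum labelled shots after balancing for a classifier run.
MIN_LABELED_SHOTS = 40

#: Minimum predictions for an upper-bound report.
MIN_PREDICTIONS = 20


# --------------------------------------------------------------------- #
# labels


def make_labels(
    trials: pd.DataFrame, level: str = "mode", condition: str | None = "full_shot"
) -> pd.DataFrame:
    """Correct/incorrect shot labels at subject or group level.

    Subject level: one label per (subject, shot), the majority over that
    subject's presentations; ties (e.g. correct then incorrect) are
    excluded.  Mode level: one label per shot, the majority across
    subjects' labels; ties excluded.  ``condition`` restricts trials to
    one presentation mode first (pass ``None`` to keep all).
    """
    if level not in ("subject", "mode"):
        raise ConfigurationError(f"make_labels: unknown level {level!r}")
    t = trials if condition is None else trials[trials["presentation_mode"] == condition]
    votes = t.groupby(["subject_id", "shot_id"])["correct"].agg(["sum", "count"])
    untied = votes[votes["sum"] * 2 != votes["count"]]
    subject_labels = pd.DataFrame(
        {
            "subject_id": untied.index.get_level_values(0),
            "shot_id": untied.index.get_level_values(1),
            "label": (untied["sum"] * 2 > untied["count"]).to_numpy(),
            "n_votes_correct": untied["sum"].to_numpy(dtype=int),
            "n_presentations": untied["count"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    if level == "subject":
        if subject_labels.empty:
            warnings.warn("make_labels: no eligible shots", stacklevel=2)
        return subject_labels
    votes = subject_labels.groupby("shot_id")["label"].agg(["sum", "count"])
    untied = votes[votes["sum"] * 2 != votes["count"]]
    out = pd.DataFrame(
        {
            "shot_id": untied.index,
            "label": (untied["sum"] * 2 > untied["count"]).to_numpy(),
            "n_votes_correct": untied["sum"].to_numpy(dtype=int),
            "n_subjects": untied["count"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    if out.empty:
        warnings.warn("make_labels: no eligible shots", stacklevel=2)
    return out


# --------------------------------------------------------------------- #
# group regression


@dataclass
class RegressionModel:
    coefficients: dict[str, float]
    intercept: float
    cv_folds: int
    r_squared_cv: float
    ridge_used: bool
    constant_outcome: bool = False


def fit_group_regression(
    vectors: pd.DataFrame,
    group_pc: pd.Series,
    feature_set: list[str] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[RegressionModel, pd.Series]:
    """Cross-validated linear regression of group accuracy on content.

    ``group_pc`` is indexed by shot_id (fraction of subjects correct).
    The model is ordinary least squares unless there are fewer than five
    shots per feature, in which case a ridge penalty (alpha=1) engages
    and is reported.  ``r_squared_cv`` is the squared Pearson correlation
    between held-out predictions and actual values across all shots;
    coefficients come from a final fit on all shots.
    """
    ann = vectors.set_index("shot_id")
    if feature_set is None:
        feature_set = list(ann.columns)
    unknown = sorted(set(feature_set) - set(ann.columns))
    if unknown:
        raise ConfigurationError(f"fit_group_regression: unknown features {unknown}")
    shots = group_pc.index.to_numpy()
    X = ann.loc[shots, feature_set].to_numpy(dtype=float)
    y = group_pc.to_numpy(dtype=float)
    ridge = len(shots) < 5 * len(feature_set)
    make_model = (lambda: Ridge(alpha=1.0)) if ridge else (lambda: LinearRegression())

    preds = np.empty_like(y)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = make_model().fit(X[train], y[train])
        preds[test] = model.predict(X[test])

    constant = bool(np.allclose(y, y[0]) or np.allclose(preds, preds[0]))
    if constant:
        r2 = 0.0
    else:
        r, _ = stats.pearsonr(preds, y)
        r2 = float(r**2)
    final = make_model().fit(X, y)
    model = RegressionModel(
        coefficients=dict(zip(feature_set, map(float, final.coef_))),
        intercept=float(final.intercept_),
        cv_folds=cv_folds,
        r_squared_cv=r2,
        ridge_used=ridge,
        constant_outcome=constant,
    )
    return model, pd.Series(preds, index=group_pc.index, name="predicted_pc")


# --------------------------------------------------------------------- #
# balanced linear classifier


def balanced_subsample(labels: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Equalise label classes: keep the minority, subsample the majority."""
    pos = labels[labels["label"]]
    neg = labels[~labels["label"]]
    if len(pos) == 0 or len(neg) == 0:
        raise DataIntegrityError("balanced_subsample: one label class is absent")
    if len(pos) == len(neg):
        return labels
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    take = rng.choice(len(majority), size=len(minority), replace=False)
    return pd.concat([minority, majority.iloc[np.sort(take)]]).reset_index(drop=True)


@dataclass
class ClassifierReport:
    feature_set: list[str]
    accuracy_mean: float
    accuracy_sd: float
    n_subsample_reps: int
    cv_folds: int
    n_labeled: int
    n_balanced: int
    weights: dict[str, float] = field(default_factory=dict)
    null_mean: float | None = None
    null_sd: float | None = None
    p_vs_null: float | None = None
    name: str | None = None


def _resolve_features(
    vectors: pd.DataFrame, feature_set: list[str] | None
) -> tuple[pd.DataFrame, list[str]]:
    ann = vectors.set_index("shot_id")
    if feature_set is None:
        feature_set = list(ann.columns)
    unknown = sorted(set(feature_set) - set(ann.columns))
    if unknown:
        raise ConfigurationError(f"unknown feature names: {unknown}")
    return ann, list(feature_set)


def classify(
    vectors: pd.DataFrame,
    labels: pd.DataFrame,
    feature_set: list[str] | None = None,
    cv_folds: int = 10,
    n_subsample_reps: int = 25,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
) -> ClassifierReport:
    """Balanced-subsample, cross-validated linear-SVM classification.

    Per subsample repetition: equalise classes, assign shots to
    stratified folds, z-score features on the training shots only, fit a
    linear-kernel SVM (hinge loss, fixed regularisation C=1) and score
    the held-out shots.  Accuracy mean/SD are over repetitions x folds;
    reported weights come from a final fit on one balanced subsample of
    all labelled shots.  Chance is 50% by construction.
    """
    rng = np.random.default_rng() if rng is None else rng
    ann, feature_set = _resolve_features(vectors, feature_set)
    n_min = int(min((~labels["label"]).sum(), labels["label"].sum()))
    if 2 * n_min < MIN_LABELED_SHOTS:
        raise DataIntegrityError(
            f"classify: only {2 * n_min} labelled shots after balancing "
            f"(need >= {MIN_LABELED_SHOTS})"
        )
    accs: list[float] = []
    for _ in range(n_subsample_reps):
        bal = balanced_subsample(labels, rng)
        X = ann.loc[bal["shot_id"], feature_set].to_numpy(dtype=float)
        y = bal["label"].to_numpy(dtype=bool)
        skf = StratifiedKFold(
            n_splits=cv_folds, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for train, test in skf.split(X, y):
            clf = make_pipeline(StandardScaler(), LinearSVC(C=C))
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    bal = balanced_subsample(labels, rng)
    X = ann.loc[bal["shot_id"], feature_set].to_numpy(dtype=float)
    y = bal["label"].to_numpy(dtype=bool)
    final = make_pipeline(StandardScaler(), LinearSVC(C=C)).fit(X, y)
    weights = dict(zip(feature_set, map(float, final[-1].coef_.ravel())))
    return ClassifierReport(
        feature_set=feature_set,
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)),
        n_subsample_reps=n_subsample_reps,
        cv_folds=cv_folds,
        n_labeled=int(len(labels)),
        n_balanced=2 * n_min,
        weights=weights,
    )


def per_property_accuracy(
    vectors: pd.DataFrame,
    labels: pd.DataFrame,
    properties: list[str],
    cv_folds: int = 10,
    n_subsample_reps: int = 25,
    rng: np.random.Generator | None = None,
) -> list[ClassifierReport]:
    """Classifier ablation: one report per property plus a combined "ALL".

    Properties that are constant across the labelled shots carry no
    decision information and are skipped with a warning.  Reports are
    sorted by decreasing accuracy, with "ALL" appended last.
    """
    rng = np.random.default_rng() if rng is None else rng
    ann, properties = _resolve_features(vectors, properties)
    labeled = ann.loc[labels["shot_id"]]
    reports = []
    for prop in properties:
        col = labeled[prop].to_numpy(dtype=float)
        if np.allclose(col, col[0]):
            warnings.warn(f"per_property_accuracy: {prop!r} constant, skipped",
                          stacklevel=2)
            continue
        rep = classify(vectors, labels, [prop], cv_folds, n_subsample_reps, rng)
        rep.name = prop
        reports.append(rep)
    reports.sort(key=lambda r: -r.accuracy_mean)
    all_rep = classify(vectors, labels, properties, cv_folds, n_subsample_reps, rng)
    all_rep.name = "ALL"
    reports.append(all_rep)
    return reports


@dataclass
class ShuffleNull:
    null_accuracies: np.ndarray
    observed: float | None
    p_value: float | None

    @property
    def null_mean(self) -> float:
        return float(self.null_accuracies.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_accuracies.std(ddof=1))


def shuffle_null(
    vectors: pd.DataFrame,
    labels: pd.DataFrame,
    feature_set: list[str] | None = None,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    observed_accuracy: float | None = None,
    cv_folds: int = 10,
) -> ShuffleNull:
    """Label-shuffle null distribution of classification accuracy.

    Labels are permuted across shots each iteration and the full
    balanced-subsample CV pipeline re-run (one subsample repetition per
    iteration).  The p-value for an observed accuracy is the add-one
    exceedance fraction.
    """
    if n_iter < 100:
        raise ConfigurationError(f"shuffle_null: n_iter must be >= 100, got {n_iter}")
    rng = np.random.default_rng() if rng is None else rng
    null = np.empty(n_iter)
    for i in range(n_iter):
        shuffled = labels.copy()
        shuffled["label"] = rng.permutation(labels["label"].to_numpy())
        rep = classify(
            vectors, shuffled, feature_set,
            cv_folds=cv_folds, n_subsample_reps=1, rng=rng,
        )
        null[i] = rep.accuracy_mean
    p = None
    if observed_accuracy is not None:
        p = float(
            (1 + int(np.sum(null >= observed_accuracy - 1e-12))) / (n_iter + 1)
        )
    return ShuffleNull(null_accuracies=null, observed=observed_accuracy, p_value=p)


# --------------------------------------------------------------------- #
# behaviour-only upper bounds


@dataclass
class UpperBoundReport:
    model: str  # "majority_based" | "self_prediction"
    subject_id: str
    accuracy: float | None
    n_predictions: int
    suppressed: bool = False
    reason: str | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "subject_id": self.subject_id,
            "accuracy": self.accuracy,
            "n_predictions": self.n_predictions,
            "suppressed": self.suppressed,
            "reason": self.reason or "",
        }


def majority_predictor(
    trials: pd.DataFrame, subject_id: str, min_voters: int = 3
) -> UpperBoundReport:
    """Predict a subject's correctness from the other subjects' majority.

    For each shot the subject was queried on and at least ``min_voters``
    other subjects have untied votes on, the prediction is the majority
    correctness of the others; accuracy is the agreement fraction.
    """
    mode = mode_labels(trials, exclude_subject=subject_id, min_voters=min_voters)
    own = _first_presentations(trials[trials["subject_id"] == subject_id])
    own = own.set_index("shot_id")["correct"]
    shared = mode.index.intersection(own.index)
    if len(shared) < MIN_PREDICTIONS:
        return UpperBoundReport("majority_based", subject_id, None, len(shared),
                                suppressed=True, reason="insufficient_overlap")
    agree = own.loc[shared].to_numpy(dtype=bool) == mode.loc[shared].to_numpy(dtype=bool)
    return UpperBoundReport(
        "majority_based", subject_id, float(agree.mean()), int(len(shared))
    )


def self_predictor(trials: pd.DataFrame, subject_id: str) -> UpperBoundReport:
    """Predict repeat presentations from the first presentation.

    Accuracy equals the subject's self-consistency rate (fraction of
    repeat pairs with matching correctness).
    """
    pairs = repeat_pairs(trials, subject_id)
    if len(pairs) < MIN_PREDICTIONS:
        return UpperBoundReport("self_prediction", subject_id, None, len(pairs),
                                suppressed=True, reason="too_few_repeat_pairs")
    agree = pairs["first"].to_numpy() == pairs["second"].to_numpy()
    return UpperBoundReport(
        "self_prediction", subject_id, float(agree.mean()), int(len(pairs))
    )
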