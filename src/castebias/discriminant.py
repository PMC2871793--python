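"""Two-class linear discriminant analysis with collinearity pruning and
leave-one-out cross-validation.

The gene-expression arm classifies larvae as foundress-reared vs
worker-reared from the significant genes. With 16 features and 17
samples the pooled covariance is ill-conditioned, and strongly
correlated gene pairs (insulin-pathway genes, lipoprotein genes) make
plain LDA fail; the remedy mirrors the published sequence: prune highly
correlated features first, fit LDA on the survivors, then validate by
leave-one-out cross-validation.

Both steps are scikit-learn-style estimators (``fit``/``transform``/
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) so they compose with sklearn pipelines and model
selection; :func:`correlation_prune`, :func:`fit_lda` and :func:`loocv`
are thin functional wrappers over them for callers holding the field's
genes-in-rows matrices.
"""

from __future__ import annotations

import copy
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._estimator import ParamsMixin
from .errors import (
    DegenerateFoldError,
    InsufficientDataError,
    SingularCovarianceError,
)
from .stats import pearson_r

__all__ = [
    "CorrelationPruner",
    "LinearDiscriminant",
    "correlation_prune",
    "fit_lda",
    "loocv",
]


def _as_feature_frame(X) -> pd.DataFrame:
    """Coerce to a samples x features DataFrame (named or positional)."""
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class CorrelationPruner(ParamsMixin):
    """Drop features until no pair correlates above ``r_threshold``.

    Greedy rule: while any pair has ``|r| > r_threshold``, drop the
    feature with the most above-threshold partners; ties go to the
    feature with the larger mean ``|r|`` over its offending partners,
    then to the lexicographically later feature id. ``drop_override``
    short-circuits the rule and removes exactly the named features —
    the reproducible stand-in for a manual curation step.

    Fitted attributes: ``retained_features_``, ``drop_log_`` (list of
    ``(feature, reason, partner, r)``).
    """

    def __init__(
        self,
        r_threshold: float = 0.9,
        drop_override: Sequence[str] | None = None,
    ):
        self.r_threshold = r_threshold
        self.drop_override = drop_override

    def fit(self, X, y=None):
        frame = _as_feature_frame(X)
        features = list(frame.columns)
        if len(features) < 2:
            raise InsufficientDataError("pruning needs at least 2 features")
        self.n_features_in_ = len(features)
        self.drop_log_: list[tuple[str, str, str | None, float]] = []

        if self.drop_override:
            absent = [f for f in self.drop_override if f not in features]
            if absent:
                raise ValueError(f"drop_override names absent features: {absent}")
            for f in self.drop_override:
                self.drop_log_.append((str(f), "manual_override", None, float("nan")))
            self.retained_features_ = [f for f in features if f not in set(self.drop_override)]
            return self

        corr = np.zeros((len(features), len(features)))
        vals = frame.to_numpy(dtype=float)
        for i in range(len(features)):
            for j in range(i + 1, len(features)):
                r, _ = pearson_r(vals[:, i], vals[:, j])
                corr[i, j] = corr[j, i] = r
        alive = list(range(len(features)))
        while True:
            sub = np.abs(corr[np.ix_(alive, alive)])
            offending = sub > self.r_threshold
            np.fill_diagonal(offending, False)
            counts = offending.sum(axis=1)
            if counts.max(initial=0) == 0:
                break
            mean_r = np.where(
                counts > 0, np.where(offending, sub, 0.0).sum(axis=1) / np.maximum(counts, 1), 0.0
            )
            names = [str(features[a]) for a in alive]
            # pick max count, then max mean |r|, then lexicographically latest id
            order = sorted(
                range(len(alive)),
                key=lambda k: (counts[k], mean_r[k], names[k]),
            )
            victim = order[-1]
            partners = np.nonzero(offending[victim])[0]
            worst = partners[np.argmax(sub[victim, partners])]
            self.drop_log_.append(
                (
                    names[victim],
                    "above_threshold_correlation",
                    names[worst],
                    float(corr[alive[victim], alive[worst]]),
                )
            )
            del alive[victim]
        self.retained_features_ = [features[a] for a in alive]
        return self

    def transform(self, X):
        frame = _as_feature_frame(X)
        return frame[self.retained_features_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class LinearDiscriminant(ParamsMixin):
    """Two-class LDA with pooled covariance and optional ridge shrinkage.

    Weights are ``S^-1 (mu2 - mu1)`` where ``S`` is the pooled
    within-class covariance, optionally ridged to
    ``S + ridge_lambda * (trace(S)/p) * I``; the intercept places the
    decision boundary at the prior-adjusted midpoint of the projected
    class means. ``priors="empirical"`` uses the class frequencies,
    ``"equal"`` uses 1/2 each.

    Fitted attributes: ``classes_``, ``weights_`` (alias ``coef_``),
    ``intercept_``, ``class_means_``, ``pooled_covariance_``,
    ``ld_scores_`` (decision-function value of each training sample).
    """

    def __init__(
        self,
        ridge_lambda: float = 0.0,
        priors: Literal["empirical", "equal"] = "empirical",
    ):
        self.ridge_lambda = ridge_lambda
        self.priors = priors

    def fit(self, X, y):
        frame = _as_feature_frame(X)
        Xa = frame.to_numpy(dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise InsufficientDataError("LinearDiscriminant requires exactly 2 classes")
        m1_mask = y == classes[0]
        n1, n2 = int(m1_mask.sum()), int((~m1_mask).sum())
        if n1 < 2 or n2 < 2:
            raise InsufficientDataError("each class needs at least 2 samples")
        n, p = Xa.shape
        if self.ridge_lambda == 0 and p > n - 2:
            raise SingularCovarianceError(
                f"{p} features with only {n} samples leaves the pooled "
                "covariance singular; prune more features or set ridge_lambda > 0"
            )
        X1, X2 = Xa[m1_mask], Xa[~m1_mask]
        mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
        S = ((X1 - mu1).T @ (X1 - mu1) + (X2 - mu2).T @ (X2 - mu2)) / (n - 2)
        if self.ridge_lambda > 0:
            S = S + self.ridge_lambda * (np.trace(S) / p) * np.eye(p)
        try:
            w = np.linalg.solve(S, mu2 - mu1)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "pooled covariance is singular; prune correlated features "
                "or set ridge_lambda > 0"
            ) from exc
        if not np.all(np.isfinite(w)):
            raise SingularCovarianceError(
                "discriminant weights are not finite; pooled covariance is "
                "effectively singular"
            )
        if self.priors == "empirical":
            log_prior_ratio = np.log(n2 / n1)
        elif self.priors == "equal":
            log_prior_ratio = 0.0
        else:
            raise ValueError(f"unknown priors {self.priors!r}")
        self.classes_ = classes
        self.feature_names_in_ = list(frame.columns)
        self.n_features_in_ = p
        self.class_means_ = np.vstack([mu1, mu2])
        self.pooled_covariance_ = S
        self.weights_ = w
        self.coef_ = w.reshape(1, -1)
        self.intercept_ = float(-w @ (mu1 + mu2) / 2.0 + log_prior_ratio)
        self.ld_scores_ = self.decision_function(frame)
        return self

    def decision_function(self, X) -> np.ndarray:
        frame = _as_feature_frame(X)
        if isinstance(X, pd.DataFrame):
            frame = frame[self.feature_names_in_]
        return frame.to_numpy(dtype=float) @ self.weights_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# functional wrappers (features-in-rows convention of the table schemas)
# ---------------------------------------------------------------------------

def correlation_prune(
    matrix: pd.DataFrame,
    feature_ids: Sequence[str] | None = None,
    r_threshold: float = 0.9,
    drop_override: Sequence[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, str | None, float]]]:
    """Prune collinear features from a features x samples matrix.

    Returns ``(retained ids, drop log)``; see :class:`CorrelationPruner`.
    """
    if feature_ids is not None:
        matrix = matrix.loc[list(feature_ids)]
    pruner = CorrelationPruner(r_threshold=r_threshold, drop_override=drop_override)
    pruner.fit(matrix.T)
    return pruner.retained_features_, pruner.drop_log_


def fit_lda(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ridge_lambda: float = 0.0,
    priors: Literal["empirical", "equal"] = "empirical",
) -> LinearDiscriminant:
    """Fit LDA on a features x samples matrix with per-sample labels."""
    model = LinearDiscriminant(ridge_lambda=ridge_lambda, priors=priors)
    model.fit(matrix.T, labels.reindex(matrix.columns).to_numpy())
    return model


def loocv(
    matrix: pd.DataFrame,
    labels: pd.Series,
    *,
    prune: CorrelationPruner | None = None,
    lda: LinearDiscriminant | None = None,
    per_fold_prune: bool = False,
) -> tuple[pd.Series, float, list[LinearDiscriminant]]:
    """Leave-one-out cross-validated classification.

    ``matrix`` is features x samples. By default the feature set is
    pruned once on the full data and held fixed across folds — the
    published sequence (prune, then LDA, then LOOCV), which is mildly
    optimistic; ``per_fold_prune=True`` re-prunes inside every fold.

    Returns ``(predicted labels, accuracy, per-fold fitted models)``.
    """
    labels = labels.reindex(matrix.columns)
    y = labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise InsufficientDataError("LOOCV requires exactly 2 classes")
    if counts.min() < 2:
        raise DegenerateFoldError(
            "leaving one sample out would empty a class "
            f"(class sizes {dict(zip(classes, counts))})"
        )
    if lda is None:
        lda = LinearDiscriminant()
    frame = matrix.T  # samples x features
    if prune is not None and not per_fold_prune:
        prune = copy.deepcopy(prune).fit(frame)
        frame = prune.transform(frame)
    preds = []
    models: list[LinearDiscriminant] = []
    for i, sample in enumerate(frame.index):
        train = frame.drop(index=sample)
        ytr = np.delete(y, i)
        if per_fold_prune and prune is not None:
            fold_pruner = copy.deepcopy(prune).fit(train)
            train_f = fold_pruner.transform(train)
            test_f = fold_pruner.transform(frame.loc[[sample]])
        else:
            train_f, test_f = train, frame.loc[[sample]]
        model = copy.deepcopy(lda).fit(train_f, ytr)
        preds.append(model.predict(test_f)[0])
        models.append(model)
    predicted = pd.Series(preds, index=frame.index, name="predicted")
    accuracy = float(np.mean(predicted.to_numpy() == y))
    return predicted, accuracy, models
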