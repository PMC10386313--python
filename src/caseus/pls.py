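"""Partial least squares comparators: PLS regression and PLS-DA.

These models use only the fully observed mineral block as predictors, since
PLS cannot handle missing cells. Fitting is delegated to scikit-learn's
NIPALS ``PLSRegression`` (both blocks autoscaled on calibration statistics);
the discriminant variant regresses a one-hot class indicator matrix and
decodes predictions by argmax with ties broken by class order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression


class PLSError(ValueError):
    pass


def _check_block(A, name: str) -> np.ndarray:
    A = np.asarray(A, float)
    if A.ndim == 1:
        A = A[:, None]
    if np.isnan(A).any():
        raise PLSError(f"{name} contains missing cells; PLS requires complete data")
    return A


class PLS:
    """Model specification for a PLS regression of Y on X.

    ``n_components`` latent variables, bounded by min(n - 1, p_x).
    """

    def __init__(self, X, Y, n_components: int, x_names=None, y_names=None):
        X = _check_block(X, "X")
        Y = _check_block(Y, "Y")
        n, px = X.shape
        if Y.shape[0] != n:
            raise PLSError("X and Y disagree in sample count")
        if n < 3:
            raise PLSError("need at least 3 samples")
        if not 1 <= n_components <= min(n - 1, px):
            raise PLSError(
                f"n_components={n_components} outside [1, min(n-1, p_x)]="
                f"[1, {min(n - 1, px)}]"
            )
        self.X, self.Y, self.n_lv = X, Y, int(n_components)
        self.x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(px)]
        self.y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(Y.shape[1])]

    def fit(self) -> "PLSResults":
        est = PLSRegression(n_components=self.n_lv, scale=True).fit(self.X, self.Y)
        return PLSResults(
            n_lv=self.n_lv,
            x_names=self.x_names,
            y_names=self.y_names,
            _est=est,
        )


@dataclass
class PLSResults:
    """Fitted PLS regression: linear predictor Y ~ X B + b0."""

    n_lv: int
    x_names: list[str]
    y_names: list[str]
    _est: PLSRegression

    @property
    def coef(self) -> np.ndarray:
        """(p_x, p_y) regression coefficients on the original variable scales."""
        return self._est.coef_.T

    @property
    def intercept(self) -> np.ndarray:
        """Intercept of the affine map y_hat = x @ coef + intercept."""
        return self._est.intercept_ - self._est._x_mean @ self.coef

    @property
    def x_scores(self) -> np.ndarray:
        """Calibration score vectors (mutually orthogonal)."""
        return self._est.x_scores_

    def predict(self, X_new) -> np.ndarray:
        X_new = _check_block(X_new, "X_new")
        if X_new.shape[1] != len(self.x_names):
            raise PLSError("predictor count mismatch")
        return np.asarray(self._est.predict(X_new), float)

    def summary(self) -> str:
        return (
            f"PLS regression ({self.n_lv} latent variables, NIPALS, autoscaled)\n"
            f"predictors: {len(self.x_names)}  responses: {len(self.y_names)}"
        )


class PLSDA:
    """PLS discriminant analysis: one-hot indicator regression + argmax decode."""

    def __init__(self, X, labels, n_components: int, x_names=None, classes=None):
        labels = np.asarray([str(l) for l in labels])
        if classes is None:
            classes = sorted(set(labels))
        if len(classes) < 2:
            raise PLSError("need at least 2 classes")
        Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
        self._pls = PLS(X, Y, n_components, x_names=x_names, y_names=list(classes))
        self.classes = list(classes)

    def fit(self) -> "PLSDAResults":
        return PLSDAResults(regression=self._pls.fit(), classes=self.classes)


@dataclass
class PLSDAResults:
    regression: PLSResults
    classes: list[str]

    @property
    def n_lv(self) -> int:
        return self.regression.n_lv

    def predict_indicator(self, X_new) -> np.ndarray:
        return self.regression.predict(X_new)

    def predict(self, X_new) -> np.ndarray:
        """Decoded class labels; argmax keeps the first (class-order) maximum."""
        ind = self.predict_indicator(X_new)
        return np.asarray(self.classes, object)[np.argmax(ind, axis=1)]

    def summary(self) -> str:
        return (
            f"PLS-DA ({self.n_lv} latent variables) over classes: "
            + ", ".join(self.classes)
        )


def fit_pls(X, Y, n_components: int, x_names=None, y_names=None) -> PLSResults:
    return PLS(X, Y, n_components, x_names=x_names, y_names=y_names).fit()


def fit_plsda(X, labels, n_components: int, x_names=None, classes=None) -> PLSDAResults:
    return PLSDA(X, labels, n_components, x_names=x_names, classes=classes).fit()
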