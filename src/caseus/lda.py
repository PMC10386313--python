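"""Linear discriminant classification in latent score space.

Samples are assigned to the class whose centroid is nearest in Mahalanobis
distance under the pooled within-class covariance, with equal priors — the
decision boundaries are therefore the loci where the Mahalanobis distances to
two class centroids are equal, which are affine in the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ppca import ScoreSet


class LDAError(ValueError):
    pass


def _coerce_scores(scores) -> np.ndarray:
    if isinstance(scores, ScoreSet):
        return np.asarray(scores.scores, float)
    return np.atleast_2d(np.asarray(scores, float))


class ScoreLDA:
    """Model specification: scores plus class labels.

    Classes are ordered alphabetically (deterministic tie-breaking order)
    unless an explicit ``classes`` sequence is given.
    """

    def __init__(self, scores, labels, classes=None):
        Z = _coerce_scores(scores)
        labels = np.asarray([str(l) for l in labels])
        if Z.shape[0] != labels.size:
            raise LDAError("scores and labels disagree in length")
        if classes is None:
            classes = sorted(set(labels))
        if len(classes) < 2:
            raise LDAError("need at least 2 classes")
        self.Z, self.labels, self.classes = Z, labels, list(classes)

    def fit(self) -> "LDAResults":
        Z, labels, classes = self.Z, self.labels, self.classes
        n, q = Z.shape
        k = len(classes)
        if n <= q + k:
            raise LDAError(
                f"n={n} samples cannot support q={q} components with {k} classes; "
                "use fewer principal components"
            )
        centroids = np.empty((k, q))
        pooled = np.zeros((q, q))
        for c, cls in enumerate(classes):
            Zi = Z[labels == cls]
            if Zi.shape[0] < 2:
                raise LDAError(f"class {cls!r} has {Zi.shape[0]} sample(s); need >= 2")
            centroids[c] = Zi.mean(axis=0)
            D = Zi - centroids[c]
            pooled += D.T @ D
        pooled /= n - k
        try:
            prec = np.linalg.inv(pooled)
            if np.linalg.cond(pooled) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            raise LDAError(
                "pooled within-class covariance is singular; use fewer principal components"
            ) from None
        return LDAResults(classes=list(classes), centroids=centroids, pooled_cov=pooled, _prec=prec)


@dataclass
class LDAResults:
    """Fitted centroids and pooled covariance; equal-prior classification."""

    classes: list[str]
    centroids: np.ndarray
    pooled_cov: np.ndarray
    _prec: np.ndarray

    @property
    def n_components(self) -> int:
        return self.centroids.shape[1]

    def mahalanobis_sq(self, scores) -> np.ndarray:
        """(n, k) squared Mahalanobis distances to every class centroid."""
        Z = _coerce_scores(scores)
        if Z.shape[1] != self.n_components:
            raise LDAError(
                f"score dimension {Z.shape[1]} != model dimension {self.n_components}"
            )
        D = np.empty((Z.shape[0], len(self.classes)))
        for c in range(len(self.classes)):
            R = Z - self.centroids[c]
            D[:, c] = np.einsum("ij,jk,ik->i", R, self._prec, R)
        return D

    def predict(self, scores) -> np.ndarray:
        """Argmin Mahalanobis distance; ties broken by class order."""
        D = self.mahalanobis_sq(scores)
        return np.asarray(self.classes, object)[np.argmin(D, axis=1)]

    def boundaries_2d(self) -> dict[tuple[str, str], tuple[float, float, float]]:
        """Pairwise equal-distance boundaries a*x + b*y + c = 0 (q = 2 only)."""
        if self.n_components != 2:
            raise LDAError("boundaries_2d requires a 2-component model")
        out = {}
        P = self._prec
        for i in range(len(self.classes)):
            for j in range(i + 1, len(self.classes)):
                mi, mj = self.centroids[i], self.centroids[j]
                ab = 2.0 * P @ (mj - mi)
                c = float(mi @ P @ mi - mj @ P @ mj)
                out[(self.classes[i], self.classes[j])] = (float(ab[0]), float(ab[1]), c)
        return out

    def summary(self) -> str:
        lines = [
            "Linear discriminant (Mahalanobis / pooled covariance, equal priors)",
            "=" * 60,
            f"classes    : {', '.join(self.classes)}",
            f"dimensions : {self.n_components}",
            "centroids  :",
        ]
        for cls, mu in zip(self.classes, self.centroids):
            lines.append(f"  {cls:<10s} " + "  ".join(f"{v:8.3f}" for v in mu))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "centroids": self.centroids.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAResults":
        pooled = np.asarray(d["pooled_cov"], float)
        return cls(
            classes=list(d["classes"]),
            centroids=np.asarray(d["centroids"], float),
            pooled_cov=pooled,
            _prec=np.linalg.inv(pooled),
        )


def fit_lda(scores, labels, classes=None) -> LDAResults:
    """Convenience wrapper around :class:`ScoreLDA`."""
    return ScoreLDA(scores, labels, classes=classes).fit()


def classify(model: LDAResults, scores) -> np.ndarray:
    return model.predict(scores)
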