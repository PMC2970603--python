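"""Linear and nonlinear (quadratic) Gaussian discriminant rules.

Both rules assume Gaussian classes with equal priors.  The linear rule uses
the pooled within-class covariance (Fisher LDA); the nonlinear rule is
quadratic discriminant analysis with class-specific covariances — a
deterministic, parameter-free nonlinear discriminant for the 3-feature
spaces produced by Fisher-coefficient selection.  A singular covariance is
regularised once with a ridge lambda = ridge_scale * trace / dim; if it is
still singular the fit raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["DiscriminantRule", "train_lda", "train_nda"]


def _factor(cov: np.ndarray, ridge_scale: float):
    """Cholesky factor of cov, with one ridge retry on failure."""
    dim = cov.shape[0]
    try:
        return linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError:
        lam = ridge_scale * (np.trace(cov) / dim if np.trace(cov) > 0 else 1.0)
        try:
            return linalg.cho_factor(cov + lam * np.eye(dim), lower=True)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                f"covariance singular even after ridge {lam:.3g}"
            ) from err


@dataclass(eq=False)
class DiscriminantRule:
    """A fitted Gaussian discriminant classifier (equal priors).

    kind = "linear": pooled covariance; kind = "quadratic": per-class
    covariances.  Score ties are broken toward the lower class label.
    """

    kind: str = "linear"
    ridge_scale: float = 1e-6
    classes_: np.ndarray = field(default=None, repr=False)
    means_: np.ndarray = field(default=None, repr=False)
    _factors: list = field(default=None, repr=False)
    _logdets: np.ndarray = field(default=None, repr=False)

    def fit(self, X, y) -> "DiscriminantRule":
        if self.kind not in ("linear", "quadratic"):
            raise ValueError(f"unknown discriminant kind {self.kind!r}")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with one label per row")
        if np.isnan(X).any():
            raise ValueError("training matrix contains undefined (NaN) values")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training observations")
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        p = X.shape[1]
        if self.kind == "linear":
            scatter = np.zeros((p, p))
            for c, m in zip(self.classes_, self.means_):
                d = X[y == c] - m
                scatter += d.T @ d
            pooled = scatter / (X.shape[0] - self.classes_.size)
            f = _factor(pooled, self.ridge_scale)
            self._factors = [f] * self.classes_.size
            self._logdets = np.zeros(self.classes_.size)  # common, cancels
        else:
            self._factors = []
            logdets = []
            for c in self.classes_:
                d = X[y == c] - X[y == c].mean(axis=0)
                cov = d.T @ d / (d.shape[0] - 1)
                f = _factor(cov, self.ridge_scale)
                self._factors.append(f)
                logdets.append(2.0 * np.log(np.diag(f[0])).sum())
            self._logdets = np.asarray(logdets)
        return self

    def scores(self, X) -> np.ndarray:
        """(n, n_classes) discriminant scores; higher is more likely."""
        X = np.asarray(X, dtype=np.float64)
        if np.isnan(X).any():
            raise ValueError("matrix contains undefined (NaN) values")
        out = np.empty((X.shape[0], self.classes_.size))
        for k, (m, f, ld) in enumerate(zip(self.means_, self._factors, self._logdets)):
            d = X - m
            sol = linalg.cho_solve(f, d.T)
            maha = (d.T * sol).sum(axis=0)
            out[:, k] = -0.5 * (maha + ld)
        return out

    def predict(self, X) -> np.ndarray:
        s = self.scores(X)
        return self.classes_[np.argmax(s, axis=1)]  # argmax tie -> lower label


def train_lda(X, y, ridge_scale: float = 1e-6) -> DiscriminantRule:
    """Pooled-covariance Fisher linear discriminant with equal priors."""
    return DiscriminantRule(kind="linear", ridge_scale=ridge_scale).fit(X, y)


def train_nda(X, y, ridge_scale: float = 1e-6) -> DiscriminantRule:
    """Quadratic (nonlinear) discriminant with equal priors."""
    return DiscriminantRule(kind="quadratic", ridge_scale=ridge_scale).fit(X, y)
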