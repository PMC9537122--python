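"""The three classifier families: KNN, Gaussian discriminant analysis, SVM.

KNN is the headline method (majority vote / inverse-distance vote over the
k nearest training segments under a configurable metric, Minkowski by
default).  Discriminant analysis fits Gaussian class-conditionals (shared
covariance for linear, per-class for quadratic) and predicts by minimum
expected classification cost, which for 0/1 costs reduces to the posterior
argmax.  The SVM solves the soft-margin dual (via scikit-learn's solver)
to a 1e-3 feasibility-gap tolerance with linear, Gaussian, or cubic
polynomial (x.x' + 1)^3 kernels.

All models standardize features with training-set mean/sd at fit time —
distances and margins are not scale-invariant and the input markers live
on different numeric ranges.

Presets: the tuned configuration is KNN with k=3, Euclidean metric and
inverse-distance weighting; documented alternatives are KNN with Minkowski
p=2/k=6, quadratic discriminant analysis, and SVM with either box 0.32 +
cubic kernel, box 7.59 + Gaussian kernel, or a linear kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

KNN_METRICS = ("minkowski", "euclidean", "cityblock", "chebychev",
               "mahalanobis", "cosine", "correlation")

#: hyperparameter presets, by provenance
PRESETS = {
    "knn_tuned": {"k": 3, "metric": "euclidean", "weighting": "inverse"},
    "knn_methods": {"k": 6, "metric": "minkowski", "p": 2.0,
                    "weighting": "uniform"},
    "da_tuned": {"kind": "quadratic"},
    "svm_optimized": {"C": 0.32, "kernel": "cubic"},
    "svm_tuned": {"C": 7.59, "kernel": "gaussian"},
    "svm_linear": {"C": 1.0, "kernel": "linear"},
}


def minkowski_distance(x: Sequence[float], y: Sequence[float],
                       p: float) -> float:
    """d(x, y) = (sum_j |x_j - y_j|^p)^(1/p), p >= 1."""
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)  # constant features pass through

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


class KNNModel:
    """k-nearest-neighbor classifier over standardized features.

    Tie rules: with uniform weighting and a tied vote the single nearest
    neighbor's class wins; with inverse-distance weighting an exact-match
    neighbor (d = 0) wins outright, as the limit of 1/d.
    """

    def __init__(self, k: int = 3, metric: str = "euclidean",
                 weighting: str = "inverse", p: float = 2.0):
        if k < 1:
            raise ValueError("k must be >= 1")
        if metric not in KNN_METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        if weighting not in ("uniform", "inverse"):
            raise ValueError(f"unknown weighting {weighting!r}")
        if metric == "minkowski" and p < 1:
            raise ValueError("Minkowski order p must be >= 1")
        self.k = k
        self.metric = metric
        self.weighting = weighting
        self.p = p

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.k > len(X):
            raise ValueError("k exceeds the number of training points")
        self._scale = _Standardizer(X)
        self.X_ = self._scale(X)
        self.y_ = y
        if self.metric == "mahalanobis":
            cov = np.cov(self.X_, rowvar=False)
            cov = np.atleast_2d(cov)
            self._VI = np.linalg.pinv(cov)
        return self

    def _distances(self, Q: np.ndarray) -> np.ndarray:
        if self.metric == "minkowski":
            return cdist(Q, self.X_, metric="minkowski", p=self.p)
        if self.metric == "chebychev":
            return cdist(Q, self.X_, metric="chebyshev")
        if self.metric == "mahalanobis":
            return cdist(Q, self.X_, metric="mahalanobis", VI=self._VI)
        return cdist(Q, self.X_, metric=self.metric)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and positive-class scores (vote weight fraction)."""
        Q = self._scale(np.atleast_2d(np.asarray(X, dtype=float)))
        if Q.shape[1] != self.X_.shape[1]:
            raise ValueError("query dimensionality mismatch")
        D = self._distances(Q)
        labels = np.empty(len(Q), dtype=int)
        scores = np.empty(len(Q), dtype=float)
        for i, d in enumerate(D):
            order = np.argsort(d, kind="stable")[:self.k]
            nd, ny = d[order], self.y_[order]
            if self.weighting == "inverse" and nd[0] == 0.0:
                exact = ny[nd == 0.0]
                labels[i] = exact[0]
                scores[i] = float(np.mean(exact == 1))
                continue
            if self.weighting == "inverse":
                w = 1.0 / nd
            else:
                w = np.ones_like(nd)
            w1 = float(w[ny == 1].sum())
            w0 = float(w[ny == 0].sum())
            if w1 > w0:
                labels[i] = 1
            elif w0 > w1:
                labels[i] = 0
            else:
                labels[i] = ny[0]  # tie: nearest neighbor decides
            scores[i] = w1 / (w0 + w1)
        return labels, scores

    def to_dict(self) -> dict:
        return {
            "family": "knn",
            "k": self.k, "metric": self.metric, "weighting": self.weighting,
            "p": self.p,
            "scale_mean": self._scale.mean.tolist(),
            "scale_sd": self._scale.sd.tolist(),
            "X": self.X_.tolist(), "y": self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KNNModel":
        m = cls(k=d["k"], metric=d["metric"], weighting=d["weighting"],
                p=d["p"])
        m._scale = _Standardizer.__new__(_Standardizer)
        m._scale.mean = np.asarray(d["scale_mean"])
        m._scale.sd = np.asarray(d["scale_sd"])
        m.X_ = np.asarray(d["X"])
        m.y_ = np.asarray(d["y"], dtype=int)
        if m.metric == "mahalanobis":
            m._VI = np.linalg.pinv(np.atleast_2d(np.cov(m.X_, rowvar=False)))
        return m


class DiscriminantModel:
    """Gaussian discriminant analysis with a classification-cost rule.

    Prediction minimizes the expected cost sum_k P(k|x) C(y|k) over
    candidate labels y; with the default 0/1 cost matrix this is the
    posterior argmax.  Ties break toward the lower class index.
    """

    def __init__(self, kind: str = "linear", cost: np.ndarray | None = None,
                 regularization: float = 1e-6):
        if kind not in ("linear", "quadratic"):
            raise ValueError("kind must be 'linear' or 'quadratic'")
        self.kind = kind
        self.cost = (np.asarray(cost, dtype=float) if cost is not None
                     else 1.0 - np.eye(2))
        self.regularization = regularization

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiscriminantModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self._scale = _Standardizer(X)
        Z = self._scale(X)
        d = Z.shape[1]
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        self.means_, covs, self.priors_ = [], [], []
        for c in self.classes_:
            Zc = Z[y == c]
            self.means_.append(Zc.mean(axis=0))
            covs.append(np.cov(Zc, rowvar=False, ddof=1).reshape(d, d)
                        if len(Zc) > 1 else np.eye(d))
            self.priors_.append(len(Zc) / len(Z))
        if self.kind == "linear":
            n0 = np.sum(y == self.classes_[0])
            n1 = np.sum(y == self.classes_[1])
            pooled = ((n0 - 1) * covs[0] + (n1 - 1) * covs[1]) / max(n0 + n1 - 2, 1)
            covs = [pooled, pooled]
        self.covs_ = [self._regularize(c) for c in covs]
        self._chol = [np.linalg.cholesky(c) for c in self.covs_]
        return self

    def _regularize(self, cov: np.ndarray) -> np.ndarray:
        d = cov.shape[0]
        tr = np.trace(cov)
        if tr <= 0:
            return np.eye(d)
        ridge = self.regularization * tr / d
        out = cov + ridge * np.eye(d)
        # escalate until well-conditioned; degenerate synthetic features can
        # make the empirical covariance singular
        while np.linalg.cond(out) > 1e10:
            ridge *= 10
            out = cov + ridge * np.eye(d)
        return out

    def _log_likelihood(self, Z: np.ndarray) -> np.ndarray:
        ll = np.empty((len(Z), 2))
        for j in range(2):
            L = self._chol[j]
            diff = Z - self.means_[j]
            sol = np.linalg.solve(L, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            d = Z.shape[1]
            ll[:, j] = -0.5 * (maha + logdet + d * np.log(2 * np.pi))
        return ll

    def posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        Z = self._scale(X)
        logp = self._log_likelihood(Z) + np.log(self.priors_)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and positive-class posteriors."""
        post = self.posterior(X)
        # expected cost of predicting y: sum_k P(k|x) C(y|k)
        exp_cost = post @ self.cost.T
        labels = self.classes_[np.argmin(exp_cost, axis=1)]  # argmin ties -> lower index
        pos = post[:, int(np.argmax(self.classes_ == 1))] \
            if 1 in self.classes_ else post[:, 1]
        return labels, pos

    def to_dict(self) -> dict:
        return {
            "family": "discriminant", "kind": self.kind,
            "cost": self.cost.tolist(),
            "classes": self.classes_.tolist(),
            "means": [m.tolist() for m in self.means_],
            "covs": [c.tolist() for c in self.covs_],
            "priors": list(self.priors_),
            "scale_mean": self._scale.mean.tolist(),
            "scale_sd": self._scale.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        m = cls(kind=d["kind"], cost=np.asarray(d["cost"]))
        m.classes_ = np.asarray(d["classes"], dtype=int)
        m.means_ = [np.asarray(v) for v in d["means"]]
        m.covs_ = [np.asarray(v) for v in d["covs"]]
        m.priors_ = list(d["priors"])
        m._chol = [np.linalg.cholesky(c) for c in m.covs_]
        m._scale = _Standardizer.__new__(_Standardizer)
        m._scale.mean = np.asarray(d["scale_mean"])
        m._scale.sd = np.asarray(d["scale_sd"])
        return m


class SVMModel:
    """Soft-margin SVM with linear / Gaussian / cubic-polynomial kernels.

    The dual problem is solved to a 1e-3 feasibility-gap tolerance.  For
    the linear kernel the primal normal ``beta`` and bias ``b`` are exposed
    in the original (unstandardized) feature coordinates.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear",
                 gamma: float = 1.0, tol: float = 1e-3):
        if C <= 0:
            raise ValueError("box constraint C must be positive")
        if kernel not in ("linear", "gaussian", "cubic"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.tol = tol

    def _make_svc(self) -> SVC:
        if self.kernel == "linear":
            return SVC(C=self.C, kernel="linear", tol=self.tol)
        if self.kernel == "gaussian":
            return SVC(C=self.C, kernel="rbf", gamma=self.gamma, tol=self.tol)
        return SVC(C=self.C, kernel="poly", degree=3, gamma=1.0, coef0=1.0,
                   tol=self.tol)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) != 2:
            raise ValueError("exactly two classes required")
        self._scale = _Standardizer(X)
        Z = self._scale(X)
        self._svc = self._make_svc().fit(Z, y)
        if self._svc.fit_status_ != 0:
            raise RuntimeError("SVM solver failed to converge "
                               f"(status {self._svc.fit_status_}, "
                               f"n={len(X)}, C={self.C}, kernel={self.kernel})")
        self.support_vectors_ = self._svc.support_vectors_
        self.dual_coef_ = self._svc.dual_coef_
        self.bias_ = float(self._svc.intercept_[0])
        if self.kernel == "linear":
            beta_std = self._svc.coef_[0]
            self.beta_ = beta_std / self._scale.sd
            self.b_ = self.bias_ - float(np.sum(beta_std *
                                                self._scale.mean / self._scale.sd))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = self._scale(np.atleast_2d(np.asarray(X, dtype=float)))
        if Z.shape[1] != self.support_vectors_.shape[1]:
            raise ValueError("query dimensionality mismatch")
        return self._svc.decision_function(Z)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels (sign of the decision value) and decision values."""
        f = self.decision_function(X)
        return (f > 0).astype(int), f

    def to_dict(self) -> dict:
        return {
            "family": "svm", "C": self.C, "kernel": self.kernel,
            "gamma": self.gamma, "tol": self.tol,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "bias": self.bias_,
            "scale_mean": self._scale.mean.tolist(),
            "scale_sd": self._scale.sd.tolist(),
        }


def make_model(family: str, **params):
    """Instantiate a model by family name ('knn', 'discriminant', 'svm')."""
    if family == "knn":
        return KNNModel(**params)
    if family == "discriminant":
        return DiscriminantModel(**params)
    if family == "svm":
        return SVMModel(**params)
    raise ValueError(f"unknown classifier family {family!r}")


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["family"] == "knn":
        return KNNModel.from_dict(d)
    if d["family"] == "discriminant":
        return DiscriminantModel.from_dict(d)
    raise ValueError(f"cannot deserialize family {d['family']!r}")
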