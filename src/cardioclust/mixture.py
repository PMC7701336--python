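"""Gaussian mixture modelling by expectation-maximization.

The model assumes the d-dimensional feature vectors are drawn from a mixture
of k Gaussian components.  Three covariance structures are supported:

* ``tied`` — all components share one d x d covariance matrix;
* ``diag`` — each component has its own diagonal covariance;
* ``full`` — each component has its own d x d covariance matrix.

Fitting follows the statsmodels convention: a :class:`GaussianMixture` model
object is constructed from the data, and :meth:`GaussianMixture.fit` returns a
:class:`GaussianMixtureResults` object carrying the estimates, fit diagnostics
(log-likelihood trace, convergence flag, BIC) and prediction methods.

Because the cardiac features span several orders of magnitude (volumes in the
tens of mL/m², ejection fractions below 1), features are z-score standardized
before fitting by default; the standardizer is stored on the results and all
reported log-likelihoods/BICs refer to the data on its original scale, so
models fitted with and without standardization are comparable.

EM runs are restarted ``n_init`` times from k-means initializations
(k-means++ seeding followed by Lloyd iterations)
and the run with the best final log-likelihood is kept.  Components that
empty out during EM are re-seeded from the worst-fit case.  Covariances are
regularized by adding ``reg_covar`` to their diagonals after every M-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = ["GaussianMixture", "GaussianMixtureResults", "fit_gmm", "bic", "predict_clusters"]

COV_TYPES = ("tied", "diag", "full")


def n_mixture_params(k: int, d: int, cov_type: str) -> int:
    """Number of free parameters: (k-1) weights + k*d means + covariance terms."""
    base = (k - 1) + k * d
    if cov_type == "tied":
        return base + d * (d + 1) // 2
    if cov_type == "diag":
        return base + k * d
    if cov_type == "full":
        return base + k * d * (d + 1) // 2
    raise ValueError(f"unknown cov_type {cov_type!r}")


def _log_gaussian_prob(X: np.ndarray, means: np.ndarray, covs, cov_type: str) -> np.ndarray:
    """(n, k) matrix of per-component Gaussian log-densities."""
    n, d = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    if cov_type == "diag":
        for j in range(k):
            var = covs[j]
            diff = X - means[j]
            out[:, j] = -0.5 * (
                d * np.log(2 * np.pi) + np.sum(np.log(var)) + np.sum(diff * diff / var, axis=1)
            )
        return out
    if cov_type == "tied":
        chol = np.linalg.cholesky(covs)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        for j in range(k):
            diff = (X - means[j]).T
            sol = solve_triangular(chol, diff, lower=True)
            out[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(sol * sol, axis=0))
        return out
    if cov_type == "full":
        for j in range(k):
            chol = np.linalg.cholesky(covs[j])
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            diff = (X - means[j]).T
            sol = solve_triangular(chol, diff, lower=True)
            out[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(sol * sol, axis=0))
        return out
    raise ValueError(f"unknown cov_type {cov_type!r}")


def _kmeanspp_labels(X: np.ndarray, k: int, rng: np.random.Generator,
                     lloyd_iter: int = 30) -> np.ndarray:
    """k-means initialization: k-means++ seeding followed by Lloyd iterations.

    Running Lloyd to (approximate) convergence hands EM compact,
    centroid-based starting clusters, the standard practice for mixture
    fitting."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    labels = None
    for _ in range(max(1, lloyd_iter)):
        dists = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(dists, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[j] = X[np.argmax(dists.min(axis=1))]
    return labels


@dataclass
class GaussianMixtureResults:
    """Fitted Gaussian mixture: estimates, diagnostics and predictors.

    ``means_`` and ``covariances_`` are reported on the original feature
    scale; ``weights_`` on the probability simplex.  ``loglik_`` is the total
    log-likelihood of the training data (original scale).
    """

    model: "GaussianMixture"
    weights_: np.ndarray
    means_std_: np.ndarray        # component means in standardized space
    covariances_std_: np.ndarray  # covariances in standardized space
    converged: bool
    loglik_trace: np.ndarray      # per-iteration mean log-likelihood (original scale)
    n_iter: int
    n_reinits: int                # empty-component re-seedings during the kept run
    seed: Optional[int] = None

    # ---- scale handling -------------------------------------------------
    @property
    def standardizer(self) -> Tuple[np.ndarray, np.ndarray]:
        """(mean, sd) applied to each feature before fitting."""
        return self.model.shift_, self.model.scale_

    @property
    def means_(self) -> np.ndarray:
        return self.means_std_ * self.model.scale_ + self.model.shift_

    @property
    def covariances_(self) -> np.ndarray:
        s = self.model.scale_
        ct = self.model.cov_type
        if ct == "diag":
            return self.covariances_std_ * s**2
        if ct == "tied":
            return self.covariances_std_ * np.outer(s, s)
        return self.covariances_std_ * np.outer(s, s)[None, :, :]

    @property
    def cov_type(self) -> str:
        return self.model.cov_type

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def n_params(self) -> int:
        return n_mixture_params(self.model.n_components, self.model.n_features, self.model.cov_type)

    @property
    def loglik_(self) -> float:
        """Total log-likelihood of the training data on its original scale."""
        return float(self.loglik_trace[-1] * self.model.n_obs)

    # ---- inference ------------------------------------------------------
    def _as_matrix(self, X) -> np.ndarray:
        if X is None:
            return self.model.X_std
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(float) if self.model.feature_names else X.to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.n_features:
            raise ValueError(
                f"expected (n, {self.model.n_features}) data, got shape {X.shape}"
            )
        return (X - self.model.shift_) / self.model.scale_

    def score_samples(self, X=None) -> np.ndarray:
        """Per-case log-density on the original data scale."""
        Z = self._as_matrix(X)
        lp = _log_gaussian_prob(Z, self.means_std_, self.covariances_std_, self.model.cov_type)
        return logsumexp(lp + np.log(self.weights_), axis=1) - self.model.log_jacobian_

    def predict_proba(self, X=None) -> np.ndarray:
        """(n, k) responsibility matrix; rows sum to 1."""
        Z = self._as_matrix(X)
        lp = _log_gaussian_prob(Z, self.means_std_, self.covariances_std_, self.model.cov_type)
        lp = lp + np.log(self.weights_)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def predict(self, X=None) -> np.ndarray:
        """Hard assignments: argmax responsibility, ties to the lowest index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def bic(self, X=None) -> float:
        """BIC = -2 logL + n_params ln(n); lower is better."""
        if X is None:
            ll = self.loglik_
            n = self.model.n_obs
        else:
            s = self.score_samples(X)
            ll = float(np.sum(s))
            n = len(s)
        return -2.0 * ll + self.n_params * np.log(n)

    def cluster_sizes(self, X=None) -> np.ndarray:
        """Hard-assignment cluster sizes (length k, may contain zeros)."""
        labels = self.predict(X)
        return np.bincount(labels, minlength=self.model.n_components)

    # ---- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Gaussian mixture model results",
            "=" * 64,
            f"components: {m.n_components}    cov_type: {m.cov_type}    n_obs: {m.n_obs}",
            f"converged: {self.converged}    iterations: {self.n_iter}    "
            f"empty-component reseeds: {self.n_reinits}",
            f"log-likelihood: {self.loglik_:.3f}    n_params: {self.n_params}    "
            f"BIC: {self.bic():.3f}",
            "-" * 64,
        ]
        names = m.feature_names or [f"x{j}" for j in range(m.n_features)]
        header = f"{'comp':>4} {'weight':>8}  " + " ".join(f"{nm:>10}" for nm in names)
        lines.append(header)
        means = self.means_
        for j in range(m.n_components):
            lines.append(
                f"{j:>4} {self.weights_[j]:>8.4f}  "
                + " ".join(f"{means[j, i]:>10.3f}" for i in range(m.n_features))
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_components": self.model.n_components,
            "cov_type": self.model.cov_type,
            "feature_names": self.model.feature_names,
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
            "standardizer": {
                "mean": self.model.shift_.tolist(),
                "scale": self.model.scale_.tolist(),
            },
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_reinits": int(self.n_reinits),
            "loglik": self.loglik_,
            "bic": self.bic(),
            "seed": self.seed,
        }


class GaussianMixture:
    """Gaussian mixture model of a case x feature matrix.

    Parameters
    ----------
    X : (n, d) array or DataFrame of finite values.
    n_components : number of Gaussian components k >= 1.
    cov_type : "tied", "diag" or "full".
    standardize : z-score features before fitting (default True).
    reg_covar : ridge added to covariance diagonals after every M-step.
    tol : convergence threshold on the change of mean per-case log-likelihood.
    max_iter : EM iteration cap per restart.
    """

    def __init__(
        self,
        X: Union[np.ndarray, pd.DataFrame],
        n_components: int,
        cov_type: str = "full",
        *,
        standardize: bool = True,
        reg_covar: float = 1e-6,
        tol: float = 1e-3,
        max_iter: int = 200,
    ):
        if isinstance(X, pd.DataFrame):
            self.feature_names: Optional[List[str]] = [c for c in X.columns]
            X = X.to_numpy(float)
        else:
            self.feature_names = None
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {n_components}")
        if X.shape[0] <= n_components:
            raise ValueError(f"need n > k, got n={X.shape[0]}, k={n_components}")
        if cov_type not in COV_TYPES:
            raise ValueError(f"cov_type must be one of {COV_TYPES}, got {cov_type!r}")
        if reg_covar < 0 or tol <= 0 or max_iter < 1:
            raise ValueError("invalid reg_covar/tol/max_iter")

        self.X = X
        self.n_obs, self.n_features = X.shape
        self.n_components = int(n_components)
        self.cov_type = cov_type
        self.standardize = bool(standardize)
        self.reg_covar = float(reg_covar)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

        if standardize:
            self.shift_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            if np.any(self.scale_ == 0):
                bad = np.nonzero(self.scale_ == 0)[0]
                raise ValueError(f"constant feature(s) at column(s) {bad.tolist()}")
        else:
            self.shift_ = np.zeros(self.n_features)
            self.scale_ = np.ones(self.n_features)
        self.X_std = (X - self.shift_) / self.scale_
        #: log |d z / d x|: converts standardized-scale log-densities to original scale
        self.log_jacobian_ = float(np.sum(np.log(self.scale_)))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, features: Optional[Sequence[str]] = None, **kwargs
    ) -> "GaussianMixture":
        if features is None:
            features = [c for c in df.columns if c != "case_id"]
        return cls(df[list(features)], **kwargs)

    # ---- EM internals ----------------------------------------------------
    def _m_step(self, resp: np.ndarray):
        Z = self.X_std
        n, d = Z.shape
        k = self.n_components
        nk = resp.sum(axis=0) + 10 * np.finfo(float).tiny
        weights = nk / n
        means = (resp.T @ Z) / nk[:, None]
        if self.cov_type == "diag":
            covs = np.empty((k, d))
            for j in range(k):
                diff = Z - means[j]
                covs[j] = (resp[:, j] @ (diff * diff)) / nk[j] + self.reg_covar
        elif self.cov_type == "full":
            covs = np.empty((k, d, d))
            for j in range(k):
                diff = Z - means[j]
                covs[j] = (resp[:, j, None] * diff).T @ diff / nk[j]
                covs[j].flat[:: d + 1] += self.reg_covar
        else:  # tied
            covs = np.zeros((d, d))
            for j in range(k):
                diff = Z - means[j]
                covs += (resp[:, j, None] * diff).T @ diff
            covs /= n
            covs.flat[:: d + 1] += self.reg_covar
        return weights, means, covs

    def _fit_single(self, rng: np.random.Generator):
        Z = self.X_std
        n = Z.shape[0]
        k = self.n_components
        labels = _kmeanspp_labels(Z, k, rng)
        resp = np.zeros((n, k))
        resp[np.arange(n), labels] = 1.0
        weights, means, covs = self._m_step(resp)

        trace = []
        n_reinits = 0
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            lp = _log_gaussian_prob(Z, means, covs, self.cov_type) + np.log(weights)
            norm = logsumexp(lp, axis=1)
            resp = np.exp(lp - norm[:, None])
            ll = float(norm.mean())  # standardized scale; shifted on report
            trace.append(ll)

            # empty components: re-seed from the worst-fit case
            nk = resp.sum(axis=0)
            empties = np.nonzero(nk < 1e-10)[0]
            if len(empties) > 0:
                worst = np.argsort(norm)
                for pos, j in enumerate(empties):
                    case = worst[pos % n]
                    resp[case] = 0.0
                    resp[case, j] = 1.0
                n_reinits += len(empties)

            weights, means, covs = self._m_step(resp)
            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll

        # final log-likelihood under the last parameter update
        lp = _log_gaussian_prob(Z, means, covs, self.cov_type) + np.log(weights)
        final_ll = float(logsumexp(lp, axis=1).mean())
        trace.append(final_ll)
        return weights, means, covs, converged, np.asarray(trace), it, n_reinits

    def fit(self, seed: Optional[int] = None, n_init: int = 10) -> GaussianMixtureResults:
        """Run ``n_init`` EM restarts; keep the best by final log-likelihood."""
        if n_init < 1:
            raise ValueError("n_init must be >= 1")
        root = np.random.SeedSequence(seed)
        best = None
        for child in root.spawn(n_init):
            rng = np.random.default_rng(child)
            out = self._fit_single(rng)
            if best is None or out[4][-1] > best[4][-1]:
                best = out
        weights, means, covs, converged, trace, n_iter, n_reinits = best
        return GaussianMixtureResults(
            model=self,
            weights_=weights,
            means_std_=means,
            covariances_std_=covs,
            converged=converged,
            loglik_trace=trace - self.log_jacobian_,  # report on original scale
            n_iter=n_iter,
            n_reinits=n_reinits,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_gmm(
    X,
    k: int,
    cov_type: str = "full",
    seed: Optional[int] = None,
    n_init: int = 10,
    tol: float = 1e-3,
    max_iter: int = 200,
    reg_covar: float = 1e-6,
    standardize: bool = True,
) -> GaussianMixtureResults:
    """Fit a k-component Gaussian mixture; returns the results object."""
    model = GaussianMixture(
        X,
        n_components=k,
        cov_type=cov_type,
        standardize=standardize,
        reg_covar=reg_covar,
        tol=tol,
        max_iter=max_iter,
    )
    return model.fit(seed=seed, n_init=n_init)


def bic(results: GaussianMixtureResults, X=None) -> float:
    """BIC = -2 logL(X) + n_params ln(n) of a fitted mixture."""
    return results.bic(X)


def predict_clusters(results: GaussianMixtureResults, X=None) -> Tuple[np.ndarray, np.ndarray]:
    """(hard assignments, responsibility matrix) for X (default: training data)."""
    resp = results.predict_proba(X)
    return np.argmax(resp, axis=1), resp
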