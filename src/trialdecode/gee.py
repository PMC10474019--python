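"""Logistic classification with generalized estimating equations.

A single logistic model is fitted over all subjects' trials at once, with
subjects as clusters.  Under the independence working correlation the point
estimates equal the pooled logistic MLE, so that path is solved directly by
Newton-IRLS with a cluster-robust (sandwich) covariance — this is the hot
path of the sliding decoder.  The exchangeable working correlation delegates
to statsmodels' GEE.  Unlike the regularised classifiers common in MVPA, the
fit is unpenalised (an optional tiny ridge on the score equations is
available for degenerate designs), so the coefficients support the usual
multiple-regression inference (Wald tests on nested models, robust CIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class ConvergenceWarning(UserWarning):
    """Emitted when a GEE fit stops before meeting the tolerance."""


@dataclass
class GEEFit:
    """A fitted GEE-logistic model.

    ``beta`` holds (intercept, channel coefficients) in log-odds per uV;
    ``robust_cov`` is the cluster-sandwich covariance on the same index.
    """

    beta: np.ndarray
    robust_cov: np.ndarray
    cluster_ids: np.ndarray
    working_corr: str
    converged: bool
    n_iter: int

    @property
    def n_features(self) -> int:
        return len(self.beta) - 1


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be observations x features")
    return np.column_stack([np.ones(len(X)), X])


def _cluster_sandwich(X1: np.ndarray, y: np.ndarray, mu: np.ndarray,
                      bread_inv: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    resid = y - mu
    meat = np.zeros((X1.shape[1], X1.shape[1]))
    for c in np.unique(clusters):
        idx = clusters == c
        g = X1[idx].T @ resid[idx]
        meat += np.outer(g, g)
    cov = bread_inv @ meat @ bread_inv
    return 0.5 * (cov + cov.T)


def fit_gee_logistic(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    working_corr: str = "independence",
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> GEEFit:
    """Fit logit(P(y=1)) = b0 + X b with subject clusters.

    Perfect separation or hitting ``max_iter`` returns ``converged=False``
    with a warning, never silently.  Requires both classes and >= 2 clusters.
    """
    y = np.asarray(y, dtype=float).ravel()
    clusters = np.asarray(clusters)
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        raise ValueError("y must be binary 0/1")
    if working_corr == "independence":
        return _fit_irls_independence(X, y, clusters, max_iter, tol, ridge)
    if working_corr == "exchangeable":
        if ridge != 0:
            raise ValueError("ridge is only supported with the independence structure")
        return _fit_statsmodels_exchangeable(X, y, clusters, max_iter, tol)
    raise ValueError(f"working_corr must be 'independence' or 'exchangeable', got {working_corr!r}")


def _fit_irls_independence(X, y, clusters, max_iter, tol, ridge) -> GEEFit:
    X1 = _as_design(X)
    n, p = X1.shape
    beta = np.zeros(p)
    penalty = ridge * np.eye(p)
    penalty[0, 0] = 0.0  # intercept unpenalised
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X1 @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        hess = (X1 * w[:, None]).T @ X1 + penalty
        score = X1.T @ (y - mu) - penalty @ beta
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
        if np.abs(beta).max() > 1e6:
            break  # diverging: separation
    if not converged:
        warnings.warn(
            "GEE-logistic fit did not converge (possible perfect separation); "
            "coefficients returned as-is with converged=False",
            ConvergenceWarning,
        )
    eta = np.clip(X1 @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    hess = (X1 * w[:, None]).T @ X1 + penalty
    try:
        bread_inv = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        bread_inv = np.linalg.pinv(hess)
    cov = _cluster_sandwich(X1, y, mu, bread_inv, clusters)
    return GEEFit(beta=beta, robust_cov=cov, cluster_ids=clusters,
                  working_corr="independence", converged=converged, n_iter=it)


def _fit_statsmodels_exchangeable(X, y, clusters, max_iter, tol) -> GEEFit:
    import statsmodels.api as sm

    X1 = _as_design(X)
    model = sm.GEE(y, X1, groups=clusters, family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Exchangeable())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            res = model.fit(maxiter=max_iter, ctol=tol)
        except Exception:
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=max_iter, ctol=tol)
            converged = False
    if not converged:
        warnings.warn("exchangeable GEE fit did not converge", ConvergenceWarning)
    return GEEFit(beta=np.asarray(res.params), robust_cov=np.asarray(res.cov_params()),
                  cluster_ids=clusters, working_corr="exchangeable",
                  converged=converged, n_iter=max_iter)


def predict_scores(fit: GEEFit, X: np.ndarray) -> np.ndarray:
    """Linear predictor (log-odds) for new observations; monotone in P(y=1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fit.n_features:
        raise ValueError(
            f"X must have {fit.n_features} features, got shape {X.shape}"
        )
    return fit.beta[0] + X @ fit.beta[1:]
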