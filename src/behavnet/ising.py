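"""Ising network estimation from binary data (eLasso) and topology metrics.

Each node is regressed on all others with L1-penalized logistic regression
over a descending lambda path; the per-node model is chosen by the extended
BIC, and the directed coefficient matrix is symmetrized by the AND (default)
or OR rule with coefficient averaging.

The L1 solver is a glmnet-style IRLS + coordinate-descent on the Gram
matrix, which is exact-zero-producing and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import BEHAVIOR_NAMES
from .exceptions import InputValidationError

__all__ = [
    "IsingFitResult",
    "elasso_fit",
    "network_density",
    "node_strength",
    "clustering_coefficient",
]


@dataclass
class IsingFitResult:
    """Estimated thresholds, symmetrized weights, and selection diagnostics."""

    tau_hat: np.ndarray
    W_hat: np.ndarray
    selected_lambda: np.ndarray  # per node
    selected_ebic: np.ndarray  # per node
    gamma: float
    rule: str
    node_names: tuple = ()
    #: per-node path detail: {"lambdas", "coefs", "intercepts", "loglik", "ebic"}
    paths: list = field(default_factory=list, repr=False)


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _l1_logistic_path(X, y, lambdas, tol=1e-8, max_irls=50, max_cd=200):
    """L1-penalized logistic path with unpenalized intercept.

    Minimizes -(1/n) loglik + lam * ||beta||_1 at each lambda (descending,
    warm-started). Returns (intercepts, coefs, loglik) over the path.
    """
    n, p = X.shape
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar / (1 - ybar))
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    loglik = np.empty(len(lambdas))
    for li, lam in enumerate(lambdas):
        for _ in range(max_irls):
            eta = b0 + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-5, None)
            z = eta + (y - mu) / w
            # quadratic subproblem statistics (per-sample scale)
            Xw = X * w[:, None]
            G = (Xw.T @ X) / n
            q = (Xw.T @ z) / n
            m = Xw.sum(axis=0) / n
            sw = w.sum() / n
            zbar = (w * z).sum() / n
            b_old = beta.copy()
            b0_old = b0
            for _ in range(max_cd):
                delta = 0.0
                b0_new = (zbar - m @ beta) / sw
                delta = max(delta, abs(b0_new - b0))
                b0 = b0_new
                for j in range(p):
                    cj = q[j] - b0 * m[j] - G[j] @ beta + G[j, j] * beta[j]
                    bj = _soft(cj, lam) / G[j, j]
                    delta = max(delta, abs(bj - beta[j]))
                    beta[j] = bj
                if delta < tol:
                    break
            if max(abs(b0 - b0_old), np.max(np.abs(beta - b_old))) < 1e-7:
                break
        intercepts[li] = b0
        coefs[li] = beta
        eta = b0 + X @ beta
        loglik[li] = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return intercepts, coefs, loglik


def elasso_fit(
    matrix,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    keep_paths: bool = False,
) -> IsingFitResult:
    """Nodewise L1 logistic regression with EBIC selection.

    EBIC(lambda) = -2*loglik + k*ln(N) + 2*gamma*k*ln(p-1), where k counts
    the nonzero predictors; per node the lambda minimizing EBIC is kept
    (ties resolve toward the sparser, larger-lambda model). Deterministic
    given the data: no randomness anywhere in the path or selection.
    """
    values = np.asarray(matrix, dtype=float)
    names = (
        tuple(matrix.columns)
        if hasattr(matrix, "columns")
        else tuple(BEHAVIOR_NAMES[: values.shape[1]])
    )
    if values.ndim != 2:
        raise InputValidationError("behavior matrix must be 2-D")
    if not np.isin(values, (0.0, 1.0)).all():
        raise InputValidationError("behavior matrix must be binary (0/1)")
    n, p = values.shape
    if n <= p:
        raise InputValidationError(f"need more records than nodes (N={n}, p={p})")
    col_means = values.mean(axis=0)
    constant = np.flatnonzero((col_means == 0) | (col_means == 1))
    if constant.size:
        raise InputValidationError(
            f"behavior {names[constant[0]]!r} is constant; its regression is undefined"
        )
    if rule not in ("AND", "OR"):
        raise InputValidationError("rule must be 'AND' or 'OR'")

    B = np.zeros((p, p))  # B[j, k]: coefficient of node k in node j's regression
    tau_hat = np.zeros(p)
    sel_lambda = np.zeros(p)
    sel_ebic = np.zeros(p)
    paths = []
    log_choose = np.log(p - 1)
    for j in range(p):
        y = values[:, j]
        X = np.delete(values, j, axis=1)
        # tiny headroom keeps the first model empty regardless of float
        # rounding in the KKT boundary condition
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n * (1 + 1e-8)
        lam_max = max(lam_max, 1e-10)
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)
        b0s, coefs, ll = _l1_logistic_path(X, y, lambdas)
        k = (coefs != 0).sum(axis=1)
        ebic = -2.0 * ll + k * np.log(n) + 2.0 * gamma * k * log_choose
        best = int(np.argmin(ebic))
        others = [c for c in range(p) if c != j]
        B[j, others] = coefs[best]
        tau_hat[j] = b0s[best]
        sel_lambda[j] = lambdas[best]
        sel_ebic[j] = ebic[best]
        if keep_paths:
            paths.append(
                {"lambdas": lambdas, "coefs": coefs, "intercepts": b0s, "loglik": ll, "ebic": ebic}
            )

    avg = (B + B.T) / 2.0
    if rule == "AND":
        mask = (B != 0) & (B.T != 0)
    else:
        mask = (B != 0) | (B.T != 0)
    W_hat = np.where(mask, avg, 0.0)
    np.fill_diagonal(W_hat, 0.0)
    return IsingFitResult(
        tau_hat=tau_hat,
        W_hat=W_hat,
        selected_lambda=sel_lambda,
        selected_ebic=sel_ebic,
        gamma=gamma,
        rule=rule,
        node_names=names,
        paths=paths,
    )


def _check_weight_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InputValidationError("W must be square")
    if not np.allclose(W, W.T):
        raise InputValidationError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise InputValidationError("W must have a zero diagonal")
    return W


def network_density(W) -> float:
    """Fraction of the p(p-1)/2 possible edges with nonzero weight."""
    W = _check_weight_matrix(W)
    p = W.shape[0]
    iu = np.triu_indices(p, k=1)
    return float((W[iu] != 0).sum() / (p * (p - 1) / 2))


def node_strength(W) -> tuple[np.ndarray, float]:
    """Per-node sum of absolute incident weights, and its mean over nodes."""
    W = _check_weight_matrix(W)
    strengths = np.abs(W).sum(axis=1)
    return strengths, float(strengths.mean())


def clustering_coefficient(W, variant: str = "binary") -> float:
    """Average local clustering coefficient.

    ``binary`` (default): binarize at nonzero and average the unweighted
    local coefficient over all nodes (degree < 2 contributes 0).
    ``barrat``: Barrat et al. weighted local coefficient on |W|, averaged
    the same way (sensitivity-analysis variant).
    """
    W = _check_weight_matrix(W)
    p = W.shape[0]
    A = (W != 0).astype(float)
    deg = A.sum(axis=1)
    if variant == "binary":
        tri = np.diag(A @ A @ A) / 2.0  # triangles through each node
        local = np.zeros(p)
        ok = deg >= 2
        local[ok] = 2.0 * tri[ok] / (deg[ok] * (deg[ok] - 1))
        return float(local.mean())
    if variant == "barrat":
        absW = np.abs(W)
        s = absW.sum(axis=1)
        local = np.zeros(p)
        for i in range(p):
            if deg[i] < 2 or s[i] == 0:
                continue
            acc = 0.0
            nbrs = np.flatnonzero(A[i])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    jn, kn = nbrs[a], nbrs[b]
                    if A[jn, kn]:
                        # (w_ij + w_ik)/2 summed over ordered neighbor pairs
                        acc += absW[i, jn] + absW[i, kn]
            local[i] = acc / (s[i] * (deg[i] - 1))
        return float(local.mean())
    raise InputValidationError(f"unknown clustering variant {variant!r}")
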