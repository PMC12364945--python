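"""Regularized partial-correlation network estimation.

The estimator is the graphical lasso: the L1-penalized Gaussian
maximum-likelihood precision matrix

    maximize  log det(Theta) - tr(S Theta) - lam * sum_{i!=j} |theta_ij|

solved by block coordinate descent (one lasso per row/column of the
working covariance, Friedman-style), with the penalty lam selected by
minimizing the extended Bayesian information criterion

    EBIC = -2 l(Theta) + E log n + 4 E gamma log p,
    l(Theta) = (n/2) (log det Theta - tr(S Theta) + p),

(the log-likelihood is measured relative to the saturated model, where
tr(S Theta) = p; the additive constant does not affect selection)

where E counts nonzero upper-triangle edges.  gamma = 0 reduces EBIC to
BIC; gamma = 0.5 is the conventional default.  Edge weights are partial
correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import EDGE_THRESHOLD, NetworkModel, SymptomTable, ValidationError
from .association import CorrelationMatrix, nearest_psd, spearman_matrix


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, gap: float):
        super().__init__(message)
        self.gap = gap


@njit(cache=True)
def _glasso_kernel(S, lam, tol, max_iter, inner_max, W, B):  # pragma: no cover
    p = S.shape[0]
    offsum = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                offsum += abs(S[i, j])
                cnt += 1
    sbar = offsum / cnt if cnt > 0 else 0.0
    thr = tol * max(sbar, 1e-12)
    converged = False
    dmax_outer = 0.0
    for _ in range(max_iter):
        dmax_outer = 0.0
        for j in range(p):
            # lasso for column j of the working covariance:
            # beta = argmin 0.5 b' W11 b - b' s12 + lam |b|_1
            for _inner in range(inner_max):
                dmax = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    old = B[k, j]
                    if r > lam:
                        b = (r - lam) / W[k, k]
                    elif r < -lam:
                        b = (r + lam) / W[k, k]
                    else:
                        b = 0.0
                    B[k, j] = b
                    d = abs(b - old)
                    if d > dmax:
                        dmax = d
                if dmax < 0.1 * thr:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > dmax_outer:
                    dmax_outer = d
                W[k, j] = w
                W[j, k] = w
        if dmax_outer < thr:
            converged = True
            break
    return converged, dmax_outer


@njit(cache=True)
def _theta_from_wb(W, B):  # pragma: no cover
    p = W.shape[0]
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for l in range(p):
            if l != j:
                dot += W[l, j] * B[l, j]
        tjj = 1.0 / (W[j, j] - dot)
        Theta[j, j] = tjj
        for k in range(p):
            if k != j:
                Theta[k, j] = -B[k, j] * tjj
    for i in range(p):
        for k in range(i + 1, p):
            if B[i, k] == 0.0 and B[k, i] == 0.0:
                Theta[i, k] = 0.0
                Theta[k, i] = 0.0
            else:
                v = 0.5 * (Theta[i, k] + Theta[k, i])
                Theta[i, k] = v
                Theta[k, i] = v
    return Theta


def _check_input(S: np.ndarray, lam: float) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("S must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValidationError("S must have unit diagonal")
    if np.linalg.eigvalsh(S)[0] < -1e-8:
        raise ValidationError("S must be positive semidefinite (repair it first)")
    if lam <= 0:
        raise ValidationError(f"penalty must be positive, got {lam}")
    return (S + S.T) / 2.0


def glasso_fit(
    S,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    warm: tuple | None = None,
) -> np.ndarray:
    """L1-penalized precision estimate for a PSD unit-diagonal matrix.

    Returns the symmetric positive-definite precision Theta.  ``warm``
    optionally carries ``(W, B)`` from a neighbouring penalty on a path.
    """
    if isinstance(S, CorrelationMatrix):
        S = S.values
    S = _check_input(S, lam)
    p = S.shape[0]
    # the diagonal is unpenalized, so the working covariance keeps
    # diag(W) = diag(S) throughout
    if warm is None:
        W = S.copy()
        B = np.zeros((p, p))
    else:
        W, B = warm[0].copy(), warm[1].copy()
        np.fill_diagonal(W, np.diag(S))
    converged, gap = _glasso_kernel(S, float(lam), float(tol), max_iter, 200, W, B)
    if not converged:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(last max coordinate change {gap:.3e})",
            gap=float(gap),
        )
    Theta = _theta_from_wb(W, B)
    glasso_fit._last_state = (W, B)  # warm-start handle for path fits
    return Theta


def partials_from_precision(theta: np.ndarray) -> np.ndarray:
    """Partial-correlation weights w_ij = -theta_ij / sqrt(theta_ii theta_jj)."""
    theta = np.asarray(theta, dtype=float)
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise ValidationError("precision must be symmetric")
    if np.linalg.eigvalsh(theta)[0] <= 0:
        raise ValidationError("precision must be positive definite")
    d = np.sqrt(np.diag(theta))
    W = -theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return np.clip((W + W.T) / 2.0, -1.0, 1.0)


def ebic(theta: np.ndarray, S: np.ndarray, n: int, gamma: float,
         edge_threshold: float = EDGE_THRESHOLD) -> float:
    """Extended BIC of a precision estimate under the Gaussian likelihood."""
    if isinstance(S, CorrelationMatrix):
        S = S.values
    theta = np.asarray(theta, dtype=float)
    p = theta.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return float("inf")
    ll = 0.5 * n * (logdet - np.trace(S @ theta) + p)
    partial = partials_from_precision(theta)
    E = int((np.abs(partial[np.triu_indices(p, 1)]) > edge_threshold).sum())
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


@dataclass
class GlassoPath:
    """Summary of a full penalty path: one row per lambda."""

    lambdas: np.ndarray
    edge_counts: np.ndarray
    ebic_values: np.ndarray
    logliks: np.ndarray
    selected_index: int = -1

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValidationError("lambda path must be strictly decreasing")


def lambda_path(S, n_lambdas: int = 100, lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced path from lambda_max = max off-diagonal |S| downward."""
    if isinstance(S, CorrelationMatrix):
        S = S.values
    p = S.shape[0]
    off = np.abs(S[np.triu_indices(p, 1)])
    lam_max = float(off.max()) if off.size else 1.0
    lam_max = max(lam_max, 1e-4)
    return np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambdas)
    )


def ebicglasso_select(
    S,
    n: int,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    node_names: list | None = None,
    edge_threshold: float = EDGE_THRESHOLD,
    return_path: bool = False,
):
    """Fit the glasso path and return the EBIC-minimizing network.

    Deterministic given (S, n, gamma); ties on EBIC resolve to the
    larger penalty (sparser model).  Fits are warm-started from the
    previous penalty down the path.
    """
    if isinstance(S, CorrelationMatrix):
        if node_names is None:
            node_names = S.node_names
        S = S.values
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if node_names is None:
        node_names = list(range(p))
    lams = lambda_path(S, n_lambdas, lambda_min_ratio)
    best = None
    ebics = np.empty(len(lams))
    counts = np.empty(len(lams), dtype=int)
    lls = np.empty(len(lams))
    warm = None
    for k, lam in enumerate(lams):
        theta = glasso_fit(S, lam, tol=tol, warm=warm)
        warm = glasso_fit._last_state
        sign, logdet = np.linalg.slogdet(theta)
        ll = 0.5 * n * (logdet - np.trace(S @ theta) + p)
        partial = partials_from_precision(theta)
        E = int((np.abs(partial[np.triu_indices(p, 1)]) > edge_threshold).sum())
        val = float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))
        ebics[k] = val
        counts[k] = E
        lls[k] = ll
        if best is None or val < best[0]:
            best = (val, k, lam, partial)
    _, k_best, lam_best, partial_best = best
    Wsel = partial_best.copy()
    Wsel[np.abs(Wsel) <= edge_threshold] = 0.0
    net = NetworkModel(
        node_names=list(node_names),
        weights=Wsel,
        lambda_selected=float(lam_best),
        gamma=float(gamma),
        ebic_value=float(ebics[k_best]),
        n_obs=int(n),
    )
    if return_path:
        path = GlassoPath(
            lambdas=lams, edge_counts=counts, ebic_values=ebics,
            logliks=lls, selected_index=int(k_best),
        )
        return net, path
    return net


@dataclass
class Density:
    n_edges: int
    possible: int
    fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def density(network: NetworkModel, edge_threshold: float = EDGE_THRESHOLD) -> Density:
    """Proportion of the m(m-1)/2 possible edges that are nonzero."""
    m = network.m
    if m < 2:
        raise ValidationError("density needs at least 2 nodes")
    possible = m * (m - 1) // 2
    E = network.n_edges(edge_threshold)
    return Density(n_edges=E, possible=possible, fraction=E / possible)


@dataclass
class NetworkConfig:
    """Estimation settings recorded in every run report."""

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    edge_threshold: float = EDGE_THRESHOLD
    tol: float = 1e-6

    def as_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "n_lambdas": self.n_lambdas,
            "lambda_min_ratio": self.lambda_min_ratio,
            "edge_threshold": self.edge_threshold,
            "tol": self.tol,
        }


def network_from_table(
    table: SymptomTable,
    include_covariates: bool = False,
    covariate_names: list | None = None,
    config: NetworkConfig | None = None,
) -> NetworkModel:
    """spearman -> nearest PSD -> EBICglasso on one table."""
    config = config or NetworkConfig()
    table.require_estimable()
    if include_covariates and covariate_names:
        sub = SymptomTable(
            person_ids=table.person_ids,
            items=table.items,
            ratings=table.ratings,
            covariates=table.covariates[list(covariate_names)],
        )
        corr = spearman_matrix(sub, include_covariates=True)
    else:
        corr = spearman_matrix(table, include_covariates=False)
    corr = nearest_psd(corr)
    return ebicglasso_select(
        corr,
        n=table.n,
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        tol=config.tol,
        edge_threshold=config.edge_threshold,
    )


def estimate_networks(
    table: SymptomTable,
    covariates: list | None = None,
    config: NetworkConfig | None = None,
) -> tuple[NetworkModel, NetworkModel]:
    """Unadjusted (symptoms only) and covariate-adjusted networks.

    Covariates enter the adjusted network as additional nodes, so the
    symptom-symptom edges condition on them; with no covariates the two
    networks coincide.
    """
    config = config or NetworkConfig()
    covariates = list(covariates or [])
    for cov in covariates:
        if table.covariates is None or cov not in table.covariates.columns:
            raise ValidationError(f"covariate {cov!r} not present in table")
    unadjusted = network_from_table(table, include_covariates=False, config=config)
    if not covariates:
        return unadjusted, unadjusted
    adjusted = network_from_table(
        table, include_covariates=True, covariate_names=covariates, config=config
    )
    return unadjusted, adjusted
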