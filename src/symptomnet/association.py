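"""Rank-based pairwise association matrix feeding network estimation.

Spearman's rho is used throughout because 5-point severity ratings are
heavily skewed; ties (guaranteed with ordinal data) are handled by
average ranks.  A Spearman matrix of discretized data need not be
positive semidefinite, so a nearest-PSD repair (eigenvalue clipping and
rescale to unit diagonal) sits between association and the graphical
lasso, which requires a PSD input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SymptomTable, ValidationError


@dataclass
class CorrelationMatrix:
    node_names: list
    values: np.ndarray
    method: str = "spearman"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        m = len(self.node_names)
        if V.shape != (m, m):
            raise ValidationError(f"matrix shape {V.shape} != ({m},{m})")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        self.values = (V + V.T) / 2.0

    @property
    def m(self) -> int:
        return len(self.node_names)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names, columns=self.node_names)


def spearman_matrix(
    table: SymptomTable, include_covariates: bool = False
) -> CorrelationMatrix:
    """Pairwise Spearman correlations of symptom items (and, optionally,
    covariate columns appended as extra nodes).

    Binary and continuous covariates are ranked identically to the
    ordinal items; categorical covariates are already indicator columns,
    each entering as one node.
    """
    df = table.ratings_frame()
    if include_covariates and table.covariates is not None:
        cov = table.covariates.copy()
        cov.index = df.index
        df = pd.concat([df, cov], axis=1)
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValidationError(f"need at least 3 rows for Spearman, got {n}")
    for j, col in enumerate(df.columns):
        if np.unique(X[:, j]).size < 2:
            raise ValidationError(
                f"column {col!r} is constant; Spearman's rho is undefined"
            )
    rho = stats.spearmanr(X).statistic
    if m == 2:  # spearmanr returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(node_names=list(df.columns), values=rho)


def nearest_psd(corr: CorrelationMatrix | np.ndarray, node_names=None) -> CorrelationMatrix:
    """Clip negative eigenvalues at zero and rescale to unit diagonal.

    Input already PSD is returned unchanged (bitwise), so the repair is
    a no-op on well-behaved matrices.
    """
    if isinstance(corr, CorrelationMatrix):
        V = corr.values
        names = corr.node_names
        method = corr.method
    else:
        V = np.asarray(corr, dtype=float)
        names = node_names if node_names is not None else list(range(V.shape[0]))
        method = "unknown"
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValidationError("nearest_psd requires a symmetric matrix")
    w, Q = np.linalg.eigh(V)
    if w[0] >= 0:
        return CorrelationMatrix(node_names=list(names), values=V, method=method)
    w_clipped = np.clip(w, 0.0, None)
    V2 = (Q * w_clipped) @ Q.T
    d = np.sqrt(np.clip(np.diag(V2), 1e-12, None))
    V2 = V2 / np.outer(d, d)
    V2 = (V2 + V2.T) / 2.0
    np.fill_diagonal(V2, 1.0)
    return CorrelationMatrix(node_names=list(names), values=V2, method=method)
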