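"""Shared domain types for the symptom-network pipeline.

The raw input is a person x item table of ordinal severity ratings on a
1-5 Likert scale, optionally accompanied by person-level covariates
(binary disease stage, continuous years since diagnosis, categorical
treatment expanded to reference-coded indicators).  All downstream
stages -- association, regularized network estimation, centrality,
resampling, predictability, severity regression -- consume these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RATING_MIN = 1
RATING_MAX = 5

#: absolute weight below which an edge is considered absent (solver noise)
EDGE_THRESHOLD = 1e-8


class ValidationError(ValueError):
    """Raised when input data violate the table or network contracts."""


@dataclass
class SymptomTable:
    """Person x item ordinal ratings plus optional covariate columns.

    Parameters
    ----------
    person_ids : list
        Opaque row identifiers, one per participant.
    items : list of str
        Ordered symptom item names (length ``p``).
    ratings : ndarray of shape (n, p)
        Integer ratings in ``{1..5}``; no missing cells (complete-case
        contract -- missingness is a hard error, never imputed).
    covariates : DataFrame or None
        Optional person-level columns: binary {0,1}, continuous, or
        categorical already expanded to reference-coded indicators.
    """

    person_ids: list
    items: list
    ratings: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings)
        n, p = self.ratings.shape
        if len(self.person_ids) != n:
            raise ValidationError(
                f"{len(self.person_ids)} person ids for {n} rating rows"
            )
        if len(self.items) != p:
            raise ValidationError(f"{len(self.items)} item names for {p} columns")
        if len(set(self.items)) != p:
            raise ValidationError("item names must be unique")
        if not np.issubdtype(self.ratings.dtype, np.number):
            raise ValidationError("ratings must be numeric")
        if np.any(~np.isfinite(self.ratings.astype(float))):
            bad = np.argwhere(~np.isfinite(self.ratings.astype(float)))[0]
            raise ValidationError(
                f"missing cell at row {bad[0]} item {self.items[bad[1]]!r}; "
                "complete cases are required (no imputation)"
            )
        if np.any(self.ratings != np.round(self.ratings)):
            bad = np.argwhere(self.ratings != np.round(self.ratings))[0]
            raise ValidationError(
                f"non-integer rating at row {bad[0]} item {self.items[bad[1]]!r}"
            )
        self.ratings = self.ratings.astype(np.int64)
        out = (self.ratings < RATING_MIN) | (self.ratings > RATING_MAX)
        if np.any(out):
            bad = np.argwhere(out)[0]
            raise ValidationError(
                f"rating {self.ratings[bad[0], bad[1]]} out of range [1,5] "
                f"at row {bad[0]} item {self.items[bad[1]]!r}"
            )
        if self.covariates is not None:
            overlap = set(self.covariates.columns) & set(self.items)
            if overlap:
                raise ValidationError(
                    f"covariate names collide with item names: {sorted(overlap)}"
                )
            if len(self.covariates) != n:
                raise ValidationError("covariate rows must match rating rows")
            if self.covariates.isna().any().any():
                col = self.covariates.columns[self.covariates.isna().any()][0]
                raise ValidationError(f"missing value in covariate {col!r}")

    @property
    def n(self) -> int:
        return self.ratings.shape[0]

    @property
    def p(self) -> int:
        return self.ratings.shape[1]

    @property
    def covariate_names(self) -> list:
        return [] if self.covariates is None else list(self.covariates.columns)

    def ratings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratings, index=self.person_ids, columns=self.items)

    def to_frame(self) -> pd.DataFrame:
        """Full table: rating columns followed by covariate columns."""
        df = self.ratings_frame()
        if self.covariates is not None:
            cov = self.covariates.copy()
            cov.index = df.index
            df = pd.concat([df, cov], axis=1)
        return df

    def subset_rows(self, idx: np.ndarray) -> "SymptomTable":
        """Row subset/resample (used by the bootstrap stages)."""
        idx = np.asarray(idx)
        cov = None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True)
        return SymptomTable(
            person_ids=[self.person_ids[i] for i in idx],
            items=list(self.items),
            ratings=self.ratings[idx],
            covariates=cov,
        )

    def require_estimable(self) -> None:
        """Estimation entry points need n >= p+1 rows."""
        if self.n < self.p + 1:
            raise ValidationError(
                f"need at least p+1={self.p + 1} rows for estimation, got {self.n}"
            )


@dataclass
class NetworkModel:
    """A weighted undirected network of regularized partial correlations.

    ``weights`` is an m x m symmetric matrix with zero diagonal; each
    entry is the partial correlation between two nodes conditional on
    all others, after L1 regularization.
    """

    node_names: list
    weights: np.ndarray
    lambda_selected: float = float("nan")
    gamma: float = float("nan")
    ebic_value: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        m = len(self.node_names)
        if W.shape != (m, m):
            raise ValidationError(f"weights shape {W.shape} != ({m},{m})")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric (tol 1e-10)")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        if np.any(np.abs(W) > 1.0 + 1e-9):
            raise ValidationError("partial correlations must satisfy |w| <= 1")
        self.weights = np.clip(W, -1.0, 1.0)

    @property
    def m(self) -> int:
        return len(self.node_names)

    def edge_mask(self, threshold: float = EDGE_THRESHOLD) -> np.ndarray:
        """Boolean m x m adjacency: |w| above the solver-noise threshold."""
        A = np.abs(self.weights) > threshold
        np.fill_diagonal(A, False)
        return A

    def n_edges(self, threshold: float = EDGE_THRESHOLD) -> int:
        return int(np.triu(self.edge_mask(threshold), 1).sum())

    def edge_list(self, threshold: float = EDGE_THRESHOLD) -> pd.DataFrame:
        """Nonzero edges, one row per unordered pair, lexicographic by index."""
        rows = []
        mask = self.edge_mask(threshold)
        for i in range(self.m):
            for j in range(i + 1, self.m):
                if mask[i, j]:
                    rows.append((self.node_names[i], self.node_names[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def subnetwork(self, names: list) -> "NetworkModel":
        idx = [self.node_names.index(nm) for nm in names]
        return NetworkModel(
            node_names=list(names),
            weights=self.weights[np.ix_(idx, idx)],
            lambda_selected=self.lambda_selected,
            gamma=self.gamma,
            ebic_value=self.ebic_value,
            n_obs=self.n_obs,
        )


@dataclass
class PredictabilityTable:
    """Per-node determinacy R^2 with interpretive category.

    ``>= 0.65`` network-embedded, ``<= 0.30`` external-driven,
    otherwise intermediate; isolated nodes carry R^2 = 0 and a flag.
    """

    table: pd.DataFrame  # index: node, columns: r2, category, isolated

    def __post_init__(self) -> None:
        r2 = self.table["r2"].to_numpy(dtype=float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValidationError("R^2 must lie in [0,1]")


@dataclass
class RegressionReport:
    """Per-predictor coefficients and diagnostics of the severity model."""

    coef_table: pd.DataFrame  # index: predictor; columns B, beta, p, ci_low, ci_high, vif
    r_squared: float
    diagnostics: dict = field(default_factory=dict)

    def selected(self, alpha: float) -> list:
        return list(self.coef_table.index[self.coef_table["p"] < alpha])


def required_sample_size(n_nodes: int) -> int:
    """Number of unique parameters in an ``n``-node partial-correlation
    network: ``n`` thresholds plus ``n(n-1)/2`` pairwise parameters --
    the minimum sample size for estimating such a network.
    """
    if int(n_nodes) != n_nodes or n_nodes < 1:
        raise ValueError(f"node count must be a positive integer, got {n_nodes}")
    n_nodes = int(n_nodes)
    return n_nodes + n_nodes * (n_nodes - 1) // 2
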