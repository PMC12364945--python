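"""Bootstrap accuracy, case-dropping stability, and difference tests.

Three resampling procedures qualify the estimated network:

* **edge-weight accuracy** -- nonparametric bootstrap (resample rows
  with replacement, re-estimate, take 2.5%/97.5% quantiles per edge);
* **centrality stability** -- case-dropping subsample bootstrap: drop a
  growing proportion of rows (without replacement), re-estimate, and
  correlate the subsample centralities with the full-sample ones.  The
  correlation-stability (CS) coefficient is the largest drop proportion
  at which at least 95% of subsamples still correlate >= 0.7 with the
  full sample; CS >= 0.25 indicates minimal and CS >= 0.5 strong
  stability;
* **difference tests** -- bootstrap distributions of pairwise
  differences between edge weights (or node strengths); a difference is
  significant when its 95% quantile interval excludes zero, with no
  multiplicity correction.

Per-replicate seeds are derived from the root seed by counter, so the
entire report is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import nearest_psd, spearman_matrix
from .centrality import expected_influence, strength, shortest_path_metrics
from .core import NetworkModel, SymptomTable, ValidationError
from .glasso import NetworkConfig, ebicglasso_select

CS_MINIMAL = 0.25
CS_STRONG = 0.5


@dataclass
class BootstrapConfig:
    n_boot: int = 1000
    ci_level: float = 0.95
    drop_grid: tuple = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))
    n_per_drop: int = 250
    cor_threshold: float = 0.7
    prob_threshold: float = 0.95
    seed: int = 0
    max_failure_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not all(0 < q < 1 for q in self.drop_grid):
            raise ValidationError("drop proportions must lie strictly in (0,1)")
        for name in ("ci_level", "cor_threshold", "prob_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0,1), got {v}")


def _fit_weights(table: SymptomTable, config: NetworkConfig) -> NetworkModel:
    corr = nearest_psd(spearman_matrix(table))
    return ebicglasso_select(
        corr,
        n=table.n,
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        tol=config.tol,
        edge_threshold=config.edge_threshold,
    )


@dataclass
class EdgeBootstrap:
    """Full-sample edge estimates with bootstrap replicates and CIs."""

    node_names: list
    pairs: list  # upper-triangle (i, j) index pairs
    estimates: np.ndarray  # full-sample weights, one per pair
    replicates: np.ndarray  # (n_ok, n_pairs)
    ci: pd.DataFrame  # node_i, node_j, estimate, ci_low, ci_high
    n_failed: int = 0
    degenerate: bool = False  # single-replicate CI


def bootstrap_edges(
    table: SymptomTable,
    net_config: NetworkConfig | None = None,
    boot_config: BootstrapConfig | None = None,
) -> EdgeBootstrap:
    """Row-resampling bootstrap of every edge weight.

    Replicates failing estimation are recorded and skipped; more than
    ``max_failure_fraction`` failures aborts.
    """
    net_config = net_config or NetworkConfig()
    boot_config = boot_config or BootstrapConfig()
    table.require_estimable()
    full = _fit_weights(table, net_config)
    m = full.m
    iu = np.triu_indices(m, 1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    estimates = full.weights[iu]
    reps = []
    n_failed = 0
    for b in range(boot_config.n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([boot_config.seed, 7, b]))
        idx = rng.integers(0, table.n, table.n)
        try:
            net_b = _fit_weights(table.subset_rows(idx), net_config)
            reps.append(net_b.weights[iu])
        except Exception:
            n_failed += 1
    if n_failed > boot_config.max_failure_fraction * boot_config.n_boot:
        raise RuntimeError(
            f"{n_failed}/{boot_config.n_boot} bootstrap replicates failed estimation"
        )
    R = np.array(reps)
    a = (1.0 - boot_config.ci_level) / 2.0
    lo = np.quantile(R, a, axis=0)
    hi = np.quantile(R, 1.0 - a, axis=0)
    ci = pd.DataFrame(
        {
            "node_i": [full.node_names[i] for i, _ in pairs],
            "node_j": [full.node_names[j] for _, j in pairs],
            "estimate": estimates,
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    return EdgeBootstrap(
        node_names=list(full.node_names),
        pairs=pairs,
        estimates=estimates,
        replicates=R,
        ci=ci,
        n_failed=n_failed,
        degenerate=R.shape[0] < 2,
    )


@dataclass
class DifferenceTest:
    """Pairwise bootstrapped difference test over edges or nodes."""

    labels: list
    significant: np.ndarray  # boolean, square over labels
    ci_low: np.ndarray
    ci_high: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.labels, columns=self.labels)


def _pairwise_difference(values: np.ndarray, estimates: np.ndarray, level: float
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # values: (n_boot, k) bootstrap replicates of k quantities
    k = values.shape[1]
    a = (1.0 - level) / 2.0
    sig = np.zeros((k, k), dtype=bool)
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    for i in range(k):
        d = values[:, [i]] - values  # (n_boot, k)
        lo[i] = np.quantile(d, a, axis=0)
        hi[i] = np.quantile(d, 1.0 - a, axis=0)
        sig[i] = (lo[i] > 0) | (hi[i] < 0)
        sig[i, i] = False
    return sig, lo, hi


def difference_test_edges(
    table: SymptomTable,
    net_config: NetworkConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    boot: EdgeBootstrap | None = None,
) -> DifferenceTest:
    """Bootstrapped difference test between every pair of nonzero
    full-sample edges (uncorrected 95% quantile intervals)."""
    boot_config = boot_config or BootstrapConfig()
    if boot is None:
        boot = bootstrap_edges(table, net_config, boot_config)
    nz = np.flatnonzero(np.abs(boot.estimates) > 0)
    labels = [
        f"{boot.node_names[boot.pairs[k][0]]}--{boot.node_names[boot.pairs[k][1]]}"
        for k in nz
    ]
    sig, lo, hi = _pairwise_difference(
        boot.replicates[:, nz], boot.estimates[nz], boot_config.ci_level
    )
    return DifferenceTest(labels=labels, significant=sig, ci_low=lo, ci_high=hi)


def _strengths_from_pairs(replicates: np.ndarray, pairs: list, m: int) -> np.ndarray:
    S = np.zeros((replicates.shape[0], m))
    for k, (i, j) in enumerate(pairs):
        w = np.abs(replicates[:, k])
        S[:, i] += w
        S[:, j] += w
    return S


def difference_test_nodes(
    table: SymptomTable,
    net_config: NetworkConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    boot: EdgeBootstrap | None = None,
) -> DifferenceTest:
    """Bootstrapped difference test between node strengths."""
    boot_config = boot_config or BootstrapConfig()
    if boot is None:
        boot = bootstrap_edges(table, net_config, boot_config)
    m = len(boot.node_names)
    S = _strengths_from_pairs(boot.replicates, boot.pairs, m)
    est = _strengths_from_pairs(boot.estimates[None, :], boot.pairs, m)[0]
    sig, lo, hi = _pairwise_difference(S, est, boot_config.ci_level)
    return DifferenceTest(labels=list(boot.node_names), significant=sig,
                          ci_low=lo, ci_high=hi)


def _index_values(network: NetworkModel, index: str) -> np.ndarray:
    if index == "strength":
        return strength(network)
    if index == "expected_influence":
        return expected_influence(network)
    if index in ("closeness", "betweenness"):
        clo, bet, _ = shortest_path_metrics(network)
        return clo if index == "closeness" else bet
    raise ValidationError(f"unknown centrality index {index!r}")


@dataclass
class CSResult:
    index: str
    cs: float  # nan when the index is degenerate
    classification: str
    proportions: pd.DataFrame  # drop proportion -> share of subsamples with corr >= threshold
    degenerate: bool = False


def classify_cs(cs: float) -> str:
    if np.isnan(cs):
        return "undefined"
    if cs >= CS_STRONG:
        return "strong stability"
    if cs >= CS_MINIMAL:
        return "minimal stability"
    return "unstable"


def cs_coefficient(
    table: SymptomTable,
    net_config: NetworkConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    index: str = "strength",
) -> CSResult:
    """Case-dropping correlation-stability coefficient for one index.

    CS is the largest drop proportion q such that at every q' <= q at
    least ``prob_threshold`` of subsamples correlate (Pearson, across
    nodes) at least ``cor_threshold`` with the full-sample index.
    """
    net_config = net_config or NetworkConfig()
    boot_config = boot_config or BootstrapConfig()
    table.require_estimable()
    grid = [q for q in boot_config.drop_grid
            if round((1 - q) * table.n) >= table.p + 1]
    if not grid:
        raise ValidationError(
            "drop grid infeasible: smallest retained subset below p+1 rows"
        )
    full = _fit_weights(table, net_config)
    ref = _index_values(full, index)
    if np.std(ref) == 0:
        # zero-variance index: no subsample correlation can reach the
        # threshold, so no drop level qualifies -- CS = 0, flagged
        return CSResult(
            index=index, cs=0.0, classification="unstable",
            proportions=pd.DataFrame(columns=["drop", "proportion"]),
            degenerate=True,
        )
    rows = []
    for qi, q in enumerate(grid):
        msize = round((1 - q) * table.n)
        ok = 0
        for r in range(boot_config.n_per_drop):
            rng = np.random.default_rng(
                np.random.SeedSequence([boot_config.seed, 11, qi, r])
            )
            idx = rng.choice(table.n, size=msize, replace=False)
            try:
                net_q = _fit_weights(table.subset_rows(idx), net_config)
                vals = _index_values(net_q, index)
            except Exception:
                continue  # failed replicate counts against stability
            if np.std(vals) == 0:
                continue
            corr = np.corrcoef(ref, vals)[0, 1]
            if corr >= boot_config.cor_threshold:
                ok += 1
        rows.append((q, ok / boot_config.n_per_drop))
    props = pd.DataFrame(rows, columns=["drop", "proportion"])
    cs = 0.0
    for q, prop in rows:
        if prop >= boot_config.prob_threshold:
            cs = q
        else:
            break
    return CSResult(
        index=index, cs=float(cs), classification=classify_cs(cs), proportions=props
    )


@dataclass
class ResamplingReport:
    """Aggregated bootstrap outputs for one network."""

    edge_ci: pd.DataFrame
    cs: dict  # index -> CSResult
    edge_diff: DifferenceTest | None = None
    node_diff: DifferenceTest | None = None
    config: BootstrapConfig | None = None


def resampling_report(
    table: SymptomTable,
    net_config: NetworkConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    cs_indices: tuple = ("strength", "expected_influence"),
) -> ResamplingReport:
    """Run all resampling stages, sharing one set of bootstrap
    replicates between the edge CIs and both difference tests."""
    net_config = net_config or NetworkConfig()
    boot_config = boot_config or BootstrapConfig()
    boot = bootstrap_edges(table, net_config, boot_config)
    edge_diff = difference_test_edges(table, net_config, boot_config, boot=boot)
    node_diff = difference_test_nodes(table, net_config, boot_config, boot=boot)
    cs = {
        ix: cs_coefficient(table, net_config, boot_config, index=ix)
        for ix in cs_indices
    }
    return ResamplingReport(
        edge_ci=boot.ci, cs=cs, edge_diff=edge_diff, node_diff=node_diff,
        config=boot_config,
    )
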