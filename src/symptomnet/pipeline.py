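"""End-to-end orchestration: descriptives, covariate screening,
network estimation, centrality, resampling, predictability, and a
single machine-readable JSON run report.

The report is deterministic: identical seed and configuration produce a
byte-identical file (keys sorted, no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .centrality import centrality_table, fruchterman_reingold, rank_core_symptoms
from .core import SymptomTable
from .glasso import NetworkConfig, density, estimate_networks
from .predictability import node_predictability
from .regression import fit_severity_model, screen_covariates
from .resampling import BootstrapConfig, resampling_report

logger = logging.getLogger("symptomnet")

REPORT_SCHEMA_VERSION = 1


def descriptives(table: SymptomTable) -> pd.DataFrame:
    """Per-item prevalence, mean (sd), median and IQR.

    A symptom is counted present when its rating is >= 2 (1 = "not at
    all").  Quantiles use the linear-interpolation (type-7) convention.
    """
    R = table.ratings
    present = (R >= 2).sum(axis=0)
    return pd.DataFrame(
        {
            "n_present": present,
            "prevalence_pct": 100.0 * present / table.n,
            "mean": R.mean(axis=0),
            "sd": R.std(axis=0, ddof=1),
            "median": np.quantile(R, 0.5, axis=0),
            "p25": np.quantile(R, 0.25, axis=0),
            "p75": np.quantile(R, 0.75, axis=0),
        },
        index=table.items,
    )


@dataclass
class PipelineConfig:
    """Everything a run needs besides the data itself."""

    seed: int = 0
    alpha_screen: float = 0.001
    network: NetworkConfig = field(default_factory=NetworkConfig)
    bootstrap: BootstrapConfig | None = None  # None skips resampling
    layout_iterations: int = 500
    run_resampling: bool = True
    cs_indices: tuple = ("strength", "expected_influence")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "alpha_screen": self.alpha_screen,
            "network": self.network.as_dict(),
            "layout_iterations": self.layout_iterations,
            "run_resampling": self.run_resampling,
        }


def run_pipeline(
    table: SymptomTable,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run every stage on one table and return the aggregated report.

    Stages: descriptives -> severity regression + covariate screening
    (when covariates exist) -> unadjusted and covariate-adjusted
    network estimation -> centrality + layout -> resampling ->
    predictability.  When ``out_dir`` is given, CSV artifacts and the
    JSON report are written there, each carrying the seed and
    configuration in its header.
    """
    config = config or PipelineConfig()
    table.require_estimable()
    meta = {"seed": config.seed, "config": config.as_dict()}
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "config": config.as_dict()}

    logger.info("descriptives: n=%d, p=%d", table.n, table.p)
    desc = descriptives(table)
    report["descriptives"] = desc.round(10)

    selected: list = []
    if table.covariates is not None and not table.covariates.empty:
        logger.info("severity regression on %d predictors", table.covariates.shape[1])
        reg = fit_severity_model(table)
        selected = screen_covariates(reg, config.alpha_screen)
        report["severity_regression"] = {
            "coefficients": reg.coef_table.round(10),
            "r_squared": reg.r_squared,
            "diagnostics": reg.diagnostics,
            "alpha_screen": config.alpha_screen,
            "selected_covariates": selected,
        }

    logger.info("network estimation (selected covariates: %s)", selected)
    unadj, adj = estimate_networks(table, covariates=selected, config=config.network)
    report["networks"] = {}
    for name, net in (("unadjusted", unadj), ("adjusted", adj)):
        if name == "adjusted" and not selected:
            report["networks"]["adjusted"] = "identical to unadjusted (no covariates selected)"
            continue
        dens = density(net, config.network.edge_threshold)
        cent = centrality_table(net)
        core, tied = rank_core_symptoms(cent, symptom_nodes=table.items)
        layout = fruchterman_reingold(net, seed=config.seed,
                                      iterations=config.layout_iterations)
        pred = node_predictability(table, net.subnetwork(table.items))
        section = {
            "n_nodes": net.m,
            "lambda": net.lambda_selected,
            "gamma": net.gamma,
            "ebic": net.ebic_value,
            "density_pct": round(dens.percent, 2),
            "n_edges": dens.n_edges,
            "possible_edges": dens.possible,
            "centrality": cent.table.round(10),
            "centrality_flags": cent.flags,
            "core_symptoms": core[:3],
            "core_tie_flag": tied,
            "predictability": pred.table.round(10),
        }
        report["networks"][name] = section
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            io.write_network(net, out / f"network_{name}.csv", header_meta=meta)
            cent.table.to_csv(out / f"centrality_{name}.csv")
            layout.coords.to_csv(out / f"layout_{name}.csv")
            pred.table.to_csv(out / f"predictability_{name}.csv")

    if config.run_resampling and config.bootstrap is not None:
        logger.info("resampling (n_boot=%d)", config.bootstrap.n_boot)
        res = resampling_report(
            table, config.network, config.bootstrap, cs_indices=config.cs_indices
        )
        report["resampling"] = {
            "cs": {
                ix: {"cs": r.cs, "classification": r.classification}
                for ix, r in res.cs.items()
            },
            "edge_ci": res.edge_ci.round(10),
            "n_significant_edge_differences": int(res.edge_diff.significant.sum() // 2),
            "n_significant_node_differences": int(res.node_diff.significant.sum() // 2),
        }
        if out_dir is not None:
            res.edge_ci.to_csv(Path(out_dir) / "edge_bootstrap_ci.csv", index=False)
            res.edge_diff.frame().to_csv(Path(out_dir) / "edge_difference_test.csv")
            res.node_diff.frame().to_csv(Path(out_dir) / "node_difference_test.csv")

    if out_dir is not None:
        io.write_json_report(report, Path(out_dir) / "report.json")
    return report
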