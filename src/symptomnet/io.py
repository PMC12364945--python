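"""Readers and writers for tables, edge lists and result files.

All delimited outputs are plain CSV; result files carry a ``#``-prefixed
header recording the seed and configuration that produced them, so every
artifact is self-describing and reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NetworkModel, SymptomTable, ValidationError


class SchemaError(ValueError):
    """A required column is absent or a covariate spec is malformed."""


def expand_categorical(
    series: pd.Series, reference: str, name: str | None = None
) -> pd.DataFrame:
    """Reference-code a categorical column into 0/1 indicator columns.

    One indicator per non-reference level, named ``<col>_<level>``; the
    reference level is the omitted contrast (e.g. surgery vs. medication).
    """
    name = name or series.name
    levels = [lv for lv in pd.unique(series) if lv != reference]
    if reference not in set(series):
        raise SchemaError(
            f"reference level {reference!r} absent from column {name!r}"
        )
    out = {}
    for lv in sorted(map(str, levels)):
        out[f"{name}_{lv}"] = (series.astype(str) == lv).astype(int)
    return pd.DataFrame(out, index=series.index)


def read_symptom_table(
    path,
    item_columns: list,
    covariate_spec: dict | None = None,
) -> SymptomTable:
    """Read a person x item CSV into a validated :class:`SymptomTable`.

    ``covariate_spec`` maps column name to ``"binary"``, ``"continuous"``
    or ``("categorical", reference_level)``.  Categorical covariates are
    expanded to reference-coded indicators.  Any missing cell or
    out-of-range rating is a hard error (complete-case contract).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in item_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing item columns: {missing}")
    ratings = df[item_columns]
    if ratings.isna().any().any():
        col = ratings.columns[ratings.isna().any()][0]
        row = int(ratings.index[ratings[col].isna()][0])
        raise ValidationError(
            f"missing rating at row {row} item {col!r}; no imputation is performed"
        )
    cov = None
    if covariate_spec:
        miss = [c for c in covariate_spec if c not in df.columns]
        if miss:
            raise SchemaError(f"missing covariate columns: {miss}")
        blocks = []
        for col, kind in covariate_spec.items():
            s = df[col]
            if s.isna().any():
                raise ValidationError(f"missing value in covariate {col!r}")
            if isinstance(kind, (tuple, list)) and kind[0] == "categorical":
                blocks.append(expand_categorical(s, reference=kind[1], name=col))
            elif kind == "binary":
                vals = set(pd.unique(s))
                if not vals <= {0, 1}:
                    raise ValidationError(
                        f"binary covariate {col!r} has values {sorted(vals)}"
                    )
                blocks.append(s.astype(int).to_frame())
            elif kind == "continuous":
                blocks.append(s.astype(float).to_frame())
            else:
                raise SchemaError(f"unknown covariate kind {kind!r} for {col!r}")
        cov = pd.concat(blocks, axis=1)
    if "person_id" in df.columns:
        ids = list(df["person_id"])
    else:
        ids = list(range(len(df)))
    return SymptomTable(
        person_ids=ids,
        items=list(item_columns),
        ratings=ratings.to_numpy(),
        covariates=cov,
    )


def write_symptom_table(table: SymptomTable, path, header_meta: dict | None = None) -> None:
    p = Path(path)
    df = table.to_frame().reset_index(names="person_id")
    with open(p, "w") as fh:
        for line in _meta_lines(header_meta):
            fh.write(line)
        df.to_csv(fh, index=False)


def _meta_lines(meta: dict | None):
    if meta:
        for k, v in meta.items():
            yield f"# {k}: {v}\n"


def write_network(network: NetworkModel, path, header_meta: dict | None = None) -> None:
    """Write a network as a CSV edge list (nonzero edges only).

    The node list travels in a ``# nodes:`` header line so isolated
    nodes survive a round trip; weights are written with 17 significant
    digits so read-back reproduces them to better than 1e-12.
    """
    p = Path(path)
    edges = network.edge_list()
    with open(p, "w") as fh:
        for line in _meta_lines(header_meta):
            fh.write(line)
        fh.write("# nodes: " + ",".join(map(str, network.node_names)) + "\n")
        fh.write(f"# lambda: {network.lambda_selected!r}\n")
        fh.write(f"# gamma: {network.gamma!r}\n")
        fh.write(f"# n_obs: {network.n_obs}\n")
        fh.write("node_i,node_j,weight\n")
        for _, row in edges.iterrows():
            fh.write(f"{row.node_i},{row.node_j},{row.weight:.17g}\n")


def read_network(path) -> NetworkModel:
    """Read an edge-list CSV written by :func:`write_network`."""
    nodes = None
    lam = float("nan")
    gamma = float("nan")
    n_obs = 0
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            val = val.strip()
            if key == "nodes":
                nodes = val.split(",")
            elif key == "lambda":
                lam = float(val)
            elif key == "gamma":
                gamma = float(val)
            elif key == "n_obs":
                n_obs = int(val)
        else:
            body.append(line)
    if nodes is None:
        raise SchemaError("edge-list file lacks a '# nodes:' header line")
    m = len(nodes)
    W = np.zeros((m, m))
    idx = {nm: i for i, nm in enumerate(nodes)}
    for line in body[1:]:  # skip the column header
        if not line.strip():
            continue
        a, b, w = line.rstrip("\n").split(",")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = float(w)
    return NetworkModel(
        node_names=nodes, weights=W, lambda_selected=lam, gamma=gamma, n_obs=n_obs
    )


def write_json_report(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON serializable: {type(obj)}")
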