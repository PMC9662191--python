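"""Cross-omics correlation network over selected features.

Selected features from all layers are pooled (autoscaled values, both
comparison groups' samples), pairwise correlations computed (Pearson by
default; Spearman and Kendall for cross-method consistency), and edges kept
when |r| >= 0.3 and p < .05.  Nodes carry their layer of origin; isolated
selected features remain as nodes so panels stay visible in the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationEdge",
    "OmicsNetwork",
    "correlate_selected",
    "filter_edges",
    "build_network",
    "cross_method_consistency",
]

METHODS = ("pearson", "spearman", "kendall")


@dataclass(frozen=True)
class CorrelationEdge:
    feature_a: str
    layer_a: str
    feature_b: str
    layer_b: str
    method: str
    r: float
    p_value: float


@dataclass
class OmicsNetwork:
    """Thresholded correlation graph with layer-tagged nodes."""

    graph: nx.Graph
    r_min: float
    p_max: float
    method: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "feature_a": a,
                "layer_a": self.graph.nodes[a]["layer"],
                "feature_b": b,
                "layer_b": self.graph.nodes[b]["layer"],
                "method": d["method"],
                "r": d["r"],
                "p": d["p"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["feature_a", "layer_a", "feature_b", "layer_b",
                           "method", "r", "p"]
        )

    def to_edge_tsv(self, path: str | Path) -> None:
        self.edges_dataframe().to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, layer=d["layer"])
        for a, b, d in self.graph.edges(data=True):
            g.add_edge(a, b, weight=float(d["r"]), p=float(d["p"]),
                       method=d["method"])
        nx.write_graphml(g, str(path))


def _pair_pvalue(method: str, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    elif method == "kendall":
        res = sps.kendalltau(x, y, method="asymptotic")
    else:
        raise ValueError(f"unknown method {method!r}; use one of {METHODS}")
    return float(res.statistic), float(res.pvalue)


def correlate_selected(
    values: pd.DataFrame,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full correlation and p-value matrices over selected features.

    ``values`` holds autoscaled samples x features data pooled over the
    comparison's groups and layers.  Zero-variance columns are excluded
    with a warning.  The Pearson p-value uses the t-transform; Spearman
    applies the same transform to ranks; Kendall uses the tie-corrected
    normal approximation.
    """
    if values.shape[0] < 4:
        raise ValueError("need at least 4 samples to correlate")
    if values.shape[1] < 1:
        raise ValueError("no selected features to correlate")
    sd = values.std(ddof=1)
    dead = list(values.columns[sd == 0])
    if dead:
        warnings.warn(f"excluding zero-variance feature(s): {dead}", stacklevel=2)
        values = values.loc[:, sd > 0]
    cols = list(values.columns)
    k = len(cols)
    X = values.to_numpy(dtype=float)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = _pair_pvalue(method, X[:, i], X[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def filter_edges(
    r: pd.DataFrame,
    p: pd.DataFrame,
    layers: dict[str, str],
    r_min: float = 0.3,
    p_max: float = 0.05,
    method: str = "pearson",
) -> list[CorrelationEdge]:
    """Retain unordered pairs with |r| >= r_min and p < p_max, each once.

    The magnitude threshold is inclusive, the p-value threshold strict, so
    the edge set is reproducible at the boundaries.
    """
    cols = list(r.columns)
    edges = []
    rv, pv = r.to_numpy(), p.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(rv[i, j]) >= r_min and pv[i, j] < p_max:
                a, b = cols[i], cols[j]
                edges.append(
                    CorrelationEdge(a, layers.get(a, ""), b, layers.get(b, ""),
                                    method, float(rv[i, j]), float(pv[i, j]))
                )
    return edges


def build_network(
    edges: Sequence[CorrelationEdge],
    node_catalog: dict[str, str],
    r_min: float = 0.3,
    p_max: float = 0.05,
    method: str = "pearson",
) -> OmicsNetwork:
    """Assemble the graph: every cataloged feature is a node (layer-tagged);
    filtered correlations are the edges.  Edges touching a feature outside
    the catalog are an error."""
    g = nx.Graph()
    for fid, layer in node_catalog.items():
        g.add_node(fid, layer=layer)
    for e in edges:
        for endpoint in (e.feature_a, e.feature_b):
            if endpoint not in node_catalog:
                raise ValueError(f"edge endpoint {endpoint!r} not in node catalog")
        if e.feature_a == e.feature_b:
            raise ValueError(f"self-loop on {e.feature_a!r}")
        g.add_edge(e.feature_a, e.feature_b, r=e.r, p=e.p_value, method=e.method)
    return OmicsNetwork(g, r_min, p_max, method)


def cross_method_consistency(
    values: pd.DataFrame,
    methods: Sequence[str] = METHODS,
    r_min: float = 0.3,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair (r, p) across correlation methods, plus edge agreement.

    Returns a tidy table with one row per unordered feature pair holding
    ``r_<method>`` / ``p_<method>`` columns, and a method x method matrix
    of the fraction of threshold-passing edges shared by each pair of
    methods (Jaccard index; 1.0 when both edge sets are empty).
    """
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    per_method = {m: correlate_selected(values, m) for m in methods}
    cols = list(next(iter(per_method.values()))[0].columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            row = {"feature_a": cols[i], "feature_b": cols[j]}
            for m in methods:
                rm, pm = per_method[m]
                row[f"r_{m}"] = float(rm.iloc[i, j])
                row[f"p_{m}"] = float(pm.iloc[i, j])
            rows.append(row)
    tidy = pd.DataFrame(rows)
    edge_sets = {}
    for m in methods:
        rm, pm = per_method[m]
        edge_sets[m] = {
            (cols[i], cols[j])
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if abs(rm.iloc[i, j]) >= r_min and pm.iloc[i, j] < p_max
        }
    agree = pd.DataFrame(1.0, index=list(methods), columns=list(methods))
    for a in methods:
        for b in methods:
            union = edge_sets[a] | edge_sets[b]
            agree.loc[a, b] = (
                len(edge_sets[a] & edge_sets[b]) / len(union) if union else 1.0
            )
    return tidy, agree
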