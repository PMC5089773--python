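"""Local weighted-directed graph measures of the connectivity matrix.

The connectivity is analyzed as a weighted digraph on W = |Gamma| (signs are
an excitatory/inhibitory annotation, not a topological property).  Three
node-level measures are computed:

* clustering coefficient C_m -- weighted directed triangle closure,
  C_m = [(W^ + W^T)^3]_mm / (2 [d_tot (d_tot - 1) - 2 d_rec]) with
  W^ = W^(1/3) elementwise, d_tot the binary total degree and d_rec the
  number of reciprocal partners;
* local efficiency E_m -- mean inverse shortest weighted path length from m
  to every other node (edge length = 1/weight, so strong connections are
  short); unreachable nodes contribute 0;
* betweenness centrality B_m -- the normalized fraction of shortest paths
  between other node pairs that pass through m.

Self-loops are removed before all three measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import ttest_ind

__all__ = [
    "TopologyMetrics",
    "clustering_coefficient",
    "local_efficiency",
    "betweenness_centrality",
    "topology_metrics",
    "role_statistics",
]


def _clean_weights(W: np.ndarray) -> np.ndarray:
    W = np.abs(np.asarray(W, dtype=float))
    np.fill_diagonal(W, 0.0)
    return W


def clustering_coefficient(W: np.ndarray) -> np.ndarray:
    """Per-node weighted directed clustering coefficient.

    Weights are normalized by the maximum entry before the cube root, so
    C_m lies in [0, 1] and is invariant to the overall weight scale.  Nodes
    with binary total degree <= 1, or whose possible-triangle count is zero
    (all partners reciprocal with no third neighbour), get C_m = 0.
    """
    W = _clean_weights(W)
    if W.max() > 0:
        W = W / W.max()
    A = (W > 0).astype(float)
    What = np.cbrt(W)
    S = What + What.T
    triangles = np.diagonal(np.linalg.matrix_power(S, 3))
    d_tot = A.sum(axis=0) + A.sum(axis=1)
    d_rec = np.diagonal(A @ A)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_rec)
    out = np.zeros(W.shape[0])
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def _length_matrix(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def local_efficiency(W: np.ndarray) -> np.ndarray:
    """E_m = mean over j != m of 1 / (shortest weighted path length m -> j)."""
    W = _clean_weights(W)
    n = W.shape[0]
    if n < 2:
        return np.zeros(n)
    D = dijkstra(_length_matrix(W), directed=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(W: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness, normalized by (N-1)(N-2), with multiple
    shortest paths fractionally counted."""
    W = _clean_weights(W)
    n = W.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, normalized=True, weight="length")
    return np.array([bc[i] for i in range(n)])


@dataclass
class TopologyMetrics:
    """Node-level topology of |Gamma|: clustering C, efficiency E,
    betweenness B, plus the weight and binary adjacency matrices used."""

    C: np.ndarray
    E: np.ndarray
    B: np.ndarray
    W: np.ndarray
    A: np.ndarray
    names: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        names = self.names or [str(i) for i in range(self.C.size)]
        return pd.DataFrame(
            {"node": names, "C": self.C, "E": self.E, "B": self.B}
        )


def topology_metrics(gamma: np.ndarray, names: list[str] | None = None) -> TopologyMetrics:
    """All three local measures of W = |gamma| (self-loops dropped)."""
    W = _clean_weights(gamma)
    return TopologyMetrics(
        C=clustering_coefficient(W),
        E=local_efficiency(W),
        B=betweenness_centrality(W),
        W=W,
        A=(W > 0).astype(int),
        names=list(names) if names else [],
    )


def role_statistics(
    metrics: TopologyMetrics,
    cfc_results: list,
    gamma: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Relate coupling roles to topology.

    Each significant coupling entry (k, l) is classified as *direct* when the
    anatomical entry gamma[k, l] is nonzero and *indirect* otherwise.
    Sender (k) and receiver (l) topology metrics are aggregated per role and
    compared with two-sample t-tests; coupling strengths are compared the
    same way.  Returns a dict with a tidy ``summary`` frame, ``tests``
    p-values, counts and the per-entry classification.
    """
    gamma = np.asarray(gamma, dtype=float)
    anatomical = gamma != 0
    rows = []
    for res in cfc_results:
        if res.mask is None:
            raise ValueError("CFC results need significance masks for role analysis")
        ks, ls = np.nonzero(res.mask)
        for k, l in zip(ks, ls):
            rows.append(
                {
                    "coupling": res.coupling.label,
                    "source": k,
                    "target": l,
                    "value": res.values[k, l],
                    "role": "direct" if anatomical[k, l] else "indirect",
                }
            )
    entries = pd.DataFrame(rows, columns=["coupling", "source", "target", "value", "role"])
    if entries.empty:
        return {"entries": entries, "summary": pd.DataFrame(), "tests": {}, "counts": {}}

    metric_of = {"C": metrics.C, "E": metrics.E, "B": metrics.B}
    summary_rows = []
    tests = {}
    for direction, col in (("send", "source"), ("receive", "target")):
        for mname, vec in metric_of.items():
            groups = {}
            for role in ("direct", "indirect"):
                nodes = entries.loc[entries.role == role, col].to_numpy()
                groups[role] = vec[nodes] if nodes.size else np.array([])
                summary_rows.append(
                    {
                        "direction": direction,
                        "metric": mname,
                        "role": role,
                        "mean": float(groups[role].mean()) if groups[role].size else np.nan,
                        "n": int(groups[role].size),
                    }
                )
            if groups["direct"].size > 1 and groups["indirect"].size > 1:
                t = ttest_ind(groups["indirect"], groups["direct"], equal_var=False)
                tests[f"{direction}_{mname}"] = float(t.pvalue)
    # strength comparison direct vs indirect
    g_dir = entries.loc[entries.role == "direct", "value"].to_numpy()
    g_ind = entries.loc[entries.role == "indirect", "value"].to_numpy()
    if g_dir.size > 1 and g_ind.size > 1:
        tests["strength"] = float(ttest_ind(g_ind, g_dir, equal_var=False).pvalue)
    counts = entries.role.value_counts().to_dict()
    return {
        "entries": entries,
        "summary": pd.DataFrame(summary_rows),
        "tests": tests,
        "counts": counts,
        "alpha": alpha,
    }
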