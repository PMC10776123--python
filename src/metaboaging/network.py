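"""Co-abundance network inference and Markov Clustering.

Edges connect metabolite pairs whose log-scale abundances correlate with
Pearson r > 0.7 and Benjamini-Hochberg adjusted p < 0.01 across all
samples of all time points (the published rule, applied literally to
positive correlations; an absolute-value mode is available).  Modules
are found with Markov Clustering (MCL) implemented from scratch on the
column-stochastic transition matrix with unit self-loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = ["MclConfig", "correlation_edges", "pearson_pairs", "mcl_cluster"]


@dataclass
class MclConfig:
    expansion: int = 2
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


def pearson_pairs(values: np.ndarray):
    """Pearson r and two-sided p for all unique row pairs.

    p-values use the t transform with df = n_samples - 2.  Returns
    ``(i, j, r, p)`` arrays over the upper triangle.
    """
    values = np.asarray(values, float)
    n = values.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 samples for correlation p-values, got {n}")
    R = np.corrcoef(values)
    iu = np.triu_indices(values.shape[0], 1)
    r = R[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return iu[0], iu[1], r, p


def correlation_edges(
    table: AbundanceTable,
    r_min: float = 0.7,
    p_max: float = 0.01,
    adjust: str = "fdr_bh",
    absolute: bool = False,
) -> nx.Graph:
    """Build the co-abundance network from pairwise Pearson correlations.

    Edges are kept iff r > r_min (|r| with ``absolute=True``) AND the
    adjusted p-value (BH by default, ``adjust="bonferroni"`` available)
    is < p_max.  Constant metabolites are excluded from pairing but kept
    as isolated nodes.  Node order follows the table; edge attributes are
    ``r`` and ``p_adj``.
    """
    if table.scale == "raw":
        raise ValueError("correlation_edges expects a log-scaled table")
    ids = list(table.values.index)
    X = table.values.to_numpy(float)
    const = X.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant metabolite(s) excluded from correlation"
        )
    keep_idx = np.where(~const)[0]

    net = nx.Graph(r_min=r_min, p_max=p_max, adjust=adjust)
    net.add_nodes_from(ids)
    if len(keep_idx) < 2:
        return net

    ii, jj, r, p = pearson_pairs(X[keep_idx])
    p_adj = multipletests(p, method=adjust)[1]
    score = np.abs(r) if absolute else r
    sel = (score > r_min) & (p_adj < p_max)
    for a, b, rv, pv in zip(ii[sel], jj[sel], r[sel], p_adj[sel]):
        u, v = ids[keep_idx[a]], ids[keep_idx[b]]
        net.add_edge(u, v, r=float(rv), p_adj=float(pv))
    return net


def mcl_cluster(net: nx.Graph, config: MclConfig | None = None):
    """Markov Clustering of an undirected network.

    Iterates expansion (matrix power), inflation (elementwise power with
    column renormalisation) and pruning on the column-stochastic
    transition matrix with unit self-loops, until the maximum column
    change drops below tolerance.  Clusters follow the attractor
    interpretation: rows with overlapping nonzero support are merged.
    Isolated nodes become singleton modules.

    Returns ``(modules, converged)`` with ``modules`` mapping node ->
    module id (ints numbered by first node appearance).
    """
    config = config or MclConfig()
    nodes = list(net.nodes)
    if not nodes:
        raise ValueError("MCL needs a non-empty node set")
    n = len(nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    M = A + np.eye(n)  # unit self-loops
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(config.max_iter):
        new = np.linalg.matrix_power(M, config.expansion)
        new **= config.inflation
        new /= new.sum(axis=0, keepdims=True)
        new[new < config.prune_threshold] = 0.0
        col = new.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        new /= col
        if np.abs(new - M).max() < config.tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        warnings.warn(f"MCL did not converge within {config.max_iter} iterations")

    # attractor interpretation: merge overlapping nonzero row supports
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > 1e-12)
    for i, j in zip(rows, cols):
        support.add_edge(i, j)
    modules: dict = {}
    next_id = 0
    seen: dict = {}
    for i in range(n):
        if i in seen:
            continue
        comp = nx.node_connected_component(support, i)
        for j in comp:
            seen[j] = next_id
        next_id += 1
    for i, node in enumerate(nodes):
        modules[node] = seen[i]
    return modules, converged
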