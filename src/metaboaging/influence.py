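"""Integrated Value of Influence (IVI) node ranking.

Six centralities feed the score: degree (DC), ClusterRank (CR),
neighborhood connectivity (NC), local H-index (LH), shortest-path
betweenness (BC) and collective influence at radius l (CI).  Each raw
vector is range-normalized to [1, 100]; hubness = DCn + LHn, spreading =
(NCn + CRn) * (BCn + CIn), and IVI is the range-normalized product of
the two, so the most influential node scores 100.  A constant raw
vector normalizes to all-1 (regular graphs therefore give IVI = 1
everywhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["IviConfig", "centralities", "range_normalize", "ivi", "rank_influential"]

_RAW_COLS = ("DC", "CR", "NC", "LH", "BC", "CI")


@dataclass
class IviConfig:
    ci_radius: int = 3  # frontier distance l for collective influence

    def __post_init__(self) -> None:
        if self.ci_radius < 1:
            raise ValueError("ci_radius must be >= 1")


def range_normalize(x) -> np.ndarray:
    """Map a vector onto [1, 100]; a constant vector maps to all ones."""
    x = np.asarray(x, float)
    if x.size == 0:
        return x
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x)
    # clip guards 1-ulp overshoot from the multiply-before-divide rounding
    return np.clip(1.0 + 99.0 * (x - lo) / (hi - lo), 1.0, 100.0)


def _h_index(degrees) -> int:
    """Largest h such that at least h of the given degrees are >= h."""
    ds = sorted(degrees, reverse=True)
    h = 0
    for rank, d in enumerate(ds, start=1):
        if d >= rank:
            h = rank
    return h


def centralities(net: nx.Graph, config: IviConfig | None = None) -> pd.DataFrame:
    """Raw and [1,100]-normalized centralities per node.

    DC = degree; NC = mean neighbor degree (0 for isolates); BC =
    unnormalized shortest-path betweenness; LH = own neighbor-degree
    H-index plus the sum of the neighbors' H-indices; CR = 10^(-c) *
    sum_{j in N(i)} (deg(j)+1) with c the local clustering coefficient
    (0 for degree <= 1 nodes); CI = (deg-1) * sum of (deg-1) over nodes
    exactly l steps away (0 when the frontier is empty).
    """
    config = config or IviConfig()
    nodes = list(net.nodes)
    if not nodes:
        return pd.DataFrame(
            columns=[*_RAW_COLS, *(c + "_n" for c in _RAW_COLS)], index=pd.Index([], name="node")
        )
    deg = dict(net.degree)
    dc = np.array([deg[v] for v in nodes], float)
    nc = np.array(
        [np.mean([deg[u] for u in net[v]]) if deg[v] else 0.0 for v in nodes]
    )
    bc_map = nx.betweenness_centrality(net, normalized=False)
    bc = np.array([bc_map[v] for v in nodes])
    clus = nx.clustering(net)
    cr = np.array(
        [10.0 ** (-clus[v]) * sum(deg[u] + 1 for u in net[v]) for v in nodes]
    )
    h = {v: _h_index(deg[u] for u in net[v]) for v in nodes}
    lh = np.array([h[v] + sum(h[u] for u in net[v]) for v in nodes], float)
    ci = np.empty(len(nodes))
    for i, v in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(net, v, cutoff=config.ci_radius)
        frontier = [u for u, d in dist.items() if d == config.ci_radius]
        ci[i] = (deg[v] - 1) * sum(deg[u] - 1 for u in frontier)

    table = pd.DataFrame(
        {"DC": dc, "CR": cr, "NC": nc, "LH": lh, "BC": bc, "CI": ci},
        index=pd.Index(nodes, name="node"),
    )
    for col in _RAW_COLS:
        table[col + "_n"] = range_normalize(table[col].to_numpy())
    return table


def ivi(cent: pd.DataFrame) -> pd.Series:
    """Combine normalized centralities into the IVI score on [1, 100]."""
    if len(cent) == 0:
        return pd.Series(dtype=float, name="IVI")
    hubness = cent["DC_n"] + cent["LH_n"]
    spreading = (cent["NC_n"] + cent["CR_n"]) * (cent["BC_n"] + cent["CI_n"])
    return pd.Series(
        range_normalize((hubness * spreading).to_numpy()), index=cent.index, name="IVI"
    )


def rank_influential(
    ivi_scores: pd.Series,
    cent: pd.DataFrame | None = None,
    trend_calls: pd.DataFrame | None = None,
    k: int = 15,
):
    """Top-k nodes by IVI with optional trend-group annotation.

    Ties break by degree (higher first), then node id.  Returns
    ``(top, group_counts)``; when k exceeds the node count, all nodes are
    returned with a warning.
    """
    if k > len(ivi_scores):
        warnings.warn(
            f"k={k} exceeds the {len(ivi_scores)} available nodes; returning all"
        )
        k = len(ivi_scores)
    frame = ivi_scores.rename("IVI").to_frame()
    frame["DC"] = (
        cent["DC"].reindex(frame.index) if cent is not None else 0.0
    )
    frame = frame.sort_values(
        ["IVI", "DC"], ascending=[False, False], kind="stable"
    )
    frame = frame.loc[
        sorted(frame.index, key=lambda n: (-frame.at[n, "IVI"], -frame.at[n, "DC"], str(n)))
    ]
    top = frame.head(k).copy()
    if trend_calls is not None and "trend_group" in trend_calls:
        top["trend_group"] = trend_calls["trend_group"].reindex(top.index)
        counts = top["trend_group"].value_counts().to_dict()
    else:
        counts = {}
    return top, counts
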