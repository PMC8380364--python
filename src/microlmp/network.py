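"""Co-abundance networks and the topology metrics that nominate hub taxa.

Edges are drawn between taxa whose basis correlation passes either a plain
magnitude threshold (|rho| > 0.5 by default) or the PCIT
(partial-correlation and information-theory) triad filter, which drops an
edge whenever its correlation is dominated by indirect paths through every
third node. Node centralities (degree, betweenness, closeness,
eccentricity) are computed per connected component on the unweighted graph,
and taxa are ranked as hubs by the mean of min–max-normalized degree,
betweenness and closeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkStats",
    "build_network",
    "pcit_filter",
    "node_metrics",
    "graph_summary",
    "degree_centralization",
    "rank_hubs",
]


@dataclass
class NetworkStats:
    nodes: pd.DataFrame              # per-node degree/betweenness/closeness/eccentricity
    summary: dict[str, float]        # graph-level metrics
    hub_ranking: list[str] = field(default_factory=list)


def _rho_frame(rho) -> pd.DataFrame:
    if isinstance(rho, pd.DataFrame):
        return rho
    rho = np.asarray(rho, dtype=float)
    ids = [f"n{i}" for i in range(rho.shape[0])]
    return pd.DataFrame(rho, index=ids, columns=ids)


def build_network(
    rho,
    rule: str = "threshold",
    tau: float = 0.5,
    node_abundance: pd.Series | None = None,
) -> nx.Graph:
    """Build the co-abundance graph from a correlation matrix.

    ``rule="threshold"`` keeps edges with |rho| > tau; ``rule="pcit"``
    keeps the edges surviving the PCIT triad test. Every node carries a
    ``mean_abundance`` attribute if ``node_abundance`` is given; every edge
    records ``rho`` and ``sign`` (+1 co-abundance, -1 co-exclusion).
    """
    rho = _rho_frame(rho)
    if rule == "threshold":
        if not 0.0 <= tau < 1.0:
            raise ValueError(f"tau must be in [0, 1), got {tau}")
        r = rho.to_numpy()
        keep = {
            (i, j)
            for i in range(len(r))
            for j in range(i + 1, len(r))
            if np.isfinite(r[i, j]) and abs(r[i, j]) > tau
        }
    elif rule == "pcit":
        keep = pcit_filter(rho.to_numpy())
    else:
        raise ValueError(f"unknown edge rule {rule!r}")

    g = nx.Graph(construction={"rule": rule, "tau": tau if rule == "threshold" else None})
    ids = rho.index.tolist()
    g.add_nodes_from(ids)
    if node_abundance is not None:
        nx.set_node_attributes(g, node_abundance.to_dict(), "mean_abundance")
    r = rho.to_numpy()
    for i, j in sorted(keep):
        g.add_edge(ids[i], ids[j], rho=float(r[i, j]),
                   sign=int(np.sign(r[i, j])))
    return g


def pcit_filter(rho: np.ndarray) -> set[tuple[int, int]]:
    """PCIT triad test: retained edge index pairs (i < j).

    For every triad (x, y, z) the first-order partial correlations are

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    and the triad tolerance is eps = (r_xy.z/r_xy + r_xz.y/r_xz +
    r_yz.x/r_yz) / 3. Edge (x, y) is flagged non-significant if for some z
    both |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|. Edges with
    r = 0 are excluded up front; |r| = 1 is clamped for the partials.
    """
    r = np.asarray(rho, dtype=float).copy()
    d = r.shape[0]
    if d < 3:
        raise ValueError("PCIT needs at least 3 nodes")
    np.fill_diagonal(r, 1.0)
    if (np.abs(r) >= 1.0 - 1e-15).sum() > d:  # off-diagonal |r| = 1 present
        warnings.warn("|r| = 1 off the diagonal; clamped for partial correlations")
    clamped = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    np.fill_diagonal(clamped, 1.0)

    # partial[z, x, y] = r_xy.z for all conditioning nodes z at once
    rz = clamped  # rz[z, x] = r_xz
    with np.errstate(divide="ignore", invalid="ignore"):
        num = r[None, :, :] - rz[:, :, None] * rz[:, None, :]
        den = np.sqrt(
            (1.0 - rz[:, :, None] ** 2) * (1.0 - rz[:, None, :] ** 2)
        )
        partial = num / den

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = partial / r[None, :, :]  # ratio[z, x, y] = r_xy.z / r_xy
    # eps[x, y, z] averages the three conditioned ratios of the triad
    eps = (
        np.transpose(ratio, (1, 2, 0))   # ratio[z, x, y] = r_xy.z / r_xy
        + np.transpose(ratio, (1, 0, 2))  # ratio[y, x, z] = r_xz.y / r_xz
        + ratio                           # ratio[x, y, z] = r_yz.x / r_yz
    ) / 3.0

    absr = np.abs(r)
    # flagged[x, y, z]: indirect paths via z dominate the direct edge
    cond = (absr[:, :, None] <= np.abs(eps) * absr[:, None, :]) & (
        absr[:, :, None] <= np.abs(eps) * absr[None, :, :]
    )
    idx = np.arange(d)
    cond[idx, :, idx] = False  # z must differ from x and y
    cond[:, idx, idx] = False
    cond[idx, idx, :] = False
    flagged = cond.any(axis=2)

    keep: set[tuple[int, int]] = set()
    for i in range(d):
        for j in range(i + 1, d):
            if r[i, j] == 0.0 or not np.isfinite(r[i, j]):
                continue
            if not (flagged[i, j] or flagged[j, i]):
                keep.add((i, j))
    return keep


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, eccentricity.

    Shortest paths are unweighted; betweenness is normalized by
    (n_c - 1)(n_c - 2)/2 within each connected component, closeness is
    (n_c - 1) / sum of within-component distances, eccentricity the maximum
    within-component distance. Isolated nodes get closeness and
    eccentricity 0.
    """
    rows = {}
    degree = dict(graph.degree())
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            (v,) = comp
            rows[v] = (degree[v], 0.0, 0.0, 0)
            continue
        btw = nx.betweenness_centrality(sub, normalized=nc > 2)
        clo = nx.closeness_centrality(sub)
        ecc = nx.eccentricity(sub)
        for v in comp:
            rows[v] = (degree[v], btw[v], clo[v], ecc[v])
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["degree", "betweenness", "closeness", "eccentricity"],
    )
    out.index.name = "taxon_id"
    return out.loc[list(graph.nodes)]


def degree_centralization(graph: nx.Graph) -> float:
    """Freeman degree centralization: sum(deg_max - deg_v) / ((n-1)(n-2))."""
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("degree centralization needs at least 3 nodes")
    degs = np.array([d for _, d in graph.degree()], dtype=float)
    return float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))


def graph_summary(graph: nx.Graph) -> dict[str, float]:
    """Graph-level topology: mean degree, mean eccentricity, centralization."""
    n = graph.number_of_nodes()
    metrics = node_metrics(graph) if n else pd.DataFrame(
        columns=["degree", "betweenness", "closeness", "eccentricity"]
    )
    return {
        "n_nodes": float(n),
        "n_edges": float(graph.number_of_edges()),
        "avg_neighbors": float(metrics["degree"].mean()) if n else 0.0,
        "avg_eccentricity": float(metrics["eccentricity"].mean()) if n else 0.0,
        "degree_centralization": degree_centralization(graph) if n >= 3 else np.nan,
    }


def rank_hubs(stats: pd.DataFrame) -> list[str]:
    """Rank taxa by the mean of min–max-normalized degree, betweenness and
    closeness (descending); ties broken by raw degree, then by id."""
    if stats.empty:
        return []
    norm = {}
    for col in ("degree", "betweenness", "closeness"):
        v = stats[col].to_numpy(dtype=float)
        rng = v.max() - v.min()
        norm[col] = (v - v.min()) / rng if rng > 0 else np.zeros_like(v)
    score = (norm["degree"] + norm["betweenness"] + norm["closeness"]) / 3.0
    order = sorted(
        range(len(stats)),
        key=lambda i: (-score[i], -stats["degree"].iloc[i], str(stats.index[i])),
    )
    return [stats.index[i] for i in order]


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Bundle per-node metrics, graph summary and the hub ranking."""
    nodes = node_metrics(graph)
    return NetworkStats(
        nodes=nodes,
        summary=graph_summary(graph),
        hub_ranking=rank_hubs(nodes),
    )
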