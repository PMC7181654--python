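"""Mutual-information network inference with DPI pruning and hub ranking.

Pairwise mutual information is estimated with a plug-in histogram over
equal-frequency bins (B = floor(sqrt(n)) by default), edges are kept above
a permutation-null threshold, and indirect edges are pruned with the data
processing inequality (DPI): in a Markov chain X-Y-Z,
MI(X,Z) <= min(MI(X,Y), MI(Y,Z)), so the weakest edge of a triangle is the
candidate indirect interaction.

This implementation uses a conservative DPI: an edge that is the maximal-MI
edge of any triangle is never removed, so triangle maxima always survive
pruning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin indices in [0, n_bins)."""
    v = np.asarray(v)
    ranks = np.empty(len(v), dtype=np.int64)
    ranks[np.argsort(v, kind="stable")] = np.arange(len(v))
    return ranks * n_bins // len(v)


def mutual_information(
    x: Sequence[float], y: Sequence[float], bins: int | str = "auto"
) -> float:
    """Plug-in mutual information in bits between two sample vectors.

    Vectors are discretized into equal-frequency bins (``floor(sqrt(n))``
    when ``bins='auto'``) and MI = sum p(a,b) log2 p(a,b)/(p(a) p(b)).
    A constant vector yields MI 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sample vectors must have equal length")
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector: MI set to 0")
        return 0.0
    b = int(math.isqrt(n)) if bins == "auto" else int(bins)
    bx = equal_frequency_bins(x, b)
    by = equal_frequency_bins(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    mi = float(
        np.sum(p[mask] * np.log2(p[mask] / np.outer(px, py)[mask]))
    )
    return max(mi, 0.0)


@dataclass
class MINetwork:
    """Undirected weighted gene graph after MI thresholding (and DPI)."""

    graph: nx.Graph
    threshold: float
    dpi_tolerance: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        """Canonical (i<j) sorted edge list with MI in bits."""
        return sorted(
            (min(u, v), max(u, v), d["mi"])
            for u, v, d in self.graph.edges(data=True)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["gene_i", "gene_j", "mi_bits"]
        )


def infer_network(
    data: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 200,
    bins: int | str = "auto",
    seed: int = 0,
) -> MINetwork:
    """Infer an MI network from a sample x gene matrix.

    The significance threshold is the (1 - alpha) quantile of a pooled
    permutation null: for each draw one random gene pair is taken and one
    member permuted.  ``alpha >= 1`` is the degenerate keep-everything
    cutoff (threshold 0).  Deterministic given the seed.
    """
    genes = list(data.columns)
    if len(genes) < 3:
        raise ValueError("network inference needs at least 3 genes")
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 30:
        logger.warning(
            "only %d samples: MI estimates will be noisy (>=30 recommended)", n
        )
    mi = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            mi[(genes[i], genes[j])] = mutual_information(
                x[:, i], x[:, j], bins
            )
    if alpha >= 1.0:
        threshold = 0.0
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for t in range(n_perm):
            i, j = rng.choice(len(genes), size=2, replace=False)
            null[t] = mutual_information(
                x[:, i], rng.permutation(x[:, j]), bins
            )
        threshold = float(np.quantile(null, 1.0 - alpha))
    g = nx.Graph()
    g.add_nodes_from(genes)
    for (u, v), w in mi.items():
        if w >= threshold:
            g.add_edge(u, v, mi=w)
    return MINetwork(graph=g, threshold=threshold)


def apply_dpi(net: MINetwork, tolerance: float = 0.15) -> MINetwork:
    """Prune indirect edges via the data processing inequality.

    For every triangle the weakest edge is marked for removal when its MI
    is below (1 - tolerance) times the smaller of the other two; edges that
    are the maximal-MI edge of any triangle are protected and never
    removed.  All marks are computed on the input graph, then applied, with
    a deterministic sorted scan order.
    """
    g = net.graph
    to_remove: set[tuple[str, str]] = set()
    protected: set[tuple[str, str]] = set()

    def key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    for u, v in sorted(key(*e) for e in g.edges):
        for w in sorted(set(g.neighbors(u)) & set(g.neighbors(v))):
            tri = [key(u, v), key(u, w), key(v, w)]
            mis = [g.edges[e]["mi"] for e in tri]
            top = max(mis)
            for e, m in zip(tri, mis):
                if m == top:
                    protected.add(e)
            low = min(mis)
            weakest = [e for e, m in zip(tri, mis) if m == low]
            if len(weakest) == 1 and low < (1.0 - tolerance) * sorted(mis)[1]:
                to_remove.add(weakest[0])

    pruned = g.copy()
    pruned.remove_edges_from(to_remove - protected)
    return MINetwork(
        graph=pruned, threshold=net.threshold, dpi_tolerance=tolerance
    )


def hub_rank(net: MINetwork) -> list[tuple[str, int]]:
    """Genes by descending degree; ties by summed edge MI, then gene id."""
    g = net.graph
    strength = {
        n: sum(d["mi"] for _, _, d in g.edges(n, data=True)) for n in g.nodes
    }
    return [
        (n, g.degree(n))
        for n in sorted(
            g.nodes, key=lambda n: (-g.degree(n), -strength[n], n)
        )
    ]


def multiedge_partner_count(net: MINetwork, gene_set: Iterable[str]) -> int:
    """Number of genes in ``gene_set`` with degree >= 2 in the network."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    g = net.graph
    return sum(1 for n in gene_set if n in g and g.degree(n) >= 2)


def network_delta(
    net_t0: MINetwork,
    net_t1: MINetwork,
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per gene set: multiedge-partner counts in both networks + change."""
    rows = []
    for name, ids in sets.items():
        ids = list(ids)
        c0 = multiedge_partner_count(net_t0, ids)
        c1 = multiedge_partner_count(net_t1, ids)
        rows.append(
            {"set": name, "count_t0": c0, "count_t1": c1, "change": c1 - c0}
        )
    return pd.DataFrame(rows).set_index("set")


def write_edges(net: MINetwork, path: str | Path) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False)
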