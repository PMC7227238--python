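"""From the score matrix to the Common Substring Network.

Rows of the aggregated score matrix M are compared with Spearman rank
correlation to give the similarity matrix Mr; edges above a correlation
cutoff form the network; remaining components are greedily connected by the
heaviest excluded edges (Kruskal over components); an optional weighted
spring embedding places nodes in the unit square for export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.utils import UnionFind
from scipy.stats import rankdata

from .ars import ScoreMatrix

logger = logging.getLogger(__name__)

ORIGIN_THRESHOLD = "thresholded"
ORIGIN_CONNECT = "connectivity-added"
ORIGIN_MATCHED = "count-matched"


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene x gene Spearman-rho matrix (matrix Mr), diagonal 1."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids),) * 2:
            raise ValueError("correlation matrix shape does not match gene ids")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def rho(self, x: str, y: str) -> float:
        i = self.gene_ids.index(x)
        j = self.gene_ids.index(y)
        return float(self.values[i, j])

    def iter_pairs(self):
        """Yield (gene_i, gene_j, rho) over the upper triangle, i < j in index order."""
        n = len(self.gene_ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.gene_ids[i], self.gene_ids[j], float(self.values[i, j])


def row_spearman_matrix(m: ScoreMatrix) -> CorrelationMatrix:
    """Spearman correlation between every pair of rows of M.

    For a pair (x, y) the self-score entries — columns x and y — are removed
    from both rows before ranking; self-similarity values are scale outliers
    that would otherwise inflate every correlation. Ties get average ranks.
    A constant row after removal yields rho = 0 with a warning.
    """
    n = len(m.gene_ids)
    if n < 3:
        raise ValueError("need at least 3 genes")
    v = m.values
    out = np.eye(n)
    warned = False
    idx = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (idx != i) & (idx != j)
            a = v[i, keep]
            b = v[j, keep]
            ra = rankdata(a)
            rb = rankdata(b)
            sa = ra.std()
            sb = rb.std()
            if sa == 0 or sb == 0:
                if not warned:
                    logger.warning("constant score row after self-score removal; rho set to 0")
                    warned = True
                rho = 0.0
            else:
                rho = float(np.mean((ra - ra.mean()) * (rb - rb.mean())) / (sa * sb))
            out[i, j] = out[j, i] = rho
    return CorrelationMatrix(m.gene_ids, out)


def _pair_key(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


def threshold_edges(c: CorrelationMatrix, cutoff: float) -> nx.Graph:
    """Keep edges with rho >= cutoff; every gene stays as a node."""
    if not (-1 < cutoff <= 1):
        raise ValueError("cutoff must lie in (-1, 1]")
    g = nx.Graph(cutoff=float(cutoff))
    g.add_nodes_from(c.gene_ids)
    for x, y, rho in c.iter_pairs():
        if rho >= cutoff:
            g.add_edge(x, y, weight=rho, origin=ORIGIN_THRESHOLD)
    return g


def density_cutoff(c: CorrelationMatrix, target_density: float) -> float:
    """Largest cutoff whose thresholded graph reaches the target edge density.

    Used to match a control or a second organism's network to a reference
    network's density. Density is relative to n(n-1)/2 possible edges. If the
    target is unattainable the minimum rho is returned with a warning.
    """
    if not (0 < target_density <= 1):
        raise ValueError("target_density must lie in (0, 1]")
    n = len(c.gene_ids)
    rhos = np.sort(c.values[np.triu_indices(n, k=1)])[::-1]
    target = target_density * n * (n - 1) / 2
    # cutting at rhos[k-1] keeps >= k edges (ties included)
    k = math.ceil(target)
    if k > len(rhos):
        logger.warning("target density %.3g unattainable; using min rho", target_density)
        return float(rhos[-1])
    return float(rhos[k - 1])


def connect_components(g: nx.Graph, c: CorrelationMatrix) -> nx.Graph:
    """Greedily connect the graph with the heaviest excluded edges.

    Kruskal's scheme run over components: excluded pairs are visited in
    descending rho (ties broken by the lexicographic gene-id pair) and an
    edge is added only when its endpoints lie in different components,
    stopping at a single component. Exactly (components - 1) edges are added,
    each flagged ``connectivity-added``.
    """
    g = g.copy()
    comps = list(nx.connected_components(g))
    need = len(comps) - 1
    if need == 0:
        return g
    uf = UnionFind(g.nodes)
    for x, y in g.edges:
        uf.union(x, y)
    candidates = sorted(
        ((x, y, rho) for x, y, rho in c.iter_pairs() if not g.has_edge(x, y)),
        key=lambda t: (-t[2], _pair_key(t[0], t[1])),
    )
    added = 0
    for x, y, rho in candidates:
        if uf[x] != uf[y]:
            uf.union(x, y)
            g.add_edge(x, y, weight=rho, origin=ORIGIN_CONNECT)
            added += 1
            if added == need:
                break
    return g


def build_network(
    c: CorrelationMatrix,
    cutoff: float | None = 0.6,
    target_density: float | None = None,
) -> nx.Graph:
    """Threshold then connect: the standard two-step network assembly.

    Either a fixed correlation cutoff (default 0.6) or a target edge density
    from which the cutoff is derived.
    """
    if target_density is not None:
        cutoff = density_cutoff(c, target_density)
    if cutoff is None:
        raise ValueError("provide either cutoff or target_density")
    return connect_components(threshold_edges(c, cutoff), c)


def embed_layout(g: nx.Graph, seed: int = 42,
                 iterations: int = 500) -> dict[str, tuple[float, float]]:
    """Weighted force-directed 2D embedding, min-max scaled to the unit square.

    Attraction grows with edge weight, so strongly correlated genes land
    close together. Deterministic for a given seed. The tight convergence
    threshold lets symmetric graphs reach their symmetric equilibrium.
    """
    pos = nx.spring_layout(g, weight="weight", seed=seed, dim=2,
                           iterations=iterations, threshold=1e-8)
    xy = np.array([pos[n] for n in g.nodes])
    lo = xy.min(axis=0)
    # uniform scale (largest span) so the embedding's geometry is preserved
    span = float((xy.max(axis=0) - lo).max()) or 1.0
    xy = (xy - lo) / span
    return {n: (float(x), float(y)) for n, (x, y) in zip(g.nodes, xy)}


def export_graph(
    g: nx.Graph,
    layout: dict[str, tuple[float, float]] | None,
    prefix,
) -> dict[str, str]:
    """Write the network in Cytoscape-friendly formats.

    Emits ``<prefix>edges.tsv`` (source, target, weight, origin),
    ``<prefix>network.sif``, ``<prefix>network.graphml`` (weights and, when a
    layout is given, x/y coordinates as attributes) and ``<prefix>nodes.tsv``
    (degree and coordinates). Returns the paths written.
    """
    prefix = str(prefix)
    paths = {
        "edges": prefix + "edges.tsv",
        "sif": prefix + "network.sif",
        "graphml": prefix + "network.graphml",
        "nodes": prefix + "nodes.tsv",
    }
    edges = sorted((_pair_key(x, y) + (d["weight"], d["origin"]))
                   for x, y, d in g.edges(data=True))
    with open(paths["edges"], "w") as fh:
        fh.write("source\ttarget\tweight\torigin\n")
        for x, y, w, o in edges:
            fh.write(f"{x}\t{y}\t{w:.10g}\t{o}\n")
    with open(paths["sif"], "w") as fh:
        for x, y, _, _ in edges:
            fh.write(f"{x}\tcsn\t{y}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")
    gx = nx.Graph()
    for n in sorted(g.nodes):
        attrs = {}
        if layout is not None:
            attrs["x"], attrs["y"] = layout[n]
        gx.add_node(n, **attrs)
    for x, y, w, o in edges:
        gx.add_edge(x, y, weight=float(w), origin=o)
    nx.write_graphml(gx, paths["graphml"])
    with open(paths["nodes"], "w") as fh:
        cols = "gene_id\tdegree" + ("\tx\ty" if layout is not None else "") + "\n"
        fh.write(cols)
        for n in sorted(g.nodes):
            row = f"{n}\t{g.degree(n)}"
            if layout is not None:
                row += f"\t{layout[n][0]:.6f}\t{layout[n][1]:.6f}"
            fh.write(row + "\n")
    return paths
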