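"""End-to-end convenience wrappers: sequences in, network out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .ars import ScoreMatrix, score_matrix
from .network import CorrelationMatrix, build_network, row_spearman_matrix
from .randomize import match_edge_count, randomize_genes
from .sequence_io import GeneRecord, RegionConfig, extract_regions


@dataclass
class BuildResult:
    genes: list[GeneRecord]
    scores: ScoreMatrix
    correlations: CorrelationMatrix
    graph: nx.Graph


def build_csn(
    cds: Mapping[str, str],
    promoters: Mapping[str, str] | None = None,
    cfg: RegionConfig | None = None,
    cutoff: float | None = 0.6,
    target_density: float | None = None,
) -> BuildResult:
    """Window, score, correlate, threshold and connect in one call."""
    cfg = cfg or RegionConfig()
    genes = extract_regions(cds, promoters, cfg)
    return build_from_records(genes, cfg, cutoff, target_density)


def build_from_records(
    genes: Sequence[GeneRecord],
    cfg: RegionConfig | None = None,
    cutoff: float | None = 0.6,
    target_density: float | None = None,
) -> BuildResult:
    cfg = cfg or RegionConfig()
    m = score_matrix(genes, cfg)
    c = row_spearman_matrix(m)
    g = build_network(c, cutoff=cutoff, target_density=target_density)
    return BuildResult(list(genes), m, c, g)


def build_ppcsn(
    csn: BuildResult,
    cfg: RegionConfig | None = None,
    seed: int = 0,
    per_sequence_only: bool = False,
) -> BuildResult:
    """Protein-preserving control paired to an already built network.

    Randomizes the windowed genes, reruns the pipeline at the CSN's cutoff,
    then forces the edge count to equality so that every downstream
    comparison sees networks of identical size.
    """
    cfg = cfg or RegionConfig()
    shuffled = randomize_genes(csn.genes, seed=seed, per_sequence_only=per_sequence_only)
    m = score_matrix(shuffled, cfg)
    c = row_spearman_matrix(m)
    g = build_network(c, cutoff=csn.graph.graph.get("cutoff", 0.6))
    g = match_edge_count(g, c, csn.graph.number_of_edges())
    return BuildResult(shuffled, m, c, g)
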