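"""Protein-preserving randomization: the ppCSN control.

The control genome keeps every protein sequence, every gene length, the
global codon usage and the per-promoter nucleotide composition, while
destroying the particular arrangement of synonymous codons and promoter
nucleotides. CDS randomization pools all occurrences of each synonymous
codon class across the whole gene set and permutes them; promoters are
permuted nucleotide-wise within each sequence. Running the standard pipeline
on the shuffled genome, then matching the edge count to the paired CSN,
yields a network that isolates the contribution of 'silent' sequence
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from Bio.Data import CodonTable

from .network import (
    ORIGIN_CONNECT,
    ORIGIN_MATCHED,
    ORIGIN_THRESHOLD,
    CorrelationMatrix,
    _pair_key,
    connect_components,
)
from .sequence_io import GeneRecord, is_valid_token

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map over all 64 codons; stops map to '*'."""

    codon_to_aa: dict[str, str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(mapping)

    def synonymous_classes(self) -> dict[str, tuple[str, ...]]:
        classes: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            classes.setdefault(aa, []).append(codon)
        return {aa: tuple(cs) for aa, cs in classes.items()}

    def translate(self, codons: Sequence[str]) -> str:
        return "".join(self.codon_to_aa.get(c, "X") for c in codons)


def shuffle_synonymous_codons(
    genes: Sequence[GeneRecord],
    code: GeneticCode | None = None,
    seed: int = 0,
) -> list[GeneRecord]:
    """Globally permute synonymous codons across the whole gene set.

    All occurrences of each synonymous class (stops form their own class)
    are pooled over every gene, permuted uniformly, and written back to
    their original (gene, position) slots — so every translated protein and
    the global codon multiset are unchanged. Codons containing ambiguity
    characters stay in place and are excluded from the pool.
    """
    code = code or GeneticCode.standard()
    rng = np.random.default_rng(seed)
    slots: dict[str, list[tuple[int, int]]] = {}
    pool: dict[str, list[str]] = {}
    n_bad = 0
    for gi, g in enumerate(genes):
        for pi, codon in enumerate(g.cds_tokens):
            if not is_valid_token(codon):
                n_bad += 1
                continue
            aa = code.codon_to_aa[codon]
            slots.setdefault(aa, []).append((gi, pi))
            pool.setdefault(aa, []).append(codon)
    if n_bad:
        logger.warning("%d ambiguous codons left in place during shuffle", n_bad)
    new_tokens = [list(g.cds_tokens) for g in genes]
    for aa in sorted(slots):
        codons = pool[aa]
        perm = rng.permutation(len(codons))
        for (gi, pi), k in zip(slots[aa], perm):
            new_tokens[gi][pi] = codons[k]
    return [
        GeneRecord(g.gene_id, "".join(toks), g.promoter_raw)
        for g, toks in zip(genes, new_tokens)
    ]


def permute_nucleotides(promoter: str, seed: int = 0) -> str:
    """Seeded uniform permutation of a sequence's characters.

    Preserves the per-sequence nucleotide multiset and hence GC content.
    """
    rng = np.random.default_rng(seed)
    chars = np.array(list(promoter))
    return "".join(chars[rng.permutation(len(chars))]) if len(chars) else ""


def randomize_genes(
    genes: Sequence[GeneRecord],
    code: GeneticCode | None = None,
    seed: int = 0,
    per_sequence_only: bool = False,
) -> list[GeneRecord]:
    """Full protein-preserving randomization of a gene set.

    Synonymous-codon shuffle over the CDS (global by default; set
    ``per_sequence_only`` to confine the shuffle within each gene for
    sensitivity analysis) plus nucleotide permutation of each promoter.
    """
    if per_sequence_only:
        shuffled: list[GeneRecord] = []
        for k, g in enumerate(genes):
            shuffled.extend(shuffle_synonymous_codons([g], code, seed=seed * 100003 + k))
        cds_done = shuffled
    else:
        cds_done = shuffle_synonymous_codons(genes, code, seed)
    out = []
    for k, g in enumerate(cds_done):
        prom = None
        if g.promoter_raw is not None:
            prom = permute_nucleotides(g.promoter_raw, seed=seed * 100003 + 31 * k + 7)
        out.append(GeneRecord(g.gene_id, g.cds_raw, prom))
    return out


def match_edge_count(pp: nx.Graph, c: CorrelationMatrix, target_edges: int) -> nx.Graph:
    """Force the control network to the paired CSN's exact edge count.

    Too few edges: the highest-rho excluded pairs are added (descending rho,
    lexicographic tie-break), flagged ``count-matched``. Too many: the
    lowest-weight thresholded edges are removed — never connectivity-added
    ones — reconnecting the graph whenever a removal splits it; an edge whose
    removal cannot reduce the count (reconnection restores it) is left alone.
    """
    n = pp.number_of_nodes()
    if target_edges < n - 1:
        raise ValueError("target below the n-1 edges needed for connectivity")
    g = pp.copy()
    have = g.number_of_edges()
    if have < target_edges:
        candidates = sorted(
            ((x, y, rho) for x, y, rho in c.iter_pairs() if not g.has_edge(x, y)),
            key=lambda t: (-t[2], _pair_key(t[0], t[1])),
        )
        for x, y, rho in candidates[: target_edges - have]:
            g.add_edge(x, y, weight=rho, origin=ORIGIN_MATCHED)
    elif have > target_edges:
        frozen: set[tuple[str, str]] = set()
        while g.number_of_edges() > target_edges:
            removable = sorted(
                (d["weight"],) + _pair_key(x, y)
                for x, y, d in g.edges(data=True)
                if d["origin"] == ORIGIN_THRESHOLD and _pair_key(x, y) not in frozen
            )
            if not removable:
                logger.warning("cannot reduce edge count further without breaking connectivity")
                break
            # remove the lightest removable edge; reconnect if that disconnects
            before = g.number_of_edges()
            _, x, y = removable[0]
            g.remove_edge(x, y)
            if not nx.is_connected(g):
                g = connect_components(g, c)
            if g.number_of_edges() >= before:
                # reconnection undid the removal (possibly re-adding the same
                # pair as a bridge); this edge cannot lower the count
                frozen.add(_pair_key(x, y))
    return g
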