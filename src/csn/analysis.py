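"""Evaluation battery for a built network.

Covers the downstream questions the network is meant to answer from sequence
alone: does the degree distribution look scale-free (log-log fit), does node
degree track protein abundance, does combining degree with the codon
adaptation index improve an expression regressor, how many experimentally
measured interactions do the edges recover (sensitivity and ROC/AUC over
edge densities), which functional terms are enriched around each node
(hypergeometric neighborhood test with BH-FDR, a simplified SAFE-style
procedure), and which gene-term annotations does that enrichment predict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .network import CorrelationMatrix, _pair_key
from .randomize import GeneticCode
from .sequence_io import GeneRecord, is_valid_token

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# evaluation side-data


@dataclass
class AnnotationTable:
    """gene -> set of term ids, with optional term names."""

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out

    def has(self, gene: str, term: str) -> bool:
        return term in self.gene_to_terms.get(gene, ())

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_id", "term_id"], dtype=str)
        out: dict[str, set[str]] = {}
        for g, t in zip(df.gene_id, df.term_id):
            out.setdefault(g, set()).add(t)
        return cls(out)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.gene_to_terms):
                for t in sorted(self.gene_to_terms[g]):
                    fh.write(f"{g}\t{t}\n")


def read_expression_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "value"], dtype={"gene_id": str})
    return dict(zip(df.gene_id, df.value.astype(float)))


def read_reference_network(path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b"], dtype=str)
    return {_pair_key(a, b) for a, b in zip(df.a, df.b) if a != b}


# --------------------------------------------------------------------------
# degree statistics


def degree_frequency_fit(g: nx.Graph) -> dict:
    """Log-log correlation between node degree and its frequency.

    A strongly negative correlation on the log-log plot is the classic
    scale-free signature. Computed over the distinct observed degrees only;
    fewer than 2 distinct degrees leaves the correlations undefined (NaN).
    """
    degrees = np.array([d for _, d in g.degree()])
    if (degrees == 0).any():
        raise ValueError("graph has isolated nodes; connect it first")
    vals, counts = np.unique(degrees, return_counts=True)
    points = list(zip(np.log10(vals), np.log10(counts)))
    if len(vals) < 2:
        return {"pearson_rho": math.nan, "pearson_p": math.nan,
                "spearman_rho": math.nan, "spearman_p": math.nan,
                "points": points}
    pr = stats.pearsonr(np.log10(vals), np.log10(counts))
    sr = stats.spearmanr(np.log10(vals), np.log10(counts))
    return {"pearson_rho": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "points": points}


def degree_expression_correlation(g: nx.Graph, expression: Mapping[str, float]) -> dict:
    """Correlate node degree with the expression/abundance measure."""
    shared = sorted(set(g.nodes) & set(expression))
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared between graph and expression table")
    deg = np.array([g.degree(n) for n in shared], dtype=float)
    ab = np.array([expression[n] for n in shared], dtype=float)
    if np.ptp(ab) == 0 or np.ptp(deg) == 0:
        logger.warning("constant degree or abundance; correlation undefined")
        return {"spearman_rho": math.nan, "spearman_p": math.nan,
                "pearson_rho": math.nan, "pearson_p": math.nan, "n_used": len(shared)}
    sr = stats.spearmanr(deg, ab)
    pr = stats.pearsonr(deg, ab)
    return {"spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "pearson_rho": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "n_used": len(shared)}


# --------------------------------------------------------------------------
# codon adaptation index


def compute_cai(genes: Sequence[GeneRecord], code: GeneticCode | None = None) -> dict[str, float]:
    """Codon Adaptation Index of every gene, referenced to the whole input set.

    Relative adaptiveness w_c = count(c) / max count within c's synonymous
    class, with a 0.5 pseudo-count for unobserved codons; CAI is the
    geometric mean of w over a gene's codons, skipping single-codon classes
    (Met, Trp) which carry no choice.
    """
    code = code or GeneticCode.standard()
    counts: dict[str, float] = {c: 0.0 for c in code.codon_to_aa}
    for g in genes:
        for codon in g.cds_tokens:
            if codon in counts:
                counts[codon] += 1.0
    classes = code.synonymous_classes()
    w: dict[str, float] = {}
    eligible: set[str] = set()
    for aa, codons in classes.items():
        cls_counts = {c: (counts[c] if counts[c] > 0 else 0.5) for c in codons}
        top = max(cls_counts.values())
        for c in codons:
            w[c] = cls_counts[c] / top
        if len(codons) > 1:
            eligible |= set(codons)
    out: dict[str, float] = {}
    for g in genes:
        logs = [math.log(w[c]) for c in g.cds_tokens
                if is_valid_token(c) and c in eligible]
        out[g.gene_id] = math.exp(sum(logs) / len(logs)) if logs else math.nan
    return out


def cai_degree_regression(
    g: nx.Graph,
    expression: Mapping[str, float],
    cai: Mapping[str, float],
) -> dict:
    """Expression regressor on (CAI, degree) vs CAI alone.

    Ordinary least squares of log abundance on CAI and degree; reports the
    Spearman correlation of the fitted values with abundance (rho_combined)
    next to the CAI-only correlation (rho_cai).
    """
    import statsmodels.api as sm

    shared = sorted(
        n for n in set(g.nodes) & set(expression) & set(cai)
        if expression[n] > 0 and not math.isnan(cai[n])
    )
    if len(shared) < 10:
        raise ValueError("fewer than 10 usable genes for the regression")
    ab = np.array([expression[n] for n in shared])
    X = np.column_stack([
        [cai[n] for n in shared],
        [g.degree(n) for n in shared],
    ]).astype(float)
    y = np.log(ab)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 3:
        raise ValueError("degenerate design matrix")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    rho_combined = stats.spearmanr(fit.fittedvalues, ab).statistic
    rho_cai = stats.spearmanr(X[:, 0], ab).statistic
    return {"rho_cai": float(rho_cai), "rho_combined": float(rho_combined),
            "n_used": len(shared), "coef": [float(b) for b in fit.params]}


# --------------------------------------------------------------------------
# reference-network comparison


def interaction_overlap(g: nx.Graph, reference: set[tuple[str, str]]) -> dict:
    """Fraction of reference interactions recovered among common genes."""
    common = set(g.nodes) & {x for p in reference for x in p}
    ref = {p for p in reference if p[0] in common and p[1] in common}
    if not ref:
        raise ValueError("no reference interactions left after restriction to common genes")
    edges = {_pair_key(x, y) for x, y in g.edges if x in common and y in common}
    tp = len(edges & ref)
    return {"sensitivity": tp / len(ref), "tp": tp,
            "ref_size": len(ref), "common_genes": len(common)}


def roc_over_densities(c: CorrelationMatrix, reference: set[tuple[str, str]]) -> dict:
    """ROC of rho-ranked gene pairs against measured interactions.

    Every pair in the common gene set is scored by its correlation; sweeping
    the threshold over all distinct rho values traces the ROC, and the AUC
    (trapezoid) equals the tie-aware rank AUC.
    """
    ref_genes = {x for p in reference for x in p}
    common = sorted(set(c.gene_ids) & ref_genes)
    if len(common) < 4:
        raise ValueError("fewer than 4 shared genes")
    cset = set(common)
    scores, labels = [], []
    for x, y, rho in c.iter_pairs():
        if x in cset and y in cset:
            scores.append(rho)
            labels.append(1 if _pair_key(x, y) in reference else 0)
    labels = np.array(labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need both interacting and non-interacting pairs")
    fpr, tpr, _ = roc_curve(labels, np.array(scores))
    return {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
            "auc": float(_trapezoid_auc(fpr, tpr))}


# --------------------------------------------------------------------------
# neighborhood functional enrichment (simplified SAFE)


@dataclass(frozen=True)
class EnrichmentRecord:
    gene_id: str
    term_id: str
    n: int          # neighborhood size
    k: int          # neighborhood genes carrying the term
    N: int          # background (all graph nodes)
    K: int          # background genes carrying the term
    p: float        # hypergeometric upper tail P(X >= k)
    q: float = math.nan   # BH-adjusted
    enriched: bool = False


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def neighborhood_enrichment(
    g: nx.Graph,
    ann: AnnotationTable,
    radius: float = 1,
    alpha: float = 0.05,
    mode: str = "hops",
    layout: Mapping[str, tuple[float, float]] | None = None,
) -> list[EnrichmentRecord]:
    """Per-node functional enrichment of network neighborhoods.

    For each node, the neighborhood is either all nodes within ``radius``
    hops (mode="hops", default radius 1, the node itself included) or all
    nodes within Euclidean distance ``radius`` of its embedded coordinate
    (mode="layout", unit-square coordinates, default radius 0.05 there).
    Each term observed in a neighborhood is tested with the hypergeometric
    upper tail against the whole-graph background, and Benjamini-Hochberg
    correction is applied across all (node, term) tests; records with
    q <= alpha are flagged enriched.
    """
    nodes = sorted(g.nodes)
    N = len(nodes)
    term_count: dict[str, int] = {}
    for node in nodes:
        for t in ann.gene_to_terms.get(node, ()):
            term_count[t] = term_count.get(t, 0) + 1
    if not term_count:
        return []

    records: list[EnrichmentRecord] = []
    for node in nodes:
        if mode == "hops":
            nb = set(nx.single_source_shortest_path_length(g, node, cutoff=int(radius)))
        elif mode == "layout":
            if layout is None:
                raise ValueError("layout mode requires coordinates")
            x0, y0 = layout[node]
            nb = {m for m in nodes
                  if (layout[m][0] - x0) ** 2 + (layout[m][1] - y0) ** 2 <= radius ** 2}
        else:
            raise ValueError(f"unknown neighborhood mode: {mode!r}")
        hits: dict[str, int] = {}
        for m in nb:
            for t in ann.gene_to_terms.get(m, ()):
                hits[t] = hits.get(t, 0) + 1
        for t in sorted(hits):
            k = hits[t]
            records.append(EnrichmentRecord(
                node, t, len(nb), k, N, term_count[t],
                hypergeom_upper_tail(k, N, term_count[t], len(nb)),
            ))
    if not records:
        return []
    pvals = np.array([r.p for r in records])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        EnrichmentRecord(r.gene_id, r.term_id, r.n, r.k, r.N, r.K, r.p,
                         float(q), bool(rej))
        for r, q, rej in zip(records, qvals, reject)
    ]


def predict_annotations(enriched: Sequence[EnrichmentRecord], ann: AnnotationTable) -> dict:
    """Turn enriched (node, term) pairs into annotation predictions.

    Every record flagged enriched proposes its term for its focal gene. The
    success rate is the fraction of proposals already present in the
    annotation table (a precision-like score); proposals absent from the
    table are the novel predictions.
    """
    candidates = sorted({(r.gene_id, r.term_id) for r in enriched if r.enriched})
    if not candidates:
        return {"predictions": [], "novel": [], "success_rate": math.nan}
    known = [c for c in candidates if ann.has(*c)]
    novel = [c for c in candidates if not ann.has(*c)]
    return {"predictions": candidates, "novel": novel,
            "success_rate": len(known) / len(candidates)}
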