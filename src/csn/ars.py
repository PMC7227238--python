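"""Average Repetitive Substring (chimeraARS) scoring over suffix arrays.

The directional score ARS(S, R) scans a target sequence S token by token
(nucleotides for promoters, codons for CDS) and records, for every start
position i, the length l_i of the longest substring of S beginning at i that
also occurs somewhere in the reference R. The score is the mean of the l_i.
The symmetric pair score averages the two directions, and the two regions'
scores are combined by a weighted arithmetic mean into the all-pairs score
matrix M.

Matching is found with a per-sequence suffix array: each l_i is a binary
search for the suffix S[i:] among the sorted suffixes of R, followed by a
longest-common-prefix comparison against the neighbouring suffixes of the
insertion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import GeneRecord, RegionConfig, is_valid_token

Tokens = Sequence[str]


@dataclass(frozen=True)
class SuffixIndex:
    """Suffix array over a token sequence.

    ``sa[k]`` is the start position (0-based) of the k-th suffix in
    lexicographic order, comparing whole tokens (codons compare as 3-char
    strings).
    """

    tokens: tuple[str, ...]
    sa: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("cannot index an empty token sequence")
        n = len(self.tokens)
        order = sorted(range(n), key=lambda i: self.tokens[i:])
        object.__setattr__(self, "sa", tuple(order))


def build_suffix_index(tokens: Tokens) -> SuffixIndex:
    return SuffixIndex(tuple(tokens))


def _valid_run_limits(tokens: Tokens) -> list[int]:
    """limit[i] = index of the first token at or after i that is not plain ACGT.

    A match starting at i can never extend past limit[i] because ambiguous
    tokens match nothing, so the binary search only ever sees the clean
    prefix of each query suffix.
    """
    n = len(tokens)
    limit = [0] * n
    nxt = n
    for i in range(n - 1, -1, -1):
        if not is_valid_token(tokens[i]):
            nxt = i
        limit[i] = nxt
    return limit


def longest_prefix_match(query: Tokens, ref: SuffixIndex, start: int = 0,
                         limit: int | None = None) -> int:
    """Length of the longest prefix of ``query[start:limit]`` occurring in ref.

    ``limit`` defaults to the first ambiguous token at or after ``start``
    (matches cannot cross one). Returns 0 when nothing matches.
    """
    rt = ref.tokens
    sa = ref.sa
    nr = len(rt)
    if limit is None:
        limit = len(query)
        for j in range(start, len(query)):
            if not is_valid_token(query[j]):
                limit = j
                break
    m = limit - start
    if m <= 0:
        return 0

    # Leftmost suffix of ref that is >= the query suffix.
    lo, hi = 0, nr
    while lo < hi:
        mid = (lo + hi) // 2
        s = sa[mid]
        # token-wise compare ref suffix rt[s:] with query[start:limit]
        k = 0
        cmp = 0
        while True:
            if s + k >= nr:
                cmp = -1  # ref suffix is a proper prefix -> smaller
                break
            if k >= m:
                cmp = 1  # query exhausted -> ref suffix larger
                break
            a, b = rt[s + k], query[start + k]
            if a != b:
                cmp = -1 if a < b else 1
                break
            k += 1
        if cmp < 0:
            lo = mid + 1
        else:
            hi = mid

    best = 0
    for pos in (lo - 1, lo):
        if 0 <= pos < nr:
            s = sa[pos]
            k = 0
            kmax = min(m, nr - s)
            while k < kmax and rt[s + k] == query[start + k]:
                k += 1
            if k > best:
                best = k
    return best


def directional_ars(target: Tokens, ref: SuffixIndex) -> float:
    """ARS(S, R): mean longest-match length over every start position of S."""
    n = len(target)
    if n == 0:
        raise ValueError("empty target sequence")
    limits = _valid_run_limits(target)
    total = 0
    for i in range(n):
        total += longest_prefix_match(target, ref, i, limits[i])
    return total / n


def normalized_ars(s: Tokens, r: Tokens) -> float:
    """Symmetric pair score: mean of ARS(S, R) and ARS(R, S)."""
    s = tuple(s)
    r = tuple(r)
    return (directional_ars(s, build_suffix_index(r))
            + directional_ars(r, build_suffix_index(s))) / 2.0


def aggregate_pair(n_utr: float, n_cds: float, cfg: RegionConfig) -> float:
    """Weighted arithmetic mean of the promoter and CDS scores.

    Weights default to the region lengths in nucleotides, giving the coding
    region roughly five times the promoter's weight at the default windows.
    """
    wp, wc = cfg.promoter_weight, cfg.cds_weight
    if wp < 0 or wc < 0:
        raise ValueError("aggregation weights must be >= 0")
    if wp + wc == 0:
        raise ValueError("at least one aggregation weight must be positive")
    return (wp * n_utr + wc * n_cds) / (wp + wc)


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric gene x gene matrix of aggregated pair scores (matrix M).

    Units are mean matched-substring length in tokens. The diagonal holds
    self-scores — these are dropped before row correlation downstream.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids),) * 2:
            raise ValueError("score matrix shape does not match gene ids")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy(dtype=float))


def _pair_score(a: GeneRecord, b: GeneRecord,
                idx_cds: dict[str, SuffixIndex],
                idx_prom: dict[str, SuffixIndex],
                cfg: RegionConfig) -> float:
    n_cds = (directional_ars(a.cds_tokens, idx_cds[b.gene_id])
             + directional_ars(b.cds_tokens, idx_cds[a.gene_id])) / 2.0
    if a.gene_id in idx_prom and b.gene_id in idx_prom:
        n_utr = (directional_ars(a.promoter_tokens, idx_prom[b.gene_id])
                 + directional_ars(b.promoter_tokens, idx_prom[a.gene_id])) / 2.0
        return aggregate_pair(n_utr, n_cds, cfg)
    # missing promoter on either side: CDS-only score
    return n_cds


def score_matrix(genes: Sequence[GeneRecord], cfg: RegionConfig | None = None) -> ScoreMatrix:
    """All-pairs aggregated score matrix M.

    Promoter parts are scored on nucleotide tokens, CDS parts on codon
    tokens, then combined per pair. Deterministic; independent of gene order
    up to simultaneous row/column permutation.
    """
    cfg = cfg or RegionConfig()
    if len(genes) < 3:
        raise ValueError("need at least 3 genes (row correlation requires >= 3)")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    idx_cds = {g.gene_id: build_suffix_index(g.cds_tokens) for g in genes}
    idx_prom = {g.gene_id: build_suffix_index(g.promoter_tokens)
                for g in genes if g.has_promoter and g.promoter_tokens}
    n = len(genes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = _pair_score(genes[i], genes[j], idx_cds, idx_prom, cfg)
            m[i, j] = m[j, i] = s
        m[i, i] = _pair_score(genes[i], genes[i], idx_cds, idx_prom, cfg)
    return ScoreMatrix(tuple(ids), m)
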