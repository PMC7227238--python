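"""FASTA input, region windowing and tokenization.

Genes are represented by two sequence regions scored separately and later
combined: a fixed-length window of the promoter (the nucleotides immediately
upstream of the start codon, tokenized nucleotide-by-nucleotide) and a
fixed-length prefix of the CDS (tokenized codon-by-codon, frame 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def is_valid_token(token: str) -> bool:
    """True if every character of the token is a plain A/C/G/T.

    Tokens containing ambiguity codes (N, Y, ...) are carried through the
    pipeline but never match any token — including an identical one — during
    substring scanning, so runs of N cannot create spurious long matches.
    """
    return not (set(token) - _ACGT)


def tokenize(seq: str, mode: str) -> tuple[str, ...]:
    """Split a nucleotide string into tokens.

    mode="nt" yields one token per nucleotide; mode="codon" yields consecutive
    non-overlapping triplets and requires ``len(seq) % 3 == 0``.
    """
    if mode == "nt":
        return tuple(seq)
    if mode == "codon":
        if len(seq) % 3 != 0:
            raise ValueError(
                f"codon tokenization requires length divisible by 3, got {len(seq)}"
            )
        return tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    raise ValueError(f"unknown tokenization mode: {mode!r}")


@dataclass(frozen=True)
class RegionConfig:
    """Windowing and aggregation-weight settings for the two gene regions.

    The default CDS window is 498 nt — the largest codon-aligned length not
    exceeding 500 — so that codon tokenization is exact; use 249 for the
    shorter prokaryote-style setting. Aggregation weights default to the
    region lengths in nucleotides (100 : 498, roughly 1 : 5), giving the
    coding region about five times the weight of the promoter.
    """

    promoter_window: int = 100
    cds_window: int = 498
    promoter_weight: float | None = None
    cds_weight: float | None = None

    def __post_init__(self) -> None:
        if self.promoter_window < 0:
            raise ValueError("promoter_window must be >= 0")
        if self.cds_window < 3 or self.cds_window % 3 != 0:
            raise ValueError("cds_window must be >= 3 and divisible by 3")
        if self.promoter_weight is None:
            object.__setattr__(self, "promoter_weight", float(self.promoter_window))
        if self.cds_weight is None:
            object.__setattr__(self, "cds_weight", float(self.cds_window))


@dataclass(frozen=True)
class GeneRecord:
    """One gene's windowed promoter and CDS, raw and tokenized."""

    gene_id: str
    cds_raw: str
    promoter_raw: str | None = None
    cds_tokens: tuple[str, ...] = field(init=False)
    promoter_tokens: tuple[str, ...] | None = field(init=False)

    def __post_init__(self) -> None:
        if len(self.cds_raw) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
        if len(self.cds_raw) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        object.__setattr__(self, "cds_tokens", tokenize(self.cds_raw, "codon"))
        object.__setattr__(
            self,
            "promoter_tokens",
            None if self.promoter_raw is None else tokenize(self.promoter_raw, "nt"),
        )

    @property
    def has_promoter(self) -> bool:
        return self.promoter_raw is not None


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{gene_id: sequence}`` map.

    The gene id is the header token before the first whitespace; sequences are
    uppercased; file order is preserved. Duplicate ids are a hard error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate gene id in {path}: {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        logger.warning("no FASTA records found in %s", path)
    return out


def extract_regions(
    cds: Mapping[str, str],
    promoters: Mapping[str, str] | None,
    cfg: RegionConfig | None = None,
) -> list[GeneRecord]:
    """Carve the scoring windows out of full-length sequences.

    CDS: the first ``cds_window`` nucleotides, frame-trimmed to a multiple of
    3; genes shorter than the window keep their full (trimmed) CDS. Promoter:
    the last ``promoter_window`` nucleotides of the supplied upstream
    sequence, i.e. the window adjacent to the start codon. Genes with a CDS
    shorter than one codon are dropped with a warning; genes without a
    promoter record are kept and scored on the CDS alone.
    """
    cfg = cfg or RegionConfig()
    promoters = promoters or {}
    missing = set(promoters) - set(cds)
    if missing:
        raise ValueError(
            f"promoter records without a CDS: {sorted(missing)[:5]}"
        )
    records: list[GeneRecord] = []
    for gene_id, seq in cds.items():
        trimmed = min(cfg.cds_window, 3 * (len(seq) // 3))
        if trimmed < 3:
            logger.warning("dropping %s: CDS shorter than one codon", gene_id)
            continue
        prom = promoters.get(gene_id)
        if prom is not None and cfg.promoter_window > 0:
            prom = prom[-cfg.promoter_window :]
        elif cfg.promoter_window == 0:
            prom = None
        records.append(GeneRecord(gene_id, seq[:trimmed], prom))
    n_noprom = sum(1 for r in records if not r.has_promoter)
    if promoters and n_noprom:
        logger.warning("%d genes lack a promoter; scored on CDS alone", n_noprom)
    return records


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA (deterministic, input order)."""
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for gene_id, seq in items:
            fh.write(f">{gene_id}\n{seq}\n")
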