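"""Ortholog support via filtered reciprocal best hits (RBH).

All-vs-all protein search results (BLAST outfmt-6-style tables) are
reduced to one *best ortholog* per query: among hits whose best HSP has
E-value strictly below 1e-20 and covers at least 30% of **both** the
query and the subject sequence, the hit with the smallest E-value wins
(ties: higher bit score, then lexicographic subject id).  A pair of
sequences that are each other's best ortholog across two genomes is a
reciprocal best pair, the operational ortholog definition used for
cross-species support and conserved-expression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import GeneCall

__all__ = [
    "AlignmentHit",
    "OrthologPair",
    "EVALUE_MAX",
    "MIN_COVERAGE",
    "read_blast_tab",
    "hits_from_table",
    "best_ortholog",
    "best_hits_table",
    "reciprocal_best_pairs",
    "annotate_ortholog_support",
    "pairs_to_table",
    "read_ortholog_table",
]

EVALUE_MAX = 1e-20  # strict: E-value must be smaller than this
MIN_COVERAGE = 0.30  # best HSP must span ≥30% of query AND subject

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    """Best-HSP summary of one query/subject alignment."""

    query_id: str
    subject_id: str
    evalue: float
    hsp_query_span: int
    hsp_subject_span: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query_id}/{self.subject_id}")
        if self.hsp_query_span < 0 or self.hsp_subject_span < 0:
            raise ValueError("negative HSP span")


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    genome_a: str = "A"
    genome_b: str = "B"
    reciprocal: bool = True


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column tabular search result (BLAST ``-outfmt 6``).

    Spans are computed from the alignment coordinate columns of the best
    HSP per (query, subject) pair — the row with the smallest E-value,
    then largest bit score.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    return hits_from_table(df)


def hits_from_table(df: pd.DataFrame) -> list[AlignmentHit]:
    """Reduce a 12-column tabular DataFrame to best-HSP AlignmentHits."""
    hits: dict[tuple[str, str], AlignmentHit] = {}
    for row in df.itertuples(index=False):
        hit = AlignmentHit(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            evalue=float(row.evalue),
            hsp_query_span=abs(int(row.qend) - int(row.qstart)) + 1,
            hsp_subject_span=abs(int(row.send) - int(row.sstart)) + 1,
            bitscore=float(row.bitscore),
        )
        key = (hit.query_id, hit.subject_id)
        prev = hits.get(key)
        if prev is None or (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            hits[key] = hit
    return list(hits.values())


def _qualifies(
    hit: AlignmentHit, query_len: int, subject_lens: Mapping[str, int]
) -> bool:
    if hit.subject_id not in subject_lens:
        raise KeyError(f"no length known for subject sequence {hit.subject_id!r}")
    return (
        hit.evalue < EVALUE_MAX
        and hit.hsp_query_span / query_len >= MIN_COVERAGE
        and hit.hsp_subject_span / subject_lens[hit.subject_id] >= MIN_COVERAGE
    )


def best_ortholog(
    hits_per_query: Sequence[AlignmentHit],
    query_len: int,
    subject_lens: Mapping[str, int],
) -> AlignmentHit | None:
    """Best qualifying hit for one query, or ``None``.

    Qualification: E-value < 1e-20 and best-HSP coverage ≥ 30% of both
    sequences.  Ranking: smallest E-value, then highest bit score, then
    lexicographic subject id.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    qualifying = [h for h in hits_per_query if _qualifies(h, query_len, subject_lens)]
    if not qualifying:
        return None
    return min(qualifying, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def best_hits_table(
    hits: Iterable[AlignmentHit],
    query_lens: Mapping[str, int],
    subject_lens: Mapping[str, int],
) -> dict[str, str]:
    """Map each query to its best ortholog's subject id (one direction)."""
    per_query: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        per_query.setdefault(hit.query_id, []).append(hit)
    best: dict[str, str] = {}
    for query_id, qhits in per_query.items():
        if query_id not in query_lens:
            raise KeyError(f"no length known for query sequence {query_id!r}")
        top = best_ortholog(qhits, query_lens[query_id], subject_lens)
        if top is not None:
            best[query_id] = top.subject_id
    return best


def reciprocal_best_pairs(
    best_ab: Mapping[str, str],
    best_ba: Mapping[str, str],
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[OrthologPair]:
    """Pairs (a, b) with ``best_ab[a] == b`` and ``best_ba[b] == a``, sorted."""
    pairs = [
        OrthologPair(a, b, genome_a, genome_b, reciprocal=True)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return sorted(pairs, key=lambda p: (p.id_a, p.id_b))


def annotate_ortholog_support(
    gene_calls: Iterable[GeneCall],
    support_by_genome: Mapping[str, Iterable[str]],
    union_genomes: Sequence[str] = (),
    protein_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flag each called gene's ortholog support per reference genome.

    ``support_by_genome`` maps a genome name to the ids (proteins if
    ``protein_to_gene`` is given, else genes) with a qualifying ortholog
    there.  ``union_genomes`` names the genomes combined into an
    "either or both" union column (e.g. the Arabidopsis/rice pair).
    """
    supported: dict[str, set[str]] = {}
    for genome, ids in support_by_genome.items():
        genes = {protein_to_gene[i] for i in ids} if protein_to_gene else set(ids)
        supported[genome] = genes
    rows = []
    for call in gene_calls:
        row = {
            "gene_id": call.gene_id,
            "category": call.category,
            "family": call.resolved_family,
        }
        for genome in support_by_genome:
            row[f"ortholog_{genome}"] = call.gene_id in supported[genome]
        if union_genomes:
            row["ortholog_union"] = any(
                call.gene_id in supported[g] for g in union_genomes
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_to_table(pairs: Iterable[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "genome_a": p.genome_a,
                "genome_b": p.genome_b,
                "reciprocal": p.reciprocal,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "genome_a", "genome_b", "reciprocal"],
    )


def read_ortholog_table(path: str | Path) -> list[OrthologPair]:
    """Read a precomputed two-column ortholog table (id_a, id_b)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, usecols=[0, 1])
    return [
        OrthologPair(str(a), str(b), reciprocal=True)
        for a, b in df.itertuples(index=False)
    ]
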