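"""Summary tables: per-family gene counts and support percentages.

Percentages follow the reporting convention of the published annotation
tables: half-up rounding at two decimals for ortholog/expression support
(e.g. 2392 of 2538 TF genes → 94.25%) and one decimal for the
TF+TC-to-genome fraction (e.g. 1979 of 35471 genes → 5.6%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .classify import GeneCall

__all__ = ["SupportSummary", "round_half_up", "percentage", "family_count_table", "support_summary"]


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at the given precision (half-up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """100 × count / total, half-up rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


@dataclass(frozen=True)
class SupportSummary:
    """Support evidence summary for one gene category (TF or TC)."""

    n_genes: int
    n_with_ortholog: int | None = None
    n_expressed: int | None = None
    n_genome_genes: int | None = None
    pct_with_ortholog: float | None = None
    pct_expressed: float | None = None
    pct_of_genome: float | None = None


def support_summary(
    n_genes: int,
    n_with_ortholog: int | None = None,
    n_expressed: int | None = None,
    n_genome_genes: int | None = None,
) -> SupportSummary:
    """Percentages of genes with ortholog / expression support.

    Support percentages are reported at two decimals; the optional
    fraction of the whole genome annotated (``n_genes`` of
    ``n_genome_genes``) at one decimal.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    for name, n in (("n_with_ortholog", n_with_ortholog), ("n_expressed", n_expressed)):
        if n is not None and not (0 <= n <= n_genes):
            raise ValueError(f"{name}={n} outside [0, n_genes={n_genes}]")
    return SupportSummary(
        n_genes=n_genes,
        n_with_ortholog=n_with_ortholog,
        n_expressed=n_expressed,
        n_genome_genes=n_genome_genes,
        pct_with_ortholog=(
            percentage(n_with_ortholog, n_genes) if n_with_ortholog is not None else None
        ),
        pct_expressed=(
            percentage(n_expressed, n_genes) if n_expressed is not None else None
        ),
        pct_of_genome=(
            percentage(n_genes, n_genome_genes, decimals=1)
            if n_genome_genes is not None
            else None
        ),
    )


def family_count_table(gene_calls: Iterable[GeneCall]) -> pd.DataFrame:
    """Per-family gene counts (one row per family present, plus category).

    Counts sum to the total number of called genes.
    """
    counts: dict[tuple[str, str], int] = {}
    for call in gene_calls:
        key = (call.category, call.resolved_family)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"category": cat, "family": fam, "n_genes": n}
        for (cat, fam), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "family", "n_genes"])
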