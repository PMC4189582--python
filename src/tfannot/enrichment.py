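"""Family × tissue expression-enrichment testing.

For every family with more than ``min_family_size`` genes and every
tissue group, a one-sided Fisher's exact test asks whether the family's
genes are over-represented among the genes expressed in that tissue,
relative to a background universe (by default all annotated TF and TC
genes).  The one-sided p-value is the hypergeometric upper tail
P(X ≥ k) with population N, K expressed genes, and m family genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "family_tissue_enrichment",
    "enrichment_heat_table",
    "results_to_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One family × tissue 2×2 test.

    k: family genes expressed in the tissue; m: family genes in the
    universe; K: universe genes expressed in the tissue; N: universe
    size.  ``significant`` means raw p < alpha (no multiple-testing
    correction unless requested).
    """

    family: str
    tissue_group: str
    k: int
    m: int
    K: int
    N: int
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.m <= self.N and self.k <= self.K <= self.N):
            raise ValueError(
                f"inconsistent 2x2 counts k={self.k} m={self.m} K={self.K} N={self.N}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _fisher_upper_tail(k: int, m: int, K: int, N: int) -> float:
    """One-sided (enrichment) Fisher p: P(X >= k), X ~ Hypergeom(N, K, m)."""
    return float(hypergeom.sf(k - 1, N, K, m))


def family_tissue_enrichment(
    membership: Mapping[str, str],
    expressed_in: pd.DataFrame,
    min_family_size: int = 5,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Test every (family, tissue group) cell for expression enrichment.

    Parameters
    ----------
    membership : mapping gene → family
        Family assignment of each annotated gene.
    expressed_in : DataFrame of booleans, genes × tissue groups
        Whether each gene is expressed in each tissue group.
    min_family_size : int
        Families must have **more than** this many genes to be tested
        (default 5, i.e. a family of exactly 5 genes is excluded).
    universe : iterable of gene ids, optional
        Background universe; defaults to all genes in ``membership``
        (all annotated TF and TC genes).
    alpha : float
        Significance level for the ``significant`` flag (raw p < alpha).
    bh_correction : bool
        If True, flag significance on Benjamini–Hochberg adjusted
        p-values instead of raw ones (off by default).
    """
    universe = sorted(set(universe) if universe is not None else set(membership))
    if not universe:
        raise ValueError("empty background universe")
    missing = [g for g in universe if g not in expressed_in.index]
    if missing:
        raise KeyError(
            f"{len(missing)} universe gene(s) missing from expression table, "
            f"e.g. {missing[:5]}"
        )
    N = len(universe)
    flags = expressed_in.loc[universe].astype(bool)

    families: dict[str, list[str]] = {}
    for gene in universe:
        fam = membership.get(gene)
        if fam is not None:
            families.setdefault(fam, []).append(gene)
    for fam, genes in families.items():
        if len(genes) > N:
            raise ValueError(f"family {fam!r} larger than the universe")

    results: list[EnrichmentResult] = []
    for fam in sorted(families):
        genes = families[fam]
        m = len(genes)
        if m <= min_family_size:
            continue
        for tissue in flags.columns:
            K = int(flags[tissue].sum())
            k = int(flags.loc[genes, tissue].sum())
            p = _fisher_upper_tail(k, m, K, N)
            results.append(
                EnrichmentResult(
                    family=fam,
                    tissue_group=str(tissue),
                    k=k,
                    m=m,
                    K=K,
                    N=N,
                    p_value=p,
                    significant=p < alpha,
                )
            )
    if bh_correction and results:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        n = len(ps)
        adj = np.empty(n)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * n / (rank_idx + 1))
            adj[i] = running
        results = [
            EnrichmentResult(
                r.family, r.tissue_group, r.k, r.m, r.K, r.N, r.p_value,
                significant=bool(adj[i] < alpha),
            )
            for i, r in enumerate(results)
        ]
    return results


def enrichment_heat_table(
    results: Sequence[EnrichmentResult],
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Family × tissue p-value matrix with a clustered tissue order.

    Tissue columns are clustered on their p-value profiles (average
    linkage, Euclidean distance); returns the matrix with columns in
    dendrogram leaf order, the leaf order itself, and the linkage matrix
    (``None`` for a single tissue).  The full family × tissue grid must
    be present.
    """
    if not results:
        raise ValueError("no enrichment results given")
    df = pd.DataFrame(
        [(r.family, r.tissue_group, r.p_value) for r in results],
        columns=["family", "tissue_group", "p_value"],
    )
    mat = df.pivot(index="family", columns="tissue_group", values="p_value")
    if mat.isna().any().any():
        missing = [
            (f, t) for f, t in zip(*np.where(mat.isna().to_numpy()))
        ]
        raise ValueError(
            f"incomplete family x tissue grid: {len(missing)} missing cell(s)"
        )
    mat = mat.sort_index().sort_index(axis=1)
    tissues = list(mat.columns)
    if len(tissues) == 1:
        return mat, tissues, None
    Z = linkage(mat.to_numpy().T, method="average", metric="euclidean")
    order = [tissues[i] for i in leaves_list(Z)]
    return mat[order], order, Z


def results_to_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Long-format results table (one row per family × tissue cell)."""
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "tissue_group": r.tissue_group,
                "k_expressed_in_family": r.k,
                "family_size": r.m,
                "K_expressed_in_universe": r.K,
                "universe_size": r.N,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
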