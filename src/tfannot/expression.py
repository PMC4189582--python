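"""Expression evidence and tissue-preference calling.

RNA-seq FPKM matrices are quantile-normalized per dataset, genes are
called *expressed* when they reach FPKM ≥ 1 in at least one sample
(microarray: log2 intensity ≥ 7.65 in at least one condition), and
tissue preference is called under one of two rules:

* **z-score rule** (many-sample compendia): per gene, normalized values
  are standardized across all samples (sample standard deviation); a
  tissue group is preferred when any of its samples reaches z ≥ 3.
* **fold rule** (one value per tissue): a tissue is preferred when its
  value is strictly more than ``factor`` (default 2) times every other
  tissue's value.

Preference conservation between two species is read off reciprocal best
hit pairs whose members are preferential in tissue groups mapping to the
same shared label (e.g. embryonic leaf and leaf at later stage both map
to "Leaf").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .orthology import OrthologPair

__all__ = [
    "ExpressionMatrix",
    "ExpressionCall",
    "FPKM_EXPRESSED_MIN",
    "MICROARRAY_EXPRESSED_MIN",
    "read_expression_tsv",
    "read_sample_groups",
    "quantile_normalize",
    "call_expressed",
    "expressed_by_tissue",
    "preferential_zscore",
    "preferential_fold",
    "conserved_preference",
    "calls_to_table",
]

FPKM_EXPRESSED_MIN = 1.0
MICROARRAY_EXPRESSED_MIN = 7.65
PLATFORMS = ("rnaseq", "microarray")


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with a sample→tissue-group map.

    ``values`` holds FPKM (``platform="rnaseq"``, nonnegative) or log2
    microarray intensities (``platform="microarray"``).  Every sample
    must map to exactly one tissue group and no value may be missing.
    """

    values: pd.DataFrame
    platform: str
    sample_groups: dict[str, str]
    #: optional sample → dataset map; normalization is applied per dataset
    datasets: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unmapped = [s for s in self.values.columns if s not in self.sample_groups]
        if unmapped:
            raise ValueError(f"samples with no tissue group: {unmapped}")
        if self.platform == "rnaseq" and (self.values.values < 0).any():
            raise ValueError("negative FPKM values")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    expressed: bool
    preferred_tissues: frozenset[str]
    rule_used: str

    def __post_init__(self) -> None:
        if self.preferred_tissues and not self.expressed:
            raise ValueError(
                f"{self.gene_id}: preferential but not expressed is inconsistent"
            )


def read_expression_tsv(
    path: str | Path, platform: str, sample_groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Load a genes × samples TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(df, platform, dict(sample_groups))


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Load a sample→tissue-group map TSV (sample_id, tissue_group[, ...])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def _quantile_normalize_block(X: np.ndarray) -> np.ndarray:
    n_genes = X.shape[0]
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns, one dataset at a time.

    Within a normalization unit every column is forced onto the common
    distribution given by the per-rank means of the unit's sorted
    columns; afterwards all columns of the unit hold the same multiset
    of values.  Ties within a column receive the mean of the tied ranks'
    target values (average-rank interpolation).  The operation is
    idempotent and preserves gene/sample labels.

    Normalization units are the datasets of ``m.datasets`` when set
    (datasets are normalized before pooling), else the whole matrix.
    A single-sample matrix (or unit) is returned unchanged.
    """
    n_genes, n_samples = m.values.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single-sample matrix returned unchanged")
        return replace(m, values=m.values.copy())
    units: dict[str, list[str]] = {}
    for s in m.values.columns:
        unit = m.datasets.get(s, "") if m.datasets else ""
        units.setdefault(unit, []).append(s)
    values = m.values.astype(float).copy()
    for cols in units.values():
        if len(cols) < 2:
            continue
        values[cols] = _quantile_normalize_block(values[cols].to_numpy())
    return replace(m, values=values)


def call_expressed(m: ExpressionMatrix) -> pd.Series:
    """Per-gene expressed flag: max over samples ≥ 1 FPKM (RNA-seq) or
    ≥ 7.65 log2 units (microarray); comparisons inclusive."""
    threshold = (
        FPKM_EXPRESSED_MIN if m.platform == "rnaseq" else MICROARRAY_EXPRESSED_MIN
    )
    return m.values.max(axis=1) >= threshold


def expressed_by_tissue(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-(gene, tissue group) expressed flags.

    A gene counts as expressed in a group when it reaches the platform's
    expression threshold in at least one sample of that group.
    """
    threshold = (
        FPKM_EXPRESSED_MIN if m.platform == "rnaseq" else MICROARRAY_EXPRESSED_MIN
    )
    return pd.DataFrame(
        {g: (m.values[m.samples_of(g)].max(axis=1) >= threshold) for g in m.groups}
    )


def preferential_zscore(
    m: ExpressionMatrix, z_thresh: float = 3.0
) -> list[ExpressionCall]:
    """Tissue-preference calls under the z-score rule.

    Per gene, z-scores are computed across **all** samples (mean and
    sample standard deviation, ddof=1); a tissue group is preferred when
    any of its samples reaches ``z >= z_thresh``.  Genes with zero
    variance get no preference.  Requires at least 3 samples.
    """
    if m.values.shape[1] < 3:
        raise ValueError("z-score rule needs at least 3 samples")
    expressed = call_expressed(m)
    X = m.values.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (X - mean) / sd, -np.inf)
    samples = list(m.values.columns)
    group_cols = {g: [samples.index(s) for s in m.samples_of(g)] for g in m.groups}
    calls = []
    for i, gene in enumerate(m.values.index):
        preferred = frozenset(
            g for g, cols in group_cols.items() if (z[i, cols] >= z_thresh).any()
        )
        # an unexpressed gene cannot be called preferential
        if not expressed.iloc[i]:
            preferred = frozenset()
        calls.append(ExpressionCall(str(gene), bool(expressed.iloc[i]), preferred, "zscore"))
    return calls


def preferential_fold(
    m: ExpressionMatrix, factor: float = 2.0
) -> list[ExpressionCall]:
    """Tissue-preference calls under the fold rule (one value per tissue).

    A tissue is preferred when its value is strictly greater than
    ``factor`` times the value in every other tissue.  The matrix must
    carry exactly one sample per tissue group.
    """
    groups = m.groups
    if len(groups) < 2:
        raise ValueError("fold rule needs at least 2 tissues")
    for g in groups:
        if len(m.samples_of(g)) != 1:
            raise ValueError(
                f"fold rule expects exactly one value per tissue; group {g!r} "
                f"has {len(m.samples_of(g))} samples"
            )
    expressed = call_expressed(m)
    tissue_values = pd.DataFrame(
        {g: m.values[m.samples_of(g)[0]] for g in groups}
    )
    calls = []
    for gene, row in tissue_values.iterrows():
        preferred = frozenset(
            g
            for g in groups
            if all(row[g] > factor * row[o] for o in groups if o != g)
        )
        if not expressed.loc[gene]:
            preferred = frozenset()
        calls.append(
            ExpressionCall(str(gene), bool(expressed.loc[gene]), preferred, "fold")
        )
    return calls


def conserved_preference(
    pairs: Iterable[OrthologPair],
    calls_a: Iterable[ExpressionCall],
    calls_b: Iterable[ExpressionCall],
    tissue_map_a: Mapping[str, str],
    tissue_map_b: Mapping[str, str],
) -> list[tuple[str, str, str]]:
    """Conserved tissue preferences across reciprocal best hit pairs.

    Each species' tissue groups are first projected onto shared labels
    (``tissue_map_*``; e.g. both "embryonic leaf" and "leaf at later
    stage" → "Leaf").  A triple ``(gene_a, gene_b, label)`` is emitted
    when both members of a reciprocal pair are preferential in groups
    carrying the same shared label.  Unmapped groups are an error;
    non-reciprocal pairs are ignored.
    """

    def project(
        calls: Iterable[ExpressionCall], tissue_map: Mapping[str, str], side: str
    ) -> dict[str, set[str]]:
        shared: dict[str, set[str]] = {}
        for call in calls:
            labels = set()
            for g in call.preferred_tissues:
                if g not in tissue_map:
                    raise KeyError(f"tissue group {g!r} ({side}) missing from map")
                labels.add(tissue_map[g])
            if labels:
                shared[call.gene_id] = labels
        return shared

    pref_a = project(calls_a, tissue_map_a, "species A")
    pref_b = project(calls_b, tissue_map_b, "species B")
    out = []
    for pair in pairs:
        if not pair.reciprocal:
            continue
        common = pref_a.get(pair.id_a, set()) & pref_b.get(pair.id_b, set())
        for label in sorted(common):
            out.append((pair.id_a, pair.id_b, label))
    return sorted(out)


def calls_to_table(calls: Iterable[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "expressed": c.expressed,
                "preferred_tissues": ",".join(sorted(c.preferred_tissues)),
                "rule": c.rule_used,
            }
            for c in calls
        ],
        columns=["gene_id", "expressed", "preferred_tissues", "rule"],
    )
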