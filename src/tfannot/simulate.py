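"""Deterministic planted-truth fixture generators.

Every pipeline stage can be exercised without downloads: the generators
emit a proteome with planted domain architectures, all-vs-all search
tables with planted reciprocal best pairs, and expression matrices with
planted tissue-preferential genes, each alongside a truth table stating
what a correct analysis must recover.  All generators are pure functions
of (spec, seed): repeat runs are byte-identical.

Design notes
------------
* Proteins are uniform-random amino-acid background with the planted
  domains' ungapped consensus segments (majority consensus of the
  registry's seed alignments) inserted; at fixture scale these score far
  above the registry cutoffs while background never does.
* Expression noise is multiplicative and uniform on
  ``[1 - noise_width, 1 + noise_width]``.  Bounded noise keeps the
  largest background z-score well under 3 regardless of scale, so the
  z-rule's false-flag behaviour is a property of the rule, not of lucky
  seeds.  Planted preferences are placed in the small tissue groups
  ("ear", "tassel" in the default design): a tissue's z-score is capped
  at sqrt((n-s)(n-1)/(s*n)) for a group of s samples among n, so only
  groups that are a small share of the compendium can ever reach z = 3 —
  the same geometry that governs real many-sample compendia.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .registry import Registry

__all__ = [
    "ARCHITECTURE_CLASSES",
    "FixtureSpec",
    "domain_consensus",
    "generate_proteome",
    "generate_expression",
    "generate_ortholog_tables",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ARCHITECTURE_CLASSES = (
    "DBD_only",
    "DBD_plus_AD",
    "DBD_plus_FD",
    "TC_only",
    "background",
)

# Concrete domain plans per architecture class, cycled gene by gene.
# Tied to the demonstration registry's domain/family names; a custom
# registry must supply the same ids or a custom plan.
DEFAULT_PLANS: dict[str, list[tuple[tuple[str, ...], str | None, str | None]]] = {
    # (domains to plant, expected category, expected family)
    "DBD_only": [
        (("WRKY",), "TF", "WRKY"),
        (("Myb_DNA-binding",), "TF", "MYB"),
        (("zf-C2H2",), "TF", "C2H2"),
        (("Homeobox",), "TF", "HB-other"),
        (("B3",), "TF", "B3"),
    ],
    "DBD_plus_AD": [
        (("Homeobox", "START"), "TF", "HD-ZIP"),
        (("B3", "Aux_IAA"), "TF", "ARF"),
    ],
    "DBD_plus_FD": [(("zf-C2H2", "RNase_T"), None, None)],
    "TC_only": [(("Aux_IAA",), "TC", "AUX/IAA")],
    "background": [((), None, None)],
}

DEFAULT_GROUP_SIZES: dict[str, int] = {
    # 7 tissue groups, 30 samples; the inflorescence groups are a small
    # share of the compendium, as in real many-dataset collections.
    "seed": 6,
    "mature_leaf": 6,
    "embryonic_leaf": 5,
    "root": 5,
    "shoot": 4,
    "ear": 2,
    "tassel": 2,
}


@dataclass
class FixtureSpec:
    """Parameters of the planted-truth generators.

    ``n_genes`` gives gene counts per architecture class.  The
    expression design defaults to the 7-group / 30-sample layout with
    planted preferences in the two small inflorescence groups at a 20×
    effect; ``fold_tissues`` drives the one-value-per-tissue design of
    the fold rule.
    """

    seed: int = 0
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {
            "DBD_only": 5,
            "DBD_plus_AD": 2,
            "DBD_plus_FD": 1,
            "TC_only": 1,
            "background": 1,
        }
    )
    isoforms_per_gene: int = 1
    # expression design
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    preferential_tissues: Sequence[str] = ("ear", "tassel")
    fold_tissues: Sequence[str] = ("root", "stem", "leaf", "spica")
    n_expr_genes: int = 100
    n_planted: int = 10
    baseline: float = 5.0
    noise_width: float = 0.3
    effect_size: float = 20.0
    # orthology design
    n_pairs: int = 5
    n_decoys: int = 3
    protein_length: int = 300

    def __post_init__(self) -> None:
        for cls, n in self.n_genes.items():
            if cls not in ARCHITECTURE_CLASSES:
                raise ValueError(f"unknown architecture class {cls!r}")
            if n < 0:
                raise ValueError(f"negative gene count for {cls!r}")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if not (0 <= self.noise_width < 1):
            raise ValueError("noise_width must lie in [0, 1)")


def domain_consensus(registry: Registry, domain_id: str) -> str:
    """Ungapped majority consensus of a domain's seed alignment."""
    path = registry.profile_path(domain_id)
    if path is None or not path.exists():
        raise ValueError(f"domain {domain_id!r} has no seed alignment available")
    seqs = []
    current: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
            current = []
        else:
            current.append(line.strip())
    if current:
        seqs.append("".join(current))
    if not seqs:
        raise ValueError(f"empty alignment for domain {domain_id!r}")
    cols = zip(*seqs)
    consensus = []
    for col in cols:
        residues = [c for c in col if c not in "-."]
        if residues:
            consensus.append(Counter(residues).most_common(1)[0][0])
    return "".join(consensus)


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n))


def generate_proteome(
    spec: FixtureSpec, registry: Registry
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate a proteome with planted domain architectures.

    Returns ``(sequences, isoform_map, truth)`` where ``sequences`` maps
    protein id → amino-acid sequence, ``isoform_map`` maps protein id →
    gene id, and ``truth`` holds one row per gene with its planted
    architecture and the expected classification (category/family, or
    none for background and FD-vetoed architectures).
    """
    rng = np.random.default_rng(spec.seed)
    plans_used: dict[str, int] = {cls: 0 for cls in DEFAULT_PLANS}
    sequences: dict[str, str] = {}
    isoform_map: dict[str, str] = {}
    truth_rows = []
    gene_no = 0
    for cls in ARCHITECTURE_CLASSES:
        n = spec.n_genes.get(cls, 0)
        for _ in range(n):
            plan = DEFAULT_PLANS[cls][plans_used[cls] % len(DEFAULT_PLANS[cls])]
            plans_used[cls] += 1
            domains, category, family = plan
            missing = [d for d in domains if d not in registry.domains]
            if missing:
                raise KeyError(
                    f"architecture {cls!r} references domains absent from the "
                    f"registry: {missing}"
                )
            gene_no += 1
            gene_id = f"g{gene_no:04d}"
            for iso in range(1, spec.isoforms_per_gene + 1):
                protein_id = f"{gene_id}_p{iso}"
                parts = [_random_residues(rng, 40)]
                for d in domains:
                    parts.append(domain_consensus(registry, d))
                    parts.append(_random_residues(rng, 20))
                if not domains:
                    parts.append(_random_residues(rng, 120))
                sequences[protein_id] = "".join(parts)
                isoform_map[protein_id] = gene_id
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "arch_class": cls,
                    "planted_domains": ",".join(domains),
                    "expected_category": category or "",
                    "expected_family": family or "",
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "arch_class",
            "planted_domains",
            "expected_category",
            "expected_family",
        ],
    )
    return sequences, isoform_map, truth


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def generate_expression(
    spec: FixtureSpec, design: str = "zscore"
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an FPKM matrix with planted tissue-preferential genes.

    ``design="zscore"`` uses the grouped many-sample layout
    (``spec.group_sizes``); planted genes have every sample of their
    tissue multiplied by ``spec.effect_size`` and the planting tissue
    cycles over ``spec.preferential_tissues``.  ``design="fold"`` emits
    one value per tissue over ``spec.fold_tissues``.  Returns the matrix
    and a truth table (gene_id, planted_tissue or empty).
    """
    rng = np.random.default_rng(spec.seed + 1)
    if design == "zscore":
        groups: list[tuple[str, str]] = []  # (sample, group)
        for g, size in spec.group_sizes.items():
            for i in range(1, size + 1):
                groups.append((f"{g}_s{i}", g))
        plant_groups = list(spec.preferential_tissues)
        unknown = [g for g in plant_groups if g not in spec.group_sizes]
        n_planted = spec.n_planted
        # each tissue group is one dataset (normalization unit)
        datasets = {s: g for s, g in groups}
    elif design == "fold":
        groups = [(f"{g}_s1", g) for g in spec.fold_tissues]
        plant_groups = list(spec.fold_tissues)
        unknown = []
        # balanced planting: equal share of each sample's upper tail,
        # so cross-sample normalization does not fabricate outliers
        n_planted = (spec.n_planted // len(plant_groups)) * len(plant_groups)
        datasets = None
    else:
        raise ValueError(f"design must be 'zscore' or 'fold', got {design!r}")
    if unknown:
        raise ValueError(f"preferential tissues not in design: {unknown}")
    if n_planted > spec.n_expr_genes:
        raise ValueError("more planted genes than genes")

    samples = [s for s, _ in groups]
    sample_groups = dict(groups)
    genes = [f"g{i:04d}" for i in range(1, spec.n_expr_genes + 1)]
    noise = rng.uniform(
        1 - spec.noise_width, 1 + spec.noise_width, size=(len(genes), len(samples))
    )
    X = spec.baseline * noise
    planted: list[str] = []
    for i in range(n_planted):
        tissue = plant_groups[i % len(plant_groups)]
        cols = [j for j, (_, g) in enumerate(groups) if g == tissue]
        X[i, cols] *= spec.effect_size
        planted.append(tissue)
    values = pd.DataFrame(X, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "planted_tissue": planted + [""] * (len(genes) - len(planted)),
        }
    )
    matrix = ExpressionMatrix(values, "rnaseq", sample_groups, datasets=datasets)
    return matrix, truth


def generate_ortholog_tables(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int], dict[str, int], pd.DataFrame]:
    """Generate paired all-vs-all search tables with planted RBH pairs.

    Returns ``(table_ab, table_ba, lens_a, lens_b, truth)``.  The tables
    are 12-column outfmt-6-style DataFrames.  Planted pairs get mutual
    best hits passing the filter (E ≪ 1e-20, ~90% coverage); decoys get
    hits failing it (E-value too large or coverage too low), so the
    reciprocal-best computation must recover exactly the planted pairs.
    """
    rng = np.random.default_rng(spec.seed + 2)
    L = spec.protein_length
    ids_a = [f"zmA{i:03d}" for i in range(1, spec.n_pairs + spec.n_decoys + 1)]
    ids_b = [f"siB{i:03d}" for i in range(1, spec.n_pairs + spec.n_decoys + 1)]
    lens_a = {i: L for i in ids_a}
    lens_b = {i: L for i in ids_b}
    span_good = int(0.9 * L)
    span_bad = int(0.2 * L)

    def row(q, s, evalue, span, bits):
        return {
            "qseqid": q,
            "sseqid": s,
            "pident": round(float(rng.uniform(40, 95)), 2),
            "length": span,
            "mismatch": int(span * 0.2),
            "gapopen": 1,
            "qstart": 1,
            "qend": span,
            "sstart": 1,
            "send": span,
            "evalue": evalue,
            "bitscore": bits,
        }

    rows_ab, rows_ba, truth_rows = [], [], []
    for i in range(spec.n_pairs + spec.n_decoys):
        a, b = ids_a[i], ids_b[i]
        if i < spec.n_pairs:
            e = 10.0 ** -float(rng.uniform(40, 80))
            bits = float(round(rng.uniform(200, 400), 1))
            rows_ab.append(row(a, b, e, span_good, bits))
            rows_ba.append(row(b, a, e, span_good, bits))
            # a weaker, still-qualifying secondary hit to a wrong partner
            if spec.n_pairs + spec.n_decoys > 1:
                other = ids_b[(i + 1) % (spec.n_pairs + spec.n_decoys)]
                rows_ab.append(row(a, other, 1e-25, span_good, bits / 2))
            truth_rows.append({"id_a": a, "id_b": b})
        elif (i - spec.n_pairs) % 2 == 0:
            # decoy failing the E-value threshold
            rows_ab.append(row(a, b, 1e-10, span_good, 50.0))
            rows_ba.append(row(b, a, 1e-10, span_good, 50.0))
        else:
            # decoy failing the coverage threshold
            rows_ab.append(row(a, b, 1e-40, span_bad, 80.0))
            rows_ba.append(row(b, a, 1e-40, span_bad, 80.0))

    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    table_ab = pd.DataFrame(rows_ab, columns=cols)
    table_ba = pd.DataFrame(rows_ba, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["id_a", "id_b"])
    return table_ab, table_ba, lens_a, lens_b, truth
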