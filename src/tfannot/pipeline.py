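"""End-to-end orchestration of the annotation stages.

:func:`run_pipeline` wires the stages together from a single config
mapping (typically loaded from YAML): simulate (optional fixture
generation), scan (profile build + search + dual-cutoff filter),
classify (family assignment and gene aggregation), orthologs,
expression, enrich and report.  Stage inputs are validated before any
computation; outputs are written as TSV into the output directory with
a provenance header (registry version, seed, package version) and the
run is deterministic for identical inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .classify import (
    aggregate_gene_calls,
    classify_proteins,
    gene_calls_to_table,
    protein_calls_to_table,
)
from .enrichment import enrichment_heat_table, family_tissue_enrichment, results_to_table
from .expression import (
    calls_to_table,
    expressed_by_tissue,
    preferential_fold,
    preferential_zscore,
    quantile_normalize,
    read_expression_tsv,
    read_sample_groups,
)
from .orthology import (
    best_hits_table,
    pairs_to_table,
    read_blast_tab,
    reciprocal_best_pairs,
)
from .registry import Registry, load_demo_registry, load_registry
from .report import family_count_table
from .scan import (
    build_profiles,
    build_protein_profiles,
    filter_hits,
    hits_to_table,
    parse_domtblout,
    scan_proteome,
    write_hits,
)
from .simulate import FixtureSpec, generate_proteome, write_fasta

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "scan", "classify", "orthologs", "expression", "enrich", "report")


class PipelineConfigError(ValueError):
    """A requested stage is missing one of its inputs."""


def _load_registry_from_config(config: Mapping[str, Any]) -> Registry:
    ref = config.get("registry", "demo")
    return load_demo_registry() if ref == "demo" else load_registry(ref)


def _check_inputs(config: Mapping[str, Any], stages: list[str]) -> None:
    produced = set()
    if "simulate" in stages:
        produced |= {"proteome", "isoform_map"}
    for stage in stages:
        if stage == "scan" and "proteome" not in produced:
            if not (config.get("proteome") or config.get("domtblout")):
                raise PipelineConfigError(
                    "scan stage needs 'proteome' (FASTA) or 'domtblout'"
                )
        if stage == "classify":
            if "scan" not in stages:
                raise PipelineConfigError("classify stage needs the scan stage")
        if stage == "orthologs":
            orth = config.get("orthology") or {}
            for key in ("table_ab", "table_ba", "lengths_a", "lengths_b"):
                if key not in orth:
                    raise PipelineConfigError(f"orthologs stage needs orthology.{key}")
        if stage == "expression":
            expr = config.get("expression") or {}
            if "matrix" not in expr or "groups" not in expr:
                raise PipelineConfigError(
                    "expression stage needs expression.matrix and expression.groups"
                )
        if stage == "enrich":
            if not ({"classify", "expression"} <= set(stages)):
                raise PipelineConfigError(
                    "enrich stage needs the classify and expression stages"
                )


def _read_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1])
    return {str(a): int(b) for a, b in df.itertuples(index=False)}


def run_pipeline(
    config: Mapping[str, Any] | str | Path, outdir: str | Path
) -> dict[str, Any]:
    """Run the configured stages and write their artifacts under ``outdir``.

    Returns the in-memory artifacts keyed by name (accepted_hits,
    protein_calls, gene_calls, ortholog_pairs, expression_calls,
    enrichment, family_counts, ... depending on the requested stages).
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise PipelineConfigError(f"unknown stages: {unknown}")
    _check_inputs(config, stages)

    registry = _load_registry_from_config(config)
    seed = int(config.get("seed", 0))
    provenance = (
        f"# tfannot {__version__} | registry {registry.version} | seed {seed}\n"
    )

    def write_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(provenance)
            df.to_csv(fh, sep="\t", index=False)

    artifacts: dict[str, Any] = {"registry": registry}

    proteome_path = config.get("proteome")
    isoform_map: dict[str, str] | None = None
    if config.get("isoform_map"):
        df = pd.read_csv(config["isoform_map"], sep="\t", header=None, comment="#")
        isoform_map = {str(p): str(g) for p, g in df.iloc[:, :2].itertuples(index=False)}

    if "simulate" in stages:
        spec = FixtureSpec(seed=seed, **(config.get("simulate") or {}))
        sequences, isoform_map, truth = generate_proteome(spec, registry)
        proteome_path = outdir / "proteome.fasta"
        write_fasta(sequences, proteome_path)
        write_tsv(
            pd.DataFrame(
                sorted(isoform_map.items()), columns=["protein_id", "gene_id"]
            ),
            "isoform_map.tsv",
        )
        write_tsv(truth, "truth.tsv")
        artifacts["truth"] = truth

    if "scan" in stages:
        if config.get("domtblout"):
            raw = parse_domtblout(config["domtblout"])
        else:
            alignments = [
                registry.profile_path(d)
                for d in registry.domains
                if registry.profile_path(d) is not None
            ]
            profiles = build_profiles(alignments)
            raw = scan_proteome(proteome_path, profiles)
        accepted = filter_hits(raw, registry)
        write_tsv(hits_to_table(accepted, registry), "accepted_hits.tsv")
        artifacts["accepted_hits"] = accepted

    if "classify" in stages:
        profiles_by_protein = build_protein_profiles(artifacts["accepted_hits"], registry)
        protein_calls = classify_proteins(profiles_by_protein, registry)
        if isoform_map is None:
            isoform_map = {c.protein_id: c.protein_id for c in protein_calls}
        gene_calls = aggregate_gene_calls(protein_calls, isoform_map)
        write_tsv(protein_calls_to_table(protein_calls), "protein_calls.tsv")
        write_tsv(gene_calls_to_table(gene_calls), "gene_calls.tsv")
        artifacts["protein_calls"] = protein_calls
        artifacts["gene_calls"] = gene_calls

    if "orthologs" in stages:
        orth = config["orthology"]
        hits_ab = read_blast_tab(orth["table_ab"])
        hits_ba = read_blast_tab(orth["table_ba"])
        lens_a = _read_lengths(orth["lengths_a"])
        lens_b = _read_lengths(orth["lengths_b"])
        best_ab = best_hits_table(hits_ab, lens_a, lens_b)
        best_ba = best_hits_table(hits_ba, lens_b, lens_a)
        pairs = reciprocal_best_pairs(best_ab, best_ba)
        write_tsv(pairs_to_table(pairs), "ortholog_pairs.tsv")
        artifacts["ortholog_pairs"] = pairs

    if "expression" in stages:
        expr = config["expression"]
        groups = read_sample_groups(expr["groups"])
        matrix = read_expression_tsv(
            expr["matrix"], expr.get("platform", "rnaseq"), groups
        )
        if matrix.platform == "rnaseq":
            matrix = quantile_normalize(matrix)
        rule = expr.get("rule", "zscore")
        if rule == "zscore":
            expr_calls = preferential_zscore(matrix)
        elif rule == "fold":
            expr_calls = preferential_fold(matrix)
        else:
            raise PipelineConfigError(f"unknown expression rule {rule!r}")
        write_tsv(calls_to_table(expr_calls), "expression_calls.tsv")
        artifacts["expression_matrix"] = matrix
        artifacts["expression_calls"] = expr_calls

    if "enrich" in stages:
        matrix = artifacts["expression_matrix"]
        flags = expressed_by_tissue(matrix)
        membership = {
            c.gene_id: c.resolved_family
            for c in artifacts["gene_calls"]
            if c.gene_id in flags.index
        }
        results = family_tissue_enrichment(membership, flags)
        write_tsv(results_to_table(results), "enrichment.tsv")
        artifacts["enrichment"] = results
        if results:
            heat, order, _ = enrichment_heat_table(results)
            artifacts["enrichment_heat"] = heat
            artifacts["tissue_order"] = order

    if "report" in stages and "gene_calls" in artifacts:
        counts = family_count_table(artifacts["gene_calls"])
        write_tsv(counts, "family_counts.tsv")
        artifacts["family_counts"] = counts

    return artifacts
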