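"""Shared fixtures: demo registry, built profiles, and an end-to-end
fixture proteome run once per session."""

from __future__ import annotations

import pytest

import tfannot as tf
from tfannot.simulate import write_fasta


@pytest.fixture(scope="session")
def registry():
    return tf.load_demo_registry()


@pytest.fixture(scope="session")
def profiles(registry):
    paths = [registry.profile_path(d) for d in registry.domains]
    return tf.build_profiles([p for p in paths if p is not None])


@pytest.fixture(scope="session")
def e2e(registry, profiles, tmp_path_factory):
    """Scan → filter → classify → aggregate on a 55-gene planted proteome."""
    spec = tf.FixtureSpec(
        seed=11,
        n_genes={
            "DBD_only": 20,
            "DBD_plus_AD": 10,
            "DBD_plus_FD": 8,
            "TC_only": 7,
            "background": 10,
        },
        isoforms_per_gene=2,
    )
    sequences, isoform_map, truth = tf.generate_proteome(spec, registry)
    fasta = tmp_path_factory.mktemp("e2e") / "proteome.fasta"
    write_fasta(sequences, fasta)
    raw = tf.scan_proteome(fasta, profiles)
    accepted = tf.filter_hits(raw, registry)
    protein_profiles = tf.build_protein_profiles(accepted, registry)
    protein_calls = tf.classify_proteins(protein_profiles, registry)
    gene_calls = tf.aggregate_gene_calls(protein_calls, isoform_map)
    return {
        "spec": spec,
        "sequences": sequences,
        "isoform_map": isoform_map,
        "truth": truth,
        "raw": raw,
        "accepted": accepted,
        "protein_calls": protein_calls,
        "gene_calls": gene_calls,
    }
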