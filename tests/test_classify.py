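import pytest

import tfannot as tf
from tfannot.classify import aggregate_gene_calls, classify_protein
from tfannot.scan import DomainHit, ProteinDomainProfile


def profile_from(domain_ids, registry, protein_id="p1"):
    prof = ProteinDomainProfile(protein_id)
    for i, d in enumerate(domain_ids):
        hit = DomainHit(protein_id, d, 1 + 100 * i, 50 + 100 * i, 200.0, 200.0)
        prof.hits.append(hit)
        prof.by_type.setdefault(registry.domain_type(d), []).append(hit)
    return prof


def call_for(domains, registry):
    return classify_protein(profile_from(domains, registry), registry)


class TestRuleEngine:
    def test_homeobox_plus_start_is_hdzip(self, registry):
        """The START auxiliary domain moves a homeobox protein to HD-ZIP."""
        call = call_for(["Homeobox", "START"], registry)
        assert call.category == "TF" and call.family == "HD-ZIP"

    def test_homeobox_alone_stays_in_base_family(self, registry):
        call = call_for(["Homeobox"], registry)
        assert call.category == "TF" and call.family == "HB-other"

    def test_forbidden_domain_vetoes_tf_call(self, registry):
        """C2H2 + RNase_T (a forbidden domain) must yield no TF call."""
        assert call_for(["zf-C2H2", "RNase_T"], registry) is None

    def test_arf_vs_auxiaa_split(self, registry):
        """B3 DBD with the Aux/IAA auxiliary domain is an ARF transcription
        factor; Aux/IAA alone (no DBD) is the AUX/IAA coregulator family."""
        arf = call_for(["B3", "Aux_IAA"], registry)
        assert (arf.category, arf.family) == ("TF", "ARF")
        tc = call_for(["Aux_IAA"], registry)
        assert (tc.category, tc.family) == ("TC", "AUX/IAA")

    def test_single_dbd_single_rule(self, registry):
        call = call_for(["WRKY"], registry)
        assert (call.category, call.family) == ("TF", "WRKY")

    def test_no_domains_no_call(self, registry):
        assert call_for([], registry) is None

    def test_tc_rule_not_evaluated_when_tf_fires(self, registry):
        # B3 + Aux_IAA could superficially satisfy the AUX/IAA TC rule,
        # but a firing TF rule takes precedence.
        call = call_for(["B3", "Aux_IAA"], registry)
        assert call.category == "TF"

    def test_evidence_restricted_to_matched_domains(self, registry):
        call = call_for(["Homeobox", "START"], registry)
        assert {h.domain_id for h in call.evidence} == {"Homeobox", "START"}

    def test_multi_dbd_flags_multi_family(self, registry):
        call = call_for(["WRKY", "Myb_DNA-binding"], registry)
        assert call.multi_family
        # lexicographically first among the maximal candidates
        assert call.family == "MYB"
        assert "WRKY" in call.alternatives


class TestRuleEngineProperties:
    def test_veto_dominance(self, registry):
        """Adding a rule's forbidden domain never creates a call for it."""
        for domains in (["zf-C2H2"], ["Homeobox", "START"], ["WRKY"], ["B3"]):
            before = call_for(domains, registry)
            after = call_for(domains + ["RNase_T"], registry)
            assert before is not None and before.category == "TF"
            assert after is None  # RNase_T is forbidden on every demo TF rule

    def test_auxiliary_specificity_never_removes_tf_status(self, registry):
        """Adding an auxiliary domain may only specialize the family."""
        plain = call_for(["Homeobox"], registry)
        special = call_for(["Homeobox", "START"], registry)
        assert plain.category == special.category == "TF"
        assert special.family == "HD-ZIP"  # strictly more specific rule wins

    def test_determinism_under_rule_reordering(self, registry):
        import dataclasses

        reversed_reg = dataclasses.replace(
            registry, families=list(reversed(registry.families))
        )
        for domains in (["Homeobox", "START"], ["B3", "Aux_IAA"], ["Aux_IAA"]):
            a = call_for(domains, registry)
            b = call_for(domains, reversed_reg)
            assert (a.category, a.family) == (b.category, b.family)


class TestGeneAggregation:
    def make_call(self, protein, family, category="TF"):
        hit = DomainHit(protein, "WRKY", 1, 50, 200, 200)
        return tf.ProteinCall(protein, category, family, family, (hit,))

    def test_two_isoforms_same_family(self):
        calls = [self.make_call("g1_p1", "WRKY"), self.make_call("g1_p2", "WRKY")]
        out = aggregate_gene_calls(calls, {"g1_p1": "g1", "g1_p2": "g1"})
        assert len(out) == 1
        g = out[0]
        assert (g.resolved_family, g.n_isoforms_called) == ("WRKY", 2)

    def test_majority_rule_with_minority_flagged(self):
        calls = [
            self.make_call("g1_p1", "MYB"),
            self.make_call("g1_p2", "MYB"),
            self.make_call("g1_p3", "ARF"),
        ]
        out = aggregate_gene_calls(calls, {f"g1_p{i}": "g1" for i in (1, 2, 3)})
        g = out[0]
        assert g.resolved_family == "MYB"
        assert g.families == frozenset({"MYB", "ARF"})
        assert g.multi_family

    def test_tie_breaks_lexicographically(self):
        calls = [self.make_call("g1_p1", "WRKY"), self.make_call("g1_p2", "MYB")]
        out = aggregate_gene_calls(calls, {"g1_p1": "g1", "g1_p2": "g1"})
        assert out[0].resolved_family == "MYB"

    def test_tf_beats_tc_category(self):
        calls = [
            self.make_call("g1_p1", "AUX/IAA", category="TC"),
            self.make_call("g1_p2", "ARF", category="TF"),
        ]
        out = aggregate_gene_calls(calls, {"g1_p1": "g1", "g1_p2": "g1"})
        assert out[0].category == "TF"
        assert out[0].resolved_family == "ARF"

    def test_no_calls_empty_output(self):
        assert aggregate_gene_calls([], {}) == []

    def test_missing_isoform_mapping_errors(self):
        with pytest.raises(KeyError, match="g1_p1"):
            aggregate_gene_calls([self.make_call("g1_p1", "WRKY")], {})


class TestCountConsistency:
    def test_family_counts_sum_to_total_calls(self, e2e):
        counts = tf.family_count_table(e2e["gene_calls"])
        assert counts["n_genes"].sum() == len(e2e["gene_calls"])
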