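import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfannot as tf
from tfannot.registry import DomainModel, Registry
from tfannot.scan import DomainHit, filter_hits, parse_domtblout
from tfannot.simulate import write_fasta

# fmt: off
DOMTBL = """\
#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name     accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
g0001_p1             -            250 WRKY           -             52   1.2e-30  105.0   0.1   1   1     3e-32   1.5e-30  104.2   0.1     1    52    41    92    41    92 0.98 -
"""
# fmt: on


def small_registry(seq_cut=20.0, dom_cut=22.0):
    return Registry(
        domains={
            "D1": DomainModel("D1", "DBD", sequence_cutoff=seq_cut, domain_cutoff=dom_cut)
        },
        families=[],
        version="t",
    )


def hit(dom_score, seq_score, domain="D1", protein="p1"):
    return DomainHit(protein, domain, 1, 50, dom_score, seq_score)


class TestDomtblout:
    def test_data_row_parsed_comments_skipped(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text(DOMTBL)
        hits = parse_domtblout(path)
        assert len(hits) == 1
        h = hits[0]
        assert h.protein_id == "g0001_p1"
        assert h.domain_id == "WRKY"
        assert (h.env_start, h.env_end) == (41, 92)
        assert h.sequence_score == pytest.approx(105.0)
        assert h.domain_score == pytest.approx(104.2)
        assert h.domain_evalue == pytest.approx(1.5e-30)

    def test_comments_only_gives_empty(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# nothing\n# here\n")
        assert parse_domtblout(path) == []

    def test_truncated_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text("# header\np1 - 250 WRKY -\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_domtblout(path)

    def test_non_numeric_score_reports_line_number(self, tmp_path):
        row = DOMTBL.strip().splitlines()[-1].replace("105.0", "notanumber")
        path = tmp_path / "bad2.domtblout"
        path.write_text(row + "\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_domtblout(path)


class TestFilterHits:
    @pytest.mark.parametrize(
        "dom_score,seq_score,kept",
        [
            (25.0, 30.0, True),   # both thresholds met
            (25.0, 21.0, False),  # fails sequence cutoff
            (19.0, 25.0, False),  # fails domain cutoff
            (20.0, 22.0, True),   # exactly at both cutoffs: inclusive
        ],
    )
    def test_dual_cutoff(self, dom_score, seq_score, kept):
        # domain cutoff 20, sequence cutoff 22
        reg = small_registry(seq_cut=22.0, dom_cut=20.0)
        out = filter_hits([hit(dom_score, seq_score)], reg)
        assert (len(out) == 1) is kept

    def test_unknown_domain_dropped_with_warning(self):
        reg = small_registry()
        with pytest.warns(UserWarning, match="absent from registry"):
            out = filter_hits([hit(99, 99, domain="mystery")], reg)
        assert out == []

    def test_unknown_domain_error_mode(self):
        with pytest.raises(KeyError):
            filter_hits([hit(99, 99, domain="mystery")], small_registry(), unknown="error")

    def test_idempotent_and_order_preserving(self):
        reg = small_registry()
        hits = [hit(30, 30, protein=f"p{i}") for i in range(5)] + [hit(1, 1)]
        once = filter_hits(hits, reg)
        assert filter_hits(once, reg) == once
        assert [h.protein_id for h in once] == [f"p{i}" for i in range(5)]

    @settings(derandomize=True, max_examples=60)
    @given(
        scores=st.lists(
            st.tuples(st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)),
            max_size=20,
        ),
        cut_lo=st.floats(0, 100, allow_nan=False),
        delta=st.floats(0, 50, allow_nan=False),
    )
    def test_raising_cutoffs_shrinks_retained_set(self, scores, cut_lo, delta):
        hits = [hit(d, s, protein=f"p{i}") for i, (d, s) in enumerate(scores)]
        lo = small_registry(seq_cut=cut_lo, dom_cut=cut_lo)
        hi = small_registry(seq_cut=cut_lo + delta, dom_cut=cut_lo + delta)
        kept_lo = {h.protein_id for h in filter_hits(hits, lo)}
        kept_hi = {h.protein_id for h in filter_hits(hits, hi)}
        assert kept_hi <= kept_lo


class TestScanProteome:
    def test_planted_domain_found(self, registry, profiles, tmp_path):
        spec = tf.FixtureSpec(seed=5, n_genes={"DBD_only": 1, "background": 1})
        sequences, _, truth = tf.generate_proteome(spec, registry)
        fasta = tmp_path / "mini.fasta"
        write_fasta(sequences, fasta)
        raw = tf.scan_proteome(fasta, profiles)
        accepted = tf.filter_hits(raw, registry)
        planted = truth.set_index("gene_id").loc["g0001", "planted_domains"]
        assert any(
            h.protein_id == "g0001_p1" and h.domain_id == planted for h in accepted
        )

    def test_background_protein_yields_no_accepted_hit(self, registry, profiles, tmp_path):
        spec = tf.FixtureSpec(seed=5, n_genes={"background": 3})
        sequences, _, _ = tf.generate_proteome(spec, registry)
        fasta = tmp_path / "bg.fasta"
        write_fasta(sequences, fasta)
        accepted = tf.filter_hits(tf.scan_proteome(fasta, profiles), registry)
        assert accepted == []

    def test_empty_proteome_gives_empty_hits(self, profiles, tmp_path):
        fasta = tmp_path / "none.fasta"
        fasta.write_text("")
        assert tf.scan_proteome(fasta, profiles) == []

    def test_hits_carry_both_scores(self, e2e):
        assert all(
            h.domain_score == h.domain_score and h.sequence_score == h.sequence_score
            for h in e2e["raw"]
        )
        assert e2e["raw"]  # nonempty


class TestBuildProfiles:
    def test_profiles_named_by_stem(self, registry):
        paths = [registry.profile_path("WRKY"), registry.profile_path("B3")]
        profs = tf.build_profiles(paths)
        assert set(profs) == {"WRKY", "B3"}

    def test_empty_alignment_file_errors(self, tmp_path):
        bad = tmp_path / "empty.afa"
        bad.write_text("")
        with pytest.raises(ValueError, match="empty.afa"):
            tf.build_profiles([bad])

    def test_identical_sequences_build_valid_profile(self, tmp_path):
        path = tmp_path / "dup.afa"
        path.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKL\n")
        profs = tf.build_profiles([path])
        assert profs["dup"].M == 10


class TestDomainHitInvariants:
    def test_invalid_envelope_rejected(self):
        with pytest.raises(ValueError):
            DomainHit("p", "d", env_start=5, env_end=2, domain_score=1, sequence_score=1)
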