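"""Vector genome model: annotation IO, HIV-1 content, deletion accounting."""

import numpy as np
import pytest

from helpers import hiv1_content_bruteforce, toy_genome

from lvsplicemap import (
    AnnotationError,
    ConfigurationError,
    ConsistencyError,
    Feature,
    VectorGenome,
    build_vector,
    deletion_accounting,
    hiv1_content,
    load_annotation,
    provirus_hiv1_content,
    write_annotation,
)


def _span(name, start, end, origin="HIV1"):
    return Feature(name, start, end, "hiv1_span", origin)


class TestAnnotationIO:
    def test_round_trip(self, plv, tmp_path):
        write_annotation(plv, tmp_path / "v.fa", tmp_path / "v.bed")
        loaded = load_annotation(tmp_path / "v.fa", tmp_path / "v.bed")
        assert loaded.name == plv.name
        assert loaded.length == plv.length
        assert loaded.r3_end == plv.r3_end
        assert loaded.features == plv.features
        assert loaded.sequence == plv.sequence

    def test_start_after_end_rejected_with_line_number(self, tmp_path):
        (tmp_path / "v.fa").write_text(">v\nACGTACGT\n")
        (tmp_path / "v.bed").write_text(
            "v\t0\t1\tSD1\t0\t+\tsplice_donor\tHIV1\nv\t5\t3\tx\t0\t+\tother\tnon-HIV1\n"
        )
        with pytest.raises(AnnotationError, match="line 2"):
            load_annotation(tmp_path / "v.fa", tmp_path / "v.bed")

    def test_missing_sd1_is_configuration_error(self, tmp_path):
        (tmp_path / "v.fa").write_text(">v\nACGTACGT\n")
        (tmp_path / "v.bed").write_text("v\t0\t4\tgag\t0\t+\thiv1_span\tHIV1\n")
        with pytest.raises(ConfigurationError, match="SD1"):
            load_annotation(tmp_path / "v.fa", tmp_path / "v.bed")

    def test_multi_record_fasta_rejected(self, tmp_path):
        (tmp_path / "v.fa").write_text(">a\nACGT\n>b\nACGT\n")
        (tmp_path / "v.bed").write_text("v\t0\t1\tSD1\t0\t+\tsplice_donor\tHIV1\n")
        with pytest.raises(AnnotationError, match="exactly one"):
            load_annotation(tmp_path / "v.fa", tmp_path / "v.bed")

    def test_conflicting_point_features_rejected(self, tmp_path):
        (tmp_path / "v.fa").write_text(">v\n" + "ACGT" * 100 + "\n")
        (tmp_path / "v.bed").write_text(
            "v\t10\t11\tSD1\t0\t+\tsplice_donor\tHIV1\n"
            "v\t10\t11\tCA1\t0\t+\tsplice_acceptor\tHIV1\n"
        )
        with pytest.raises(AnnotationError, match="conflicting point features"):
            load_annotation(tmp_path / "v.fa", tmp_path / "v.bed")


class TestHiv1Content:
    def test_disjoint_gag_env_spans(self):
        g = toy_genome([_span("gag", 700, 1064), _span("env", 1200, 2058)])
        assert hiv1_content(g) == 364 + 858 == 1222

    def test_no_hiv1_features(self):
        g = toy_genome([_span("x", 0, 100, origin="non-HIV1")])
        assert hiv1_content(g) == 0

    def test_overlap_counted_once(self):
        g = toy_genome([_span("a", 100, 200), _span("b", 150, 250)])
        assert hiv1_content(g) == 150
        assert hiv1_content(g) == hiv1_content_bruteforce(g)

    def test_matches_per_base_brute_force_on_random_genomes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            feats = []
            for i in range(rng.integers(0, 8)):
                start = int(rng.integers(0, 900))
                end = start + int(rng.integers(1, 120))
                origin = "HIV1" if rng.random() < 0.7 else "non-HIV1"
                feats.append(_span(f"f{i}", start, end, origin=origin))
            g = toy_genome(feats, length=1200, r3_end=int(rng.integers(400, 1200)))
            assert hiv1_content(g) == hiv1_content_bruteforce(g)
            assert provirus_hiv1_content(g) == hiv1_content_bruteforce(g, g.r3_end)
            assert provirus_hiv1_content(g) <= hiv1_content(g)

    def test_monotone_under_added_feature(self):
        base = [_span("a", 100, 300)]
        g1 = toy_genome(base)
        g2 = toy_genome(base + [_span("b", 250, 400)])
        assert hiv1_content(g2) >= hiv1_content(g1)


class TestDeletionAccounting:
    def test_gag_retains_first_21nt(self):
        parent = toy_genome([_span("gag", 700, 1064)])
        derived = toy_genome([_span("gag", 700, 721)])
        acc = deletion_accounting(parent, derived)
        assert dict(acc.removed_features)["gag"] == 343

    def test_env_reduced_to_rre_with_gag_deletion(self):
        acc = deletion_accounting(build_vector("pLV"), build_vector("pLV-RREgag21"))
        removed = dict(acc.removed_features)
        assert removed["gag"] == 343
        assert removed["env"] == 507
        assert acc.removed_hiv1_nt == 850

    def test_identity(self, plv):
        acc = deletion_accounting(plv, plv)
        assert acc.removed_hiv1_nt == 0
        assert acc.removed_features == []

    def test_derived_feature_longer_than_parent_rejected(self):
        parent = toy_genome([_span("gag", 700, 721)])
        derived = toy_genome([_span("gag", 700, 1064)])
        with pytest.raises(ConsistencyError, match="gag"):
            deletion_accounting(parent, derived)

    def test_total_equals_content_difference_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            spans = []
            for i in range(rng.integers(1, 6)):
                start = int(rng.integers(0, 800))
                spans.append((f"f{i}", start, start + int(rng.integers(10, 150))))
            parent = toy_genome([_span(n, s, e) for n, s, e in spans], length=1000)
            derived_feats = [
                _span(n, s, s + max(1, int(rng.integers(1, e - s + 1))))
                for n, s, e in spans
                if rng.random() < 0.8
            ]
            derived = toy_genome(derived_feats, length=1000)
            acc = deletion_accounting(parent, derived)
            assert acc.removed_hiv1_nt == hiv1_content(parent) - hiv1_content(derived)
            assert sum(n for _, n in acc.removed_features) == acc.removed_hiv1_nt


class TestProvirusContent:
    def test_repositioned_rre_reduces_provirus_by_1201(self):
        acc = deletion_accounting(
            build_vector("pLV"), build_vector("pLV-gag21-3'RRE"), provirus=True
        )
        assert acc.removed_hiv1_nt == 343 + 507 + 351 == 1201
        # in the genomic RNA the RRE is still present: only 850 nt removed
        genomic = deletion_accounting(build_vector("pLV"), build_vector("pLV-gag21-3'RRE"))
        assert genomic.removed_hiv1_nt == 850

    def test_equals_total_content_when_nothing_past_r3(self, plv):
        assert provirus_hiv1_content(plv) == hiv1_content(plv)

    def test_rre_past_r3_excluded(self):
        g = build_vector("pLV-3'RRE")
        rre = g.feature("RRE")
        assert rre.start >= g.r3_end
        assert provirus_hiv1_content(g) == hiv1_content(g) - 351


class TestUnionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    spans = st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=0, max_size=10
    )

    @given(spans)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_union_matches_per_base_count(self, spans):
        feats = [_span(f"f{i}", s, s + l) for i, (s, l) in enumerate(spans)]
        g = toy_genome(feats, length=1100)
        assert hiv1_content(g) == hiv1_content_bruteforce(g)

    @given(spans, st.integers(1, 1100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_provirus_restriction_never_increases_content(self, spans, r3_end):
        feats = [_span(f"f{i}", s, s + l) for i, (s, l) in enumerate(spans)]
        g = toy_genome(feats, length=1100, r3_end=r3_end)
        assert provirus_hiv1_content(g) <= hiv1_content(g)
        assert provirus_hiv1_content(g) == hiv1_content_bruteforce(g, r3_end)


def test_genome_validation():
    with pytest.raises(AnnotationError):
        Feature("SD1", 5, 7, "splice_donor", "HIV1")  # point features are 1 nt
    with pytest.raises(AnnotationError):
        VectorGenome(
            name="v",
            length=50,
            features=[Feature("SD1", 10, 11, "splice_donor", "HIV1"),
                      Feature("x", 0, 100, "other", "non-HIV1")],
            r3_end=50,
        )
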