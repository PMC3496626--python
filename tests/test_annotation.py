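"""Partitioning, best-hit annotation, coverage arithmetic and ORF scanning."""

import random

import pytest
from hypothesis import given, strategies as st

from txome454._util import ValidationError
from txome454.annotation import (
    AnnotationTable,
    AssemblyGroupSummary,
    annotate,
    assess_cds,
    list_coverage,
    list_coverage_int_percent,
    merge_summaries,
    partition_queries,
    reference_coverage,
)
from txome454.formats import HitRecord


def hit(q, s, e, bit=100.0):
    return HitRecord(q, s, 95.0, 100, 2, 0, 1, 100, 1, 100, e, bit)


def random_hit_table(rng, n_queries=8, n_subjects=5, n_hits=20):
    return [
        hit(
            f"q{rng.randrange(n_queries)}",
            f"g{rng.randrange(n_subjects)}",
            10.0 ** -rng.randrange(0, 60),
            bit=float(rng.randrange(50, 1000)),
        )
        for _ in range(n_hits)
    ]


class TestPartition:
    def test_no_hits_everything_unclustered(self):
        clustered, unclustered = partition_queries([], ["q1", "q2", "q3", "q4", "q5"])
        assert clustered == set() and len(unclustered) == 5

    def test_threshold_is_inclusive_boundary(self):
        hits = [hit("q1", "g1", 1e-25), hit("q2", "g1", 1e-10), hit("q3", "g1", 1e-20)]
        clustered, unclustered = partition_queries(hits, ["q1", "q2", "q3"], 1e-20)
        assert clustered == {"q1", "q3"} and unclustered == {"q2"}

    def test_unknown_query_rejected(self):
        with pytest.raises(ValidationError):
            partition_queries([hit("qX", "g1", 1e-30)], ["q1"])

    def test_matches_brute_force_minimum_evalue(self):
        rng = random.Random(7)
        for _ in range(300):
            hits = random_hit_table(rng)
            queries = [f"q{i}" for i in range(8)]
            thr = 10.0 ** -rng.randrange(0, 50)
            clustered, unclustered = partition_queries(hits, queries, thr)
            for q in queries:
                evs = [h.e_value for h in hits if h.query_id == q]
                expect = bool(evs) and min(evs) <= thr
                assert (q in clustered) == expect
            assert clustered | unclustered == set(queries)
            assert not clustered & unclustered


class TestAnnotate:
    def test_single_hit_assigned(self):
        table = annotate([hit("q1", "g9", 1e-30)])
        assert table.gene_of("q1") == "g9"

    def test_tie_broken_by_bit_score_then_subject(self):
        hits = [hit("q1", "gB", 1e-30, bit=880), hit("q1", "gA", 1e-30, bit=900)]
        assert annotate(hits).gene_of("q1") == "gA"
        hits = [hit("q1", "gB", 1e-30, bit=900), hit("q1", "gA", 1e-30, bit=900)]
        assert annotate(hits).gene_of("q1") == "gA"

    def test_above_threshold_queries_are_unannotated(self):
        table = annotate([hit("q1", "g1", 1e-5)])
        assert table.gene_of("q1") is None and "q1" in table.unannotated

    def test_matches_exhaustive_scan_and_is_order_invariant(self):
        rng = random.Random(11)
        for _ in range(200):
            hits = random_hit_table(rng)
            table = annotate(hits)
            shuffled = hits[:]
            rng.shuffle(shuffled)
            assert annotate(shuffled).assignments == table.assignments
            for q in {h.query_id for h in hits}:
                cands = [h for h in hits if h.query_id == q and h.e_value <= 1e-20]
                if not cands:
                    assert q in table.unannotated
                else:
                    best = min(cands, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
                    assert table.gene_of(q) == best.subject_id


class TestCoverage:
    def test_one_of_four_covered(self):
        table = annotate([hit("q1", "g1", 1e-30)])
        rep = reference_coverage(table, ["g1", "g2", "g3", "g4"])
        assert rep.n_covered_genes == 1 and rep.percent_covered == 25.00

    def test_full_coverage(self):
        table = annotate([hit("q1", "g1", 1e-30), hit("q2", "g2", 1e-30)])
        rep = reference_coverage(table, ["g1", "g2"])
        assert rep.percent_covered == 100.00

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            reference_coverage(annotate([]), [])

    def test_monotone_in_hits(self):
        rng = random.Random(3)
        hits = random_hit_table(rng, n_hits=15)
        reference = [f"g{i}" for i in range(5)]
        rep = reference_coverage(annotate(hits), reference)
        more = hits + [hit("q_extra", "g4", 1e-45)]
        rep2 = reference_coverage(annotate(more), reference)
        assert rep2.n_covered_genes >= rep.n_covered_genes
        assert rep2.n_matched_queries >= rep.n_matched_queries

    def test_matched_query_percent_matches_brute_force(self, default_bundle, default_annotations):
        rep = reference_coverage(default_annotations, default_bundle.reference_genes)
        strong = {h.query_id for h in default_bundle.hits if h.e_value <= 1e-20}
        allq = {h.query_id for h in default_bundle.hits}
        assert rep.n_matched_queries == len(strong)
        assert rep.n_queries == len(allq)


class TestListCoverage:
    def test_omim_scale_percent_is_truncated(self):
        # 1,935 of 2,579 genes covered -> 75.02 (truncation, not rounding)
        genes = [f"g{i}" for i in range(2579)]
        hits = [hit(f"q{i}", f"g{i}", 1e-30) for i in range(1935)]
        n, n_cov, pct = list_coverage(annotate(hits), genes)
        assert (n, n_cov, pct) == (2579, 1935, 75.02)

    def test_pathway_scale_integer_percent_rounds(self):
        assert list_coverage_int_percent(115, 129) == 89

    def test_zero_covered(self):
        n, n_cov, pct = list_coverage(annotate([]), ["g1", "g2", "g3"])
        assert (n_cov, pct) == (0, 0.00)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            list_coverage(annotate([]), [])


class TestMergeSummaries:
    CLUSTERED = AssemblyGroupSummary("clustered", 38750, 31786, 24884, 99283, 132121, 3240337)
    UNCLUSTERED = AssemblyGroupSummary("unclustered", 16108, 12672, 10640, 248877, 57613, 818319)

    def test_study_scale_totals(self):
        combined = merge_summaries(self.CLUSTERED, self.UNCLUSTERED)
        assert combined.n_isotigs == 44458
        assert combined.n_isogroups == 35524
        assert combined.n_contigs == 54858
        assert combined.n_singletons == 348160
        assert combined.n_input_reads == 4058656

    def test_all_zero(self):
        z1 = AssemblyGroupSummary("clustered", 0, 0, 0, 0, 0, 0)
        z2 = AssemblyGroupSummary("unclustered", 0, 0, 0, 0, 0, 0)
        c = merge_summaries(z1, z2)
        assert (c.n_contigs, c.n_isotigs, c.n_isogroups, c.n_singletons) == (0, 0, 0, 0)

    def test_same_label_rejected(self):
        with pytest.raises(ValidationError):
            merge_summaries(self.CLUSTERED, self.CLUSTERED)


def brute_force_longest_orf(seq: str):
    """Oracle: enumerate every ATG/stop pair over the three forward frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops and j > i:
                length = j + 3 - i
                if best is None or length > best:
                    best = length
                break
            j += 3
    return best


class TestAssessCds:
    def test_exact_reference_cds_is_intact(self):
        cds = "ATG" + "GCT" * 30 + "TAA"
        a = assess_cds(cds, reference_cds_length=len(cds))
        assert a.status == "intact_full_length"
        assert a.orf_fraction_of_reference == 1.0
        assert (a.orf_start, a.orf_end) == (0, len(cds))

    def test_poly_n_is_absent(self):
        assert assess_cds("N" * 300, 300).status == "absent"

    def test_short_orf_is_truncated(self):
        seq = "ATG" + "GCT" * 5 + "TAA"  # 21 nt vs 300 reference
        assert assess_cds(seq, 300).status == "truncated_or_utr"

    def test_open_orf_to_sequence_end_is_truncated(self):
        seq = "ATG" + "GCT" * 40  # no stop
        assert assess_cds(seq, 1000).status == "truncated_or_utr"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            assess_cds("", 100)

    def test_longest_orf_matches_brute_force(self):
        rng = random.Random(42)
        for _ in range(400):
            n = rng.randrange(10, 400)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            expect = brute_force_longest_orf(seq)
            a = assess_cds(seq, reference_cds_length=30, min_fraction=0.9)
            if expect is None:
                assert a.orf_start is None
            else:
                assert a.orf_end - a.orf_start == expect

    @given(st.text(alphabet="ACGT", min_size=30, max_size=2000))
    def test_longest_orf_matches_brute_force_property(self, seq):
        expect = brute_force_longest_orf(seq)
        a = assess_cds(seq, reference_cds_length=60)
        got = None if a.orf_start is None else a.orf_end - a.orf_start
        assert got == expect
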