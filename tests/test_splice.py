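"""Global contig ordering, AS event detection, classification, summary."""

import random

import pytest

from txome454.formats import Isogroup, Isotig
from txome454.splice import (
    ASSummary,
    OrderConflictError,
    classify_position,
    detect_events,
    global_contig_order,
    summarize,
)


def tig(tid, contigs):
    return Isotig(tid, tuple((c, "+") for c in contigs))


def group(gid, *isotig_contigs):
    return Isogroup(
        gid, tuple(tig(f"{gid}_t{i}", cs) for i, cs in enumerate(isotig_contigs))
    )


class TestGlobalOrder:
    def test_single_isotig_is_its_own_order(self):
        assert global_contig_order(group("g", ["c1", "c2", "c3"])) == ("c1", "c2", "c3")

    def test_subsequence_isotig_forces_order(self):
        g = group("g", ["c1", "c2", "c3"], ["c1", "c3"])
        assert global_contig_order(g) == ("c1", "c2", "c3")

    def test_novel_contig_inserted_between_anchors(self):
        g = group("g", ["c1", "c3"], ["c1", "c2", "c3"])
        assert global_contig_order(g) == ("c1", "c2", "c3")

    def test_contradictory_order_raises_naming_pair(self):
        g = group("g", ["c1", "c2"], ["c2", "c1"])
        with pytest.raises(OrderConflictError) as exc:
            global_contig_order(g)
        assert set(exc.value.pair) == {"c1", "c2"}

    def test_every_isotig_is_subsequence_of_result(self):
        rng = random.Random(23)
        for _ in range(200):
            universe = [f"c{i}" for i in range(rng.randrange(2, 9))]
            tigs = []
            for t in range(rng.randrange(1, 5)):
                members = [c for c in universe if rng.random() < 0.7]
                if not members:
                    members = [rng.choice(universe)]
                tigs.append(members)
            g = group("g", *tigs)
            order = global_contig_order(g)
            pos = {c: i for i, c in enumerate(order)}
            for t in g.isotigs:
                placed = [pos[c] for c in t.contig_ids]
                assert placed == sorted(placed)
            assert set(order) == g.contig_ids


class TestDetectEvents:
    def test_single_isotig_no_events(self):
        assert detect_events(group("g", ["c1", "c2"])) == []

    def test_skipped_contig_is_one_event(self):
        (ev,) = detect_events(group("g", ["c1", "c2", "c3"], ["c1", "c3"]))
        assert ev.block == ("c2",)
        assert ev.position_class == "internal"

    def test_run_maximality_merges_consecutive_contigs(self):
        (ev,) = detect_events(group("g", ["c1", "c2", "c3", "c4"], ["c1", "c4"]))
        assert ev.block == ("c2", "c3")

    def test_events_disjoint_and_cover_variable_contigs(self):
        g = group(
            "g",
            ["c0", "c1", "c2", "c3", "c4", "c5"],
            ["c1", "c3", "c5"],
            ["c0", "c1", "c3", "c4", "c5"],
        )
        events = detect_events(g)
        covered = [c for ev in events for c in ev.block]
        assert len(covered) == len(set(covered))  # disjoint
        order = global_contig_order(g)
        members = [set(t.contig_ids) for t in g.isotigs]
        variable = {c for c in order if not all(c in m for m in members)}
        assert set(covered) == variable

    def test_isotig_renaming_does_not_change_events(self):
        g1 = group("g", ["c1", "c2", "c3"], ["c1", "c3"])
        g2 = Isogroup(
            "g",
            tuple(
                Isotig(f"zz{i}", t.members) for i, t in enumerate(g1.isotigs)
            ),
        )
        e1 = [(e.block, e.position_class) for e in detect_events(g1)]
        e2 = [(e.block, e.position_class) for e in detect_events(g2)]
        assert e1 == e2

    def test_matches_exhaustive_enumeration(self):
        """Oracle: for every contiguous span of the global order, keep it
        iff all its contigs share one non-all-ones inclusion vector and
        extending either way changes the vector."""
        rng = random.Random(29)
        checked = 0
        for _ in range(1200):
            universe = [f"c{i}" for i in range(rng.randrange(2, 9))]
            tigs = []
            for t in range(rng.randrange(2, 6)):
                members = [c for c in universe if rng.random() < 0.75]
                if not members:
                    members = [rng.choice(universe)]
                if members not in tigs:
                    tigs.append(members)
            if len(tigs) < 2:
                continue
            g = group("g", *tigs)
            order = global_contig_order(g)
            membership = [set(t.contig_ids) for t in g.isotigs]
            vec = {
                c: tuple(1 if c in m else 0 for m in membership) for c in order
            }
            all_ones = (1,) * len(g.isotigs)
            expect = []
            n = len(order)
            for i in range(n):
                for j in range(i, n):
                    span = order[i : j + 1]
                    vs = {vec[c] for c in span}
                    if len(vs) != 1 or all_ones in vs:
                        continue
                    v = vs.pop()
                    if i > 0 and vec[order[i - 1]] == v:
                        continue
                    if j < n - 1 and vec[order[j + 1]] == v:
                        continue
                    expect.append(span)
            got = [ev.block for ev in detect_events(g)]
            assert got == expect
            checked += 1
        assert checked >= 1000


class TestClassifyPosition:
    def test_block_with_first_contig_is_five_prime(self):
        order = ("c1", "c2", "c3")
        assert classify_position(("c1",), order) == "five_prime"

    def test_block_with_last_contig_only_is_three_prime(self):
        order = ("c1", "c2", "c3")
        assert classify_position(("c3",), order) == "three_prime"

    def test_middle_block_is_internal(self):
        order = ("c1", "c2", "c3")
        assert classify_position(("c2",), order) == "internal"

    def test_block_spanning_both_termini_is_five_prime(self):
        order = ("c1", "c2")
        assert classify_position(("c1", "c2"), order) == "five_prime"


class TestSummarize:
    def test_study_scale_mean_and_fraction(self):
        # printed totals: 6,931 events over 4,314 AS isogroups of 24,884
        s = ASSummary(
            n_isogroups_examined=24884,
            n_as_isogroups=4314,
            n_events=6931,
            counts_by_class={"five_prime": 2270, "three_prime": 2313, "internal": 1727},
            max_events=("AKR1B10", 63),
        )
        assert s.mean_events_per_as_isogroup == 1.60
        assert s.percent_as_isogroups == 17

    def test_no_multi_isotig_groups_flagged(self):
        s = summarize([group("g1", ["c1", "c2"]), group("g2", ["d1"])])
        assert s.n_events == 0
        assert s.no_as_isogroups is True
        assert s.mean_events_per_as_isogroup == 0.00

    def test_aggregation_over_groups(self):
        gs = [
            group("g1", ["a1", "a2", "a3"], ["a1", "a3"]),  # 1 internal event
            group("g2", ["b1", "b2"], ["b2"]),  # 1 five_prime event
            group("g3", ["c1"]),  # single isotig
        ]
        s = summarize(gs)
        assert s.n_isogroups_examined == 3
        assert s.n_as_isogroups == 2
        assert s.n_events == 2
        assert s.counts_by_class == {"five_prime": 1, "three_prime": 0, "internal": 1}
        assert s.max_events == ("g1", 1)  # tie broken lexicographically

    def test_conflicting_group_skipped_unless_strict(self):
        bad = group("bad", ["c1", "c2"], ["c2", "c1"])
        ok = group("ok", ["d1", "d2"], ["d1"])
        s = summarize([bad, ok])
        assert s.n_events == 1
        with pytest.raises(OrderConflictError):
            summarize([bad, ok], strict=True)


class TestSyntheticRecovery:
    def test_planted_events_and_classes_recovered_exactly(self, default_bundle):
        detected = {
            (ev.isogroup_id, ev.block, ev.position_class)
            for g in default_bundle.isogroups
            for ev in detect_events(g)
        }
        assert detected == set(default_bundle.truth.as_events)
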