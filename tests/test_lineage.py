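"""Join/break lineage between input and scaffolded assemblies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scafeval._util import revcomp
from scafeval.assembly import Assembly, Scaffold, detect_gaps
from scafeval.lineage import (
    JoinEvent,
    adjacency_pairs,
    call_breaks,
    call_joins,
    compare_join_sets,
    join_size_classes,
    join_summary,
    median_break_gap_distance,
    place_inputs,
)


def rand_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


class TestPlaceInputs:
    def test_simple_concatenation_join(self, rng):
        s1, s2 = rand_seq(rng, 3000), rand_seq(rng, 2500)
        inp = Assembly("in", [Scaffold("s1", s1), Scaffold("s2", s2)])
        outp = Assembly("out", [Scaffold("o1", s1 + "N" * 100 + s2)])
        ps = place_inputs(inp, outp)
        placed = {(p.input_scaffold, p.orientation, p.output_interval) for p in ps}
        assert ("s1", "+", (1, 3000)) in placed
        assert ("s2", "+", (3101, 5600)) in placed

    def test_reverse_complement_member_gets_minus_orientation(self, rng):
        s1, s2 = rand_seq(rng, 3000), rand_seq(rng, 2500)
        inp = Assembly("in", [Scaffold("s1", s1), Scaffold("s2", s2)])
        outp = Assembly("out", [Scaffold("o1", s1 + "N" * 100 + revcomp(s2))])
        ps = place_inputs(inp, outp)
        orient = {p.input_scaffold: p.orientation for p in ps}
        assert orient == {"s1": "+", "s2": "-"}

    def test_unrelated_assemblies_rejected(self, rng):
        inp = Assembly("in", [Scaffold("s1", rand_seq(rng, 2000))])
        outp = Assembly("out", [Scaffold("o1", rand_seq(rng, 2000))])
        with pytest.raises(ValueError, match="unrelated"):
            place_inputs(inp, outp)

    def test_repeat_contig_flagged_ambiguous(self, rng):
        rep = rand_seq(rng, 1000)
        uniq = rand_seq(rng, 3000)
        inp = Assembly("in", [Scaffold("s1", rep), Scaffold("s2", uniq)])
        outp = Assembly(
            "out", [Scaffold("o1", rep + "N" * 100 + uniq + "N" * 100 + rep)]
        )
        ps = place_inputs(inp, outp)
        assert any(a.startswith("s1:") for a in ps.ambiguous)
        assert {p.input_scaffold for p in ps} == {"s2"}

    def test_broken_contig_placed_as_two_pieces(self, rng):
        """A chimeric contig split by the scaffolder yields one placement per piece."""
        a, b = rand_seq(rng, 4000), rand_seq(rng, 3500)
        inp = Assembly("in", [Scaffold("chim", a + b)])
        outp = Assembly("out", [Scaffold("o1", a), Scaffold("o2", b)])
        ps = place_inputs(inp, outp)
        ivals = sorted(p.input_interval for p in ps)
        assert ivals == [(1, 4000), (4001, 7500)]

    def test_pass_through_scaffold_with_gaps_merges_to_one_placement(self, rng):
        seq = rand_seq(rng, 2000) + "N" * 150 + rand_seq(rng, 2000)
        inp = Assembly("in", [Scaffold("s1", seq)])
        outp = Assembly("out", [Scaffold("o1", seq)])
        ps = place_inputs(inp, outp)
        assert len(ps.placements) == 1
        assert ps.placements[0].input_interval == (1, len(seq))


class TestCallJoinsAndBreaks:
    def test_no_joins_on_pass_through(self, rng):
        seq = rand_seq(rng, 3000)
        inp = Assembly("in", [Scaffold("s1", seq)])
        outp = Assembly("out", [Scaffold("o1", seq)])
        assert call_joins(place_inputs(inp, outp)) == []
        assert call_breaks(place_inputs(inp, outp)) == []

    def test_join_members_ordered_with_gap_between(self, rng):
        s1, s2 = rand_seq(rng, 3000), rand_seq(rng, 2500)
        inp = Assembly("in", [Scaffold("s1", s1), Scaffold("s2", s2)])
        outp = Assembly("out", [Scaffold("o1", s2 + "N" * 100 + s1)])
        gaps, _ = detect_gaps(outp)
        joins = call_joins(place_inputs(inp, outp), gaps)
        assert len(joins) == 1
        assert [m for m, _ in joins[0].members] == ["s2", "s1"]
        assert joins[0].gap_between[0].length == 100

    def test_break_position_and_gap_distance(self, rng):
        left = rand_seq(rng, 5000)
        right = rand_seq(rng, 4000)
        seq = left + "N" * 200 + right
        inp = Assembly("in", [Scaffold("s1", seq)])
        outp = Assembly("out", [Scaffold("o1", left), Scaffold("o2", right)])
        in_gaps, _ = detect_gaps(inp)
        breaks = call_breaks(place_inputs(inp, outp), in_gaps)
        assert len(breaks) == 1
        (pos,) = breaks[0].break_positions
        assert pos == 5000
        assert breaks[0].gap_distances[0] == 1  # break right at the gap edge
        assert median_break_gap_distance(breaks) == 1

    def test_join_summary_counts(self):
        joins = [
            JoinEvent("o1", [("a", "+"), ("b", "+"), ("c", "-")], []),
            JoinEvent("o2", [("d", "+"), ("e", "+")], []),
        ]
        s = join_summary(joins)
        assert s.n_input_scaffolds_joined == 5
        assert s.n_join_events == 2
        assert s.mean_scaffolds_per_join == 2.5


class TestJoinSizeClasses:
    def test_counts_match_direct_filter(self):
        lengths = {"a": 4_765, "b": 50_000, "c": 150_000, "d": 2_000_000}
        asm = Assembly("in", [Scaffold(n, "A" * l) for n, l in lengths.items()])
        joins = [JoinEvent("o1", [(n, "+") for n in lengths], [])]
        table = join_size_classes(joins, asm)
        rows = {r["class"]: r for _, r in table.iterrows()}
        assert rows["all"]["n_scaffolds"] == 4
        assert rows["all"]["min_scaffold"] == 4_765
        assert rows["<100000"]["n_scaffolds"] == 2
        assert rows[">=100000"]["n_scaffolds"] == 2
        assert rows[">=1000000"]["n_scaffolds"] == 1

    def test_all_large_means_empty_small_class(self):
        asm = Assembly("in", [Scaffold(n, "A" * 2_000_000) for n in ("a", "b")])
        joins = [JoinEvent("o1", [("a", "+"), ("b", "+")], [])]
        table = join_size_classes(joins, asm)
        rows = {r["class"]: r for _, r in table.iterrows()}
        assert rows["<100000"]["n_scaffolds"] == 0


class TestCompareJoinSets:
    def test_shared_is_orientation_and_order_blind(self):
        a = [JoinEvent("x", [("s1", "+"), ("s2", "+")], []),
             JoinEvent("y", [("s3", "+"), ("s4", "+")], [])]
        b = [JoinEvent("z", [("s2", "-"), ("s1", "-")], []),
             JoinEvent("w", [("s5", "+"), ("s6", "+")], [])]
        cmp = compare_join_sets(a, b)
        assert cmp.shared_pairs == [frozenset({"s1", "s2"})]
        assert cmp.unique_a == [frozenset({"s3", "s4"})]
        assert cmp.unique_b == [frozenset({"s5", "s6"})]
        assert cmp.shared_input_scaffolds == ["s1", "s2"]

    def test_identical_sets_have_no_uniques(self):
        a = [JoinEvent("x", [("s1", "+"), ("s2", "+")], [])]
        cmp = compare_join_sets(a, a)
        assert cmp.unique_a == [] and cmp.unique_b == []

    @given(
        st.lists(
            st.lists(st.integers(0, 12), min_size=2, max_size=4, unique=True),
            max_size=5,
        ),
        st.lists(
            st.lists(st.integers(0, 12), min_size=2, max_size=4, unique=True),
            max_size=5,
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, mems_a, mems_b):
        a = [JoinEvent(f"a{i}", [(f"s{m}", "+") for m in ms], []) for i, ms in enumerate(mems_a)]
        b = [JoinEvent(f"b{i}", [(f"s{m}", "+") for m in ms], []) for i, ms in enumerate(mems_b)]
        ab = compare_join_sets(a, b)
        ba = compare_join_sets(b, a)
        assert ab.shared_pairs == ba.shared_pairs
        assert ab.unique_a == ba.unique_b
        assert ab.unique_b == ba.unique_a


class TestSimulatedLineage:
    """Ground-truth recovery on the shared small simulation."""

    @pytest.mark.parametrize("tech", ["optical", "proximity"])
    def test_all_planted_joins_recovered(self, sim_bundle, tech):
        from scafeval.simulate import source_name

        res = sim_bundle[tech]
        base = sim_bundle["base"]
        ps = place_inputs(base.assembly, res.assembly)
        rec = adjacency_pairs(call_joins(ps, res.gaps))
        truth = set()
        for j in res.joins:
            truth |= {
                frozenset(source_name(x) for x in p) for p in j.adjacency_pairs()
            }
        assert rec == truth

    def test_planted_chimera_breaks_recovered_exactly(self, sim_bundle):
        from scafeval.simulate import source_name

        res = sim_bundle["proximity"]
        base = sim_bundle["base"]
        ps = place_inputs(base.assembly, res.assembly)
        rec = {
            (b.input_scaffold, p)
            for b in call_breaks(ps)
            for p in b.break_positions
        }
        truth = {(source_name(n), pos) for n, pos in res.executed_breaks}
        assert rec == truth
        assert len(truth) == sim_bundle["config"].n_chimeras

    def test_conservation_each_contig_placed_once(self, sim_bundle):
        base = sim_bundle["base"]
        res = sim_bundle["optical"]
        ps = place_inputs(base.assembly, res.assembly)
        _, contigs = detect_gaps(base.assembly)
        covered = {}
        for p in ps:
            covered.setdefault(p.input_scaffold, 0)
            covered[p.input_scaffold] += p.input_interval[1] - p.input_interval[0] + 1
        for sc in base.assembly:
            assert covered[sc.name] == len(sc.sequence)

    def test_calls_invariant_to_input_order(self, sim_bundle):
        base = sim_bundle["base"]
        res = sim_bundle["proximity"]
        shuffled = Assembly("shuf", list(reversed(base.assembly.scaffolds)))
        p1 = place_inputs(base.assembly, res.assembly)
        p2 = place_inputs(shuffled, res.assembly)
        assert adjacency_pairs(call_joins(p1)) == adjacency_pairs(call_joins(p2))
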