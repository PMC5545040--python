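"""Synteny blocks, join validation, breakpoints, novel sequence."""

import itertools

import numpy as np
import pytest

from scafeval.assembly import Assembly, Scaffold
from scafeval.lineage import JoinEvent, JoinSetComparison
from scafeval.synteny import (
    AlignmentRecord,
    SyntenyBlock,
    chain_blocks,
    classify_join,
    dust_score,
    find_breakpoints,
    is_low_complexity,
    is_tandem,
    novel_genes,
    novel_sequence,
    rate_difference,
    read_paf,
    validation_rates,
    write_paf,
)


def rec(query, qs, qe, target, ts, te, strand="+", matches=None, q_len=10_000_000, t_len=50_000_000):
    return AlignmentRecord(
        query, q_len, qs, qe, strand, target, t_len, ts, te,
        matches if matches is not None else qe - qs + 1,
    )


def block(query, qs, qe, target, ts, te, strand="+"):
    return SyntenyBlock(query, qs, qe, target, ts, te, strand, 1, qe - qs + 1)


class TestChainBlocks:
    def test_collinear_records_form_single_block(self):
        recs = [
            rec("q", 1, 10_000, "chr4", 100_000, 110_000),
            rec("q", 12_000, 20_000, "chr4", 112_000, 120_000),
            rec("q", 25_000, 40_000, "chr4", 125_000, 140_000),
        ]
        blocks = chain_blocks(recs)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.q_start, b.q_end, b.n_records) == (1, 40_000, 3)

    def test_alternating_targets_never_mix(self):
        recs = [
            rec("q", 1, 10_000, "chr4", 1, 10_000),
            rec("q", 11_000, 20_000, "chr8", 1, 10_000),
            rec("q", 21_000, 30_000, "chr4", 20_000, 30_000),
            rec("q", 31_000, 40_000, "chr8", 20_000, 30_000),
        ]
        blocks = chain_blocks(recs)
        assert len(blocks) >= 2
        assert all(len({b.target}) == 1 for b in blocks)

    def test_far_jump_breaks_chain(self):
        recs = [
            rec("q", 1, 10_000, "chr4", 1, 10_000),
            rec("q", 11_000, 20_000, "chr4", 5_000_000, 5_010_000),
        ]
        assert len(chain_blocks(recs)) == 2

    def test_minus_strand_chains_descending_target(self):
        recs = [
            rec("q", 1, 10_000, "chr4", 90_000, 100_000, "-"),
            rec("q", 12_000, 20_000, "chr4", 78_000, 88_000, "-"),
        ]
        blocks = chain_blocks(recs)
        assert len(blocks) == 1 and blocks[0].strand == "-"

    def test_best_chain_matches_exhaustive_oracle(self):
        """DP chaining equals brute-force best collinear subset (aligned bases)."""
        rng = np.random.default_rng(8)
        max_gap = 50_000
        for trial in range(25):
            n = int(rng.integers(2, 9))
            recs = []
            for _ in range(n):
                qs = int(rng.integers(1, 200_000))
                ln = int(rng.integers(1_000, 20_000))
                ts = int(rng.integers(1, 250_000))
                recs.append(rec("q", qs, qs + ln, "chr1", ts, ts + ln))
            best = 0
            for r in range(1, n + 1):
                for combo in itertools.combinations(sorted(recs, key=lambda r: r.q_start), r):
                    ok = all(
                        b.q_start > a.q_end
                        and b.q_start - a.q_end - 1 <= max_gap
                        and b.t_start > a.t_end
                        and b.t_start - a.t_end - 1 <= max_gap
                        for a, b in zip(combo, combo[1:])
                    )
                    if ok:
                        best = max(best, sum(r.matches for r in combo))
            blocks = chain_blocks(recs, max_join_gap=max_gap, min_block=1)
            assert blocks and max(b.aligned_bases for b in blocks) == best

    def test_paf_round_trip(self, tmp_path):
        recs = [rec("q", 5, 1000, "chr1", 101, 1096), rec("q", 2000, 3000, "chr2", 1, 1001, "-")]
        write_paf(recs, tmp_path / "a.paf")
        back = read_paf(tmp_path / "a.paf")
        assert [(r.query, r.q_start, r.q_end, r.target, r.t_start, r.t_end, r.strand) for r in back] == [
            (r.query, r.q_start, r.q_end, r.target, r.t_start, r.t_end, r.strand) for r in recs
        ]


class TestClassifyJoin:
    def _join(self, *members):
        return JoinEvent("o1", [(m, "+") for m in members], [])

    def test_same_chromosome_members(self):
        blocks = [block("a", 1, 10_000, "chr4", 1, 10_000), block("b", 1, 8_000, "chr4", 50_000, 58_000)]
        v = classify_join(self._join("a", "b"), blocks)
        assert v.verdict == "same" and v.member_chromosomes == ["chr4", "chr4"]

    def test_translocation_join_reads_as_different(self):
        blocks = [block("a", 1, 10_000, "chr4", 1, 10_000), block("b", 1, 8_000, "chr8", 1, 8_000)]
        assert classify_join(self._join("a", "b"), blocks).verdict == "different"

    def test_chromosome_u_member_makes_verdict_unknown(self):
        blocks = [block("a", 1, 10_000, "chr4", 1, 10_000), block("b", 1, 8_000, "U", 1, 8_000)]
        v = classify_join(self._join("a", "b"), blocks)
        assert v.verdict == "unknown" and "U" in v.member_chromosomes

    def test_unaligned_member_is_unassigned(self):
        blocks = [block("a", 1, 10_000, "chr4", 1, 10_000)]
        v = classify_join(self._join("a", "b"), blocks)
        assert v.verdict == "unknown" and v.member_chromosomes[1] == "unassigned"

    def test_no_dominant_chromosome_is_unassigned(self):
        blocks = [
            block("a", 1, 10_000, "chr4", 1, 10_000),
            block("a", 11_001, 21_000, "chr8", 1, 10_000),
            block("b", 1, 8_000, "chr4", 50_000, 58_000),
        ]
        v = classify_join(self._join("a", "b"), blocks)
        assert v.member_chromosomes[0] == "unassigned"

    def test_verdict_invariant_to_member_order_and_strand(self):
        blocks = [
            block("a", 1, 10_000, "chr4", 1, 10_000),
            block("b", 1, 8_000, "chr8", 1, 8_000, "-"),
        ]
        j1 = JoinEvent("o", [("a", "+"), ("b", "-")], [])
        j2 = JoinEvent("o", [("b", "+"), ("a", "-")], [])
        assert classify_join(j1, blocks).verdict == classify_join(j2, blocks).verdict


class TestValidationRates:
    def _vals(self, n_same, n_diff, prefix=""):
        out = []
        for i in range(n_same + n_diff):
            chrom = "chr4" if i < n_same else "chr8"
            j = JoinEvent(f"{prefix}o{i}", [(f"{prefix}a{i}", "+"), (f"{prefix}b{i}", "+")], [])
            blocks = [
                block(f"{prefix}a{i}", 1, 10_000, "chr4", 1, 10_000),
                block(f"{prefix}b{i}", 1, 10_000, chrom, 1, 10_000),
            ]
            out.append(classify_join(j, blocks))
        return out

    def test_overall_and_supported_rates_with_delta(self):
        # 14 joins, 11 same -> 78.57%; supported stratum 11 joins, 10 same -> 90.91%
        vals = self._vals(11, 3)
        shared = [frozenset((f"a{i}", f"b{i}")) for i in list(range(10)) + [11]]
        support = JoinSetComparison(shared, [], [])
        r = validation_rates(vals, support)
        assert r.same_rate_pct == 78.57
        assert r.supported_same_rate_pct == 90.91
        assert r.supported_delta_pct == 12.34

    def test_all_same_is_100_with_zero_delta(self):
        vals = self._vals(5, 0)
        support = JoinSetComparison([frozenset((f"a{i}", f"b{i}")) for i in range(5)], [], [])
        r = validation_rates(vals, support)
        assert r.same_rate_pct == 100.0
        assert r.supported_delta_pct == 0.0

    def test_printed_rate_difference(self):
        assert rate_difference(90.91, 78.57) == 12.34
        assert rate_difference(94.29, 93.75) == 0.54


class TestFindBreakpoints:
    def test_chr4_interval_between_flanks(self):
        blocks = [
            block("scfA", 1, 5_000_000, "chr4", 34_021_788, 39_021_787),
            block("scfA", 5_100_000, 9_000_000, "chr8", 34_275_526, 38_175_525),
            block("scfB", 1, 3_000_000, "chr4", 39_021_892, 42_021_891),
        ]
        bps = find_breakpoints(blocks)
        chr4 = [b for b in bps if b.chromosome == "chr4"]
        assert len(chr4) == 1
        assert (chr4[0].start, chr4[0].end, chr4[0].length) == (39_021_788, 39_021_891, 104)

    def test_chr8_interval_length(self):
        blocks = [
            block("scfA", 1, 5_000_000, "chr8", 28_996_307, 33_996_307),
            block("scfA", 5_100_000, 9_000_000, "chr4", 1, 3_900_001),
            block("scfB", 1, 3_000_000, "chr8", 34_003_973, 37_003_972),
        ]
        bps = find_breakpoints(blocks)
        chr8 = [b for b in bps if b.chromosome == "chr8"]
        assert len(chr8) == 1
        assert (chr8[0].start, chr8[0].end, chr8[0].length) == (33_996_308, 34_003_972, 7_665)

    def test_lengths_follow_inclusive_arithmetic(self):
        bps = find_breakpoints(
            [
                block("q", 1, 1_000_000, "c1", 1, 1_000_000),
                block("q", 1_100_000, 2_000_000, "c2", 1, 900_001),
                block("r", 1, 500_000, "c1", 1_000_101, 1_500_100),
            ]
        )
        assert bps
        for b in bps:
            assert b.length == b.end - b.start + 1 >= 1

    def test_collinear_blocks_produce_no_breakpoints(self):
        blocks = [
            block("q", 1, 1_000_000, "c1", 1, 1_000_000),
            block("q", 1_100_000, 2_000_000, "c1", 1_100_001, 2_000_001),
        ]
        assert find_breakpoints(blocks) == []

    def test_planted_translocation_recovered(self, sim_bundle):
        from scafeval.simulate import truth_alignments

        base = sim_bundle["base"]
        recs = truth_alignments(
            base.provenance, sim_bundle["accession"], base.assembly, sim_bundle["reference"]
        )
        bps = find_breakpoints(chain_blocks(recs))
        truth = {(b.ref_chrom, b.start, b.end) for b in sim_bundle["accession"].breakpoints}
        found = {(b.chromosome, b.start, b.end) for b in bps}
        assert truth == found  # both truth sides of each junction, deduplicated


class TestNovelSequence:
    def test_fully_aligned_assembly_has_no_novel(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 5_000))
        asm = Assembly("t", [Scaffold("s1", seq)])
        recs = [rec("s1", 1, 5_000, "chr1", 1, 5_000, q_len=5_000)]
        rep = novel_sequence(asm, recs)
        assert rep.novel_bases == 0 and rep.aligned_bases == 5_000

    def test_tandem_segment_reclassified(self):
        rng = np.random.default_rng(2)
        left = "".join("ACGT"[c] for c in rng.integers(0, 4, 2_000))
        tandem = "ATATATAT" * 200
        asm = Assembly("t", [Scaffold("s1", left + tandem)])
        recs = [rec("s1", 1, 2_000, "chr1", 1, 2_000, q_len=len(left) + len(tandem))]
        rep = novel_sequence(asm, recs)
        assert rep.removed_bases["tandem_removed"] == len(tandem)
        assert rep.novel_bases == 0

    def test_short_segment_reclassified(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 3_050))
        asm = Assembly("t", [Scaffold("s1", seq)])
        recs = [rec("s1", 1, 1_500, "chr1", 1, 1_500, q_len=3_050),
                rec("s1", 1_551, 3_050, "chr1", 2_001, 3_500, q_len=3_050)]
        rep = novel_sequence(asm, recs, min_segment=100)
        assert rep.removed_bases["short_removed"] == 50

    def test_partition_identity_on_simulation(self, sim_bundle):
        from scafeval.simulate import truth_alignments

        for which in ("base", "optical", "proximity"):
            res = sim_bundle[which]
            asm = res.assembly
            prov = res.provenance
            recs = truth_alignments(
                prov, sim_bundle["accession"], asm, sim_bundle["reference"]
            )
            rep = novel_sequence(asm, recs)
            assert rep.partition_total() == rep.total_bases == asm.total_length

    def test_planted_novel_total_recovered(self, sim_bundle):
        from scafeval.simulate import truth_alignments

        base = sim_bundle["base"]
        recs = truth_alignments(
            base.provenance, sim_bundle["accession"], base.assembly, sim_bundle["reference"]
        )
        rep = novel_sequence(base.assembly, recs)
        truth = sim_bundle["accession"].novel_total
        assert abs(rep.novel_bases + rep.removed_bases["short_removed"] - truth) <= 0.01 * truth

    def test_exclusion_intervals_count_as_aligned(self):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 4_000))
        asm = Assembly("t", [Scaffold("s1", seq)])
        recs = [rec("s1", 1, 2_000, "chr1", 1, 2_000, q_len=4_000)]
        rep = novel_sequence(asm, recs, exclusion=[("s1", 2_001, 4_000)])
        assert rep.novel_bases == 0


class TestFilters:
    def test_dust_scores_separate_random_from_repeats(self):
        rng = np.random.default_rng(5)
        rand = "".join("ACGT"[c] for c in rng.integers(0, 4, 64))
        assert dust_score(rand) < 4
        assert dust_score("A" * 64) > 4
        assert dust_score("AT" * 32) > 4
        assert dust_score("ACG" * 22) > 4

    def test_low_complexity_flags_homopolymer_and_dinucleotide_runs(self):
        rng = np.random.default_rng(6)
        rand = "".join("ACGT"[c] for c in rng.integers(0, 4, 500))
        assert not is_low_complexity(rand)
        assert is_low_complexity("A" * 500)
        assert is_low_complexity("AG" * 250)

    def test_tandem_detector_on_constructed_strings(self):
        rng = np.random.default_rng(7)
        unit = "".join("ACGT"[c] for c in rng.integers(0, 4, 37))
        assert is_tandem(unit * 10)
        assert not is_tandem("".join("ACGT"[c] for c in rng.integers(0, 4, 370)))
        assert not is_tandem(unit * 3)  # too few copies


class TestNovelGenes:
    def _write_gff(self, tmp_path, genes):
        lines = ["##gff-version 3"]
        for gid, scf, cds_list in genes:
            start = min(s for s, _ in cds_list)
            end = max(e for _, e in cds_list)
            lines.append(f"{scf}\ttoy\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
            lines.append(f"{scf}\ttoy\tmRNA\t{start}\t{end}\t.\t+\t.\tID={gid}.t;Parent={gid}")
            for k, (s, e) in enumerate(cds_list):
                lines.append(
                    f"{scf}\ttoy\tCDS\t{s}\t{e}\t.\t+\t0\tID={gid}.c{k};Parent={gid}.t"
                )
        p = tmp_path / "g.gff3"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_strictly_more_than_half_cds_required(self, tmp_path):
        from scafeval.synteny import NovelSegment

        segs = [NovelSegment("s1", 1_000, 2_000, "novel")]
        gff = self._write_gff(
            tmp_path,
            [
                ("fully_inside", "s1", [(1_100, 1_400)]),
                ("exactly_half", "s1", [(1_801, 2_000), (2_001, 2_200)]),
                ("mostly_outside", "s1", [(1_951, 2_000), (2_001, 2_500)]),
                ("elsewhere", "s1", [(5_000, 5_500)]),
            ],
        )
        hits = novel_genes(segs, gff)
        assert hits == ["fully_inside"]

    def test_planted_novel_genes_recovered(self, tmp_path, sim_bundle):
        """Genes written inside known novel segments (and control genes in
        aligned sequence) are recovered exactly."""
        from scafeval.simulate import acc_to_assembly, truth_alignments

        base = sim_bundle["base"]
        acc = sim_bundle["accession"]
        recs = truth_alignments(base.provenance, acc, base.assembly, sim_bundle["reference"])
        rep = novel_sequence(base.assembly, recs)
        big_novel = [s for s in rep.segments if s.klass == "novel" and s.length > 3_000]
        assert len(big_novel) >= 3
        genes = []
        for i, seg in enumerate(big_novel[:3]):
            genes.append((f"novel_gene{i}", seg.scaffold, [(seg.start + 100, seg.start + 700)]))
        # control genes inside aligned (non-novel) space
        ref_seg = acc.segments["acc3"][0]
        locs = acc_to_assembly(
            base.provenance, "acc3", ref_seg.acc_start + 10_000, ref_seg.acc_start + 12_000
        )
        scf, s, _ = locs[0]
        genes.append(("background_gene", scf, [(s, s + 600)]))
        gff = self._write_gff(tmp_path, genes)
        hits = novel_genes(rep.segments, gff)
        assert sorted(hits) == ["novel_gene0", "novel_gene1", "novel_gene2"]
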