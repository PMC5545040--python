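"""Continuity and gap statistics for assemblies.

Provides the classical Nxx family (N50/N90/N10), the *adjusted* N50 variant
that evaluates the cumulative threshold against a fixed genome size instead
of the assembly total (so that assemblies of different sizes are comparable),
captured-gap summaries, and gap-filling before/after accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

from ._util import pct, pct_change, round_half_away
from .assembly import Assembly, GapRecord, detect_gaps

#: Fixed genome size used by default for adjusted N50 comparisons (400 Mb).
DEFAULT_ADJUSTED_GENOME_SIZE = 400_000_000


def nxx(lengths: Sequence[int], x: float, genome_size: int | str = "sum") -> int:
    """Smallest length L such that sequences >= L sum to >= x% of genome_size.

    ``genome_size="sum"`` gives the classical Nxx; a fixed integer gives the
    adjusted variant. Returns 0 when the assembly never reaches x% of the
    genome size (possible only in the adjusted case).
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("non-positive length")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    gs = sum(lengths) if genome_size == "sum" else int(genome_size)
    target100 = x * gs  # compare cum*100 >= x*gs to avoid float division
    cum = 0
    for l in sorted(lengths, reverse=True):
        cum += l
        if cum * 100 >= target100:
            return l
    return 0


@dataclass
class GapStats:
    count: int
    total: int
    min: int | None
    max: int | None
    mean: int | None
    gap_n50: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def gap_stats(gaps: Iterable[GapRecord]) -> GapStats:
    """Count/min/max/mean/N50/total over captured gap lengths.

    The mean is reported as an integer (nearest nt, ties away from zero);
    min/max/mean/N50 are None for an empty gap list.
    """
    lengths = [g.length for g in gaps]
    if not lengths:
        return GapStats(0, 0, None, None, None, None)
    mean = int(round_half_away(sum(lengths) / len(lengths), 0))
    return GapStats(
        count=len(lengths),
        total=sum(lengths),
        min=min(lengths),
        max=max(lengths),
        mean=mean,
        gap_n50=nxx(lengths, 50),
    )


@dataclass
class StatsReport:
    name: str
    n_scaffolds: int
    n_contigs: int
    scaffold_length: int
    contig_length: int
    scaffold_n50: int
    contig_n50: int
    adjusted_scaffold_n50: int
    adjusted_contig_n50: int
    scaffold_n90: int
    scaffold_n10: int
    max_scaffold: int
    min_scaffold: int
    gaps: GapStats

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gaps"] = self.gaps.to_dict()
        return d


def compute_stats(
    assembly: Assembly,
    min_contig: int = 200,
    min_gap: int = 1,
    genome_size: int = DEFAULT_ADJUSTED_GENOME_SIZE,
    drop_short_scaffolds: bool = False,
) -> StatsReport:
    """Full continuity report for one assembly.

    ``drop_short_scaffolds`` additionally removes free-standing scaffolds
    shorter than ``min_contig`` from the statistics (off by default: the
    island rule targets fragments inside gaps, not whole scaffolds).
    """
    scaffolds = [s for s in assembly if not drop_short_scaffolds or len(s) >= min_contig]
    if not scaffolds:
        raise ValueError("no scaffolds left to summarise")
    sub = Assembly(assembly.name, scaffolds)
    gaps, contigs = detect_gaps(sub, min_contig=min_contig, min_gap=min_gap)
    scaffold_lengths = [len(s) for s in scaffolds]
    contig_lengths = [c.length for c in contigs]
    return StatsReport(
        name=assembly.name,
        n_scaffolds=len(scaffolds),
        n_contigs=len(contigs),
        scaffold_length=sum(scaffold_lengths),
        contig_length=sum(contig_lengths),
        scaffold_n50=nxx(scaffold_lengths, 50),
        contig_n50=nxx(contig_lengths, 50),
        adjusted_scaffold_n50=nxx(scaffold_lengths, 50, genome_size),
        adjusted_contig_n50=nxx(contig_lengths, 50, genome_size),
        scaffold_n90=nxx(scaffold_lengths, 90),
        scaffold_n10=nxx(scaffold_lengths, 10),
        max_scaffold=max(scaffold_lengths),
        min_scaffold=min(scaffold_lengths),
        gaps=gap_stats(gaps),
    )


@dataclass
class GapfillReport:
    gaps_before: int
    gaps_after: int
    gaps_filled: int
    pct_filled: float
    gap_n50_before: int | None
    gap_n50_after: int | None
    total_gap_before: int
    total_gap_after: int
    total_gap_reduction_pct: float
    contig_n50_before: int
    contig_n50_after: int
    contig_n50_change_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def gapfill_delta(
    before: Assembly,
    after: Assembly,
    min_contig: int = 200,
    min_gap: int = 1,
    flank_k: int = 32,
) -> GapfillReport:
    """Compare an assembly before and after gap filling (names stable).

    Each gap of ``before`` is lifted onto ``after`` by locating the flanking
    contig sequence (up to ``flank_k`` nt on each side, searched left to
    right so lifting is monotone). A gap counts as filled when no gap of
    ``after`` overlaps the lifted interval.
    """
    gaps_b, contigs_b = detect_gaps(before, min_contig, min_gap)
    gaps_a, contigs_a = detect_gaps(after, min_contig, min_gap)
    after_seqs = {s.name: s.sequence for s in after}
    after_gaps_by_scf: dict[str, list[GapRecord]] = {}
    for g in gaps_a:
        after_gaps_by_scf.setdefault(g.scaffold, []).append(g)

    filled = 0
    gaps_by_scf: dict[str, list[GapRecord]] = {}
    for g in gaps_b:
        gaps_by_scf.setdefault(g.scaffold, []).append(g)
    before_seqs = {s.name: s.sequence for s in before}
    for scf, scf_gaps in gaps_by_scf.items():
        if scf not in after_seqs:
            raise KeyError(f"scaffold {scf!r} missing from gap-filled assembly")
        bseq = before_seqs[scf]
        aseq = after_seqs[scf].upper()
        cursor = 0
        for g in sorted(scf_gaps, key=lambda g: g.start):
            left = bseq[max(0, g.start - 1 - flank_k) : g.start - 1].upper()
            right = bseq[g.end : g.end + flank_k].upper()
            if left:
                i = aseq.find(left, cursor)
                if i < 0:
                    continue  # flank lost: treat as unfilled, keep cursor
                lifted_start = i + len(left)  # 0-based start of lifted gap region
                cursor = lifted_start
            else:
                lifted_start = 0
            if right:
                j = aseq.find(right, lifted_start)
                if j < 0:
                    continue
                lifted_end = j  # 0-based exclusive
            else:
                lifted_end = len(aseq)
            overlapped = any(
                ga.start - 1 < lifted_end and ga.end > lifted_start
                for ga in after_gaps_by_scf.get(scf, [])
            )
            if not overlapped:
                filled += 1

    gs_b = gap_stats(gaps_b)
    gs_a = gap_stats(gaps_a)
    n50_b = nxx([c.length for c in contigs_b], 50)
    n50_a = nxx([c.length for c in contigs_a], 50)
    return GapfillReport(
        gaps_before=gs_b.count,
        gaps_after=gs_a.count,
        gaps_filled=filled,
        pct_filled=pct(filled, gs_b.count) if gs_b.count else 0.0,
        gap_n50_before=gs_b.gap_n50,
        gap_n50_after=gs_a.gap_n50,
        total_gap_before=gs_b.total,
        total_gap_after=gs_a.total,
        total_gap_reduction_pct=(
            pct(gs_b.total - gs_a.total, gs_b.total) if gs_b.total else 0.0
        ),
        contig_n50_before=n50_b,
        contig_n50_after=n50_a,
        contig_n50_change_pct=pct_change(n50_b, n50_a),
    )
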