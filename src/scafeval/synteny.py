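"""Synteny blocks against a reference, join validation, breakpoints, novel sequence.

Alignments are consumed as PAF-like tabular records (columns 1-12), chained
into collinear synteny blocks per (query, target chromosome, strand), and
used to (a) classify scaffold joins by reference-chromosome agreement,
(b) pinpoint rearrangement breakpoints as the reference interval between the
flanking blocks of a chromosome transition, and (c) extract novel sequence
by subtracting aligned regions from the gap-removed assembly, with
low-complexity and tandem-repeat filtering of the raw complement.

All reported coordinates are 1-based inclusive; PAF input/output uses the
standard 0-based half-open convention.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._util import pct, round_half_away, seq_to_codes
from .assembly import Assembly, detect_gaps
from .lineage import JoinEvent, JoinSetComparison, adjacency_pairs


@dataclass
class AlignmentRecord:
    query: str
    q_len: int
    q_start: int  # 1-based inclusive
    q_end: int
    strand: str
    target: str
    t_len: int
    t_start: int
    t_end: int
    matches: int

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.t_start > self.t_end:
            raise ValueError(f"inverted interval in alignment of {self.query}")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class SyntenyBlock:
    query: str
    q_start: int
    q_end: int
    target: str
    t_start: int
    t_end: int
    strand: str
    n_records: int
    aligned_bases: int


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        c = line.split("\t")
        records.append(
            AlignmentRecord(
                query=c[0],
                q_len=int(c[1]),
                q_start=int(c[2]) + 1,
                q_end=int(c[3]),
                strand=c[4],
                target=c[5],
                t_len=int(c[6]),
                t_start=int(c[7]) + 1,
                t_end=int(c[8]),
                matches=int(c[9]),
            )
        )
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            aln_len = max(r.q_span, r.t_end - r.t_start + 1)
            fh.write(
                f"{r.query}\t{r.q_len}\t{r.q_start - 1}\t{r.q_end}\t{r.strand}\t"
                f"{r.target}\t{r.t_len}\t{r.t_start - 1}\t{r.t_end}\t{r.matches}\t{aln_len}\t60\n"
            )


def chain_blocks(
    alignments: Sequence[AlignmentRecord],
    max_join_gap: int = 100_000,
    min_block: int = 1_000,
) -> list[SyntenyBlock]:
    """Chain collinear alignments into synteny blocks.

    Within each (query, target, strand) group an optimal collinear chain is
    found by dynamic programming on aligned bases (gaps on either side capped
    at ``max_join_gap``); chains are peeled off best-first. Query coverage is
    then resolved to a single block per position: blocks are kept best-first
    and discarded when more than half their query span is already covered.
    Blocks spanning less than ``min_block`` on the query are dropped.
    """
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = defaultdict(list)
    for r in alignments:
        groups[(r.query, r.target, r.strand)].append(r)
    candidates: list[tuple[str, str, str, list[AlignmentRecord]]] = []
    for (query, target, strand), recs in groups.items():
        recs.sort(key=lambda r: r.q_start)
        used = [False] * len(recs)
        while not all(used):
            chain = _best_chain(recs, used, strand, max_join_gap)
            if not chain:
                break
            for i in chain:
                used[i] = True
            candidates.append((query, target, strand, [recs[i] for i in chain]))

    # Single coverage per query position, best chain first: member records
    # mostly inside already-covered query space are removed ("fixing"), the
    # survivors re-chained into blocks.
    by_query: dict[str, list] = defaultdict(list)
    for cand in candidates:
        by_query[cand[0]].append(cand)
    kept: list[SyntenyBlock] = []
    for query, cands in by_query.items():
        cands.sort(key=lambda c: -sum(r.matches for r in c[3]))
        covered: list[tuple[int, int]] = []
        for _, target, strand, members in cands:
            survivors = []
            for r in members:
                overlap = sum(
                    max(0, min(r.q_end, e) - max(r.q_start, s) + 1) for s, e in covered
                )
                if overlap * 2 <= r.q_span:
                    survivors.append(r)
            runs: list[list[AlignmentRecord]] = []
            for r in survivors:
                if runs and _collinear(runs[-1][-1], r, strand, max_join_gap):
                    runs[-1].append(r)
                else:
                    runs.append([r])
            for run in runs:
                b = SyntenyBlock(
                    query=query,
                    q_start=min(m.q_start for m in run),
                    q_end=max(m.q_end for m in run),
                    target=target,
                    t_start=min(m.t_start for m in run),
                    t_end=max(m.t_end for m in run),
                    strand=strand,
                    n_records=len(run),
                    aligned_bases=sum(m.matches for m in run),
                )
                covered.append((b.q_start, b.q_end))
                if b.q_end - b.q_start + 1 >= min_block:
                    kept.append(b)
    kept.sort(key=lambda b: (b.query, b.q_start))
    return kept


def _best_chain(
    recs: list[AlignmentRecord], used: list[bool], strand: str, max_gap: int
) -> list[int]:
    """Highest-scoring collinear chain over unused records (DP, O(n^2))."""
    n = len(recs)
    best_score = np.full(n, -1.0)
    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        if used[i]:
            continue
        best_score[i] = recs[i].matches
        for j in range(i):
            if used[j] or best_score[j] < 0:
                continue
            if not _collinear(recs[j], recs[i], strand, max_gap):
                continue
            if best_score[j] + recs[i].matches > best_score[i]:
                best_score[i] = best_score[j] + recs[i].matches
                parent[i] = j
    if best_score.max() < 0:
        return []
    i = int(best_score.argmax())
    chain = []
    while i >= 0:
        chain.append(i)
        i = int(parent[i])
    return chain[::-1]


def _collinear(a: AlignmentRecord, b: AlignmentRecord, strand: str, max_gap: int) -> bool:
    """Can b follow a in a chain (b is downstream on the query)?"""
    if b.q_start <= a.q_end:
        return False
    if b.q_start - a.q_end - 1 > max_gap:
        return False
    if strand == "+":
        return b.t_start > a.t_end and b.t_start - a.t_end - 1 <= max_gap
    return b.t_end < a.t_start and a.t_start - b.t_end - 1 <= max_gap


@dataclass
class JoinValidation:
    join: JoinEvent
    member_chromosomes: list[str]  # chromosome, "U", or "unassigned" per member
    verdict: str  # "same" | "different" | "unknown"


def member_chromosome(
    member: str,
    blocks_by_query: dict[str, list[SyntenyBlock]],
    majority_fraction: float = 0.5,
) -> str:
    """Dominant reference chromosome of a scaffold (> majority of aligned bases)."""
    blocks = blocks_by_query.get(member, [])
    if not blocks:
        return "unassigned"
    per_chrom: dict[str, int] = defaultdict(int)
    for b in blocks:
        per_chrom[b.target] += b.aligned_bases
    total = sum(per_chrom.values())
    chrom, bases = max(per_chrom.items(), key=lambda kv: kv[1])
    if bases <= majority_fraction * total:
        return "unassigned"
    return chrom


def classify_join(
    join: JoinEvent,
    blocks: Sequence[SyntenyBlock],
    majority_fraction: float = 0.5,
) -> JoinValidation:
    """Verdict on a join from reference-chromosome agreement of its members.

    "same" iff every member has an assigned chromosome and all agree;
    "unknown" if any member is unassigned or maps to chromosome "U";
    otherwise "different" (which is also how a true translocation-spanning
    join appears against a reference that lacks the translocation).
    """
    by_query: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        by_query[b.query].append(b)
    chroms = [
        member_chromosome(m, by_query, majority_fraction) for m, _ in join.members
    ]
    if any(c in ("U", "unassigned") for c in chroms):
        verdict = "unknown"
    elif len(set(chroms)) == 1:
        verdict = "same"
    else:
        verdict = "different"
    return JoinValidation(join, chroms, verdict)


@dataclass
class ValidationRates:
    n_same: int
    n_different: int
    n_unknown: int
    same_rate_pct: float | None
    pair_same_rate_pct: float | None
    supported_same_rate_pct: float | None = None
    unsupported_same_rate_pct: float | None = None
    supported_delta_pct: float | None = None


def rate_difference(rate_a: float, rate_b: float) -> float:
    """Difference between two (already rounded) percentage rates."""
    return round_half_away(rate_a - rate_b, 2)


def validation_rates(
    validations: Sequence[JoinValidation],
    support: JoinSetComparison | None = None,
) -> ValidationRates:
    """Same-chromosome rates overall and stratified by cross-technology support.

    A join is "supported" when any of its adjacent member pairs is among the
    shared pairs of the comparison. Event-level and member-pair-level rates
    are both reported (the pair rate treats each adjacent assigned pair as a
    trial); unknown verdicts are excluded from denominators.
    """
    n_same = sum(v.verdict == "same" for v in validations)
    n_diff = sum(v.verdict == "different" for v in validations)
    n_unk = sum(v.verdict == "unknown" for v in validations)
    overall = pct(n_same, n_same + n_diff) if (n_same + n_diff) else None

    pair_same = pair_total = 0
    for v in validations:
        for (c1, c2) in zip(v.member_chromosomes, v.member_chromosomes[1:]):
            if c1 in ("U", "unassigned") or c2 in ("U", "unassigned"):
                continue
            pair_total += 1
            pair_same += c1 == c2
    pair_rate = pct(pair_same, pair_total) if pair_total else None

    sup_rate = unsup_rate = delta = None
    if support is not None:
        shared = set(support.shared_pairs)
        sup, unsup = [], []
        for v in validations:
            target = sup if adjacency_pairs([v.join]) & shared else unsup
            target.append(v)
        s_same = sum(v.verdict == "same" for v in sup)
        s_diff = sum(v.verdict == "different" for v in sup)
        u_same = sum(v.verdict == "same" for v in unsup)
        u_diff = sum(v.verdict == "different" for v in unsup)
        sup_rate = pct(s_same, s_same + s_diff) if (s_same + s_diff) else None
        unsup_rate = pct(u_same, u_same + u_diff) if (u_same + u_diff) else None
        if sup_rate is not None and overall is not None:
            delta = rate_difference(sup_rate, overall)
    return ValidationRates(
        n_same=n_same,
        n_different=n_diff,
        n_unknown=n_unk,
        same_rate_pct=overall,
        pair_same_rate_pct=pair_rate,
        supported_same_rate_pct=sup_rate,
        unsupported_same_rate_pct=unsup_rate,
        supported_delta_pct=delta,
    )


@dataclass
class Breakpoint:
    chromosome: str
    start: int  # 1-based inclusive reference interval
    end: int
    flanking_blocks: tuple[int, int] | None = None  # indices into the block list

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_breakpoints(
    blocks: Sequence[SyntenyBlock],
    non_collinear_gap: int = 1_000_000,
) -> list[Breakpoint]:
    """Reference intervals at which synteny transitions between chromosomes.

    For every pair of blocks adjacent on a query that map to different
    chromosomes (or jump non-collinearly on the same chromosome), the
    breakpoint on each side is the reference interval between the flanking
    block's transition-facing end and the nearest block beyond it on that
    same chromosome (from any query). Identical intervals found from both
    sides of a reciprocal event are reported once.
    """
    by_query: dict[str, list[tuple[int, SyntenyBlock]]] = defaultdict(list)
    by_chrom: dict[str, list[tuple[int, SyntenyBlock]]] = defaultdict(list)
    for i, b in enumerate(blocks):
        by_query[b.query].append((i, b))
        by_chrom[b.target].append((i, b))
    for lst in by_query.values():
        lst.sort(key=lambda ib: ib[1].q_start)

    found: dict[tuple[str, int, int], Breakpoint] = {}
    for query, lst in by_query.items():
        for (i, up), (j, down) in zip(lst, lst[1:]):
            transition = up.target != down.target
            if not transition:
                gap = max(down.t_start - up.t_end, up.t_start - down.t_end) - 1
                wrong_order = (
                    (up.strand == "+" and down.t_start <= up.t_end)
                    or (up.strand == "-" and down.t_end >= up.t_start)
                    or up.strand != down.strand
                )
                transition = wrong_order or gap > non_collinear_gap
            if not transition:
                continue
            for flank_idx, flank, side in ((i, up, "up"), (j, down, "down")):
                bp = _one_sided_breakpoint(flank_idx, flank, side, by_chrom)
                if bp is not None:
                    key = (bp.chromosome, bp.start, bp.end)
                    found.setdefault(key, bp)
    return sorted(found.values(), key=lambda b: (b.chromosome, b.start))


def _one_sided_breakpoint(
    flank_idx: int,
    flank: SyntenyBlock,
    side: str,
    by_chrom: dict[str, list[tuple[int, SyntenyBlock]]],
) -> Breakpoint | None:
    # The reference end of the flank that faces the transition: for a block on
    # the upstream side of the transition this is its query-3' reference end,
    # which is t_end on "+" and t_start on "-" (mirrored downstream).
    outward_high = (side == "up") == (flank.strand == "+")
    if outward_high:
        edge = flank.t_end
        others = [
            (i, b)
            for i, b in by_chrom[flank.target]
            if i != flank_idx and b.t_start > edge
        ]
        if not others:
            return None
        nxt = min(others, key=lambda ib: ib[1].t_start)
        start, end = edge + 1, nxt[1].t_start - 1
        pair = (flank_idx, nxt[0])
    else:
        edge = flank.t_start
        others = [
            (i, b)
            for i, b in by_chrom[flank.target]
            if i != flank_idx and b.t_end < edge
        ]
        if not others:
            return None
        prev = max(others, key=lambda ib: ib[1].t_end)
        start, end = prev[1].t_end + 1, edge - 1
        pair = (prev[0], flank_idx)
    if end < start:
        return None
    return Breakpoint(flank.target, start, end, pair)


# ---------------------------------------------------------------------------
# Novel sequence extraction


@dataclass
class NovelSegment:
    scaffold: str
    start: int
    end: int
    klass: str  # novel | low_complexity_removed | tandem_removed | short_removed

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NovelReport:
    segments: list[NovelSegment]
    total_bases: int
    aligned_bases: int
    gap_bases: int
    novel_bases: int
    removed_bases: dict[str, int]
    novel_pct: float
    aligned_pct: float

    def partition_total(self) -> int:
        return (
            self.aligned_bases
            + self.gap_bases
            + self.novel_bases
            + sum(self.removed_bases.values())
        )


def dust_score(window: str) -> float:
    """DUST-style low-complexity score of a window: triplet-coincidence pairs
    normalised by window length (random sequence ~0.5, homopolymer ~31)."""
    n = len(window) - 2
    if n < 2:
        return 0.0
    counts: dict[str, int] = defaultdict(int)
    for i in range(n):
        counts[window[i : i + 3]] += 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (n - 1)


def is_low_complexity(
    seq: str, window: int = 64, threshold: float = 4.0, fraction: float = 0.5
) -> bool:
    """True when at least ``fraction`` of windows exceed the DUST threshold.

    The threshold of 4 keeps random sequence (score ~0.5) while flagging
    homopolymer (~31), dinucleotide (~15) and trinucleotide (~10) runs.
    """
    seq = seq.upper()
    if len(seq) <= window:
        return dust_score(seq) > threshold
    step = max(1, window // 2)
    scores = [
        dust_score(seq[i : i + window]) for i in range(0, len(seq) - window + 1, step)
    ]
    return sum(s > threshold for s in scores) >= fraction * len(scores)


def is_tandem(
    seq: str, max_period: int = 500, min_copies: int = 5, min_identity: float = 0.8
) -> bool:
    """Detect tandem repetition by self-match under shift (autocorrelation).

    A sequence is tandem when some period p (allowing at least ``min_copies``
    copies) aligns the sequence to itself at >= ``min_identity``.
    """
    codes = seq_to_codes(seq)
    n = codes.size
    if n < 2 * min_copies:
        return False
    limit = min(max_period, n // min_copies)
    for p in range(1, limit + 1):
        if np.mean(codes[:-p] == codes[p:]) >= min_identity:
            return True
    return False


def novel_sequence(
    assembly: Assembly,
    blocks_or_alignments: Sequence[SyntenyBlock] | Sequence[AlignmentRecord],
    min_segment: int = 100,
    min_contig: int = 200,
    min_gap: int = 1,
    exclusion: Sequence[tuple[str, int, int]] | None = None,
) -> NovelReport:
    """Assembly sequence with no alignment to the reference.

    Subtracts merged aligned query intervals from the contig (gap-removed)
    space of every scaffold; raw complement segments shorter than
    ``min_segment`` or failing the low-complexity/tandem filters are
    reclassified rather than counted novel. ``exclusion`` intervals
    (1-based inclusive) are treated like aligned sequence (e.g. a
    contaminant mask supplied as BED).
    """
    gaps, contigs = detect_gaps(assembly, min_contig=min_contig, min_gap=min_gap)
    aligned_by_scf: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rec in blocks_or_alignments:
        if isinstance(rec, SyntenyBlock):
            aligned_by_scf[rec.query].append((rec.q_start, rec.q_end))
        else:
            aligned_by_scf[rec.query].append((rec.q_start, rec.q_end))
    for scf, start, end in exclusion or []:
        aligned_by_scf[scf].append((start, end))

    contigs_by_scf: dict[str, list] = defaultdict(list)
    for c in contigs:
        contigs_by_scf[c.scaffold].append(c)

    segments: list[NovelSegment] = []
    aligned_total = 0
    seqs = {s.name: s.sequence for s in assembly}
    for scf, scf_contigs in contigs_by_scf.items():
        merged = _merge_intervals(aligned_by_scf.get(scf, []))
        for c in scf_contigs:
            clipped = [
                (max(s, c.start), min(e, c.end)) for s, e in merged if s <= c.end and e >= c.start
            ]
            aligned_total += sum(e - s + 1 for s, e in clipped)
            for s, e in _complement(clipped, c.start, c.end):
                seg_seq = seqs[scf][s - 1 : e]
                if e - s + 1 < min_segment:
                    klass = "short_removed"
                elif is_tandem(seg_seq):
                    klass = "tandem_removed"
                elif is_low_complexity(seg_seq):
                    klass = "low_complexity_removed"
                else:
                    klass = "novel"
                segments.append(NovelSegment(scf, s, e, klass))

    total = assembly.total_length
    gap_bases = sum(g.length for g in gaps)
    removed: dict[str, int] = {
        "short_removed": 0,
        "tandem_removed": 0,
        "low_complexity_removed": 0,
    }
    novel_bases = 0
    for seg in segments:
        if seg.klass == "novel":
            novel_bases += seg.length
        else:
            removed[seg.klass] += seg.length
    return NovelReport(
        segments=segments,
        total_bases=total,
        aligned_bases=aligned_total,
        gap_bases=gap_bases,
        novel_bases=novel_bases,
        removed_bases=removed,
        novel_pct=pct(novel_bases, total),
        aligned_pct=pct(aligned_total, total),
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _complement(
    merged: list[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    out = []
    cursor = start
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= end:
        out.append((cursor, end))
    return out


def novel_genes(
    novel_segments: Sequence[NovelSegment],
    gff_path: str | Path,
    min_cds_fraction: float = 0.5,
) -> list[str]:
    """Genes whose CDS overlaps novel segments for strictly more than half
    of the total CDS length (the accession-specific gene set)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    novel_by_scf: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for seg in novel_segments:
        if seg.klass == "novel":
            novel_by_scf[seg.scaffold].append((seg.start, seg.end))
    for scf in novel_by_scf:
        novel_by_scf[scf] = _merge_intervals(novel_by_scf[scf])

    hits = []
    for gene in db.features_of_type("gene"):
        cds_total = 0
        overlap = 0
        for cds in db.children(gene, featuretype="CDS"):
            cds_total += cds.end - cds.start + 1
            for s, e in novel_by_scf.get(cds.seqid, []):
                overlap += max(0, min(e, cds.end) - max(s, cds.start) + 1)
        if cds_total and overlap > min_cds_fraction * cds_total:
            hits.append(gene.id)
    return hits
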