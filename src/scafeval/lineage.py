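"""Scaffold lineage: joins and breaks between an input and an output assembly.

Scaffolding reorders, joins, breaks and possibly reverse-complements input
scaffolds but never edits sequence inside a contig, so placement does not
need alignment: each input contig is located in the output by exact, unique
64-mer anchors. Contigs whose anchors hit multiple output loci (repeats) are
flagged ambiguous and excluded from event calling; contigs too short to hold
enough anchors are left unplaced.

Joins are output scaffolds containing two or more distinct input scaffolds;
breaks are input scaffolds distributed over two or more output scaffolds.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from ._util import revcomp, round_half_away
from .assembly import Assembly, GapRecord, detect_gaps
from .stats import nxx

_HASH_BASE = np.uint64(0x9E3779B97F4A7C55)  # odd -> invertible mod 2^64
_HASH_BASE_INV = np.uint64(pow(int(_HASH_BASE), -1, 1 << 64))


@dataclass
class Placement:
    input_scaffold: str
    output_scaffold: str
    input_interval: tuple[int, int]  # 1-based inclusive on input scaffold
    output_interval: tuple[int, int]
    orientation: str  # "+" or "-"


@dataclass
class PlacementSet:
    placements: list[Placement]
    ambiguous: list[str] = field(default_factory=list)  # input contig descriptors
    unplaced: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.placements)


@dataclass
class JoinEvent:
    output_scaffold: str
    members: list[tuple[str, str]]  # (input_scaffold, orientation) in output order
    gap_between: list[GapRecord | None] = field(default_factory=list)


@dataclass
class BreakEvent:
    input_scaffold: str
    break_positions: list[int]  # 1-based input coordinates (end of upstream piece)
    resulting_outputs: list[str]
    gap_distances: list[int | None] = field(default_factory=list)


@dataclass
class JoinSetComparison:
    shared_pairs: list[frozenset]
    unique_a: list[frozenset]
    unique_b: list[frozenset]

    @property
    def shared_input_scaffolds(self) -> list[str]:
        return sorted({s for p in self.shared_pairs for s in p})


def _rolling_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Polynomial rolling hash (mod 2^64) of every k-window of a code array."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    with np.errstate(over="ignore"):
        binv = np.full(n, _HASH_BASE_INV, dtype=np.uint64)
        binv[0] = np.uint64(1)
        binv = np.cumprod(binv)  # binv[j] = base^-j
        bpow = np.full(n, _HASH_BASE, dtype=np.uint64)
        bpow[0] = np.uint64(1)
        bpow = np.cumprod(bpow)  # bpow[j] = base^j
        weighted = codes.astype(np.uint64) * binv
        csum = np.cumsum(weighted)
        upper = csum[k - 1 :]
        lower = np.concatenate(([np.uint64(0)], csum[: n - k]))
        return (upper - lower) * bpow[k - 1 :]


_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def _hash_kmer_fast(kmer: str) -> np.uint64:
    h = 0
    b = int(_HASH_BASE)
    m = (1 << 64) - 1
    for c in kmer:
        h = (h * b + _CODE.get(c, 0)) & m
    return np.uint64(h)


def _extend_match(
    ctg_codes: np.ndarray,
    out_codes: np.ndarray,
    scf_lo: int,
    scf_hi: int,
    diag: int,
    anchor_p: int,
) -> tuple[int, int]:
    """Maximal exact-match run (0-based, inclusive) containing anchor_p along
    a fixed diagonal (oriented contig position p <-> concat position diag+p),
    clamped to one output scaffold."""
    L = ctg_codes.size
    lo = max(0, scf_lo - diag)
    hi = min(L, scf_hi - diag)
    eq = ctg_codes[lo:hi] == out_codes[lo + diag : hi + diag]
    idx = anchor_p - lo
    mism = np.flatnonzero(~eq)
    left = mism[mism < idx]
    right = mism[mism > idx]
    a = lo + (int(left[-1]) + 1 if left.size else 0)
    b = lo + (int(right[0]) - 1 if right.size else eq.size - 1)
    return a, b


def place_inputs(
    input_asm: Assembly,
    output_asm: Assembly,
    anchor_k: int = 64,
    min_anchor_count: int = 3,
    n_anchors: int = 16,
    min_contig: int = 200,
    min_gap: int = 1,
) -> PlacementSet:
    """Place every input contig in the output assembly by unique k-mer anchors.

    Each single-locus anchor seeds a diagonal that is extended to the maximal
    exact match, so a contig broken across output scaffolds yields one exact
    placement per piece (uncovered stretches are re-anchored for a few
    rounds). A contig whose placements overlap on the input (true
    multi-mapping, e.g. repeats) is flagged ambiguous and excluded.
    """
    from ._util import seq_to_codes

    _, contigs = detect_gaps(input_asm, min_contig=min_contig, min_gap=min_gap)
    names, offsets, parts = [], [], []
    off = 0
    for sc in output_asm:
        names.append(sc.name)
        offsets.append(off)
        parts.append(sc.sequence.upper())
        off += len(sc.sequence)
    concat = "".join(parts)
    offsets_arr = np.array(offsets + [off], dtype=np.int64)
    out_codes = seq_to_codes(concat)
    hashes = _rolling_hashes(out_codes, anchor_k)
    order = np.argsort(hashes, kind="stable")
    sorted_hashes = hashes[order]

    def lookup(kmer: str) -> list[int]:
        h = _hash_kmer_fast(kmer)
        lo = int(np.searchsorted(sorted_hashes, h, side="left"))
        hi = int(np.searchsorted(sorted_hashes, h, side="right"))
        return [
            int(order[i])
            for i in range(lo, min(hi, lo + 8))
            if concat[order[i] : order[i] + anchor_k] == kmer
        ]

    input_seqs = {s.name: s.sequence for s in input_asm}
    placements: list[Placement] = []
    ambiguous: list[str] = []
    unplaced: list[str] = []
    any_anchor_match = False

    for ctg in contigs:
        seq = input_seqs[ctg.scaffold][ctg.start - 1 : ctg.end].upper()
        L = len(seq)
        label = f"{ctg.scaffold}:{ctg.start}-{ctg.end}"
        if L < anchor_k:
            unplaced.append(label)
            continue
        oriented = {"+": seq, "-": revcomp(seq)}
        codes = {s: seq_to_codes(o) for s, o in oriented.items()}
        # group -> extended oriented interval; anchors are oriented positions
        extents: dict[tuple[int, str, int], tuple[int, int]] = {}
        single_hits = 0
        multi_hit = 0
        tried: set[tuple[str, int]] = set()
        pending = [
            int(p)
            for p in np.unique(
                np.linspace(0, L - anchor_k, min(n_anchors, L - anchor_k + 1)).astype(int)
            )
        ]
        for _round in range(4):
            new_group = False
            for p in pending:
                for strand in ("+", "-"):
                    # test the same input window on both strands
                    p_o = p if strand == "+" else L - anchor_k - p
                    if (strand, p_o) in tried:
                        continue
                    tried.add((strand, p_o))
                    hits = lookup(oriented[strand][p_o : p_o + anchor_k])
                    if len(hits) > 1:
                        multi_hit += 1
                        continue
                    if not hits:
                        continue
                    single_hits += 1
                    any_anchor_match = True
                    q = hits[0]
                    scf_idx = int(np.searchsorted(offsets_arr, q, side="right")) - 1
                    key = (scf_idx, strand, q - p_o)
                    if key not in extents:
                        a, b = _extend_match(
                            codes[strand],
                            out_codes,
                            int(offsets_arr[scf_idx]),
                            int(offsets_arr[scf_idx + 1]),
                            q - p_o,
                            p_o,
                        )
                        if b - a + 1 >= anchor_k:
                            extents[key] = (a, b)
                            new_group = True
            # input-coordinate coverage so far
            covered = []
            for (_, strand, _), (a, b) in extents.items():
                covered.append((a, b) if strand == "+" else (L - 1 - b, L - 1 - a))
            covered.sort()
            uncovered = []
            cur = 0
            for a, b in covered:
                if a > cur:
                    uncovered.append((cur, a - 1))
                cur = max(cur, b + 1)
            if cur < L:
                uncovered.append((cur, L - 1))
            pending = []
            for a, b in uncovered:
                if b - a + 1 >= anchor_k:
                    mid = (a + b - anchor_k) // 2
                    pending.extend(
                        sorted({a, max(a, mid), min(b - anchor_k + 1, b)})
                    )
            pending = [p for p in pending if 0 <= p <= L - anchor_k]
            if not pending or (not new_group and _round > 0):
                break

        if not extents:
            (ambiguous if multi_hit else unplaced).append(label)
            continue
        if single_hits < min(min_anchor_count, len(tried)):
            ambiguous.append(label)
            continue
        # overlapping input coverage between groups = true multi-mapping
        ivals = []
        for (scf_idx, strand, diag), (a, b) in extents.items():
            ia, ib = (a, b) if strand == "+" else (L - 1 - b, L - 1 - a)
            ivals.append((ia, ib, scf_idx, strand, diag, a, b))
        ivals.sort()
        overlap = any(
            n_start <= p_end - anchor_k // 2
            for (_, p_end, *_), (n_start, *_) in zip(ivals, ivals[1:])
        )
        if overlap:
            ambiguous.append(label)
            continue
        for ia, ib, scf_idx, strand, diag, a, b in ivals:
            scf_off = int(offsets_arr[scf_idx])
            out0 = diag + a - scf_off
            placements.append(
                Placement(
                    input_scaffold=ctg.scaffold,
                    output_scaffold=names[scf_idx],
                    input_interval=(ctg.start + ia, ctg.start + ib),
                    output_interval=(out0 + 1, out0 + (b - a + 1)),
                    orientation=strand,
                )
            )
    if contigs and not placements and not any_anchor_match:
        raise ValueError("assemblies appear unrelated: no anchor placements found")
    return PlacementSet(_merge_placements(placements), ambiguous, unplaced)


def _merge_placements(placements: list[Placement]) -> list[Placement]:
    """Merge runs of collinear placements of the same (input, output, strand) pair."""
    by_out: dict[str, list[Placement]] = defaultdict(list)
    for p in placements:
        by_out[p.output_scaffold].append(p)
    merged: list[Placement] = []
    for out_scf, plist in by_out.items():
        plist.sort(key=lambda p: p.output_interval[0])
        cur: Placement | None = None
        for p in plist:
            out_gap = p.output_interval[0] - cur.output_interval[1] if cur else 0
            if (
                cur is not None
                and p.input_scaffold == cur.input_scaffold
                and p.orientation == cur.orientation
                and (
                    (
                        p.orientation == "+"
                        and p.input_interval[0] - cur.input_interval[1] == out_gap
                    )
                    or (
                        p.orientation == "-"
                        and cur.input_interval[0] - p.input_interval[1] == out_gap
                    )
                )
            ):
                cur = Placement(
                    cur.input_scaffold,
                    out_scf,
                    (
                        min(cur.input_interval[0], p.input_interval[0]),
                        max(cur.input_interval[1], p.input_interval[1]),
                    ),
                    (cur.output_interval[0], p.output_interval[1]),
                    cur.orientation,
                )
            else:
                if cur is not None:
                    merged.append(cur)
                cur = p
        if cur is not None:
            merged.append(cur)
    merged.sort(key=lambda p: (p.output_scaffold, p.output_interval[0]))
    return merged


def _as_placements(placements: PlacementSet | Iterable[Placement]) -> list[Placement]:
    if isinstance(placements, PlacementSet):
        return list(placements.placements)
    return list(placements)


def call_joins(
    placements: PlacementSet | Iterable[Placement],
    output_gaps: Iterable[GapRecord] | None = None,
) -> list[JoinEvent]:
    """One JoinEvent per output scaffold holding >= 2 distinct input scaffolds."""
    plist = _as_placements(placements)
    gaps_by_scf: dict[str, list[GapRecord]] = defaultdict(list)
    for g in output_gaps or []:
        gaps_by_scf[g.scaffold].append(g)
    by_out: dict[str, list[Placement]] = defaultdict(list)
    for p in plist:
        by_out[p.output_scaffold].append(p)
    joins: list[JoinEvent] = []
    for out_scf in sorted(by_out):
        ps = sorted(by_out[out_scf], key=lambda p: p.output_interval[0])
        members: list[tuple[str, str]] = []
        spans: list[tuple[int, int]] = []
        for p in ps:
            if members and members[-1][0] == p.input_scaffold and members[-1][1] == p.orientation:
                spans[-1] = (spans[-1][0], p.output_interval[1])
                continue
            members.append((p.input_scaffold, p.orientation))
            spans.append(p.output_interval)
        if len({m for m, _ in members}) < 2:
            continue
        gap_between: list[GapRecord | None] = []
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            between = [
                g for g in gaps_by_scf.get(out_scf, []) if g.start > e1 and g.end < s2
            ]
            gap_between.append(between[0] if between else None)
        joins.append(JoinEvent(out_scf, members, gap_between))
    return joins


@dataclass
class JoinSummary:
    n_input_scaffolds_joined: int
    n_join_events: int
    mean_scaffolds_per_join: float
    mean_members_per_event: float


def join_summary(joins: Sequence[JoinEvent]) -> JoinSummary:
    inputs = {m for j in joins for m, _ in j.members}
    n_members = sum(len(j.members) for j in joins)
    n = len(joins)
    return JoinSummary(
        n_input_scaffolds_joined=len(inputs),
        n_join_events=n,
        mean_scaffolds_per_join=round_half_away(len(inputs) / n, 2) if n else 0.0,
        mean_members_per_event=round_half_away(n_members / n, 2) if n else 0.0,
    )


def call_breaks(
    placements: PlacementSet | Iterable[Placement],
    input_gaps: Iterable[GapRecord] | None = None,
) -> list[BreakEvent]:
    """One BreakEvent per input scaffold placed on >= 2 output scaffolds.

    Break positions are input coordinates at the end of each upstream piece.
    When input gaps are supplied, the distance from each break to the nearest
    input gap edge is reported (None when the scaffold has no gaps).
    """
    plist = _as_placements(placements)
    gaps_by_scf: dict[str, list[GapRecord]] = defaultdict(list)
    for g in input_gaps or []:
        gaps_by_scf[g.scaffold].append(g)
    by_in: dict[str, list[Placement]] = defaultdict(list)
    for p in plist:
        by_in[p.input_scaffold].append(p)
    breaks: list[BreakEvent] = []
    for in_scf in sorted(by_in):
        ps = sorted(by_in[in_scf], key=lambda p: p.input_interval[0])
        outputs = []
        for p in ps:
            if not outputs or outputs[-1] != p.output_scaffold:
                outputs.append(p.output_scaffold)
        if len(set(outputs)) < 2:
            continue
        positions = [
            ps[i].input_interval[1]
            for i in range(len(ps) - 1)
            if ps[i].output_scaffold != ps[i + 1].output_scaffold
        ]
        distances: list[int | None] = []
        for pos in positions:
            scf_gaps = gaps_by_scf.get(in_scf)
            if not scf_gaps:
                distances.append(None)
            else:
                distances.append(
                    min(min(abs(pos - g.start), abs(pos - g.end)) for g in scf_gaps)
                )
        breaks.append(BreakEvent(in_scf, positions, outputs, distances))
    return breaks


def median_break_gap_distance(breaks: Sequence[BreakEvent]) -> float | None:
    dists = [d for b in breaks for d in b.gap_distances if d is not None]
    return float(median(dists)) if dists else None


def join_size_classes(
    joins: Sequence[JoinEvent],
    input_asm: Assembly,
    cutoffs: Sequence[int] = (100_000, 1_000_000),
):
    """Joined-input-scaffold counts and length stats per size class.

    Returns a pandas DataFrame with one row for "all", one for scaffolds below
    the first cutoff, and one ">= c" row per cutoff (Table-style fields:
    count, min, max, N50, N90, total length).
    """
    import pandas as pd

    lengths_by_name = {s.name: len(s) for s in input_asm}
    joined = sorted({m for j in joins for m, _ in j.members})
    lengths = [lengths_by_name[n] for n in joined]
    rows = []

    def row(label: str, vals: list[int]) -> dict:
        return {
            "class": label,
            "n_scaffolds": len(vals),
            "min_scaffold": min(vals) if vals else None,
            "max_scaffold": max(vals) if vals else None,
            "scaffold_n50": nxx(vals, 50) if vals else None,
            "scaffold_n90": nxx(vals, 90) if vals else None,
            "total_length": sum(vals),
        }

    rows.append(row("all", lengths))
    c0 = cutoffs[0]
    rows.append(row(f"<{c0}", [l for l in lengths if l < c0]))
    for c in cutoffs:
        rows.append(row(f">={c}", [l for l in lengths if l >= c]))
    return pd.DataFrame(rows)


def adjacency_pairs(joins: Sequence[JoinEvent]) -> set[frozenset]:
    """Unordered pairs of directly adjacent join members."""
    pairs = set()
    for j in joins:
        for (a, _), (b, _) in zip(j.members, j.members[1:]):
            if a != b:
                pairs.add(frozenset((a, b)))
    return pairs


def compare_join_sets(
    joins_a: Sequence[JoinEvent], joins_b: Sequence[JoinEvent]
) -> JoinSetComparison:
    """Shared vs technology-unique adjacent join pairs (orientation-blind)."""
    pa, pb = adjacency_pairs(joins_a), adjacency_pairs(joins_b)
    return JoinSetComparison(
        shared_pairs=sorted(pa & pb, key=sorted),
        unique_a=sorted(pa - pb, key=sorted),
        unique_b=sorted(pb - pa, key=sorted),
    )
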