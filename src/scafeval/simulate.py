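"""Synthetic genomes, fragmented assemblies and simulated scaffolding rounds.

The generator produces every input the evaluation pipeline consumes, with
full ground truth:

* a reference genome with interspersed and tandem repeat families
  (softmasked lowercase, plus a BED) and toy gene models;
* a diverged accession carrying a reciprocal chromosome-arm translocation,
  large novel insertions next to the translocation junctions, dispersed
  smaller novel insertions, and SNP/indel divergence;
* a fragmented, gap-free base assembly whose break positions follow a
  log-normal renewal process, optionally snapped into nearby repeats;
* one or more rounds of simulated scaffolding under configurable technology
  profiles that differ in minimum joinable scaffold size, maximum spanned
  distance, gap-size convention (estimated sizes vs fixed 100 N), and
  chimera handling (automatic breaking vs logging).

Coordinates in all truth records are 1-based inclusive. Everything is
reproducible from the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

from ._util import revcomp, softmask_mask
from .assembly import Assembly, GapRecord, Scaffold

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RepeatFamily:
    name: str
    unit_length: int
    divergence: float  # per-copy substitution rate vs the family consensus
    tandem: bool = False
    weight: float = 1.0  # share of the total repeat budget
    min_copies: int = 5  # tandem arrays only
    max_copies: int = 20


@dataclass
class TechnologyProfile:
    """Behaviour of one long-range scaffolding technology."""

    name: str
    min_joinable: int  # smallest scaffold the technology can incorporate
    max_span: int  # largest gap it can bridge
    gap_convention: str  # "sized" | "fixed_100N"
    gap_size_error: float = 0.0  # multiplicative sd on sized gaps
    min_gap_emitted: int = 1
    chimera_break_behavior: str = "logs_only"  # "breaks" | "logs_only"
    join_error_rate: float = 0.0
    join_success_rate: float = 1.0  # fraction of candidate joins with enough evidence
    gap_islands: bool = False  # scatter restriction-site fragments in gaps

    def __post_init__(self) -> None:
        if self.min_joinable <= 0:
            raise ValueError("min_joinable must be positive")
        if self.gap_convention not in ("sized", "fixed_100N"):
            raise ValueError("gap_convention must be 'sized' or 'fixed_100N'")


#: Optical-map-like profile: joins only large scaffolds, spans long distances,
#: estimates gap sizes (never below 500 nt), leaves restriction-site islands
#: inside its gaps, and only logs suspected chimeras.
OPTICALMAP_LIKE = TechnologyProfile(
    name="opticalmap",
    min_joinable=100_000,
    max_span=650_000,
    gap_convention="sized",
    gap_size_error=0.10,
    min_gap_emitted=500,
    chimera_break_behavior="logs_only",
    join_success_rate=0.8,
    gap_islands=True,
)

#: Proximity-ligation-like profile: joins scaffolds down to a few kb over
#: spans bounded by the library insert (~100 kb), emits fixed 100-N gaps and
#: breaks chimeric scaffolds automatically.
PROXIMITY_LIKE = TechnologyProfile(
    name="proximity",
    min_joinable=5_000,
    max_span=100_000,
    gap_convention="fixed_100N",
    gap_size_error=0.0,
    min_gap_emitted=100,
    chimera_break_behavior="breaks",
    join_success_rate=0.8,
)


@dataclass
class TranslocationSpec:
    donor: str = "chr1"
    acceptor: str = "chr2"
    donor_arm_fraction: float = 0.60
    acceptor_arm_fraction: float = 0.55
    slop: int = 2_000  # reference bases lost at each junction


def _default_families() -> list[RepeatFamily]:
    return [
        RepeatFamily("LTR-like", 5_000, 0.10, tandem=False, weight=0.60),
        RepeatFamily("DNA-like", 800, 0.15, tandem=False, weight=0.25),
        RepeatFamily("satellite", 156, 0.05, tandem=True, weight=0.15),
    ]


@dataclass
class SimConfig:
    genome_size: int = 50_000_000
    n_chromosomes: int = 4
    repeat_fraction: float = 0.25
    repeat_families: list[RepeatFamily] = field(default_factory=_default_families)
    snp_rate: float = 0.005
    indel_rate: float = 2e-4
    translocation: TranslocationSpec | None = field(default_factory=TranslocationSpec)
    junction_insertion_fractions: tuple[float, float] = (0.0023, 0.00086)
    n_extra_novel: int = 90
    extra_novel_mean: int = 25_000
    mean_contig: int = 300_000
    contig_sigma: float = 1.0
    min_contig_piece: int = 2_000
    repeat_break_weight: float = 3.0
    snap_window: int = 25_000
    n_chimeras: int = 8
    scaffold_flip_rate: float = 0.3
    gene_spacing: int = 50_000
    gene_length: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.repeat_fraction, self.snp_rate, self.indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.genome_size <= 0 or self.n_chromosomes <= 0:
            raise ValueError("sizes must be positive")


# ---------------------------------------------------------------------------
# Sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i


def _rand_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _str_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _mutate_arr(
    arr: np.ndarray, snp_rate: float, indel_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitutions (case preserved) plus short (1-5 nt) indels."""
    arr = arr.copy()
    n = arr.size
    if n == 0:
        return arr
    if snp_rate > 0:
        n_snp = rng.binomial(n, snp_rate)
        if n_snp:
            pos = np.unique(rng.integers(0, n, n_snp))
            codes = _CODE_TABLE[arr[pos]]
            ok = codes >= 0
            pos, codes = pos[ok], codes[ok]
            lower = arr[pos] >= 97
            new = _BASES[(codes + rng.integers(1, 4, pos.size)) % 4]
            arr[pos] = new + 32 * lower.astype(np.uint8)
    if indel_rate > 0:
        n_ind = rng.binomial(n, indel_rate)
        n_del, n_ins = n_ind // 2, n_ind - n_ind // 2
        if n_del:
            starts = rng.integers(0, max(1, n - 6), n_del)
            lens = rng.integers(1, 6, n_del)
            idx = np.concatenate([np.arange(s, s + l) for s, l in zip(starts, lens)])
            arr = np.delete(arr, np.unique(idx[idx < arr.size]))
        if n_ins and arr.size:
            starts = np.sort(rng.integers(0, arr.size, n_ins))
            lens = rng.integers(1, 6, n_ins)
            at = np.repeat(starts, lens)
            arr = np.insert(arr, at, _rand_seq_arr(rng, int(lens.sum())))
    return arr


# ---------------------------------------------------------------------------
# Reference


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list[tuple[int, int]]


@dataclass
class Reference:
    assembly: Assembly
    repeat_bed: list[tuple[str, int, int, str]]  # chrom, start, end (1-based), family
    genes: list[Gene]


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> Reference:
    """Chromosomes with softmasked repeat copies/arrays and toy gene models."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_len = config.genome_size // config.n_chromosomes
    consensus = {
        fam.name: _rand_seq_arr(rng, fam.unit_length) for fam in config.repeat_families
    }
    scaffolds: list[Scaffold] = []
    bed: list[tuple[str, int, int, str]] = []
    genes: list[Gene] = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        arr = _rand_seq_arr(rng, chrom_len)
        total_weight = sum(f.weight for f in config.repeat_families) or 1.0
        tree = IntervalTree()
        for fam in config.repeat_families:
            budget = config.repeat_fraction * chrom_len * fam.weight / total_weight
            placed = 0
            attempts = 0
            while placed < budget and attempts < 100_000:
                attempts += 1
                if fam.tandem:
                    ncopy = int(rng.integers(fam.min_copies, fam.max_copies + 1))
                    copy = np.concatenate(
                        [
                            _mutate_arr(consensus[fam.name], fam.divergence, 0, rng)
                            for _ in range(ncopy)
                        ]
                    )
                else:
                    copy = _mutate_arr(consensus[fam.name], fam.divergence, 0, rng)
                L = copy.size
                if L >= chrom_len:
                    break
                start = int(rng.integers(0, chrom_len - L))
                if tree.overlaps(start, start + L):
                    continue
                tree[start : start + L] = fam.name
                arr[start : start + L] = copy + 32  # lowercase = softmask
                bed.append((chrom, start + 1, start + L, fam.name))
                placed += L
        scaffolds.append(Scaffold(chrom, _arr_to_str(arr)))
        gi = 0
        pos = 5_000
        while pos + config.gene_length < chrom_len:
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_cds = int(rng.integers(1, 6))
            exon_len = config.gene_length // (2 * n_cds)
            cds = [
                (
                    pos + k * 2 * exon_len + 1,
                    pos + k * 2 * exon_len + exon_len,
                )
                for k in range(n_cds)
            ]
            genes.append(
                Gene(f"{chrom}g{gi:05d}", chrom, pos + 1, pos + config.gene_length, strand, cds)
            )
            pos += config.gene_spacing
    bed.sort()
    return Reference(Assembly("reference", scaffolds), bed, genes)


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\ttoy\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{k};Parent={g.gene_id}.t1\n"
                )


def write_bed(bed: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write 1-based inclusive intervals in BED (0-based half-open) convention."""
    with open(path, "w") as fh:
        for chrom, start, end, name in bed:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals back to 1-based inclusive tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        c = line.split("\t")
        out.append((c[0], int(c[1]) + 1, int(c[2])))
    return out


# ---------------------------------------------------------------------------
# Accession


@dataclass
class AccSegment:
    acc_chrom: str
    acc_start: int  # 1-based inclusive, on the accession
    acc_end: int
    kind: str  # "ref" | "novel"
    ref_chrom: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None


@dataclass
class BreakpointTruth:
    ref_chrom: str
    start: int
    end: int
    junction: str  # which accession junction this side belongs to


@dataclass
class Accession:
    assembly: Assembly
    segments: dict[str, list[AccSegment]]
    breakpoints: list[BreakpointTruth]
    novel_segments: list[tuple[str, int, int]]  # accession coordinates
    snp_rate: float

    @property
    def novel_total(self) -> int:
        return sum(e - s + 1 for _, s, e in self.novel_segments)


def simulate_accession(
    reference: Reference, config: SimConfig, rng: np.random.Generator | None = None
) -> Accession:
    """Derive a diverged accession with a reciprocal arm translocation.

    The donor chromosome's lower arm and the acceptor's lower arm are
    exchanged; ``slop`` reference bases are lost at each junction (the truth
    breakpoint intervals), and a large novel insertion is placed right at
    each junction, mirroring how novel sequence clusters next to real
    rearrangement breakpoints. Additional novel insertions are dispersed
    genome-wide, then SNPs and short indels are applied to reference-derived
    segments.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ref_seqs = {s.name: s.sequence for s in reference.assembly}
    plans: dict[str, list[tuple]] = {}
    breakpoints: list[BreakpointTruth] = []
    t = config.translocation
    ins1 = int(round(config.junction_insertion_fractions[0] * config.genome_size))
    ins2 = int(round(config.junction_insertion_fractions[1] * config.genome_size))
    for ci, sc in enumerate(reference.assembly):
        acc_name = f"acc{ci + 1}"
        plans[acc_name] = [("ref", sc.name, 1, len(sc.sequence))]
    if t is not None:
        donor_len = len(ref_seqs[t.donor])
        acc_len = len(ref_seqs[t.acceptor])
        arm_d = int(t.donor_arm_fraction * donor_len)
        arm_a = int(t.acceptor_arm_fraction * acc_len)
        acc_of = {f"chr{i + 1}": f"acc{i + 1}" for i in range(config.n_chromosomes)}
        plans[acc_of[t.donor]] = [
            ("ref", t.donor, 1, arm_d),
            ("novel", ins1),
            ("ref", t.acceptor, arm_a + t.slop + 1, acc_len),
        ]
        plans[acc_of[t.acceptor]] = [
            ("ref", t.acceptor, 1, arm_a),
            ("novel", ins2),
            ("ref", t.donor, arm_d + t.slop + 1, donor_len),
        ]
        for junction, sides in (
            ("junction1", ((t.donor, arm_d), (t.acceptor, arm_a))),
            ("junction2", ((t.acceptor, arm_a), (t.donor, arm_d))),
        ):
            for chrom, arm in sides:
                breakpoints.append(
                    BreakpointTruth(chrom, arm + 1, arm + t.slop, junction)
                )
    # dispersed extra novel insertions
    for _ in range(config.n_extra_novel):
        acc_name = f"acc{int(rng.integers(1, config.n_chromosomes + 1))}"
        plan = plans[acc_name]
        ref_entries = [i for i, e in enumerate(plan) if e[0] == "ref"]
        if not ref_entries:
            continue
        i = int(rng.choice(ref_entries))
        _, chrom, s, e = plan[i]
        if e - s < 10_000:
            continue
        cut = int(rng.integers(s + 1_000, e - 1_000))
        length = max(200, int(rng.lognormal(math.log(config.extra_novel_mean), 0.6)))
        plan[i : i + 1] = [
            ("ref", chrom, s, cut),
            ("novel", length),
            ("ref", chrom, cut + 1, e),
        ]

    scaffolds: list[Scaffold] = []
    segments: dict[str, list[AccSegment]] = {}
    novel: list[tuple[str, int, int]] = []
    for acc_name in sorted(plans, key=lambda n: int(n[3:])):
        parts: list[str] = []
        segs: list[AccSegment] = []
        pos = 1
        for entry in plans[acc_name]:
            if entry[0] == "ref":
                _, chrom, s, e = entry
                arr = _str_to_arr(ref_seqs[chrom][s - 1 : e])
                arr = _mutate_arr(arr, config.snp_rate, config.indel_rate, rng)
                seq = _arr_to_str(arr)
                segs.append(
                    AccSegment(acc_name, pos, pos + len(seq) - 1, "ref", chrom, s, e)
                )
            else:
                length = entry[1]
                seq = _arr_to_str(_rand_seq_arr(rng, length))
                segs.append(AccSegment(acc_name, pos, pos + length - 1, "novel"))
                novel.append((acc_name, pos, pos + length - 1))
            parts.append(seq)
            pos += len(seq)
        scaffolds.append(Scaffold(acc_name, "".join(parts)))
        segments[acc_name] = segs
    return Accession(
        Assembly("accession", scaffolds), segments, breakpoints, novel, config.snp_rate
    )


# ---------------------------------------------------------------------------
# Fragmentation


@dataclass
class ContigPiece:
    acc_chrom: str
    acc_start: int  # 1-based inclusive accession interval
    acc_end: int
    orient: str  # "+" | "-"
    scaf_start: int  # 1-based inclusive position within the scaffold
    scaf_end: int


@dataclass
class FragmentResult:
    assembly: Assembly
    provenance: dict[str, list[ContigPiece]]
    chimeras: list[tuple[str, int]]  # (scaffold, junction position)
    break_positions: dict[str, list[int]]


def fragment(
    accession: Accession, config: SimConfig, rng: np.random.Generator | None = None
) -> FragmentResult:
    """Fragment the accession into a gap-free base assembly.

    Contig lengths follow a log-normal renewal process around
    ``mean_contig``; with ``repeat_break_weight`` w > 1 each break is moved
    into a softmasked (repeat) position within ``snap_window`` with
    probability 1 - 1/w, emulating assemblers stalling in repeats. A few
    chimeric scaffolds concatenate distant contigs (junction positions are
    recorded as truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    mu = math.log(config.mean_contig) - config.contig_sigma**2 / 2
    contigs: list[tuple[str, int, int]] = []  # chrom, start, end (1-based)
    break_positions: dict[str, list[int]] = {}
    for sc in accession.assembly:
        L = len(sc.sequence)
        mask = softmask_mask(sc.sequence)
        breaks: list[int] = []
        cur = 0
        while True:
            step = max(config.min_contig_piece, int(rng.lognormal(mu, config.contig_sigma)))
            cur += step
            if cur >= L:
                break
            pos = cur
            w = config.repeat_break_weight
            if w > 1 and rng.random() < 1 - 1 / w:
                lo = max(0, pos - config.snap_window)
                hi = min(L, pos + config.snap_window)
                cand = np.flatnonzero(mask[lo:hi])
                if cand.size:
                    pos = int(lo + rng.choice(cand))
            if breaks and pos - breaks[-1] < config.min_contig_piece:
                continue
            if pos <= 0 or pos >= L:
                continue
            breaks.append(pos)
            cur = pos
        breaks = sorted(set(breaks))
        break_positions[sc.name] = breaks
        edges = [0] + breaks + [L]
        for s0, e0 in zip(edges, edges[1:]):
            contigs.append((sc.name, s0 + 1, e0))

    order = rng.permutation(len(contigs))
    scaffolds: list[Scaffold] = []
    provenance: dict[str, list[ContigPiece]] = {}
    chimeras: list[tuple[str, int]] = []
    acc_seqs = {s.name: s.sequence for s in accession.assembly}

    # choose chimera pairs among large-ish contigs, distant or cross-chromosome
    chim_members: set[int] = set()
    pairs: list[tuple[int, int, str]] = []
    idx_pool = [i for i in order if contigs[i][2] - contigs[i][1] + 1 >= config.min_contig_piece]
    attempts = 0
    while len(pairs) < config.n_chimeras and attempts < 1000 and len(idx_pool) >= 2:
        attempts += 1
        i, j = rng.choice(len(idx_pool), 2, replace=False)
        a, b = idx_pool[int(i)], idx_pool[int(j)]
        if a in chim_members or b in chim_members:
            continue
        ca, cb = contigs[a], contigs[b]
        if ca[0] == cb[0] and abs(ca[1] - cb[1]) < 5_000_000:
            continue
        orient = "+" if rng.random() < 0.5 else "-"
        pairs.append((a, b, orient))
        chim_members.update((a, b))

    ctg_i = 0
    for k, (a, b, orient) in enumerate(pairs, 1):
        ca, cb = contigs[a], contigs[b]
        seq_a = acc_seqs[ca[0]][ca[1] - 1 : ca[2]]
        seq_b = acc_seqs[cb[0]][cb[1] - 1 : cb[2]]
        if orient == "-":
            seq_b = revcomp(seq_b)
        name = f"chim{k:02d}"
        la, lb = len(seq_a), len(seq_b)
        scaffolds.append(Scaffold(name, seq_a + seq_b))
        provenance[name] = [
            ContigPiece(ca[0], ca[1], ca[2], "+", 1, la),
            ContigPiece(cb[0], cb[1], cb[2], orient, la + 1, la + lb),
        ]
        chimeras.append((name, la))
    for i in order:
        if int(i) in chim_members:
            continue
        chrom, s, e = contigs[int(i)]
        ctg_i += 1
        name = f"ctg{ctg_i:05d}"
        scaffolds.append(Scaffold(name, acc_seqs[chrom][s - 1 : e]))
        provenance[name] = [ContigPiece(chrom, s, e, "+", 1, e - s + 1)]
    return FragmentResult(
        Assembly("base", scaffolds), provenance, chimeras, break_positions
    )


# ---------------------------------------------------------------------------
# Scaffolding


@dataclass
class GapTruth:
    scaffold: str
    start: int
    end: int
    acc_chrom: str | None
    acc_start: int  # accession interval the gap stands for (start > end: empty)
    acc_end: int
    orient: str = "+"


@dataclass
class JoinTruth:
    output_scaffold: str
    members: list[tuple[str, str]]  # (input scaffold, emitted orientation)
    gap_lengths: list[int]
    true_distances: list[int]
    error: bool = False

    def adjacency_pairs(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for (a, _), (b, _) in zip(self.members, self.members[1:])
            if a != b
        }


@dataclass
class ScaffoldingResult:
    assembly: Assembly
    provenance: dict[str, list[ContigPiece]]
    gaps: list[GapRecord]
    gap_truths: list[GapTruth]
    joins: list[JoinTruth]
    executed_breaks: list[tuple[str, int]]  # (input scaffold, scaffold position)
    chimera_log: list[tuple[str, int]]
    profile: str


@dataclass
class _Unit:
    name: str
    seq: str
    pieces: list[ContigPiece]
    gaps: list[GapRecord]
    gap_truths: list[GapTruth]

    @property
    def length(self) -> int:
        return len(self.seq)


_CHIMERA_ADJACENT_MAX = 2_000_000


def _near_adjacent(p: ContigPiece, q: ContigPiece) -> bool:
    """Could q plausibly follow p within one genomic locus?"""
    if p.acc_chrom != q.acc_chrom or p.orient != q.orient:
        return False
    if p.orient == "+":
        gap = q.acc_start - p.acc_end - 1
    else:
        gap = p.acc_start - q.acc_end - 1
    return 0 <= gap <= _CHIMERA_ADJACENT_MAX


def _chimeric_junctions(unit: _Unit) -> list[int]:
    """Scaffold positions (end of upstream piece) of implausible junctions."""
    return [
        p.scaf_end
        for p, q in zip(unit.pieces, unit.pieces[1:])
        if not _near_adjacent(p, q)
    ]


def _flip_unit(unit: _Unit) -> _Unit:
    L = len(unit.seq)

    def flip_piece(p: ContigPiece) -> ContigPiece:
        return ContigPiece(
            p.acc_chrom,
            p.acc_start,
            p.acc_end,
            "-" if p.orient == "+" else "+",
            L - p.scaf_end + 1,
            L - p.scaf_start + 1,
        )

    return _Unit(
        unit.name,
        revcomp(unit.seq),
        [flip_piece(p) for p in reversed(unit.pieces)],
        [
            GapRecord(g.scaffold, L - g.end + 1, L - g.start + 1, g.origin)
            for g in reversed(unit.gaps)
        ],
        [
            GapTruth(
                t.scaffold,
                L - t.end + 1,
                L - t.start + 1,
                t.acc_chrom,
                t.acc_start,
                t.acc_end,
                "-" if t.orient == "+" else "+",
            )
            for t in reversed(unit.gap_truths)
        ],
    )


def _unit_direction(unit: _Unit) -> str:
    return unit.pieces[0].orient


def _unit_span(unit: _Unit) -> tuple[str, int, int]:
    chrom = unit.pieces[0].acc_chrom
    return (
        chrom,
        min(p.acc_start for p in unit.pieces),
        max(p.acc_end for p in unit.pieces),
    )


def _emit_gap(
    profile: TechnologyProfile, true_distance: int, rng: np.random.Generator
) -> tuple[str, int]:
    if profile.gap_convention == "fixed_100N":
        g = 100
    else:
        est = true_distance * (1 + rng.normal(0, profile.gap_size_error))
        g = max(profile.min_gap_emitted, int(round(est)))
    seq = ["N"] * g
    if profile.gap_islands and g >= 1_000:
        n_isl = rng.poisson(g / 8_000)
        placed: list[tuple[int, int]] = []
        for _ in range(n_isl):
            il = int(rng.integers(20, 151))
            if g - il - 4 <= 2:
                continue
            for _attempt in range(10):
                s = int(rng.integers(2, g - il - 2))
                if all(s + il + 2 <= ps or s >= pe + 2 for ps, pe in placed):
                    placed.append((s, s + il))
                    frag = _arr_to_str(_rand_seq_arr(rng, il))
                    seq[s : s + il] = list(frag)
                    break
    return "".join(seq), g


def simulate_scaffolding(
    base: FragmentResult | ScaffoldingResult,
    profile: TechnologyProfile,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ScaffoldingResult:
    """Apply one round of simulated scaffolding to a (possibly scaffolded) assembly.

    Candidate joins are pairs of non-chimeric scaffolds adjacent on the
    accession, both at least ``min_joinable`` long, with an intervening true
    distance of at most ``max_span`` (the intervening sequence lives in
    scaffolds too short to join). Chains of candidates become output
    super-scaffolds whose gaps follow the profile's convention; whole
    super-scaffolds are reverse-complemented at the configured rate.
    Chimeras are split first ("breaks" behaviour) or reported ("logs_only").
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    units: list[_Unit] = []
    prev_gaps: dict[str, list[GapRecord]] = {}
    prev_truths: dict[str, list[GapTruth]] = {}
    if isinstance(base, ScaffoldingResult):
        for g in base.gaps:
            prev_gaps.setdefault(g.scaffold, []).append(g)
        for t in base.gap_truths:
            prev_truths.setdefault(t.scaffold, []).append(t)
    for sc in base.assembly:
        units.append(
            _Unit(
                sc.name,
                sc.sequence,
                list(base.provenance[sc.name]),
                list(prev_gaps.get(sc.name, [])),
                list(prev_truths.get(sc.name, [])),
            )
        )

    executed_breaks: list[tuple[str, int]] = []
    chimera_log: list[tuple[str, int]] = []
    work: list[_Unit] = []
    for u in units:
        junctions = _chimeric_junctions(u)
        if not junctions:
            work.append(u)
            continue
        if profile.chimera_break_behavior == "logs_only":
            chimera_log.extend((u.name, j) for j in junctions)
            work.append(u)
            continue
        executed_breaks.extend((u.name, j) for j in junctions)
        bounds = [0] + junctions + [len(u.seq)]
        piece_groups: list[list[ContigPiece]] = [[] for _ in range(len(bounds) - 1)]
        for p in u.pieces:
            for gi, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
                if p.scaf_start > lo and p.scaf_end <= hi:
                    piece_groups[gi].append(p)
                    break
        for gi, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            name = f"{u.name}.{gi + 1}"
            shift = lo
            pieces = [
                replace(p, scaf_start=p.scaf_start - shift, scaf_end=p.scaf_end - shift)
                for p in piece_groups[gi]
            ]
            gaps = [
                GapRecord(name, g.start - shift, g.end - shift, g.origin)
                for g in u.gaps
                if g.start > lo and g.end <= hi
            ]
            truths = [
                replace(t, scaffold=name, start=t.start - shift, end=t.end - shift)
                for t in u.gap_truths
                if t.start > lo and t.end <= hi
            ]
            work.append(_Unit(name, u.seq[lo:hi], pieces, gaps, truths))

    joinable = [
        u
        for u in work
        if u.length >= profile.min_joinable
        and not _chimeric_junctions(u)
        and len({p.acc_chrom for p in u.pieces}) == 1
    ]

    by_chrom: dict[str, list[_Unit]] = {}
    for u in joinable:
        by_chrom.setdefault(_unit_span(u)[0], []).append(u)
    chains: list[list[tuple[_Unit, int]]] = []  # (unit, distance to previous)
    chained: set[str] = set()
    for chrom in sorted(by_chrom):
        us = sorted(by_chrom[chrom], key=lambda u: _unit_span(u)[1])
        cur: list[tuple[_Unit, int]] = []
        for prev, nxt in zip([None] + us[:-1], us):
            if prev is None:
                cur = [(nxt, 0)]
                continue
            d = _unit_span(nxt)[1] - _unit_span(prev)[2] - 1
            if 0 <= d <= profile.max_span and rng.random() < profile.join_success_rate:
                cur.append((nxt, d))
            else:
                if len(cur) > 1:
                    chains.append(cur)
                    chained.update(u.name for u, _ in cur)
                cur = [(nxt, 0)]
        if len(cur) > 1:
            chains.append(cur)
            chained.update(u.name for u, _ in cur)

    out_scaffolds: list[Scaffold] = []
    provenance: dict[str, list[ContigPiece]] = {}
    gaps_out: list[GapRecord] = []
    truths_out: list[GapTruth] = []
    joins: list[JoinTruth] = []

    def shift_unit(u: _Unit, offset: int, out_name: str) -> tuple[list, list, list]:
        pieces = [
            replace(p, scaf_start=p.scaf_start + offset, scaf_end=p.scaf_end + offset)
            for p in u.pieces
        ]
        gaps = [
            GapRecord(out_name, g.start + offset, g.end + offset, g.origin)
            for g in u.gaps
        ]
        truths = [
            replace(t, scaffold=out_name, start=t.start + offset, end=t.end + offset)
            for t in u.gap_truths
        ]
        return pieces, gaps, truths

    for ci, chain in enumerate(chains, 1):
        out_name = f"{profile.name}_scf{ci:04d}"
        parts: list[str] = []
        pieces_all: list[ContigPiece] = []
        gaps_local: list[GapRecord] = []
        truths_local: list[GapTruth] = []
        members: list[tuple[str, str]] = []
        gap_lengths: list[int] = []
        distances: list[int] = []
        offset = 0
        prev_span_end: int | None = None
        for u, d in chain:
            oriented = u if _unit_direction(u) == "+" else _flip_unit(u)
            emit_orient = "+" if _unit_direction(u) == "+" else "-"
            if parts:
                gap_seq, g = _emit_gap(profile, d, rng)
                span = _unit_span(u)
                truths_local.append(
                    GapTruth(
                        out_name,
                        offset + 1,
                        offset + g,
                        span[0],
                        prev_span_end + 1,
                        span[1] - 1,
                        "+",
                    )
                )
                gaps_local.append(
                    GapRecord(out_name, offset + 1, offset + g, profile.name)
                )
                parts.append(gap_seq)
                offset += g
                gap_lengths.append(g)
                distances.append(d)
            p, gp, tr = shift_unit(oriented, offset, out_name)
            pieces_all.extend(p)
            gaps_local.extend(gp)
            truths_local.extend(tr)
            parts.append(oriented.seq)
            offset += oriented.length
            members.append((u.name, emit_orient))
            prev_span_end = _unit_span(u)[2]
        out_unit = _Unit(out_name, "".join(parts), pieces_all, gaps_local, truths_local)
        if rng.random() < config.scaffold_flip_rate:
            out_unit = _flip_unit(out_unit)
            members = [(n, "-" if o == "+" else "+") for n, o in reversed(members)]
            gap_lengths = gap_lengths[::-1]
            distances = distances[::-1]
        out_scaffolds.append(Scaffold(out_name, out_unit.seq))
        provenance[out_name] = out_unit.pieces
        gaps_out.extend(out_unit.gaps)
        truths_out.extend(out_unit.gap_truths)
        joins.append(JoinTruth(out_name, members, gap_lengths, distances))

    for u in work:
        if u.name in chained:
            continue
        out_scaffolds.append(Scaffold(u.name, u.seq))
        provenance[u.name] = u.pieces
        gaps_out.extend(u.gaps)
        truths_out.extend(u.gap_truths)

    return ScaffoldingResult(
        Assembly(f"{base.assembly.name}+{profile.name}", out_scaffolds),
        provenance,
        gaps_out,
        truths_out,
        joins,
        executed_breaks,
        chimera_log,
        profile.name,
    )


# ---------------------------------------------------------------------------
# Gap filling


def simulate_gapfill(
    scaffolded: ScaffoldingResult,
    accession: Accession,
    rng: np.random.Generator | None = None,
    max_fill_span: int = 20_000,
    fill_prob: float = 1.0,
    seed: int = 0,
) -> tuple[Assembly, list[tuple[str, int, int]]]:
    """Replace small gaps with the true accession sequence they stand for.

    Only gaps whose true span is at most ``max_fill_span`` are candidates,
    reproducing the preferential filling of small gaps. Returns the filled
    assembly (names stable) and the list of filled gap coordinates.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    acc_seqs = {s.name: s.sequence for s in accession.assembly}
    by_scf: dict[str, list[GapTruth]] = {}
    for t in scaffolded.gap_truths:
        by_scf.setdefault(t.scaffold, []).append(t)
    filled: list[tuple[str, int, int]] = []
    new_scaffolds: list[Scaffold] = []
    for sc in scaffolded.assembly:
        seq = sc.sequence
        for t in sorted(by_scf.get(sc.name, []), key=lambda t: -t.start):
            span = t.acc_end - t.acc_start + 1
            if span > max_fill_span or rng.random() > fill_prob:
                continue
            ins = acc_seqs[t.acc_chrom][t.acc_start - 1 : t.acc_end] if span > 0 else ""
            if t.orient == "-":
                ins = revcomp(ins)
            seq = seq[: t.start - 1] + ins + seq[t.end :]
            filled.append((sc.name, t.start, t.end))
        new_scaffolds.append(Scaffold(sc.name, seq))
    return Assembly(scaffolded.assembly.name + "+fill", new_scaffolds), filled


# ---------------------------------------------------------------------------
# Truth-derived alignments (PAF)


def truth_alignments(
    provenance: dict[str, list[ContigPiece]],
    accession: Accession,
    assembly: Assembly,
    reference: Reference,
    min_record: int = 50,
):
    """Perfect PAF-like records for an assembly, derived from provenance.

    Each contig piece is intersected with the accession's reference-derived
    segments; novel segments yield no record. Reference coordinates inside a
    segment are linearly interpolated (exact at segment boundaries; indel
    drift within a segment is bounded by the indel load). Records shorter
    than ``min_record`` are dropped.
    """
    from .synteny import AlignmentRecord

    q_lens = {s.name: len(s) for s in assembly}
    t_lens = {s.name: len(s) for s in reference.assembly}
    records = []
    for scf, pieces in provenance.items():
        if scf not in q_lens:
            continue
        for p in pieces:
            for seg in accession.segments[p.acc_chrom]:
                if seg.kind != "ref":
                    continue
                lo = max(p.acc_start, seg.acc_start)
                hi = min(p.acc_end, seg.acc_end)
                if hi - lo + 1 < min_record:
                    continue
                seg_acc_len = seg.acc_end - seg.acc_start + 1
                seg_ref_len = seg.ref_end - seg.ref_start + 1
                scale = seg_ref_len / seg_acc_len

                def ref_of(a: int) -> int:
                    return seg.ref_start + int(round((a - seg.acc_start) * scale))

                t_start, t_end = ref_of(lo), ref_of(hi)
                t_end = max(t_start, min(t_end, seg.ref_end))
                if p.orient == "+":
                    q_start = p.scaf_start + (lo - p.acc_start)
                    q_end = p.scaf_start + (hi - p.acc_start)
                else:
                    q_start = p.scaf_start + (p.acc_end - hi)
                    q_end = p.scaf_start + (p.acc_end - lo)
                span = hi - lo + 1
                matches = span - int(span * accession.snp_rate)
                records.append(
                    AlignmentRecord(
                        query=scf,
                        q_len=q_lens[scf],
                        q_start=q_start,
                        q_end=q_end,
                        strand=p.orient,
                        target=seg.ref_chrom,
                        t_len=t_lens[seg.ref_chrom],
                        t_start=t_start,
                        t_end=t_end,
                        matches=matches,
                    )
                )
    records.sort(key=lambda r: (r.query, r.q_start))
    return records


def acc_to_assembly(
    provenance: dict[str, list[ContigPiece]], chrom: str, start: int, end: int
) -> list[tuple[str, int, int]]:
    """Map an accession interval onto assembly scaffold coordinates."""
    out = []
    for scf, pieces in provenance.items():
        for p in pieces:
            if p.acc_chrom != chrom:
                continue
            lo, hi = max(start, p.acc_start), min(end, p.acc_end)
            if lo > hi:
                continue
            if p.orient == "+":
                out.append((scf, p.scaf_start + (lo - p.acc_start), p.scaf_start + (hi - p.acc_start)))
            else:
                out.append((scf, p.scaf_start + (p.acc_end - hi), p.scaf_start + (p.acc_end - lo)))
    return sorted(out)


def source_name(name: str) -> str:
    """Original input-scaffold name of a (possibly chimera-split) piece."""
    return name.split(".")[0]
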