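"""Assembly data model and I/O.

An :class:`Assembly` is an ordered collection of scaffolds. Each scaffold is a
nucleotide string in which runs of ``N`` are *captured gaps* separating
*contigs*. Optical-map scaffolders scatter short restriction-site fragments
inside the gaps they emit; following the GAEMR convention, any non-N island
shorter than ``min_contig`` (default 200 nt) that sits between two gaps is
folded into a single merged gap so that one join contributes one gap to the
statistics.

Coordinates in all records are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from ._util import revcomp  # noqa: F401  (re-exported convenience)

# Full IUPAC nucleotide alphabet, both cases (lowercase = softmasked).
_IUPAC = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")
_GAP_CHARS = ("N", "n")


@dataclass
class Scaffold:
    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GapRecord:
    """A captured gap. ``origin`` names the technology that introduced it."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    origin: str = "unknown"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ContigRecord:
    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Assembly:
    name: str
    scaffolds: list[Scaffold] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.scaffolds]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate scaffold name(s): {', '.join(dup)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def get(self, name: str) -> Scaffold:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)


def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an Assembly, preserving order and case.

    Raises ValueError on an empty file, duplicated headers, or characters
    outside the IUPAC nucleotide alphabet (reported with their position).
    """
    path = Path(path)
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        bad = next((i for i, c in enumerate(seq) if c not in _IUPAC), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {seq[bad]!r} in {rec.id} at position {bad + 1}"
            )
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        scaffolds.append(Scaffold(rec.id, seq))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    return Assembly(name or path.stem, scaffolds)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sc in assembly:
            fh.write(f">{sc.name}\n")
            for i in range(0, len(sc.sequence), width):
                fh.write(sc.sequence[i : i + width] + "\n")


_N_RUN = re.compile("[Nn]+")


def detect_gaps(
    assembly: Assembly, min_contig: int = 200, min_gap: int = 1
) -> tuple[list[GapRecord], list[ContigRecord]]:
    """Partition every scaffold into captured gaps and contigs.

    Maximal N-runs of at least ``min_gap`` seed the gaps; a non-N island
    shorter than ``min_contig`` with a gap seed on both sides is merged into a
    single gap together with its neighbours (terminal islands are kept as
    contigs — they are not *between* gaps). Gaps and contigs tile each
    scaffold exactly.
    """
    if min_contig < 1:
        raise ValueError("min_contig must be >= 1")
    gaps: list[GapRecord] = []
    contigs: list[ContigRecord] = []
    for sc in assembly:
        runs = _runs(sc.sequence, min_gap)
        runs = _merge_islands(runs, min_contig)
        for is_gap, start, end in runs:
            if is_gap:
                gaps.append(GapRecord(sc.name, start + 1, end))
            else:
                contigs.append(ContigRecord(sc.name, start + 1, end))
    return gaps, contigs


def _runs(seq: str, min_gap: int) -> list[tuple[bool, int, int]]:
    """Alternating (is_gap, start0, end0-exclusive) runs; N-runs < min_gap count as sequence."""
    runs: list[tuple[bool, int, int]] = []
    pos = 0
    for m in _N_RUN.finditer(seq):
        if m.end() - m.start() < min_gap:
            continue
        if m.start() > pos:
            runs.append((False, pos, m.start()))
        runs.append((True, m.start(), m.end()))
        pos = m.end()
    if pos < len(seq):
        runs.append((False, pos, len(seq)))
    # coalesce adjacent runs of the same kind (possible when short N-runs were kept)
    return _coalesce(runs)


def _coalesce(runs: list[tuple[bool, int, int]]) -> list[tuple[bool, int, int]]:
    out: list[tuple[bool, int, int]] = []
    for r in runs:
        if out and out[-1][0] == r[0]:
            out[-1] = (r[0], out[-1][1], r[2])
        else:
            out.append(r)
    return out


def _merge_islands(
    runs: list[tuple[bool, int, int]], min_contig: int
) -> list[tuple[bool, int, int]]:
    merged = []
    for i, (is_gap, start, end) in enumerate(runs):
        is_island = (
            not is_gap
            and end - start < min_contig
            and 0 < i < len(runs) - 1
            and runs[i - 1][0]
            and runs[i + 1][0]
        )
        merged.append((True if is_island else is_gap, start, end))
    return _coalesce(merged)


def gap_islands(assembly: Assembly, gaps: Iterable[GapRecord]) -> list[tuple[str, int, int, str]]:
    """Non-N stretches inside gap intervals (merged restriction-site islands).

    Returns (scaffold, start, end, sequence) with 1-based inclusive coordinates.
    """
    out = []
    for g in gaps:
        sc = None
        for s in assembly:
            if s.name == g.scaffold:
                sc = s
                break
        if sc is None:
            raise KeyError(g.scaffold)
        seg = sc.sequence[g.start - 1 : g.end]
        for m in re.finditer("[^Nn]+", seg):
            out.append((g.scaffold, g.start + m.start(), g.start + m.end() - 1, m.group()))
    return out


def write_agp(
    assembly: Assembly,
    gaps: list[GapRecord],
    agp_path: str | Path,
    contig_fasta_path: str | Path | None = None,
) -> None:
    """Write an AGP v2.1 description of the assembly.

    Components are the contigs implied by ``gaps``; gap lines carry the gap's
    originating technology in the linkage-evidence column. Non-N islands that
    were merged into gaps cannot be represented on N lines, so they are
    preserved as ``#island`` comment metadata, which :func:`read_agp` replays
    to make the round trip byte-identical.
    """
    by_scaffold: dict[str, list[GapRecord]] = {}
    for g in gaps:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    lines = ["##agp-version\t2.1"]
    components: list[tuple[str, str]] = []
    lengths = {sc.name: len(sc.sequence) for sc in assembly}
    for scf, scf_gaps in by_scaffold.items():
        for g in scf_gaps:
            if g.start < 1 or g.end < g.start or g.end > lengths.get(scf, 0):
                raise ValueError(f"inconsistent gap coordinates on {scf}")
    for sc in assembly:
        scf_gaps = sorted(by_scaffold.get(sc.name, []), key=lambda g: g.start)
        for scf, start, end, seq in gap_islands(
            Assembly("tmp", [sc]), [g for g in scf_gaps]
        ):
            lines.append(f"#island\t{scf}\t{start}\t{end}\t{seq}")
        part = 0
        ctg_idx = 0
        cursor = 1
        segments: list[tuple[str, int, int, GapRecord | None]] = []
        for g in scf_gaps:
            if g.start > cursor:
                segments.append(("W", cursor, g.start - 1, None))
            segments.append(("N", g.start, g.end, g))
            cursor = g.end + 1
        if cursor <= len(sc.sequence):
            segments.append(("W", cursor, len(sc.sequence), None))
        for kind, start, end, g in segments:
            part += 1
            if kind == "W":
                ctg_idx += 1
                comp_id = f"{sc.name}_ctg{ctg_idx}"
                components.append((comp_id, sc.sequence[start - 1 : end]))
                lines.append(
                    f"{sc.name}\t{start}\t{end}\t{part}\tW\t{comp_id}\t1\t{end - start + 1}\t+"
                )
            else:
                assert g is not None
                lines.append(
                    f"{sc.name}\t{start}\t{end}\t{part}\tN\t{end - start + 1}\tscaffold\tyes\t{g.origin}"
                )
    Path(agp_path).write_text("\n".join(lines) + "\n")
    if contig_fasta_path is not None:
        with open(contig_fasta_path, "w") as fh:
            for comp_id, seq in components:
                fh.write(f">{comp_id}\n{seq}\n")


def read_agp(agp_path: str | Path, contig_fasta_path: str | Path) -> Assembly:
    """Reconstruct scaffold sequences from an AGP file plus its component FASTA."""
    comps = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(contig_fasta_path), "fasta")}
    islands: list[tuple[str, int, int, str]] = []
    pieces: dict[str, list[str]] = {}
    order: list[str] = []
    for line in Path(agp_path).read_text().splitlines():
        if line.startswith("#island\t"):
            _, scf, start, end, seq = line.split("\t")
            islands.append((scf, int(start), int(end), seq))
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        scf = cols[0]
        if scf not in pieces:
            pieces[scf] = []
            order.append(scf)
        if cols[4] == "W":
            comp = comps[cols[5]]
            pieces[scf].append(comp[int(cols[6]) - 1 : int(cols[7])])
        else:
            pieces[scf].append("N" * int(cols[5]))
    seqs = {scf: "".join(p) for scf, p in pieces.items()}
    for scf, start, end, seq in islands:
        s = seqs[scf]
        seqs[scf] = s[: start - 1] + seq + s[end:]
    return Assembly("agp", [Scaffold(n, seqs[n]) for n in order])


def gaps_to_tsv(gaps: list[GapRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tlength\torigin\n")
        for g in gaps:
            fh.write(f"{g.scaffold}\t{g.start}\t{g.end}\t{g.length}\t{g.origin}\n")


def gaps_from_tsv(path: str | Path) -> list[GapRecord]:
    gaps = []
    for line in Path(path).read_text().splitlines()[1:]:
        scf, start, end, _length, origin = line.split("\t")
        gaps.append(GapRecord(scf, int(start), int(end), origin))
    return gaps
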