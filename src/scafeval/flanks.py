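"""Repeat enrichment in sequence flanking technology-introduced gaps and breaks.

The observed statistic is the pooled repeat fraction over fixed-width flanks
(default 10 kb each side, truncated at scaffold ends, N excluded) around the
supplied events. Significance comes from a one-sided permutation test that
re-draws equally many event positions uniformly over contig (non-N) space
and recomputes the pooled flank fraction under the null of no association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import n_mask, softmask_mask
from .assembly import Assembly, GapRecord


@dataclass
class FlankReport:
    observed_fraction: float
    background_fraction: float
    enrichment_ratio: float
    p_value: float
    n_events: int
    n_permutations: int
    seed: int | None
    per_event: list[tuple[str, int, int, float]] = field(default_factory=list)


def _normalise_events(events: Iterable) -> list[tuple[str, int, int]]:
    out = []
    for ev in events:
        if isinstance(ev, GapRecord):
            out.append((ev.scaffold, ev.start, ev.end))
        elif isinstance(ev, tuple) and len(ev) == 3:
            out.append((ev[0], int(ev[1]), int(ev[2])))
        elif hasattr(ev, "input_scaffold") and hasattr(ev, "break_positions"):
            for pos in ev.break_positions:
                out.append((ev.input_scaffold, pos, pos))
        else:
            raise TypeError(f"unsupported event type: {type(ev)!r}")
    return out


def flank_repeat_enrichment(
    assembly: Assembly,
    events: Iterable,
    repeats_bed: Sequence[tuple[str, int, int]] | None = None,
    use_softmask: bool = False,
    flank: int = 10_000,
    n_perm: int = 1_000,
    seed: int | None = None,
) -> FlankReport:
    """Permutation test for repeat enrichment in event flanks.

    ``repeats_bed`` holds 1-based inclusive intervals; softmasked (lowercase)
    runs are used instead of, or in union with, the BED when
    ``use_softmask`` is set. Events may be GapRecords, BreakEvents, or
    (scaffold, start, end) tuples.

    p = (1 + #{null >= observed}) / (1 + n_perm), one-sided for enrichment.
    """
    ev = _normalise_events(events)
    if not ev:
        raise ValueError("no events")
    if repeats_bed is None and not use_softmask:
        raise ValueError("no repeat annotation: supply repeats_bed and/or use_softmask")

    names = []
    rep_prefix: dict[str, np.ndarray] = {}
    valid_prefix: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    bed_by_scf: dict[str, list[tuple[int, int]]] = {}
    for scf, s, e in repeats_bed or []:
        bed_by_scf.setdefault(scf, []).append((s, e))
    for sc in assembly:
        names.append(sc.name)
        L = len(sc.sequence)
        lengths[sc.name] = L
        nm = n_mask(sc.sequence)
        rep = np.zeros(L, dtype=bool)
        if use_softmask:
            rep |= softmask_mask(sc.sequence)
        for s, e in bed_by_scf.get(sc.name, []):
            rep[max(0, s - 1) : min(L, e)] = True
        rep &= ~nm
        valid = ~nm
        rep_prefix[sc.name] = np.concatenate(([0], np.cumsum(rep)))
        valid_prefix[sc.name] = np.concatenate(([0], np.cumsum(valid)))

    def flank_counts(scf: str, start: int, end: int) -> tuple[int, int]:
        """(repeat bases, valid bases) in the two flanks of [start, end]."""
        L = lengths[scf]
        rp, vp = rep_prefix[scf], valid_prefix[scf]
        lo1, hi1 = max(0, start - 1 - flank), max(0, start - 1)
        lo2, hi2 = min(L, end), min(L, end + flank)
        rep = int(rp[hi1] - rp[lo1] + rp[hi2] - rp[lo2])
        val = int(vp[hi1] - vp[lo1] + vp[hi2] - vp[lo2])
        return rep, val

    per_event = []
    obs_rep = obs_val = 0
    for scf, s, e in ev:
        if scf not in lengths:
            raise KeyError(f"event scaffold {scf!r} not in assembly")
        r, v = flank_counts(scf, s, e)
        per_event.append((scf, s, e, r / v if v else float("nan")))
        obs_rep += r
        obs_val += v
    if obs_val == 0:
        raise ValueError("all event flanks are empty")
    observed = obs_rep / obs_val

    total_rep = sum(int(rep_prefix[n][-1]) for n in names)
    total_valid = sum(int(valid_prefix[n][-1]) for n in names)
    background = total_rep / total_valid if total_valid else float("nan")

    # Null: event positions uniform over contig (non-N) space, lengths kept.
    rng = np.random.default_rng(seed)
    valid_per_scf = np.array([int(valid_prefix[n][-1]) for n in names], dtype=np.int64)
    cum_valid = np.concatenate(([0], np.cumsum(valid_per_scf)))
    ev_lengths = np.array([e - s + 1 for _, s, e in ev], dtype=np.int64)
    n_ev = len(ev)
    draws = rng.integers(0, cum_valid[-1], size=(n_perm, n_ev))
    flat = draws.ravel()
    scf_idx = np.searchsorted(cum_valid, flat, side="right") - 1
    lens = np.tile(ev_lengths, n_perm)
    rep_counts = np.zeros(flat.size, dtype=np.int64)
    val_counts = np.zeros(flat.size, dtype=np.int64)
    for si, scf in enumerate(names):
        mask = scf_idx == si
        if not mask.any():
            continue
        vp, rp = valid_prefix[scf], rep_prefix[scf]
        L = lengths[scf]
        rank = flat[mask] - cum_valid[si]
        pos = np.searchsorted(vp, rank + 1, side="left")  # 1-based coordinate
        start = np.minimum(pos, L)
        end = np.minimum(start + lens[mask] - 1, L)
        lo1 = np.maximum(0, start - 1 - flank)
        hi1 = np.maximum(0, start - 1)
        lo2 = np.minimum(L, end)
        hi2 = np.minimum(L, end + flank)
        rep_counts[mask] = rp[hi1] - rp[lo1] + rp[hi2] - rp[lo2]
        val_counts[mask] = vp[hi1] - vp[lo1] + vp[hi2] - vp[lo2]
    null_rep = rep_counts.reshape(n_perm, n_ev).sum(axis=1)
    null_val = val_counts.reshape(n_perm, n_ev).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_frac = null_rep / null_val
    null_ge = int(np.sum(null_frac[null_val > 0] >= observed))
    p = (1 + null_ge) / (1 + n_perm)
    return FlankReport(
        observed_fraction=observed,
        background_fraction=background,
        enrichment_ratio=observed / background if background else float("inf"),
        p_value=p,
        n_events=len(ev),
        n_permutations=n_perm,
        seed=seed,
        per_event=per_event,
    )
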