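"""Small shared helpers: rounding, reverse complement, sequence codecs."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention used in all reports).

    Python's built-in round() is banker's rounding; reported percentages here
    follow half-away-from-zero so that e.g. 0.125 -> 0.13.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage of numerator over denominator, rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def pct_change(before: float, after: float, ndigits: int = 2) -> float:
    """Percent change from before to after ((after-before)/before)."""
    if before == 0:
        raise ZeroDivisionError("percent change from zero")
    return round_half_away(100.0 * (after - before) / before, ndigits)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8: A/C/G/T (any case) -> 1..4, other -> 0."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    upper = np.where((raw >= 97) & (raw <= 122), raw - 32, raw)
    codes = np.zeros(raw.shape, dtype=np.uint8)
    for base, code in ((65, 1), (67, 2), (71, 3), (84, 4)):  # A C G T
        codes[upper == base] = code
    return codes


def n_mask(seq: str) -> np.ndarray:
    """Boolean mask of N/n positions."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (raw == 78) | (raw == 110)


def softmask_mask(seq: str) -> np.ndarray:
    """Boolean mask of lowercase (softmasked) positions."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (raw >= 97) & (raw <= 122)
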