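"""Small shared helpers: alphabet handling and the rounding conventions
used by every report in the package."""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal-style half-up rounding (0.25 -> 0.3 at 1 digit), unlike
    Python's banker's rounding."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def trunc_decimal(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals.

    Report percentages are truncated, not rounded: 96/102 prints as 94.11
    and a density of 0.0699% prints as 0.06. A small epsilon absorbs float
    representation artifacts (49.999999996 still truncates to 50.0).
    """
    factor = 10.0 ** ndigits
    eps = 1e-9
    if x >= 0:
        return math.floor(x * factor + eps) / factor
    return -math.floor(-x * factor + eps) / factor
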