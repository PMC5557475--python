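"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 59.175 -> 59.2.

    Python's built-in round() is banker's rounding, which disagrees with how
    percentage tables are conventionally printed.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def bed_score(q: float, cap: int = 1000) -> int:
    """-10*log10(q) rounded to int and capped; q<=0 maps to the cap."""
    if q <= 0.0:
        return cap
    return min(cap, round(-10.0 * math.log10(q)))


def enumerate_windows(chrom_length: int, w: int, step: int) -> list[tuple[int, int, bool]]:
    """Sliding windows over [1, chrom_length], 1-based inclusive.

    Full windows start at 1, 1+step, ... while they fit; if the last full
    window does not reach the chromosome end, one final partial window is
    emitted (flagged True) so no position is silently dropped.  A chromosome
    shorter than ``w`` yields a single partial window.

    Returns (start, end, is_partial) triples.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    if step <= 0 or step > w:
        raise ValueError("step must satisfy 0 < step <= window size")
    if chrom_length < 1:
        raise ValueError("chromosome length must be >= 1")
    out: list[tuple[int, int, bool]] = []
    if chrom_length < w:
        return [(1, chrom_length, True)]
    last_full_start = chrom_length - w + 1
    s = 1
    while s <= last_full_start:
        out.append((s, s + w - 1, False))
        s += step
    if out[-1][1] < chrom_length:
        out.append((out[-1][0] + step, chrom_length, True))
    return out
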