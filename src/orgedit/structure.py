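"""Genome-level structural statistics.

GC content, detection of the maximal exactly identical inverted repeat
(IR), partitioning of a circular plastome into the quadripartite
IRa/IRb/LSC/SSC layout, and cross-genome gene-inventory comparison.

The IR finder looks for the longest pair of *disjoint, exact*
reverse-complement repeats (hornwort plastome IRs are identical copies);
no mismatch tolerance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeRecord, ValidationError
from .util import revcomp, round_half_up


def gc_content(seq: str | GenomeRecord, interval: tuple[int, int] | None = None,
               ndigits: int = 1) -> float:
    """Percent G+C over a sequence or sub-interval, half-up rounded.

    N bases are excluded from both numerator and denominator. Raises on an
    empty or all-N region.
    """
    if isinstance(seq, GenomeRecord):
        seq = seq.sequence
    if interval is not None:
        s, e = interval
        seq = seq[s:e]
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValidationError("gc_content: empty or all-N region")
    return round_half_up(100.0 * gc / denom, ndigits)


def at_content(seq: str | GenomeRecord, ndigits: int = 1) -> float:
    if isinstance(seq, GenomeRecord):
        seq = seq.sequence
    at = seq.count("A") + seq.count("T")
    denom = at + seq.count("G") + seq.count("C")
    if denom == 0:
        raise ValidationError("at_content: empty or all-N region")
    return round_half_up(100.0 * at / denom, ndigits)


# ---------------------------------------------------------------------------
# inverted-repeat detection

_MOD = (1 << 61) - 1
_BASE = 1315423911 % _MOD


def _prefix_hashes(encoded: list[int]) -> list[int]:
    h = [0] * (len(encoded) + 1)
    for i, c in enumerate(encoded):
        h[i + 1] = (h[i] * _BASE + c + 1) % _MOD
    return h


class _WindowHasher:
    """O(1) substring hashes after O(n) preprocessing."""

    def __init__(self, seq: str):
        enc = [ord(c) for c in seq]
        self.h = _prefix_hashes(enc)
        self.pw = [1] * (len(seq) + 1)
        for i in range(len(seq)):
            self.pw[i + 1] = (self.pw[i] * _BASE) % _MOD

    def window(self, i: int, length: int) -> int:
        return (self.h[i + length] - self.h[i] * self.pw[length]) % _MOD


def find_max_inverted_repeat(
    genome: GenomeRecord | str, min_len: int = 50
) -> tuple[tuple[int, int], tuple[int, int], int] | None:
    """Longest pair of disjoint exact reverse-complement repeats.

    Returns ``(interval_a, interval_b, length)`` with ``interval_a`` the
    leftmost copy, or ``None`` if no such pair of length >= ``min_len``
    exists. Found by binary search over the repeat length with rolling-hash
    matching between the genome and its reverse complement; every hash hit
    is verified by direct comparison.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    n = len(seq)
    if min_len < 1 or n < 2 * min_len:
        return None
    rc = revcomp(seq)
    hf = _WindowHasher(seq)
    hr = _WindowHasher(rc)

    def candidate(L: int) -> tuple[int, int] | None:
        """Some (i, j) with seq[i:i+L] == revcomp-copy at [j, j+L), disjoint."""
        table: dict[int, list[int]] = {}
        for i in range(n - L + 1):
            table.setdefault(hf.window(i, L), []).append(i)
        for jr in range(n - L + 1):
            hits = table.get(hr.window(jr, L))
            if not hits:
                continue
            j = n - jr - L  # genome-coordinate start of the rc window
            for i in hits:
                a, b = (i, j) if i <= j else (j, i)
                if a + L <= b and seq[i:i + L] == rc[jr:jr + L]:
                    return a, b
        return None

    lo, hi = min_len, n // 2
    best = None
    # invariant: feasibility is monotone (any repeat of length L contains one
    # of length L-1), so plain binary search finds the maximum
    while lo <= hi:
        mid = (lo + hi) // 2
        hit = candidate(mid)
        if hit is not None:
            best = (hit[0], hit[1], mid)
            lo = mid + 1
        else:
            hi = mid - 1
    if best is None:
        return None
    a, b, L = best
    return (a, a + L), (b, b + L), L


@dataclass(frozen=True)
class QuadripartitePartition:
    """IRa/IRb/LSC/SSC layout of a circular plastome.

    The SSC interval (and in degenerate layouts the LSC) may wrap the
    origin, in which case it is given as the pair of sub-intervals.
    """

    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[tuple[int, int], ...]
    ssc: tuple[tuple[int, int], ...]

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    @property
    def lsc_length(self) -> int:
        return sum(e - s for s, e in self.lsc)

    @property
    def ssc_length(self) -> int:
        return sum(e - s for s, e in self.ssc)


def partition_quadripartite(
    genome: GenomeRecord, ir_pair: tuple[tuple[int, int], tuple[int, int]]
) -> QuadripartitePartition:
    """Partition a circular genome into IRa/IRb and the two single-copy gaps.

    The longer gap is labeled LSC; on a tie the gap containing genome
    position 0 is the LSC (deterministic tie-break).
    """
    (a0, a1), (b0, b1) = sorted(ir_pair)
    if a1 > b0:
        raise ValidationError("partition_quadripartite: IR intervals overlap")
    if genome.sequence[a0:a1] != revcomp(genome.sequence[b0:b1]):
        raise ValidationError("partition_quadripartite: intervals are not an IR pair")
    n = genome.length
    gap_inner: tuple[tuple[int, int], ...] = ((a1, b0),) if a1 < b0 else ()
    outer_parts = []
    if b1 < n:
        outer_parts.append((b1, n))
    if a0 > 0:
        outer_parts.append((0, a0))
    gap_outer = tuple(outer_parts)
    inner_len = sum(e - s for s, e in gap_inner)
    outer_len = sum(e - s for s, e in gap_outer)
    if inner_len > outer_len:
        lsc, ssc = gap_inner, gap_outer
    elif outer_len > inner_len:
        lsc, ssc = gap_outer, gap_inner
    else:
        # tie: the gap containing position 0 is the LSC
        outer_has_origin = any(s == 0 for s, _ in gap_outer)
        lsc, ssc = (gap_outer, gap_inner) if outer_has_origin else (gap_inner, gap_outer)
    return QuadripartitePartition(ira=(a0, a1), irb=(b0, b1), lsc=lsc, ssc=ssc)


# ---------------------------------------------------------------------------
# gene inventories

PRESENT, PSEUDO, ABSENT = "+", "ψ", "-"


@dataclass
class GeneInventory:
    """Gene -> status map for one genome; statuses: '+', 'ψ', '-'."""

    genome_id: str
    status: dict[str, str]

    def __post_init__(self):
        bad = {g: s for g, s in self.status.items() if s not in (PRESENT, PSEUDO, ABSENT)}
        if bad:
            raise ValidationError(f"{self.genome_id}: invalid statuses {bad}")


def compare_inventories(inventories: list[GeneInventory]) -> pd.DataFrame:
    """Presence/pseudogene/absence matrix across genomes.

    One row per union gene name (first-seen order), one column per genome;
    genes unlisted in an inventory are '-'.
    """
    if len(inventories) < 2:
        raise ValidationError("compare_inventories needs at least two genomes")
    genes: list[str] = []
    seen = set()
    for inv in inventories:
        for g in inv.status:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    data = {
        inv.genome_id: [inv.status.get(g, ABSENT) for g in genes]
        for inv in inventories
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def structure_report(genome: GenomeRecord, min_ir_len: int = 1000) -> dict:
    """Length, GC, and (when an IR is found) quadripartite metrics."""
    report: dict = {
        "genome": genome.id,
        "length_bp": genome.length,
        "gc_percent": gc_content(genome),
    }
    ir = find_max_inverted_repeat(genome, min_len=min_ir_len)
    if ir is None:
        report["ir_length_bp"] = 0
        return report
    (a0, a1), (b0, b1), L = ir
    part = partition_quadripartite(genome, ((a0, a1), (b0, b1)))
    report.update(
        ir_length_bp=L,
        ir_gc_percent=gc_content(genome.sequence[a0:a1]),
        lsc_length_bp=part.lsc_length,
        ssc_length_bp=part.ssc_length,
        ira=(a0 + 1, a1),  # 1-based inclusive for reporting
        irb=(b0 + 1, b1),
    )
    return report
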