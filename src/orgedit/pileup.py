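"""Strand-aware per-position base counts from SAM alignments.

Converts alignments against the organelle reference into a compact count
matrix (position x base x read strand), the input of the editing caller,
and can retrieve the reads supporting a given allele for the contamination
screen.

Counting rules: CIGAR M/=/X contribute, I/S/H contribute nothing, D/N
leave the covered positions uncounted for that read; bases below
``min_base_quality`` are dropped when qualities are present; reads below
``min_mapq`` and unmapped/secondary/supplementary/duplicate records are
skipped. The count strand is the SAM flag strand of the read; transcript
sense is resolved later by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam

from .genome import FormatError, GenomeRecord

BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

STRANDS = "+-"


@dataclass(frozen=True)
class SiteCounts:
    """Base tallies at one genome position, split by read strand."""

    pos: int
    ref_base: str
    counts: dict  # (base, strand) -> int

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def base_count(self, base: str) -> int:
        return self.counts.get((base, "+"), 0) + self.counts.get((base, "-"), 0)


class Pileup:
    """Count matrix over the whole genome.

    ``counts[pos, base_index, strand_index]`` with bases in ACGT order and
    strands (+, -). Exposes per-site views as :class:`SiteCounts`.
    """

    def __init__(self, genome: GenomeRecord, counts: np.ndarray):
        assert counts.shape == (genome.length, 4, 2)
        self.genome = genome
        self.counts = counts

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def site(self, pos: int) -> SiteCounts:
        c = {
            (b, s): int(self.counts[pos, bi, si])
            for bi, b in enumerate(BASES)
            for si, s in enumerate(STRANDS)
            if self.counts[pos, bi, si]
        }
        return SiteCounts(pos=pos, ref_base=self.genome.sequence[pos], counts=c)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = [f"{b}{s}" for b in BASES for s in STRANDS]
            fh.write("pos\tref\t" + "\t".join(cols) + "\tdepth\n")
            depth = self.depth
            for pos in np.nonzero(depth)[0]:
                vals = "\t".join(str(int(v)) for v in self.counts[pos].ravel())
                fh.write(
                    f"{pos + 1}\t{self.genome.sequence[pos]}\t{vals}\t{int(depth[pos])}\n"
                )


def read_sam(path, genome: GenomeRecord) -> Iterator[pysam.AlignedSegment]:
    """Yield mapped, primary, non-duplicate alignments against ``genome``.

    Raises :class:`FormatError` if the reference name in the header does
    not match the genome id.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        refs = list(fh.references)
        if genome.id not in refs:
            raise FormatError(
                f"{path}: reference(s) {refs} do not include genome {genome.id!r}"
            )
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_duplicate:
                continue
            if aln.reference_name != genome.id:
                continue
            yield aln


def build_pileup(
    alignments: Iterable[pysam.AlignedSegment],
    genome: GenomeRecord,
    min_base_quality: int = 20,
    min_mapq: int = 0,
) -> Pileup:
    """Accumulate strand-aware base counts from an alignment stream."""
    counts = np.zeros((genome.length, 4, 2), dtype=np.int32)
    flat = counts.reshape(-1)
    for aln in alignments:
        if aln.mapping_quality < min_mapq:
            continue
        seq = aln.query_sequence
        if not seq:
            continue
        pairs = aln.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        arr = np.asarray(pairs, dtype=np.int64)
        qpos, rpos = arr[:, 0], arr[:, 1]
        codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)][qpos]
        keep = codes >= 0
        quals = aln.query_qualities
        if quals is not None and min_base_quality > 0:
            keep &= np.asarray(quals, dtype=np.int16)[qpos] >= min_base_quality
        if not keep.all():
            qpos, rpos, codes = qpos[keep], rpos[keep], codes[keep]
        strand = 1 if aln.is_reverse else 0
        np.add.at(flat, rpos * 8 + codes * 2 + strand, 1)
    return Pileup(genome, counts)


@dataclass(frozen=True)
class SupportingRead:
    name: str
    segment: str  # aligned query sequence, reference orientation
    strand: str


def collect_site_reads(
    path,
    genome: GenomeRecord,
    positions: Iterable[int],
    min_base_quality: int = 20,
    min_mapq: int = 0,
) -> dict[int, dict[str, list[SupportingRead]]]:
    """Reads supporting each allele at the requested positions.

    Second pass over the SAM; returns ``{pos: {base: [SupportingRead]}}``.
    Filters match :func:`build_pileup` so support is consistent with counts.
    """
    wanted = set(int(p) for p in positions)
    out: dict[int, dict[str, list[SupportingRead]]] = {p: {} for p in wanted}
    for aln in read_sam(path, genome):
        if aln.mapping_quality < min_mapq:
            continue
        if not aln.query_sequence:
            continue
        start, end = aln.reference_start, aln.reference_end
        hits = [p for p in wanted if start <= p < end]
        if not hits:
            continue
        quals = aln.query_qualities
        pairs = dict((r, q) for q, r in aln.get_aligned_pairs(matches_only=True))
        for p in hits:
            q = pairs.get(p)
            if q is None:
                continue
            base = aln.query_sequence[q].upper()
            if base not in BASES:
                continue
            if quals is not None and min_base_quality > 0 and quals[q] < min_base_quality:
                continue
            rec = SupportingRead(
                name=aln.query_name,
                segment=aln.query_alignment_sequence.upper(),
                strand="-" if aln.is_reverse else "+",
            )
            out[p].setdefault(base, []).append(rec)
    return out
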