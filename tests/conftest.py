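"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import pytest
from hypothesis import HealthCheck, settings

from orgedit.caller import CandidateSite, EditingSite
from orgedit.context import SiteContext
from orgedit.genome import Annotation, Feature, GenomeRecord
from orgedit.util import revcomp

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independently hand-entered standard genetic code (oracle for translation):
# amino acids in TCAG x TCAG x TCAG codon order
_AA_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def standard_code_oracle() -> dict[str, str]:
    order = "TCAG"
    table = {}
    i = 0
    for b1 in order:
        for b2 in order:
            for b3 in order:
                table[b1 + b2 + b3] = _AA_TCAG[i]
                i += 1
    return table


@pytest.fixture(scope="session")
def code_oracle():
    return standard_code_oracle()


# ---------------------------------------------------------------------------
# toy genome fixtures


def make_cds_genome(codons: str, strand: str = "+", flank: int = 12):
    """Genome carrying one CDS 'ATG'+codons+'TAA' on the given strand.

    Returns (genome, cds_feature). Flanks are A-runs (never C/T on the
    sense strand used by tests).
    """
    coding = "ATG" + codons + "TAA"
    insert = coding if strand == "+" else revcomp(coding)
    seq = "A" * flank + insert + "A" * flank
    cds = Feature(
        gene="toy", kind="CDS", strand=strand,
        parts=((flank, flank + len(coding)),),
    )
    return GenomeRecord(id="toy", sequence=seq), cds


def make_site(pos: int, ref: str, alt: str, conversion: str, efficiency: float,
              feature: Feature | None = None, kind: str = "CDS",
              gene: str | None = "toy", status: str = "accepted") -> EditingSite:
    """Minimal accepted EditingSite for aggregation tests."""
    depth = 1000
    ctx = SiteContext(
        feature_kind=kind, gene=gene,
        strand=feature.strand if feature else "+", feature=feature,
    )
    return EditingSite(
        candidate=CandidateSite(pos=pos, ref_base=ref, alt_base=alt,
                                alt_count=int(efficiency * depth), depth=depth),
        sense_ref="C" if conversion == "C→U" else "T",
        sense_alt="T" if conversion == "C→U" else "C",
        sense_conversion=conversion,
        orientation_source="gene_strand",
        context=ctx,
        status=status,
    )


# ---------------------------------------------------------------------------
# SAM helpers and the per-read re-walk pileup oracle


def write_sam(path, reads, ref_id="toy", ref_len=100):
    """Write a minimal SAM. reads: (name, flag, pos1, mapq, cigar, seq, qual)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{ref_id}\tLN:{ref_len}"]
    for name, flag, pos1, mapq, cigar, seq, qual in reads:
        lines.append(
            f"{name}\t{flag}\t{ref_id}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def pileup_oracle(reads, ref_len, min_base_quality=20, min_mapq=0):
    """Re-walk each CIGAR by hand; returns {(pos, base, strand): count}.

    Independent of pysam: consumes the SAM tuples directly. Skips
    unmapped (0x4), secondary (0x100), supplementary (0x800) and duplicate
    (0x400) records, applies MAPQ and base-quality filters, counts M/=/X
    columns only.
    """
    counts: dict[tuple[int, str, str], int] = {}
    for name, flag, pos1, mapq, cigar, seq, qual in reads:
        if flag & (0x4 | 0x100 | 0x800 | 0x400):
            continue
        if mapq < min_mapq:
            continue
        strand = "-" if flag & 0x10 else "+"
        rpos = pos1 - 1
        qpos = 0
        for n, op in _CIG_RE.findall(cigar):
            n = int(n)
            if op in "M=X":
                for k in range(n):
                    base = seq[qpos + k].upper()
                    q = ord(qual[qpos + k]) - 33 if qual != "*" else None
                    if base in "ACGT" and (q is None or q >= min_base_quality):
                        key = (rpos + k, base, strand)
                        counts[key] = counts.get(key, 0) + 1
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
            # H and P consume nothing we track
    return counts


def pileup_to_dict(pile):
    """Flatten a Pileup into the oracle's {(pos, base, strand): count} form."""
    out = {}
    import numpy as np

    from orgedit.pileup import BASES, STRANDS

    for pos in np.nonzero(pile.depth)[0]:
        for bi, b in enumerate(BASES):
            for si, s in enumerate(STRANDS):
                c = int(pile.counts[pos, bi, si])
                if c:
                    out[(int(pos), b, s)] = c
    return out


# ---------------------------------------------------------------------------
# O(n^2) inverted-repeat oracle


def brute_force_ir(seq: str, min_len: int):
    """Longest disjoint exact reverse-complement repeat, quadratic DP.

    Returns the length, or None. M[i][j] = longest common extension of
    seq[i:] and revcomp(seq)[j:]; the largest disjoint-feasible L for each
    (i, j) follows in closed form from the interval geometry.
    """
    n = len(seq)
    t = revcomp(seq)
    best = 0
    rows = [[0] * (n + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(n - 1, -1, -1):
            rows[i][j] = rows[i + 1][j + 1] + 1 if seq[i] == t[j] else 0
    for i in range(n):
        for j in range(n):
            m = rows[i][j]
            if m <= best:
                continue
            # match at genome intervals [i, i+L) and [n-j-L, n-j)
            if n - j <= i:  # rc copy lies left of i for every L <= m
                L = m
            else:
                L = min(m, (n - j - i) // 2)
            if L > best:
                best = L
    return best if best >= min_len else None


@pytest.fixture
def toy_two_exon():
    """30 bp genome with a two-exon minus-strand CDS for splice tests.

    Transcript-sense coding sequence is ATGCCTTGGTAA (Met-Pro-Trp-Stop):
    exon2 (genomic [5, 11)) then exon1 (genomic [17, 23)) in genome order,
    transcript reads exon at [17,23) first because strand is '-'.
    """
    coding = "ATGCCTTGGTAA"
    ex1, ex2 = coding[:6], coding[6:]
    seq = "AAAAA" + revcomp(ex2) + "GGGTTT" + revcomp(ex1) + "AAAAAAA"
    assert len(seq) == 30
    genome = GenomeRecord(id="toy2ex", sequence=seq)
    cds = Feature(gene="toy", kind="CDS", strand="-",
                  parts=((17, 23), (5, 11)))
    ann = Annotation(genome_id="toy2ex", features=[cds])
    return genome, ann, cds, coding
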