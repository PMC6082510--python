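"""Genome and annotation data model.

Holds the coordinate backbone for the whole pipeline: organelle genome
sequences, stranded (possibly multi-exon) gene models, sequence I/O,
spliced-sequence extraction, translation, and codon bookkeeping.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere; GFF3 and SAM
  1-based coordinates are converted at the I/O boundary only.
* Sequences are stored uppercase over {A, C, G, T, N}; ``U`` on input is
  stored as ``T`` (the internal model is DNA, conversions are discussed in
  the RNA alphabet downstream).
* Circular genomes are supported at the feature level (an origin-spanning
  feature is simply two parts); pileups treat the sequence as linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pyranges as pr
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import VALID_BASES, revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron", "pseudogene")


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3)."""


class ValidationError(ValueError):
    """Internally inconsistent genome/annotation."""


class ContextError(ValueError):
    """A position queried outside the feature that should contain it."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single organelle genome sequence."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"genome {self.id!r}: illegal character {self.sequence[pos]!r} "
                f"at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


Interval = tuple[int, int]


@dataclass(frozen=True)
class Feature:
    """A stranded gene model.

    ``parts`` are 0-based half-open genomic intervals ordered 5'->3' in
    transcript sense: ascending genomic order on the + strand, descending
    on the - strand. For a CDS, parts are the exons and
    ``codon_start_offset`` (0/1/2) is the number of leading bases to trim
    before the first complete codon.
    """

    gene: str
    kind: str
    strand: str
    parts: tuple[Interval, ...]
    codon_start_offset: int = 0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"{self.gene}: unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene}: strand must be + or -")
        if not self.parts:
            raise ValidationError(f"{self.gene}: feature has no parts")
        if self.codon_start_offset not in (0, 1, 2):
            raise ValidationError(f"{self.gene}: codon_start_offset not in 0..2")
        for s, e in self.parts:
            if not (0 <= s < e):
                raise ValidationError(f"{self.gene}: bad interval [{s},{e})")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.parts)


@dataclass
class Annotation:
    """All gene models on one genome."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def validate(self, genome: GenomeRecord) -> None:
        for f in self.features:
            if f.end > genome.length:
                raise ValidationError(
                    f"{f.gene}: part ends at {f.end} beyond genome length "
                    f"{genome.length}"
                )
            if f.kind == "CDS":
                if (f.spliced_length - f.codon_start_offset) % 3 != 0:
                    raise ValidationError(
                        f"{f.gene}: CDS spliced length {f.spliced_length} "
                        f"(offset {f.codon_start_offset}) not a multiple of 3"
                    )


class GeneticCode:
    """Codon -> amino-acid table; defaults to the standard code (NCBI 1)."""

    def __init__(self, table: dict[str, str], start_codons: set[str], name: str = ""):
        if len(table) != 64:
            raise ValidationError(f"genetic code must have 64 entries, got {len(table)}")
        self.table = dict(table)
        self.start_codons = set(start_codons)
        self.name = name

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(t.forward_table)
        for stop in t.stop_codons:
            table[stop] = "*"
        return cls(table, set(t.start_codons), name=t.names[0])

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


# ---------------------------------------------------------------------------
# sequence I/O


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords.

    Sequences are uppercased and U is stored as T. Illegal characters or an
    empty file raise :class:`FormatError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(GenomeRecord(id=rec.id, sequence=seq))
        except (FormatError, ValidationError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_gff3(path, genome: GenomeRecord) -> Annotation:
    """Read CDS/tRNA/rRNA/intron/pseudogene features from a GFF3 file.

    Multi-line CDS features sharing an ID (or Parent) are grouped into one
    Feature with parts ordered in transcript sense; the phase column of the
    transcript-first segment supplies ``codon_start_offset``.
    """
    df = pr.read_gff3(str(path)).df
    df = df[df.Feature.isin(FEATURE_KINDS)]
    features: list[Feature] = []
    if df.empty:
        return Annotation(genome_id=genome.id, features=features)

    def _attr(row, *names):
        for n in names:
            v = row.get(n)
            if v is not None and isinstance(v, str) and v and v != "nan":
                return v
        return None

    # group discontinuous features by (kind, grouping id)
    df = df.copy()
    ids = []
    for _, row in df.iterrows():
        gid = _attr(row, "ID") or _attr(row, "Parent") or f"_anon{len(ids)}"
        ids.append((row["Feature"], gid))
    df["_group"] = ids
    for (kind, _gid), grp in df.groupby("_group", sort=False):
        strand = grp.Strand.iloc[0]
        parts = sorted(zip(grp.Start.astype(int), grp.End.astype(int)))
        for s, e in parts:
            if s < 0 or e > genome.length:
                raise ValidationError(
                    f"{path}: feature {_gid!r} interval [{s},{e}) outside "
                    f"genome of length {genome.length}"
                )
        if strand == "-":
            parts = parts[::-1]
        first = grp.sort_values("Start").iloc[-1 if strand == "-" else 0]
        phase = str(first.get("Frame", "0"))
        offset = int(phase) if phase in ("0", "1", "2") else 0
        gene = _attr(grp.iloc[0], "gene", "Name", "ID") or _gid
        feat = Feature(
            gene=gene,
            kind=kind,
            strand=strand,
            parts=tuple((int(s), int(e)) for s, e in parts),
            codon_start_offset=offset if kind == "CDS" else 0,
        )
        features.append(feat)
    ann = Annotation(genome_id=genome.id, features=features)
    ann.validate(genome)
    return ann


def write_gff3(annotation: Annotation, genome: GenomeRecord, path) -> None:
    """Write the annotation back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for i, f in enumerate(annotation.features):
            fid = f"{f.kind.lower()}{i}"
            parts = sorted(f.parts)
            for j, (s, e) in enumerate(parts):
                phase = "."
                if f.kind == "CDS":
                    # phase of the transcript-first segment only
                    is_first = (j == 0) if f.strand == "+" else (j == len(parts) - 1)
                    phase = str(f.codon_start_offset) if is_first else "0"
                fh.write(
                    f"{genome.id}\torgedit\t{f.kind}\t{s + 1}\t{e}\t.\t"
                    f"{f.strand}\t{phase}\tID={fid};gene={f.gene}\n"
                )


# ---------------------------------------------------------------------------
# coordinate arithmetic


def spliced_sequence(genome: GenomeRecord, feature: Feature) -> str:
    """Transcript-sense sequence of a feature.

    Parts are concatenated in transcript order; minus-strand features are
    reverse-complemented. For a CDS the ``codon_start_offset`` leading bases
    are trimmed so the result starts on a codon boundary.
    """
    if feature.strand == "+":
        seq = "".join(genome.sequence[s:e] for s, e in feature.parts)
    else:
        seq = "".join(revcomp(genome.sequence[s:e]) for s, e in feature.parts)
    if feature.kind == "CDS":
        seq = seq[feature.codon_start_offset:]
    return seq


def transcript_index(feature: Feature, pos: int) -> int:
    """0-based index of genomic ``pos`` within the (untrimmed) transcript."""
    offset = 0
    for s, e in feature.parts:
        if s <= pos < e:
            if feature.strand == "+":
                return offset + (pos - s)
            return offset + (e - 1 - pos)
        offset += e - s
    raise ContextError(f"position {pos} not in feature {feature.gene}")


def translate(seq: str, code: GeneticCode | None = None) -> str:
    """Translate a codon-aligned DNA string; internal stops render as '*'."""
    if code is None:
        code = GeneticCode.standard()
    if len(seq) % 3 != 0:
        raise ValidationError(f"sequence length {len(seq)} not a multiple of 3")
    return "".join(code[seq[i:i + 3]] for i in range(0, len(seq), 3))


class CodonAddress(NamedTuple):
    codon: str
    codon_index: int
    codon_position: int  # 1-based position of the site within its codon
    offset_in_codon: int  # 0-based, transcript sense


def codon_of(genome: GenomeRecord, cds: Feature, genomic_pos: int) -> CodonAddress:
    """Locate the codon containing a genomic position of a CDS.

    The codon is read in transcript sense, across splice junctions if
    needed. Raises :class:`ContextError` if the position is not inside the
    CDS or falls in the trimmed codon_start_offset region.
    """
    if cds.kind != "CDS":
        raise ContextError(f"{cds.gene}: codon_of requires a CDS feature")
    t = transcript_index(cds, genomic_pos) - cds.codon_start_offset
    if t < 0:
        raise ContextError(
            f"{cds.gene}: position {genomic_pos} precedes the first full codon"
        )
    coding = spliced_sequence(genome, cds)
    idx = t // 3
    codon = coding[idx * 3: idx * 3 + 3]
    if len(codon) < 3:
        raise ContextError(f"{cds.gene}: position {genomic_pos} in trailing partial codon")
    return CodonAddress(codon, idx, t % 3 + 1, t % 3)
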