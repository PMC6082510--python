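"""Synthetic organelle dataset generator with planted editing truth.

Generates an organelle-like genome (target GC, non-overlapping stranded
genes with optional introns, optional planted inverted repeat yielding a
quadripartite layout), plants C->U and U->C editing sites with per-site
efficiencies drawn from class-specific distributions, and emits aligned
RNA-seq-like reads (SAM) carrying the confounders a real experiment shows:
sequencing error, DNA-polymorphism sites at intermediate allele fractions,
and contaminant reads copied from a divergent decoy locus.

Default parameters emulate the mitogenome study conditions: 88 C->U plus
20 U->C sites spread over CDS/tRNA/intron/UTR contexts, ~100 bp reads at
200x mean depth, 0.5% base error, polymorphism allele fractions between
0.33 and 0.88. The default genome is 25 kb — organelle-like composition
at a scale where multi-replicate recovery studies stay fast; the real
mitogenome is ~212 kb.

The simulator writes post-mapping alignments directly (mapping is out of
scope); reads are genome-contiguous (unspliced organellar transcript
model) and never span the circular origin.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .caller import EditingSite
from .context import FeatureIndex
from .effects import codon_effect
from .genome import (
    Annotation,
    Feature,
    GeneticCode,
    GenomeRecord,
    ValidationError,
    codon_of,
    spliced_sequence,
    translate,
    write_fasta,
    write_gff3,
)
from .util import complement, revcomp

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    genome_length: int = 25_000
    gc_target: float = 44.0          # mitogenome-like GC percent
    n_genes: int = 18
    n_trna: int = 1
    n_rrna: int = 1
    intron_prob: float = 0.3
    ir_length: int = 0               # 0 = no inverted repeat (mitogenome-like)
    n_c_to_u: int = 88
    n_u_to_c: int = 20
    context_counts: dict = field(
        default_factory=lambda: {"CDS": 95, "tRNA": 1, "intron": 2, "UTR_proxy": 10}
    )
    u_to_c_context_counts: dict = field(
        default_factory=lambda: {"CDS": 17, "UTR_proxy": 3}
    )
    class_efficiency: dict = field(
        default_factory=lambda: {
            "conservative": (0.694, 0.12),
            "non_conservative": (0.55, 0.12),
            "synonymous": (0.414, 0.12),
            "noncoding": (0.50, 0.15),
        }
    )
    min_efficiency: float = 0.06     # truncation floor, just above the 5% preset
    codon_position_counts: tuple | None = None  # (n1, n2, n3) over CDS sites
    read_length: int = 100
    mean_depth: float = 200.0
    error_rate: float = 0.005
    n_polymorphism_sites: int = 0
    polymorphism_fraction_range: tuple = (0.33, 0.88)
    contaminant_fraction: float = 0.0
    decoy_divergence: float = 0.10
    utr_window: int = 100
    seed: int = 0

    def __post_init__(self):
        if sum(self.context_counts.values()) != self.n_c_to_u + self.n_u_to_c:
            raise ValidationError(
                "context_counts must sum to n_c_to_u + n_u_to_c"
            )
        if sum(self.u_to_c_context_counts.values()) != self.n_u_to_c:
            raise ValidationError("u_to_c_context_counts must sum to n_u_to_c")
        for k, n in self.u_to_c_context_counts.items():
            if n > self.context_counts.get(k, 0):
                raise ValidationError(f"more U->C sites than total sites in {k}")
        if not 0 <= self.error_rate < 1:
            raise ValidationError("error_rate must be in [0, 1)")
        if self.codon_position_counts is not None:
            if sum(self.codon_position_counts) != self.context_counts.get("CDS", 0):
                raise ValidationError(
                    "codon_position_counts must sum to the CDS context count"
                )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted editing site."""

    pos: int                  # 0-based genome position
    ref_base: str             # reference orientation
    alt_base: str
    sense_conversion: str     # C→U | U→C
    strand: str
    efficiency: float
    feature_kind: str
    gene: str
    intended_class: str       # conservative | non_conservative | synonymous | noncoding
    event: str | None = None  # codon event for CDS sites


@dataclass(frozen=True)
class PolymorphismRecord:
    pos: int
    ref_base: str
    alt_base: str
    sense_conversion: str     # anomalous label, e.g. A→G
    fraction: float


@dataclass
class SimulatedGenome:
    genome: GenomeRecord
    annotation: Annotation
    decoy: GenomeRecord
    decoy_locus: tuple[int, int]  # genome interval the decoy mirrors


# ---------------------------------------------------------------------------
# genome generation


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=probs)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _random_codons(n: int, gc: float, rng: np.random.Generator) -> str:
    """n sense codons, GC-biased, none of them stops."""
    out = []
    while len(out) < n:
        chunk = _random_bases(3 * (n - len(out)), gc, rng).reshape(-1, 3)
        for row in chunk:
            codon = _codes_to_str(row)
            if codon not in _STOPS:
                out.append(codon)
            if len(out) == n:
                break
    return "".join(out)


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Random organelle-like genome, annotation, and decoy contaminant.

    Genes (CDS with occasional single introns, one tRNA, one rRNA) are
    packed left to right with >= 250 bp intergenic gaps so UTR-proxy flanks
    never collide. When ``ir_length`` > 0 the tail of the genome is laid
    out as IRa / small single-copy gap / IRb (= revcomp of IRa), and the
    IR junction bases are adjusted so the planted repeat is maximal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = _random_bases(L, config.gc_target, rng)
    features: list[Feature] = []

    # region available for genes: keep the IR block (if any) gene-free
    ir_block = 2 * config.ir_length + max(2000, config.ir_length // 2) if config.ir_length else 0
    gene_space_end = L - ir_block - 10
    cursor = int(rng.integers(150, 300))

    def place(local_seq: str, kind: str, name: str, strand: str,
              intron: tuple[int, int] | None = None) -> bool:
        """Insert local_seq at cursor; intron = (start, length) in local coords."""
        nonlocal cursor, seq
        g0 = cursor
        glen = len(local_seq)
        if g0 + glen > gene_space_end:
            return False
        placed = local_seq if strand == "+" else revcomp(local_seq)
        seq[g0:g0 + glen] = [BASES.index(c) for c in placed]
        if intron is None:
            local_parts = [(0, glen)]
        else:
            i0, ilen = intron
            local_parts = [(0, i0), (i0 + ilen, glen)]
            ipart = [(i0, i0 + ilen)]
        def to_genomic(parts):
            if strand == "+":
                return [(g0 + s, g0 + e) for s, e in parts]
            return [(g0 + glen - e, g0 + glen - s) for s, e in parts]
        features.append(
            Feature(gene=name, kind=kind, strand=strand,
                    parts=tuple(to_genomic(local_parts)))
        )
        if intron is not None:
            features.append(
                Feature(gene=name, kind="intron", strand=strand,
                        parts=tuple(to_genomic(ipart)))
            )
        cursor = g0 + glen + int(rng.integers(250, 400))
        return True

    placed_genes = 0
    for i in range(config.n_genes):
        n_codons = int(rng.integers(90, 180))
        coding = "ATG" + _random_codons(n_codons, config.gc_target, rng) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        intron = None
        if rng.random() < config.intron_prob:
            ilen = int(rng.integers(120, 200))
            isite = int(rng.integers(30, len(coding) - 30))
            coding_genomic = coding[:isite] + _codes_to_str(
                _random_bases(ilen, config.gc_target, rng)
            ) + coding[isite:]
            if place(coding_genomic, "CDS", f"gene{i + 1:02d}", strand, (isite, ilen)):
                placed_genes += 1
            continue
        if place(coding, "CDS", f"gene{i + 1:02d}", strand, intron):
            placed_genes += 1
    if placed_genes < config.n_genes:
        raise SimulationError(
            f"could not pack {config.n_genes} genes into {L} bp "
            f"({placed_genes} placed)"
        )
    rrna = None
    for j in range(config.n_trna):
        strand = "+" if rng.random() < 0.5 else "-"
        if not place(_codes_to_str(_random_bases(75, config.gc_target, rng)),
                     "tRNA", f"trn{chr(88 + j)}", strand):
            raise SimulationError("no room for tRNA gene")
    for j in range(config.n_rrna):
        rrna_seq = _codes_to_str(_random_bases(1200, config.gc_target, rng))
        rrna_strand = "+" if rng.random() < 0.5 else "-"
        if not place(rrna_seq, "rRNA", f"rrn{26 - j}", rrna_strand):
            raise SimulationError("no room for rRNA gene")
        rrna = features[-1]

    if config.ir_length:
        ir = config.ir_length
        b1 = L
        b0 = b1 - ir
        a1 = b0 - max(2000, ir // 2)  # small single-copy gap
        a0 = a1 - ir
        if a0 <= cursor:
            raise SimulationError("ir_length too large for genome_length")
        seq[b0:b1] = [3 - c for c in seq[a0:a1][::-1]]  # revcomp copy
        # IRb abuts the genome end, so the pair can only extend at the inner
        # junction (right of IRa pairing with left of IRb); break it so the
        # planted repeat is exactly maximal
        if seq[a1] == 3 - seq[b0 - 1]:
            seq[a1] = (seq[a1] + 1) % 4
            if seq[a1] == 3 - seq[b0 - 1]:
                seq[a1] = (seq[a1] + 1) % 4

    # coding sequence rejects stop codons (AT-rich), which drifts genome GC
    # above target; retune free intergenic bases outside genes and IR to
    # land on gc_target
    occupied = np.zeros(L, dtype=bool)
    for f in features:
        for s, e in f.parts:
            occupied[s:e] = True
    if config.ir_length:
        occupied[a0:b1] = True
        occupied[max(0, a0 - 1)] = True  # junction guards: keep the planted
        occupied[b0 - 1] = True          # repeat exactly maximal
    seq_arr = np.asarray(seq)
    is_gc = (seq_arr == 1) | (seq_arr == 2)
    delta = int(is_gc.sum()) - int(round(L * config.gc_target / 100.0))
    free = np.nonzero(~occupied)[0]
    if delta > 0:
        pool = free[is_gc[free]]
        flip = rng.choice(pool, size=min(delta, pool.size), replace=False)
        seq_arr[flip] = rng.choice([0, 3], size=flip.size)  # G/C -> A/T
    elif delta < 0:
        pool = free[~is_gc[free]]
        flip = rng.choice(pool, size=min(-delta, pool.size), replace=False)
        seq_arr[flip] = rng.choice([1, 2], size=flip.size)  # A/T -> G/C
    seq = seq_arr.tolist()

    genome = GenomeRecord(id="synthOrg", sequence=_codes_to_str(seq), circular=True)
    annotation = Annotation(genome_id=genome.id, features=features)
    annotation.validate(genome)

    # decoy: divergent copy of the rRNA locus plus flanks (contamination in
    # real data concentrated in rRNA); central window if no rRNA gene
    if rrna is not None:
        d0 = max(0, rrna.start - 300)
        d1 = min(L, rrna.end + 300)
    else:
        d0, d1 = L // 2 - min(900, L // 4), L // 2 + min(900, L // 4)
    decoy_codes = np.array(seq[d0:d1])
    mut = rng.random(len(decoy_codes)) < config.decoy_divergence
    decoy_codes[mut] = (decoy_codes[mut] + rng.integers(1, 4, mut.sum())) % 4
    decoy = GenomeRecord(id="decoy_contaminant", sequence=_codes_to_str(decoy_codes))
    return SimulatedGenome(genome=genome, annotation=annotation, decoy=decoy,
                           decoy_locus=(d0, d1))


# ---------------------------------------------------------------------------
# truth planting


def _sense_base(genome: GenomeRecord, pos: int, strand: str) -> str:
    b = genome.sequence[pos]
    return b if strand == "+" else complement(b)


def _ref_alt(sense_conversion: str, strand: str) -> tuple[str, str]:
    sref, salt = ("C", "T") if sense_conversion == "C→U" else ("T", "C")
    if strand == "-":
        return complement(sref), complement(salt)
    return sref, salt


def _draw_efficiency(mean: float, sd: float, floor: float,
                     rng: np.random.Generator) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if floor < x <= 1.0:
            return float(x)
    raise SimulationError(f"cannot draw efficiency in ({floor}, 1] from N({mean},{sd})")


def plant_edits(sim: SimulatedGenome, config: SimConfig,
                rng: np.random.Generator | None = None) -> list[TruthRecord]:
    """Plant editing sites per the configured context/conversion composition.

    CDS sites land one per codon, outside the first and last codons;
    per-site efficiency is drawn from the intended class's truncated normal
    distribution. Raises :class:`SimulationError` when a context lacks
    enough eligible positions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genome, ann = sim.genome, sim.annotation
    code = GeneticCode.standard()
    index = FeatureIndex(ann, utr_window=config.utr_window)

    # eligible positions by context: (pos, strand, gene, feature, codon_key)
    eligible: dict[str, list] = {k: [] for k in config.context_counts}
    occupied = set()
    for f in ann.features:
        for s, e in f.parts:
            occupied.update(range(s, e))
    for f in ann.features:
        if f.kind == "CDS" and "CDS" in eligible:
            n_codons = (f.spliced_length - f.codon_start_offset) // 3
            for s, e in f.parts:
                for pos in range(s, e):
                    try:
                        addr = codon_of(genome, f, pos)
                    except Exception:
                        continue
                    if addr.codon_index in (0, n_codons - 1):
                        continue
                    eligible["CDS"].append(
                        (pos, f.strand, f.gene, f, (f.gene, addr.codon_index),
                         addr.codon_position)
                    )
        elif f.kind in eligible and f.kind in ("tRNA", "rRNA", "intron"):
            for s, e in f.parts:
                for pos in range(s, e):
                    eligible[f.kind].append((pos, f.strand, f.gene, f, None, None))
    if "UTR_proxy" in eligible:
        for f in ann.features:
            if f.kind == "intron":
                continue
            for w0, w1 in ((f.start - config.utr_window, f.start),
                           (f.end, f.end + config.utr_window)):
                for pos in range(max(0, w0), min(genome.length, w1)):
                    if pos not in occupied:
                        eligible["UTR_proxy"].append((pos, f.strand, f.gene, f, None, None))

    truth: list[TruthRecord] = []
    used_pos: set[int] = set()
    used_codons: set = set()
    # optional codon-position composition quota for CDS sites
    pos_quota = (
        {i + 1: n for i, n in enumerate(config.codon_position_counts)}
        if config.codon_position_counts is not None else None
    )
    for kind, total in config.context_counts.items():
        n_utc = config.u_to_c_context_counts.get(kind, 0)
        wanted = [("U→C", n_utc), ("C→U", total - n_utc)]
        pool = eligible.get(kind, [])
        order = rng.permutation(len(pool))
        for conversion, n_needed in wanted:
            need_base = "T" if conversion == "U→C" else "C"
            got = 0
            for idx in order:
                if got == n_needed:
                    break
                pos, strand, gene, feat, codon_key, codon_pos = pool[idx]
                if pos in used_pos or (codon_key and codon_key in used_codons):
                    continue
                if _sense_base(genome, pos, strand) != need_base:
                    continue
                if kind == "CDS" and pos_quota is not None:
                    if pos_quota.get(codon_pos, 0) <= 0:
                        continue
                event = None
                intended = "noncoding"
                if kind == "CDS":
                    eff_obj = codon_effect(genome, feat, pos, conversion, code)
                    event = eff_obj.event
                    if eff_obj.event == "synonymous":
                        intended = "synonymous"
                    else:
                        intended = ("conservative" if rng.random() < 0.7
                                    else "non_conservative")
                mean, sd = config.class_efficiency[intended]
                eff = _draw_efficiency(mean, sd, config.min_efficiency, rng)
                ref, alt = _ref_alt(conversion, strand)
                truth.append(TruthRecord(
                    pos=pos, ref_base=ref, alt_base=alt,
                    sense_conversion=conversion, strand=strand, efficiency=eff,
                    feature_kind=kind, gene=gene, intended_class=intended,
                    event=event,
                ))
                used_pos.add(pos)
                if codon_key:
                    used_codons.add(codon_key)
                if kind == "CDS" and pos_quota is not None:
                    pos_quota[codon_pos] -= 1
                got += 1
            if got < n_needed:
                raise SimulationError(
                    f"only {got}/{n_needed} eligible {conversion} positions in {kind}"
                )
    # sanity: context classification must agree with planting
    for t in truth:
        ctx = index.locate(t.pos)
        if ctx.feature_kind != t.feature_kind:
            raise SimulationError(
                f"planted {t.feature_kind} site at {t.pos} located as {ctx.feature_kind}"
            )
    return sorted(truth, key=lambda t: t.pos)


def plant_polymorphisms(sim: SimulatedGenome, config: SimConfig,
                        truth: list[TruthRecord],
                        rng: np.random.Generator | None = None) -> list[PolymorphismRecord]:
    """Plant DNA-polymorphism sites with intermediate allele fractions.

    Conversions are drawn in *sense* orientation from the anomalous set
    {A->G, T->G, G->T} so no polymorphism can masquerade as C->U or U->C
    editing regardless of the local gene strand.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    index = FeatureIndex(sim.annotation, utr_window=config.utr_window)
    taken = {t.pos for t in truth}
    lo, hi = config.polymorphism_fraction_range
    sense_alt = {"A": "G", "T": "G", "G": "T"}  # A→G, T→G, G→T
    out: list[PolymorphismRecord] = []
    tries = 0
    while len(out) < config.n_polymorphism_sites:
        tries += 1
        if tries > 100 * max(1, config.n_polymorphism_sites):
            raise SimulationError("cannot place polymorphism sites")
        pos = int(rng.integers(0, sim.genome.length))
        if pos in taken:
            continue
        ctx = index.locate(pos)
        strand = ctx.strand or "+"
        sbase = _sense_base(sim.genome, pos, strand)
        if sbase not in sense_alt:
            continue
        salt = sense_alt[sbase]
        ref, alt = (sbase, salt) if strand == "+" else (complement(sbase), complement(salt))
        out.append(PolymorphismRecord(
            pos=pos, ref_base=ref, alt_base=alt,
            sense_conversion=f"{sbase}→{salt}",
            fraction=float(rng.uniform(lo, hi)),
        ))
        taken.add(pos)
    return sorted(out, key=lambda p: p.pos)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    sim: SimulatedGenome,
    truth: list[TruthRecord],
    config: SimConfig,
    sam_path,
    polymorphisms: list[PolymorphismRecord] | None = None,
    rng: np.random.Generator | None = None,
    fastq_path=None,
) -> int:
    """Write aligned reads (SAM) with planted edits and confounders.

    Read count is mean_depth * genome_length / read_length; positions and
    strands are uniform. A read covering a planted site carries the edited
    base with probability equal to the planted efficiency; polymorphism
    alts appear in each covering read with probability equal to the allele
    fraction; iid base errors at ``error_rate``. Contaminant reads are
    copied from the decoy at the homologous locus and aligned there with
    all-M CIGARs like every other read. Returns the number of reads
    written.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    genome = sim.genome
    L, rl = genome.length, config.read_length
    n_reads = int(round(config.mean_depth * L / rl))
    code_of = {b: i for i, b in enumerate(BASES)}
    garr = np.array([code_of[c] for c in genome.sequence], dtype=np.int8)

    n_cont = int(round(config.contaminant_fraction * n_reads))
    d0, d1 = sim.decoy_locus
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    is_cont = np.zeros(n_reads, dtype=bool)
    if n_cont and d1 - d0 >= rl:
        cont_rows = rng.choice(n_reads, size=n_cont, replace=False)
        is_cont[cont_rows] = True
        starts[cont_rows] = rng.integers(d0, d1 - rl + 1, size=n_cont)
    reads = garr[starts[:, None] + np.arange(rl)[None, :]].copy()
    if n_cont and d1 - d0 >= rl:
        darr = np.array([code_of[c] for c in sim.decoy.sequence], dtype=np.int8)
        local = starts[cont_rows] - d0
        reads[cont_rows] = darr[local[:, None] + np.arange(rl)[None, :]]

    def inject(pos: int, alt: str, prob: float, allow_cont: bool = False):
        rows = np.nonzero((starts <= pos) & (starts > pos - rl)
                          & (allow_cont | ~is_cont))[0]
        if rows.size == 0:
            return
        hit = rows[rng.random(rows.size) < prob]
        reads[hit, pos - starts[hit]] = code_of[alt]

    for t in truth:
        inject(t.pos, t.alt_base, t.efficiency)
    for p in polymorphisms or []:
        inject(p.pos, p.alt_base, p.fraction)

    if config.error_rate > 0:
        err = rng.random(reads.shape) < config.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.int8)
        reads[err] = (reads[err] + shift) % 4

    is_rev = rng.integers(0, 2, size=n_reads).astype(bool)
    base_lookup = np.frombuffer(BASES.encode(), dtype=np.uint8)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": L}],
        "CO": [f"orgedit simulate_reads seed={config.seed}"],
    }
    quals = pysam.qualitystring_to_array("I" * rl)
    fq = open(fastq_path, "w") if fastq_path else None
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i in range(n_reads):
            a = pysam.AlignedSegment(out.header)
            prefix = "cont" if is_cont[i] else "read"
            a.query_name = f"{prefix}{i:07d}"
            seq = base_lookup[reads[i]].tobytes().decode()
            a.query_sequence = seq
            a.flag = 16 if is_rev[i] else 0
            a.reference_id = 0
            a.reference_start = int(starts[i])
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.query_qualities = quals
            out.write(a)
            if fq is not None:
                rseq = revcomp(seq) if is_rev[i] else seq
                fq.write(f"@{a.query_name}\n{rseq}\n+\n{'I' * rl}\n")
    if fq is not None:
        fq.close()
    return n_reads


# ---------------------------------------------------------------------------
# synthetic ortholog alignments


def write_ortholog_alignments(
    sim: SimulatedGenome,
    truth: list[TruthRecord],
    n_orthologs: int = 5,
    species_id: str = "study_species",
    noise: float = 0.02,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, str]]:
    """Synthetic ortholog protein alignments consistent with planted classes.

    For each CDS gene the study-species row is its pre-edit protein; the
    ortholog rows carry the post-edit amino acid at columns of sites
    planted as conservative and the pre-edit one at non-conservative (and
    synonymous) columns, plus light random noise elsewhere. Gap-free, so
    codon index equals alignment column.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    code = GeneticCode.standard()
    aas = "ACDEFGHIKLMNPQRSTVWY"
    by_gene: dict[str, list[TruthRecord]] = {}
    for t in truth:
        if t.feature_kind == "CDS":
            by_gene.setdefault(t.gene, []).append(t)
    out: dict[str, dict[str, str]] = {}
    for feat in sim.annotation.features:
        if feat.kind != "CDS":
            continue
        coding = spliced_sequence(sim.genome, feat)
        protein = translate(coding[: len(coding) // 3 * 3], code).rstrip("*")
        rows = {species_id: protein}
        edited_cols: dict[int, tuple[str, str]] = {}
        for t in by_gene.get(feat.gene, []):
            eff = codon_effect(sim.genome, feat, t.pos, t.sense_conversion, code)
            if eff.codon_index < len(protein):
                edited_cols[eff.codon_index] = (t.intended_class, eff.post_aa)
        for o in range(n_orthologs):
            chars = list(protein)
            for col, ch in enumerate(chars):
                if col in edited_cols:
                    klass, post_aa = edited_cols[col]
                    chars[col] = post_aa if klass == "conservative" else protein[col]
                elif rng.random() < noise:
                    chars[col] = aas[rng.integers(0, len(aas))]
            rows[f"ortholog{o + 1}"] = "".join(chars)
        out[feat.gene] = rows
    return out


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(
    called: list[EditingSite],
    truth: list[TruthRecord],
) -> dict:
    """Precision/recall/efficiency-MAE of called sites against truth.

    Matching is by exact genome position; the conversion confusion counter
    records (truth conversion, called conversion) pairs over matches.
    """
    truth_by_pos = {t.pos: t for t in truth}
    matched = []
    false_pos = []
    for s in called:
        t = truth_by_pos.get(s.pos)
        if t is None:
            false_pos.append(s)
        else:
            matched.append((s, t))
    n_called, n_truth = len(called), len(truth)
    precision = len(matched) / n_called if n_called else 0.0
    recall = len(matched) / n_truth if n_truth else 0.0
    mae = (
        sum(abs(s.efficiency - t.efficiency) for s, t in matched) / len(matched)
        if matched else 0.0
    )
    conv_confusion = Counter(
        (t.sense_conversion, s.sense_conversion) for s, t in matched
    )
    return {
        "n_called": n_called,
        "n_truth": n_truth,
        "n_matched": len(matched),
        "n_false_positive": len(false_pos),
        "precision": precision,
        "recall": recall,
        "efficiency_mae": mae,
        "conversion_confusion": dict(conv_confusion),
    }


# ---------------------------------------------------------------------------
# dataset assembly / truth table I/O

_TRUTH_COLS = ["pos", "ref", "alt", "sense_conversion", "strand", "efficiency",
               "feature_kind", "gene", "intended_class", "event"]


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TRUTH_COLS)
        for t in truth:
            w.writerow([t.pos + 1, t.ref_base, t.alt_base, t.sense_conversion,
                        t.strand, f"{t.efficiency:.4f}", t.feature_kind, t.gene,
                        t.intended_class, t.event or ""])


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(TruthRecord(
                pos=int(row["pos"]) - 1, ref_base=row["ref"], alt_base=row["alt"],
                sense_conversion=row["sense_conversion"], strand=row["strand"],
                efficiency=float(row["efficiency"]), feature_kind=row["feature_kind"],
                gene=row["gene"], intended_class=row["intended_class"],
                event=row["event"] or None,
            ))
    return out


@dataclass
class SimDataset:
    config: SimConfig
    sim: SimulatedGenome
    truth: list[TruthRecord]
    polymorphisms: list[PolymorphismRecord]
    orthologs: dict[str, dict[str, str]]
    sam_path: Path
    n_reads: int


def simulate_dataset(config: SimConfig, outdir) -> SimDataset:
    """Generate and write a complete dataset under ``outdir``.

    Produces ref.fa, genes.gff3, decoy.fa, reads.sam, truth.tsv and
    per-gene ortholog alignments under orthologs/.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = generate_genome(config, rng)
    truth = plant_edits(sim, config, rng)
    polys = plant_polymorphisms(sim, config, truth, rng)
    sam_path = outdir / "reads.sam"
    n_reads = simulate_reads(sim, truth, config, sam_path, polymorphisms=polys, rng=rng)
    orthologs = write_ortholog_alignments(sim, truth, rng=rng)
    write_fasta([sim.genome], outdir / "ref.fa")
    write_fasta([sim.decoy], outdir / "decoy.fa")
    write_gff3(sim.annotation, sim.genome, outdir / "genes.gff3")
    write_truth(truth, outdir / "truth.tsv")
    odir = outdir / "orthologs"
    odir.mkdir(exist_ok=True)
    for gene, rows in orthologs.items():
        with open(odir / f"{gene}.afa", "w") as fh:
            for sid, s in rows.items():
                fh.write(f">{sid}\n{s}\n")
    return SimDataset(config=config, sim=sim, truth=truth, polymorphisms=polys,
                      orthologs=orthologs, sam_path=sam_path, n_reads=n_reads)
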