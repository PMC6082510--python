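"""RNA-editing site caller.

From a strand-aware pileup, calls candidate RNA-DNA differences by
thresholding the edited-read fraction, orients each conversion into
transcript sense using the containing (or flanking) gene, quarantines
conversions outside the C->U / U->C editing space as anomalous, and
optionally screens alt-supporting reads against decoy contaminant
sequences with a k-mer containment test.

Editing efficiency is the fraction of all quality-passing covering reads
that carry the edited base (alt/depth, not alt/(alt+ref)). Thresholds are
inclusive: a site seen in at least 12% of plastome reads (5% mitogenome)
passes the organelle presets.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, replace

import numpy as np

from .context import DEFAULT_UTR_WINDOW, FeatureIndex, SiteContext
from .genome import Annotation, GenomeRecord
from .pileup import BASES, Pileup, SupportingRead
from .util import complement, revcomp

log = logging.getLogger(__name__)

#: minimum edited-read fractions used in the study
ORGANELLE_PRESETS = {"plastome": 0.12, "mitogenome": 0.05}

EDITING_CONVERSIONS = {("C", "T"): "C→U", ("T", "C"): "U→C"}

#: anomalous raw conversions the screen attributes to DNA polymorphism
POLYMORPHISM_CONVERSIONS = {"A→G", "T→G", "G→T"}


@dataclass(frozen=True)
class CallerConfig:
    min_edit_fraction: float = 0.05
    min_depth: int = 20
    decoy_kmer: int = 15
    utr_window: int = DEFAULT_UTR_WINDOW

    def __post_init__(self):
        if not (0 < self.min_edit_fraction <= 1):
            raise ValueError("min_edit_fraction must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @classmethod
    def preset(cls, organelle: str, **kw) -> "CallerConfig":
        return cls(min_edit_fraction=ORGANELLE_PRESETS[organelle], **kw)


@dataclass(frozen=True)
class CandidateSite:
    """A threshold-passing RNA-DNA difference in reference orientation."""

    pos: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int

    @property
    def efficiency(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class EditingSite:
    """An oriented candidate with its feature context and status."""

    candidate: CandidateSite
    sense_ref: str
    sense_alt: str
    sense_conversion: str  # "C→U", "U→C", or raw label like "A→G"
    orientation_source: str  # gene_strand | flank_gene_strand | unknown
    context: SiteContext
    status: str  # accepted | anomalous | contaminant_flagged
    in_rrna: bool = False

    @property
    def pos(self) -> int:
        return self.candidate.pos

    @property
    def efficiency(self) -> float:
        return self.candidate.efficiency


@dataclass(frozen=True)
class AnomalousSite:
    pos: int
    raw_conversion: str
    fraction: float
    gene: str | None
    feature_kind: str
    suspected_cause: str  # contamination | polymorphism | unknown


def call_candidates(pileup: Pileup, config: CallerConfig) -> list[CandidateSite]:
    """Threshold-passing candidates, one per position.

    Only the single most frequent non-reference base is considered at each
    position; a candidate is emitted iff alt/depth >= min_edit_fraction and
    depth >= min_depth (both inclusive).
    """
    counts = pileup.counts.sum(axis=2)  # pos x base, strands pooled
    depth = counts.sum(axis=1)
    ref_codes = np.array(
        [BASES.index(b) if b in BASES else -1 for b in pileup.genome.sequence],
        dtype=np.int64,
    )
    alt_counts = counts.copy()
    valid_ref = ref_codes >= 0
    rows = np.nonzero(valid_ref)[0]
    alt_counts[rows, ref_codes[rows]] = 0
    best_alt = alt_counts.argmax(axis=1)
    best_count = alt_counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
    mask = (
        valid_ref
        & (depth >= config.min_depth)
        & (best_count > 0)
        & (frac >= config.min_edit_fraction)
    )
    return [
        CandidateSite(
            pos=int(p),
            ref_base=BASES[ref_codes[p]],
            alt_base=BASES[best_alt[p]],
            alt_count=int(best_count[p]),
            depth=int(depth[p]),
        )
        for p in np.nonzero(mask)[0]
    ]


def orient_and_classify(candidate: CandidateSite, index: FeatureIndex) -> EditingSite:
    """Express the conversion in transcript sense and classify it.

    The sense strand is taken from the containing feature (gene body or
    intron), else from the nearest gene whose UTR-proxy flank covers the
    site, else the conversion is reported on the + strand with orientation
    ``unknown``. Sense C->T is canonical C->U editing, sense T->C is
    reverse U->C editing; anything else is anomalous.
    """
    ctx = index.locate(candidate.pos)
    if ctx.feature_kind == "intergenic":
        source, strand = "unknown", "+"
    elif ctx.feature_kind == "UTR_proxy":
        source, strand = "flank_gene_strand", ctx.strand
    else:
        source, strand = "gene_strand", ctx.strand
    if strand == "+":
        sref, salt = candidate.ref_base, candidate.alt_base
    else:
        sref, salt = complement(candidate.ref_base), complement(candidate.alt_base)
    conversion = EDITING_CONVERSIONS.get((sref, salt))
    if conversion is None:
        # anomalous conversions keep their DNA-alphabet label (G→T, A→G, ...)
        conversion = f"{sref}→{salt}"
        status = "anomalous"
    else:
        status = "accepted"
    return EditingSite(
        candidate=candidate,
        sense_ref=sref,
        sense_alt=salt,
        sense_conversion=conversion,
        orientation_source=source,
        context=ctx,
        status=status,
        in_rrna=ctx.feature_kind == "rRNA",
    )


# ---------------------------------------------------------------------------
# contamination screen


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _containment(segment: str, target_kmers: set[str], k: int) -> float:
    kmers = _kmer_set(segment, k)
    if not kmers:
        return 0.0
    return sum(km in target_kmers for km in kmers) / len(kmers)


def contamination_screen(
    site: EditingSite,
    site_reads: dict[str, list[SupportingRead]],
    genome: GenomeRecord,
    decoys: list[GenomeRecord],
    k: int = 15,
    flank: int = 200,
) -> EditingSite:
    """Flag a site whose alt reads look foreign.

    For each alt-supporting read segment, k-mer containment is computed
    against the reference locus (site +- ``flank``) and against every decoy
    sequence (both strands). If the median read scores strictly higher
    against a decoy than against the reference, the site status becomes
    ``contaminant_flagged``. With no decoys the site is returned unchanged.
    """
    if not decoys:
        return site
    reads = site_reads.get(site.candidate.alt_base, [])
    lo = max(0, site.pos - flank)
    hi = min(genome.length, site.pos + flank)
    ref_kmers = _kmer_set(genome.sequence[lo:hi], k)
    decoy_kmers: set[str] = set()
    for d in decoys:
        decoy_kmers |= _kmer_set(d.sequence, k)
        decoy_kmers |= _kmer_set(revcomp(d.sequence), k)
    margins = []
    for read in reads:
        if len(read.segment) < k:
            log.warning(
                "site %d: read %s shorter than k=%d, skipped in screen",
                site.pos + 1, read.name, k,
            )
            continue
        ref_score = _containment(read.segment, ref_kmers, k)
        decoy_score = _containment(read.segment, decoy_kmers, k)
        margins.append(decoy_score - ref_score)
    if margins and statistics.median(margins) > 0:
        return replace(site, status="contaminant_flagged")
    return site


def finalize_sites(sites: list[EditingSite]) -> tuple[list[EditingSite], list[AnomalousSite]]:
    """Partition processed sites into accepted sites and anomalies.

    Anomalies carry a suspected cause: ``contamination`` if flagged by the
    screen, ``polymorphism`` if the raw conversion is one of the DNA
    polymorphism signatures (A->G, T->G, G->T outside C/U space), else
    ``unknown``. The two outputs are disjoint and cover the input.
    """
    accepted: list[EditingSite] = []
    anomalies: list[AnomalousSite] = []
    for s in sites:
        if s.status == "accepted":
            accepted.append(s)
            continue
        if s.status == "contaminant_flagged":
            cause = "contamination"
        elif s.sense_conversion in POLYMORPHISM_CONVERSIONS:
            cause = "polymorphism"
        else:
            cause = "unknown"
        anomalies.append(
            AnomalousSite(
                pos=s.pos,
                raw_conversion=s.sense_conversion,
                fraction=s.efficiency,
                gene=s.context.gene,
                feature_kind=s.context.feature_kind,
                suspected_cause=cause,
            )
        )
    return accepted, anomalies


def call_editing_sites(
    pileup: Pileup,
    annotation: Annotation,
    config: CallerConfig,
    decoys: list[GenomeRecord] | None = None,
    sam_path=None,
) -> tuple[list[EditingSite], list[AnomalousSite]]:
    """Full calling pipeline: candidates -> orientation -> screen -> partition.

    The contamination screen runs only when both ``decoys`` and the
    ``sam_path`` needed to retrieve alt-supporting reads are provided.
    """
    from .pileup import collect_site_reads

    index = FeatureIndex(annotation, utr_window=config.utr_window)
    candidates = call_candidates(pileup, config)
    sites = [orient_and_classify(c, index) for c in candidates]
    if decoys and sam_path is not None and sites:
        reads = collect_site_reads(
            sam_path, pileup.genome, [s.pos for s in sites]
        )
        sites = [
            contamination_screen(
                s, reads.get(s.pos, {}), pileup.genome, decoys, k=config.decoy_kmer
            )
            for s in sites
        ]
    return finalize_sites(sites)
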