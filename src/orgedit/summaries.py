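"""Aggregate statistics over annotated editing sites.

Produces the study-style summary: total site counts split by conversion
type, codon-position spectrum over CDS sites, start/stop events, counts by
genomic context, editing density relative to genome size, the amino-acid
conversion matrix, and cross-genome shared-site comparison through
per-gene protein alignments.

Percentages use the denominators the summary table implies (conversion
percentages over all sites, codon-position percentages over CDS sites)
and are truncated — not rounded — at two decimals, reproducing printed
values such as 94.11 for 96/102 and a density of 0.05% for 108 sites in a
212,153 bp genome.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .effects import AA3, AnnotatedSite, map_codon_to_column
from .genome import ValidationError
from .util import trunc_decimal

log = logging.getLogger(__name__)


def editing_density(n_sites: int, genome_length: int) -> float:
    """Edited sites as a percentage of genome size, truncated to 2 decimals."""
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    return trunc_decimal(100.0 * n_sites / genome_length, 2)


def _pct(num: int, denom: int) -> float:
    return trunc_decimal(100.0 * num / denom, 2) if denom else 0.0


@dataclass
class SummaryReport:
    n_sites: int
    n_c_to_u: int
    n_u_to_c: int
    pct_c_to_u: float
    pct_u_to_c: float
    n_cds_sites: int
    codon_position_counts: tuple[int, int, int]
    codon_position_pct: tuple[float, float, float]
    start_created: int
    start_removed: int
    stop_created: int
    stop_removed: int
    context_counts: dict = field(default_factory=dict)
    density_pct: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "n_sites": self.n_sites,
            "n_C_to_U": self.n_c_to_u,
            "n_U_to_C": self.n_u_to_c,
            "pct_C_to_U": self.pct_c_to_u,
            "pct_U_to_C": self.pct_u_to_c,
            "n_CDS_sites": self.n_cds_sites,
            "codon_position_counts": list(self.codon_position_counts),
            "codon_position_pct": list(self.codon_position_pct),
            "start_created": self.start_created,
            "start_removed": self.start_removed,
            "stop_created": self.stop_created,
            "stop_removed": self.stop_removed,
            "density_pct": self.density_pct,
        }
        d.update({f"n_{k}": v for k, v in sorted(self.context_counts.items())})
        return d


def editing_summary(annotated: list[AnnotatedSite], genome_length: int) -> SummaryReport:
    """Summary-table statistics over accepted, annotated sites."""
    n = len(annotated)
    n_ctu = sum(a.site.sense_conversion == "C→U" for a in annotated)
    n_utc = sum(a.site.sense_conversion == "U→C" for a in annotated)
    cds = [a for a in annotated if a.effect is not None]
    pos_counts = [0, 0, 0]
    events = Counter(a.effect.event for a in cds)
    for a in cds:
        pos_counts[a.effect.codon_position - 1] += 1
    ctx = Counter(a.site.context.feature_kind for a in annotated)
    return SummaryReport(
        n_sites=n,
        n_c_to_u=n_ctu,
        n_u_to_c=n_utc,
        pct_c_to_u=_pct(n_ctu, n),
        pct_u_to_c=_pct(n_utc, n),
        n_cds_sites=len(cds),
        codon_position_counts=tuple(pos_counts),
        codon_position_pct=tuple(_pct(c, len(cds)) for c in pos_counts),
        start_created=events.get("start_created", 0),
        start_removed=events.get("start_removed", 0),
        stop_created=events.get("stop_created", 0),
        stop_removed=events.get("stop_removed", 0),
        context_counts=dict(ctx),
        density_pct=editing_density(n, genome_length),
    )


@dataclass
class ConversionMatrix:
    """Per source amino acid: edited-codon total and destination multiset.

    Codons are counted once even when two sites hit the same codon; such
    codons get the jointly edited destination and are flagged.
    """

    rows: dict  # pre_aa(3-letter) -> Counter of post_aa(3-letter)
    start_created: int
    stop_created: int
    stop_removed: int
    multi_edited_codons: list

    @property
    def grand_total(self) -> int:
        return sum(sum(c.values()) for c in self.rows.values())

    def row_total(self, pre_aa3: str) -> int:
        return sum(self.rows.get(pre_aa3, Counter()).values())


def aa_conversion_matrix(annotated: list[AnnotatedSite], code=None) -> ConversionMatrix:
    """Amino-acid conversion matrix over edited codons.

    Groups CDS sites by (gene, codon index); a codon edited at several
    positions contributes one entry whose destination codon carries all
    edits jointly.
    """
    from .genome import GeneticCode

    if code is None:
        code = GeneticCode.standard()
    by_codon: dict[tuple[str, int], list[AnnotatedSite]] = {}
    for a in annotated:
        if a.effect is None:
            continue
        key = (a.site.context.gene or "?", a.effect.codon_index)
        by_codon.setdefault(key, []).append(a)
    rows: dict[str, Counter] = {}
    start_created = stop_created = stop_removed = 0
    multi = []
    for key, group in sorted(by_codon.items()):
        pre_codon = group[0].effect.pre_codon
        post_codon = list(pre_codon)
        for a in group:
            post_codon[a.effect.codon_position - 1] = a.effect.post_codon[
                a.effect.codon_position - 1
            ]
        post_codon = "".join(post_codon)
        pre_aa, post_aa = code[pre_codon], code[post_codon]
        rows.setdefault(AA3[pre_aa], Counter())[AA3[post_aa]] += 1
        if len(group) > 1:
            multi.append(key)
        events = {a.effect.event for a in group}
        start_created += "start_created" in events
        stop_created += pre_aa != "*" and post_aa == "*"
        stop_removed += pre_aa == "*" and post_aa != "*"
    return ConversionMatrix(
        rows=rows,
        start_created=start_created,
        stop_created=stop_created,
        stop_removed=stop_removed,
        multi_edited_codons=multi,
    )


def shared_sites(
    sites_a: list[AnnotatedSite],
    sites_b: list[AnnotatedSite],
    gene_name_map: dict[str, str] | None = None,
    alignments: dict[str, tuple[str, str]] | None = None,
) -> tuple[int, dict[str, int]]:
    """Editing sites shared between two genomes' CDS site lists.

    A pair of sites is shared iff they lie in the same gene (names mapped
    through ``gene_name_map`` from A's to B's nomenclature), at the same
    aligned protein column of the per-gene pairwise alignment
    ``alignments[geneA] = (rowA, rowB)``, with the same sense conversion.
    Genes without an alignment are skipped with a log message. Symmetric in
    its arguments by construction.
    """
    gene_name_map = gene_name_map or {}
    alignments = alignments or {}
    by_gene_b: dict[str, list[AnnotatedSite]] = {}
    for b in sites_b:
        if b.effect is not None and b.site.context.gene:
            by_gene_b.setdefault(b.site.context.gene, []).append(b)
    n_shared = 0
    per_gene: dict[str, int] = {}
    seen_b: set[int] = set()
    for a in sites_a:
        if a.effect is None or not a.site.context.gene:
            continue
        gene_a = a.site.context.gene
        gene_b = gene_name_map.get(gene_a, gene_a)
        if gene_a not in alignments:
            log.warning("gene %s has no pairwise alignment; skipped", gene_a)
            continue
        row_a, row_b = alignments[gene_a]
        col = map_codon_to_column(row_a, a.effect.codon_index)
        for b in by_gene_b.get(gene_b, []):
            if id(b) in seen_b:
                continue
            if b.site.sense_conversion != a.site.sense_conversion:
                continue
            if map_codon_to_column(row_b, b.effect.codon_index) == col:
                n_shared += 1
                per_gene[gene_a] = per_gene.get(gene_a, 0) + 1
                seen_b.add(id(b))
                break
    return n_shared, per_gene
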