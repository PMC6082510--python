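"""Codon-level effects and conservation classes of accepted editing sites.

For each accepted site in a CDS, computes the pre/post codon and amino
acid, detects start/stop events, and classifies the change against an
ortholog protein alignment: an edit is *conservative* when the post-edit
amino acid is strictly better represented than the pre-edit one at the
aligned column among the other species, *non-conservative* otherwise,
and *synonymous* when the amino acid is unchanged. Ties break to
non-conservative (a conservative call requires strict improvement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .caller import EditingSite
from .genome import Feature, GeneticCode, GenomeRecord, codon_of
from .util import round_half_up

log = logging.getLogger(__name__)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}


class DataError(ValueError):
    """Site and reference sequence disagree."""


@dataclass(frozen=True)
class CodonEffect:
    pre_codon: str
    post_codon: str
    pre_aa: str
    post_aa: str
    codon_index: int
    codon_position: int  # 1-based within the codon
    event: str  # synonymous | missense | start_created | start_removed |
    #             stop_created | stop_removed


@dataclass(frozen=True)
class ConservationCall:
    klass: str  # conservative | non_conservative | synonymous | unknown
    pre_support: int
    post_support: int


@dataclass(frozen=True)
class AnnotatedSite:
    site: EditingSite
    effect: CodonEffect | None  # None outside CDS
    conservation: ConservationCall | None


_SENSE_BASES = {"C→U": ("C", "T"), "U→C": ("T", "C")}


def codon_effect(
    genome: GenomeRecord,
    cds: Feature,
    pos: int,
    sense_conversion: str,
    code: GeneticCode | None = None,
) -> CodonEffect:
    """Effect of one editing event on its codon.

    The pre-codon is read from the genome in transcript sense; the
    post-codon substitutes the edited base. Raises :class:`DataError` if
    the genome base does not match the conversion's pre base.
    """
    if code is None:
        code = GeneticCode.standard()
    pre_base, post_base = _SENSE_BASES[sense_conversion]
    addr = codon_of(genome, cds, pos)
    if addr.codon[addr.offset_in_codon] != pre_base:
        raise DataError(
            f"{cds.gene} position {pos + 1}: codon {addr.codon} has "
            f"{addr.codon[addr.offset_in_codon]!r} where conversion "
            f"{sense_conversion} expects {pre_base!r}"
        )
    post_codon = (
        addr.codon[: addr.offset_in_codon] + post_base + addr.codon[addr.offset_in_codon + 1:]
    )
    pre_aa, post_aa = code[addr.codon], code[post_codon]
    if addr.codon_index == 0 and addr.codon not in code.start_codons and post_codon == "ATG":
        event = "start_created"
    elif addr.codon_index == 0 and addr.codon == "ATG" and post_codon != "ATG":
        event = "start_removed"
    elif pre_aa != "*" and post_aa == "*":
        event = "stop_created"
    elif pre_aa == "*" and post_aa != "*":
        event = "stop_removed"
    elif pre_aa == post_aa:
        event = "synonymous"
    else:
        event = "missense"
    return CodonEffect(
        pre_codon=addr.codon,
        post_codon=post_codon,
        pre_aa=pre_aa,
        post_aa=post_aa,
        codon_index=addr.codon_index,
        codon_position=addr.codon_position,
        event=event,
    )


def map_codon_to_column(aligned_row: str, codon_index: int) -> int:
    """Alignment column of the ``codon_index``-th residue of a species row.

    Counts ungapped positions; raises :class:`DataError` if the row has
    fewer residues.
    """
    seen = 0
    for col, ch in enumerate(aligned_row):
        if ch != "-":
            if seen == codon_index:
                return col
            seen += 1
    raise DataError(
        f"aligned row has only {seen} residues, codon index {codon_index} out of range"
    )


def conservation_class(
    effect: CodonEffect,
    alignment: dict[str, str],
    species_id: str,
    codon_index: int | None = None,
) -> ConservationCall:
    """Classify a codon effect against an ortholog protein alignment.

    ``alignment`` maps sequence id to aligned (gapped) protein string and
    must contain ``species_id``. Classification is invariant to the order
    of ortholog rows. On a missing species row or an all-gap column the
    class is ``unknown`` (logged), never silently guessed.
    """
    if effect.pre_aa == effect.post_aa:
        return ConservationCall("synonymous", 0, 0)
    if species_id not in alignment:
        log.warning("species %r absent from alignment; class unknown", species_id)
        return ConservationCall("unknown", 0, 0)
    idx = effect.codon_index if codon_index is None else codon_index
    try:
        col = map_codon_to_column(alignment[species_id], idx)
    except DataError as exc:
        log.warning("%s; class unknown", exc)
        return ConservationCall("unknown", 0, 0)
    others = [row[col] for sid, row in alignment.items() if sid != species_id]
    residues = [c for c in others if c != "-"]
    if not residues:
        log.warning("column %d all gaps among orthologs; class unknown", col)
        return ConservationCall("unknown", 0, 0)
    pre_n = sum(c == effect.pre_aa for c in residues)
    post_n = sum(c == effect.post_aa for c in residues)
    klass = "conservative" if post_n > pre_n else "non_conservative"
    return ConservationCall(klass, pre_n, post_n)


def annotate_sites(
    accepted: list[EditingSite],
    genome: GenomeRecord,
    code: GeneticCode | None = None,
    orthologs: dict[str, dict[str, str]] | None = None,
    species_id: str | None = None,
) -> list[AnnotatedSite]:
    """Attach codon effects (CDS sites) and conservation calls.

    ``orthologs`` maps gene name to an aligned protein dict; genes without
    an alignment (or with no ``species_id`` given) get class ``unknown``
    for non-synonymous effects.
    """
    if code is None:
        code = GeneticCode.standard()
    out = []
    for site in accepted:
        effect = conservation = None
        if site.context.feature_kind == "CDS" and site.context.feature is not None:
            effect = codon_effect(
                genome, site.context.feature, site.pos, site.sense_conversion, code
            )
            aln = (orthologs or {}).get(site.context.gene or "")
            if aln is not None and species_id is not None:
                conservation = conservation_class(effect, aln, species_id)
            elif effect.pre_aa == effect.post_aa:
                conservation = ConservationCall("synonymous", 0, 0)
            else:
                conservation = ConservationCall("unknown", 0, 0)
        out.append(AnnotatedSite(site=site, effect=effect, conservation=conservation))
    return out


def efficiency_by_class(annotated: list[AnnotatedSite]) -> dict[str, float]:
    """Unweighted mean editing efficiency per conservation class, percent.

    Only CDS sites with a known class contribute; empty classes are
    omitted. One-decimal half-up rounding.
    """
    sums: dict[str, list[float]] = {}
    for a in annotated:
        if a.conservation is None or a.conservation.klass == "unknown":
            continue
        sums.setdefault(a.conservation.klass, []).append(a.site.efficiency)
    return {
        k: round_half_up(100.0 * sum(v) / len(v), 1) for k, v in sums.items()
    }
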