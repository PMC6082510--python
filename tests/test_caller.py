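"""Editing caller: thresholding, strand orientation, anomaly handling,
contamination screen."""

import numpy as np
import pytest

from orgedit.caller import (
    CallerConfig,
    CandidateSite,
    call_candidates,
    contamination_screen,
    finalize_sites,
    orient_and_classify,
)
from orgedit.context import FeatureIndex
from orgedit.genome import Annotation, Feature, GenomeRecord
from orgedit.pileup import BASES, Pileup, SupportingRead
from orgedit.util import revcomp


def make_pileup(genome: GenomeRecord, site_counts: dict) -> Pileup:
    """site_counts: {pos: {base: n}} (counts split evenly across strands)."""
    counts = np.zeros((genome.length, 4, 2), dtype=np.int32)
    for pos, bases in site_counts.items():
        for base, n in bases.items():
            bi = BASES.index(base)
            counts[pos, bi, 0] = n // 2
            counts[pos, bi, 1] = n - n // 2
    return Pileup(genome, counts)


@pytest.fixture
def flat_genome():
    # C at every even position, A at odd: easy to place ref C sites
    return GenomeRecord(id="g", sequence="CA" * 150)


class TestCallCandidates:
    def test_inclusive_threshold_boundary(self, flat_genome):
        pile = make_pileup(flat_genome, {10: {"C": 88, "T": 12}})
        cfg = CallerConfig(min_edit_fraction=0.12, min_depth=20)
        (cand,) = call_candidates(pile, cfg)
        assert cand.pos == 10 and cand.alt_base == "T"
        assert cand.efficiency == pytest.approx(0.12)

    def test_below_threshold_rejected(self, flat_genome):
        pile = make_pileup(flat_genome, {10: {"C": 89, "T": 11}})
        cfg = CallerConfig(min_edit_fraction=0.12, min_depth=20)
        assert call_candidates(pile, cfg) == []

    def test_min_depth_filter(self, flat_genome):
        pile = make_pileup(flat_genome, {10: {"C": 10, "T": 9}})
        cfg = CallerConfig(min_edit_fraction=0.12, min_depth=20)
        assert call_candidates(pile, cfg) == []

    def test_only_most_frequent_alt_considered(self, flat_genome):
        pile = make_pileup(flat_genome, {10: {"C": 70, "T": 20, "G": 10}})
        (cand,) = call_candidates(pile, CallerConfig(min_edit_fraction=0.05))
        assert cand.alt_base == "T" and cand.alt_count == 20

    def test_efficiency_is_alt_over_total_depth(self, flat_genome):
        # denominator includes the minor third allele
        pile = make_pileup(flat_genome, {10: {"C": 70, "T": 20, "G": 10}})
        (cand,) = call_candidates(pile, CallerConfig(min_edit_fraction=0.05))
        assert cand.efficiency == pytest.approx(0.20)


def _annotation_with_gene(strand="+"):
    feat = Feature(gene="g1", kind="CDS", strand=strand, parts=((100, 160),))
    return Annotation(genome_id="g", features=[feat])


def _cand(genome_seq, pos, alt, frac=0.5):
    depth = 100
    return CandidateSite(pos=pos, ref_base=genome_seq[pos], alt_base=alt,
                         alt_count=int(frac * depth), depth=depth)


class TestOrientation:
    def test_plus_strand_c_to_t_is_canonical(self):
        seq = "A" * 100 + "C" + "A" * 199
        index = FeatureIndex(_annotation_with_gene("+"))
        site = orient_and_classify(_cand(seq, 100, "T"), index)
        assert site.sense_conversion == "C→U" and site.status == "accepted"
        assert site.orientation_source == "gene_strand"

    def test_minus_strand_g_to_a_is_canonical(self):
        seq = "A" * 100 + "G" + "A" * 199
        index = FeatureIndex(_annotation_with_gene("-"))
        site = orient_and_classify(_cand(seq, 100, "A"), index)
        assert site.sense_conversion == "C→U" and site.status == "accepted"

    def test_plus_strand_a_to_g_is_anomalous(self):
        seq = "C" * 100 + "A" + "C" * 199
        index = FeatureIndex(_annotation_with_gene("+"))
        site = orient_and_classify(_cand(seq, 100, "G"), index)
        assert site.status == "anomalous" and site.sense_conversion == "A→G"

    def test_flank_gives_utr_proxy_orientation(self):
        seq = "A" * 80 + "C" + "A" * 219
        index = FeatureIndex(_annotation_with_gene("+"), utr_window=100)
        site = orient_and_classify(_cand(seq, 80, "T"), index)
        assert site.orientation_source == "flank_gene_strand"
        assert site.context.feature_kind == "UTR_proxy"

    def test_intergenic_reported_on_plus_strand(self):
        seq = "T" * 300
        index = FeatureIndex(Annotation(genome_id="g", features=[]))
        site = orient_and_classify(_cand(seq, 10, "C"), index)
        assert site.orientation_source == "unknown"
        assert site.sense_conversion == "U→C"  # + strand reading


class TestFinalize:
    def test_partition_sizes_and_disjointness(self):
        seq = "A" * 100 + "CCCAA" + "A" * 195
        index = FeatureIndex(_annotation_with_gene("+"))
        sites = [
            orient_and_classify(_cand(seq, 100, "T"), index),  # C→U ok
            orient_and_classify(_cand(seq, 101, "T"), index),  # C→U ok
            orient_and_classify(_cand(seq, 102, "T"), index),  # C→U ok
            orient_and_classify(_cand(seq, 103, "G"), index),  # A→G anomalous
            orient_and_classify(_cand(seq, 104, "C"), index),  # A→C anomalous
        ]
        accepted, anomalies = finalize_sites(sites)
        assert len(accepted) == 3 and len(anomalies) == 2
        assert {a.pos for a in accepted}.isdisjoint({a.pos for a in anomalies})

    def test_polymorphism_cause_assignment(self):
        seq = "C" * 50 + "ATG" + "C" * 247
        index = FeatureIndex(Annotation(genome_id="g", features=[]))
        sites = [
            orient_and_classify(_cand(seq, 50, "G"), index),  # A→G
            orient_and_classify(_cand(seq, 51, "G"), index),  # T→G
            orient_and_classify(_cand(seq, 52, "T"), index),  # G→T
            orient_and_classify(_cand(seq, 52, "A"), index),  # G→A
        ]
        _, anomalies = finalize_sites(sites)
        causes = [a.suspected_cause for a in anomalies]
        assert causes == ["polymorphism", "polymorphism", "polymorphism", "unknown"]

    def test_contaminant_flag_overrides(self):
        seq = "A" * 100 + "C" + "A" * 199
        index = FeatureIndex(_annotation_with_gene("+"))
        site = orient_and_classify(_cand(seq, 100, "T"), index)
        from dataclasses import replace

        flagged = replace(site, status="contaminant_flagged")
        accepted, anomalies = finalize_sites([flagged])
        assert accepted == [] and anomalies[0].suspected_cause == "contamination"


class TestContaminationScreen:
    def _genome(self, rng):
        return GenomeRecord(
            id="g", sequence="".join("ACGT"[c] for c in rng.integers(0, 4, 600))
        )

    def test_decoy_copied_reads_flagged(self):
        rng = np.random.default_rng(42)
        genome = self._genome(rng)
        # decoy: 10% divergent copy of positions [200, 400)
        decoy_seq = list(genome.sequence[200:400])
        for i in range(0, 200, 10):
            decoy_seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy_seq[i]]
        decoy = GenomeRecord(id="decoy", sequence="".join(decoy_seq))
        pos = 300
        index = FeatureIndex(Annotation(genome_id="g", features=[
            Feature(gene="rrn", kind="rRNA", strand="+", parts=((200, 400),))
        ]))
        alt = "A" if genome.sequence[pos] != "A" else "C"
        site = orient_and_classify(_cand(genome.sequence, pos, alt), index)
        # alt reads copied verbatim from the decoy around the site
        reads = {alt: [
            SupportingRead(name=f"r{i}", segment=decoy.sequence[60 + i:160 + i], strand="+")
            for i in range(5)
        ]}
        out = contamination_screen(site, reads, genome, [decoy], k=15)
        assert out.status == "contaminant_flagged"

    def test_no_decoys_is_a_no_op(self):
        rng = np.random.default_rng(1)
        genome = self._genome(rng)
        index = FeatureIndex(Annotation(genome_id="g", features=[]))
        site = orient_and_classify(_cand(genome.sequence, 300, "A" if genome.sequence[300] != "A" else "C"), index)
        assert contamination_screen(site, {}, genome, []) == site

    def test_reads_matching_reference_not_flagged(self):
        rng = np.random.default_rng(2)
        genome = self._genome(rng)
        decoy = GenomeRecord(
            id="d", sequence="".join("ACGT"[c] for c in rng.integers(0, 4, 400))
        )
        ref = genome.sequence
        pos = ref.index("C", 280)  # a genuine C→U site so the baseline is accepted
        alt = "T"
        site = orient_and_classify(
            _cand(ref, pos, alt), FeatureIndex(Annotation(genome_id="g", features=[]))
        )
        # reads identical to the reference except the edited base
        reads = {alt: [
            SupportingRead(
                name=f"r{i}",
                segment=ref[pos - 50 - i:pos] + alt + ref[pos + 1:pos + 50 - i],
                strand="+",
            )
            for i in range(5)
        ]}
        out = contamination_screen(site, reads, genome, [decoy], k=15)
        assert out.status == site.status == "accepted"


def test_accepted_sites_respect_thresholds_end_to_end(tmp_path):
    """No accepted site may fall below the fraction or depth floor."""
    from orgedit.caller import call_editing_sites
    from orgedit.pileup import build_pileup, read_sam
    from orgedit.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(genome_length=12_000, n_genes=9, mean_depth=80,
                    n_c_to_u=20, n_u_to_c=5,
                    context_counts={"CDS": 21, "intron": 1, "UTR_proxy": 3},
                    u_to_c_context_counts={"CDS": 5}, seed=31)
    ds = simulate_dataset(cfg, tmp_path)
    g = ds.sim.genome
    pile = build_pileup(read_sam(ds.sam_path, g), g)
    ccfg = CallerConfig(min_edit_fraction=0.05, min_depth=20)
    accepted, anomalies = call_editing_sites(pile, ds.sim.annotation, ccfg)
    for s in accepted:
        assert s.efficiency >= 0.05 and s.candidate.depth >= 20
    assert {s.pos for s in accepted}.isdisjoint({a.pos for a in anomalies})


@pytest.mark.parametrize("seed", [4000, 4001, 4002])
def test_contaminant_reads_are_screened_not_accepted(tmp_path, seed):
    """Reads from a divergent decoy create apparent RNA-DNA differences at
    their locus; the k-mer screen quarantines every one while all planted
    editing sites are still recovered."""
    from orgedit.caller import call_editing_sites
    from orgedit.pileup import build_pileup, read_sam
    from orgedit.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(genome_length=8000, n_genes=5, mean_depth=150,
                    n_c_to_u=10, n_u_to_c=2,
                    context_counts={"CDS": 12}, u_to_c_context_counts={"CDS": 2},
                    contaminant_fraction=0.10, seed=seed)
    ds = simulate_dataset(cfg, tmp_path)
    g = ds.sim.genome
    d0, d1 = ds.sim.decoy_locus
    pile = build_pileup(read_sam(ds.sam_path, g), g)
    accepted, anomalies = call_editing_sites(
        pile, ds.sim.annotation, CallerConfig(min_edit_fraction=0.05),
        decoys=[ds.sim.decoy], sam_path=ds.sam_path,
    )
    truth_pos = {t.pos for t in ds.truth}
    assert {s.pos for s in accepted} == truth_pos
    assert not any(d0 <= s.pos < d1 and s.pos not in truth_pos for s in accepted)
    assert sum(a.suspected_cause == "contamination" for a in anomalies) > 50
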