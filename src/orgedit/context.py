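"""Genomic context lookup: which feature contains a position.

Organelle annotations have no UTR features, so positions within a
configurable flank window of a gene terminus are classed ``UTR_proxy``.
Overlapping features are resolved by precedence CDS > tRNA > rRNA >
intron > UTR_proxy > intergenic, then by leftmost gene start.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .genome import Annotation, Feature

KIND_PRECEDENCE = {"CDS": 0, "tRNA": 1, "rRNA": 2, "pseudogene": 3, "intron": 4}

DEFAULT_UTR_WINDOW = 100


@dataclass(frozen=True)
class SiteContext:
    feature_kind: str  # CDS | tRNA | rRNA | pseudogene | intron | UTR_proxy | intergenic
    gene: str | None
    strand: str | None  # sense strand of the assigned feature, None if intergenic
    feature: Feature | None


class FeatureIndex:
    """Interval index over an annotation for O(log n) context queries."""

    def __init__(self, annotation: Annotation, utr_window: int = DEFAULT_UTR_WINDOW):
        self.annotation = annotation
        self.utr_window = utr_window
        self.tree = IntervalTree()
        self.flank_tree = IntervalTree()
        for feat in annotation.features:
            for s, e in feat.parts:
                self.tree[s:e] = feat
            # UTR proxy flanks of gene-bearing features (not introns)
            if feat.kind != "intron" and utr_window > 0:
                if feat.start > 0:
                    self.flank_tree[max(0, feat.start - utr_window):feat.start] = feat
                self.flank_tree[feat.end:feat.end + utr_window] = feat

    def locate(self, pos: int) -> SiteContext:
        hits = sorted(
            (iv.data for iv in self.tree[pos]),
            key=lambda f: (KIND_PRECEDENCE.get(f.kind, 9), f.start, f.gene),
        )
        if hits:
            feat = hits[0]
            return SiteContext(
                feature_kind=feat.kind, gene=feat.gene, strand=feat.strand, feature=feat
            )
        flanks = sorted(
            (iv.data for iv in self.flank_tree[pos]),
            key=lambda f: (min(abs(pos - f.start), abs(pos - f.end)), f.start, f.gene),
        )
        if flanks:
            feat = flanks[0]
            return SiteContext(
                feature_kind="UTR_proxy", gene=feat.gene, strand=feat.strand, feature=feat
            )
        return SiteContext(feature_kind="intergenic", gene=None, strand=None, feature=None)
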