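"""Peak-to-gene annotators and the peak feature-distribution classifier.

Three annotator families stand in for the nearest-gene assignment tools used
in ChIP-seq target prioritization:

* ``nearest_tss`` — a gene is reported when a peak anchor lies within a
  symmetric window of its TSS (default 100 kb), the convention of
  binding-to-target assignment tools.
* ``feature``     — each peak anchor is classified against gene structure
  (promoter/UTR/exon/intron/downstream/intergenic) with a fixed precedence,
  the convention of feature-relative annotation tools; non-intergenic calls
  carry the assigned gene.
* ``gene_span``   — a gene is reported when a peak interval overlaps the
  strand-aware extended gene span [TSS - upstream, TES + downstream).

All three emit gene sets that feed the consensus voting stage.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .genome_model import Gene, GeneModel, GenomicInterval, Peak, PeakSet

log = logging.getLogger(__name__)

FEATURE_CATEGORIES = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "intergenic",
)
_PRECEDENCE = {cat: i for i, cat in enumerate(FEATURE_CATEGORIES)}

ANNOTATOR_KINDS = ("nearest_tss", "feature", "gene_span")


@dataclass(frozen=True)
class AnnotatorConfig:
    """Parameters of one annotator.

    tss_window applies to ``nearest_tss``; upstream/downstream to ``feature``
    (promoter and downstream window sizes) and ``gene_span`` (span
    extensions). ``anchor`` selects the peak summit when available, falling
    back to the peak center.
    """

    kind: str = "nearest_tss"
    tss_window: int = 100_000
    upstream: int = 5_000
    downstream: int = 1_000
    anchor: str = "peak_center"

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATOR_KINDS:
            raise ValueError(f"unknown annotator kind {self.kind!r}")
        if self.anchor not in ("peak_center", "summit"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if min(self.tss_window, self.upstream, self.downstream) < 0:
            raise ValueError("windows must be >= 0")

    def anchor_of(self, peak: Peak) -> int:
        return peak.anchor(use_summit=self.anchor == "summit")


@dataclass(frozen=True)
class FeatureCall:
    """One peak's feature classification (exactly one category per peak)."""

    peak: Peak
    category: str
    gene_id: str | None = None


def _check(peaks: PeakSet, model: GeneModel) -> None:
    if len(model) and len(peaks):
        model.check_chromosomes(peaks.chromosomes())


def annotate_nearest_tss(
    peaks: PeakSet, model: GeneModel, cfg: AnnotatorConfig
) -> set[str]:
    """Genes with a TSS within ``cfg.tss_window`` bp of any peak anchor.

    Every qualifying gene is reported; there is no single-nearest truncation.
    """
    if cfg.kind != "nearest_tss":
        raise ValueError(f"config kind {cfg.kind!r} != nearest_tss")
    if not len(model):
        log.warning("empty gene model: no genes to annotate")
        return set()
    _check(peaks, model)

    by_chrom: dict[str, tuple[list[int], list[str]]] = {}
    for g in model:
        by_chrom.setdefault(g.chrom, ([], []))
    for chrom in by_chrom:
        genes = sorted(model.genes_on(chrom), key=lambda g: g.tss)
        by_chrom[chrom] = ([g.tss for g in genes], [g.gene_id for g in genes])

    hits: set[str] = set()
    for peak in peaks:
        entry = by_chrom.get(peak.interval.chrom)
        if entry is None:
            continue
        tss_list, ids = entry
        a = cfg.anchor_of(peak)
        lo = bisect.bisect_left(tss_list, a - cfg.tss_window)
        hi = bisect.bisect_right(tss_list, a + cfg.tss_window)
        hits.update(ids[lo:hi])
    return hits


def _promoter(g: Gene, upstream: int) -> GenomicInterval | None:
    """Strand-aware promoter window [tss - upstream, tss) in gene direction."""
    if upstream == 0:
        return None
    if g.strand == "+":
        start, end = g.tss - upstream, g.tss
    else:
        start, end = g.tss + 1, g.tss + 1 + upstream
    if max(start, 0) >= end:
        return None
    return GenomicInterval(g.chrom, max(start, 0), end, g.strand)


def _downstream(g: Gene, downstream: int) -> GenomicInterval | None:
    """Strand-aware downstream window (tes, tes + downstream] in gene direction."""
    if downstream == 0:
        return None
    if g.strand == "+":
        start, end = g.tes + 1, g.tes + 1 + downstream
    else:
        start, end = g.tes - downstream, g.tes
    if max(start, 0) >= end:
        return None
    return GenomicInterval(g.chrom, max(start, 0), end, g.strand)


def _categorize(anchor: int, g: Gene, cfg: AnnotatorConfig) -> str | None:
    """Category of ``anchor`` relative to gene ``g``, or None if unrelated."""
    prom = _promoter(g, cfg.upstream)
    if prom is not None and prom.contains(anchor):
        return "promoter"
    if any(iv.contains(anchor) for iv in g.utr5):
        return "utr5"
    if any(iv.contains(anchor) for iv in g.utr3):
        return "utr3"
    if g.body.contains(anchor):
        if any(e.contains(anchor) for e in g.exons):
            return "exon"
        return "intron"
    down = _downstream(g, cfg.downstream)
    if down is not None and down.contains(anchor):
        return "downstream"
    return None


def annotate_by_feature(
    peaks: PeakSet, model: GeneModel, cfg: AnnotatorConfig
) -> tuple[set[str], list[FeatureCall]]:
    """Classify each peak anchor against gene structure.

    Precedence promoter > utr5 > utr3 > exon > intron > downstream >
    intergenic resolves anchors falling in several genes' features; ties at
    equal precedence break deterministically on gene_id. Non-intergenic calls
    carry the winning gene.
    """
    if cfg.kind != "feature":
        raise ValueError(f"config kind {cfg.kind!r} != feature")
    _check(peaks, model)
    margin = max(cfg.upstream, cfg.downstream)
    calls: list[FeatureCall] = []
    genes_hit: set[str] = set()
    for peak in peaks:
        a = cfg.anchor_of(peak)
        candidates = model.query(peak.interval.chrom, max(a - margin, 0), a + margin + 1)
        best: tuple[int, str, str] | None = None  # (precedence, gene_id, category)
        for g in candidates:
            cat = _categorize(a, g, cfg)
            if cat is None:
                continue
            key = (_PRECEDENCE[cat], g.gene_id, cat)
            if best is None or key < best:
                best = key
        if best is None:
            calls.append(FeatureCall(peak, "intergenic", None))
        else:
            _, gene_id, cat = best
            calls.append(FeatureCall(peak, cat, gene_id))
            genes_hit.add(gene_id)
    return genes_hit, calls


def annotate_gene_span(
    peaks: PeakSet, model: GeneModel, cfg: AnnotatorConfig
) -> set[str]:
    """Genes whose extended span overlaps any peak interval.

    The span is strand-aware: [TSS - upstream, TES + downstream) in the
    direction of transcription.
    """
    if cfg.kind != "gene_span":
        raise ValueError(f"config kind {cfg.kind!r} != gene_span")
    _check(peaks, model)
    hits: set[str] = set()
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for g in model:
        if g.strand == "+":
            start = g.body.start - cfg.upstream
            end = g.body.end + cfg.downstream
        else:
            start = g.body.start - cfg.downstream
            end = g.body.end + cfg.upstream
        span = GenomicInterval(g.chrom, max(start, 0), end, g.strand)
        for p in by_chrom.get(g.chrom, []):
            if span.overlaps(p.interval):
                hits.add(g.gene_id)
                break
    return hits


def annotate(peaks: PeakSet, model: GeneModel, cfg: AnnotatorConfig) -> set[str]:
    """Dispatch to the annotator selected by ``cfg.kind``."""
    if cfg.kind == "nearest_tss":
        return annotate_nearest_tss(peaks, model, cfg)
    if cfg.kind == "feature":
        return annotate_by_feature(peaks, model, cfg)[0]
    return annotate_gene_span(peaks, model, cfg)


def feature_distribution(
    calls: Iterable[FeatureCall],
) -> dict[str, tuple[int, float]]:
    """Counts and fractions per feature category; fractions sum to 1."""
    calls = list(calls)
    if not calls:
        raise ValueError("feature_distribution requires at least one call")
    counts = Counter(c.category for c in calls)
    total = len(calls)
    return {
        cat: (counts[cat], counts[cat] / total)
        for cat in FEATURE_CATEGORIES
        if counts[cat]
    }
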