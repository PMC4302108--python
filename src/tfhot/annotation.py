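"""Assign regions to genomic feature classes and putative target genes.

Feature calls are made at the region midpoint against a priority hierarchy
(promoter > 5' UTR > 3' UTR > exon > intron > intergenic) so that even wide
merged regions receive exactly one call. Gene assignment follows the
standard proximity rule: a promoter or gene-body hit wins outright,
otherwise the nearest gene within 50 kb (either side) is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel
from .stats import two_proportion_test

FEATURES = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")

DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 100
DEFAULT_MAX_DISTANCE = 50_000


@dataclass(frozen=True)
class FeatureCall:
    feature: str
    distance_to_tss: int | None  # signed; negative = upstream (strand-aware)

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str | None
    basis: str  # promoter | gene_body | nearest_within_50kb | unassigned

    def __post_init__(self) -> None:
        if (self.basis == "unassigned") != (self.gene_id is None):
            raise ValueError("unassigned iff gene_id absent")


def promoter_window(
    gene: GeneModel,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> GenomicInterval:
    """Strand-aware promoter interval: [TSS-up, TSS+down) on '+', mirrored
    on '-' (upstream is to the right of a minus-strand TSS)."""
    t = gene.tss
    if gene.interval.strand == "+":
        start, end = t - promoter_up, t + promoter_down
    else:
        start, end = t - promoter_down + 1, t + promoter_up + 1
    return GenomicInterval(gene.interval.chrom, max(0, start), end, gene.interval.strand)


def tss_distance(position: int, gene: GeneModel) -> int:
    """Signed strand-aware distance of a position from the gene's TSS
    (negative = upstream of transcription)."""
    if gene.interval.strand == "+":
        return position - gene.tss
    return gene.tss - position


def _contains(iv: GenomicInterval, chrom: str, pos: int) -> bool:
    return iv.chrom == chrom and iv.start <= pos < iv.end


def assign_feature(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> FeatureCall:
    """Classify a region by its midpoint into one genomic feature class.

    The call is order-invariant with respect to the gene list: membership
    in each feature class is evaluated over all genes before moving down
    the priority order. Genes without exon structure contribute their
    whole body as a single exon.
    """
    mid = region.midpoint
    chrom = region.chrom
    in_promoter = in_utr5 = in_utr3 = in_exon = in_body = False
    for gene in genes:
        if _contains(promoter_window(gene, promoter_up, promoter_down), chrom, mid):
            in_promoter = True
        if any(_contains(u, chrom, mid) for u in gene.utr5):
            in_utr5 = True
        if any(_contains(u, chrom, mid) for u in gene.utr3):
            in_utr3 = True
        if gene.interval.chrom == chrom and _contains(gene.interval, chrom, mid):
            in_body = True
            if any(_contains(e, chrom, mid) for e in gene.effective_exons):
                in_exon = True

    dist = nearest_tss_distance(region, genes)
    if in_promoter:
        feature = "promoter"
    elif in_utr5:
        feature = "utr5"
    elif in_utr3:
        feature = "utr3"
    elif in_exon:
        feature = "exon"
    elif in_body:
        feature = "intron"
    else:
        feature = "intergenic"
    return FeatureCall(feature, dist)


def nearest_tss_distance(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> int | None:
    """Signed distance from the region midpoint to the nearest TSS."""
    mid = region.midpoint
    best: int | None = None
    for gene in genes:
        if gene.interval.chrom != region.chrom:
            continue
        d = tss_distance(mid, gene)
        if best is None or abs(d) < abs(best):
            best = d
    return best


def map_to_gene(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> GeneAssignment:
    """Assign a region to at most one putative target gene.

    Overlap (>=1 bp) with a promoter window wins first, then overlap with a
    gene body, then the nearest gene by edge-to-edge distance within
    ``max_distance`` bp on either side. Distance ties break to the
    lexicographically smaller gene id.
    """
    promoter_hits = []
    body_hits = []
    for gene in genes:
        if gene.interval.chrom != region.chrom:
            continue
        if region.overlaps(promoter_window(gene, promoter_up, promoter_down)):
            promoter_hits.append(gene.gene_id)
        if region.overlaps(gene.interval):
            body_hits.append(gene.gene_id)
    if promoter_hits:
        return GeneAssignment(min(promoter_hits), "promoter")
    if body_hits:
        return GeneAssignment(min(body_hits), "gene_body")

    best: tuple[int, str] | None = None
    for gene in genes:
        if gene.interval.chrom != region.chrom:
            continue
        if region.end <= gene.interval.start:
            d = gene.interval.start - region.end
        elif gene.interval.end <= region.start:
            d = region.start - gene.interval.end
        else:  # pragma: no cover - overlap handled above
            d = 0
        cand = (d, gene.gene_id)
        if best is None or cand < best:
            best = cand
    if best is not None and best[0] <= max_distance:
        return GeneAssignment(best[1], "nearest_within_50kb")
    return GeneAssignment(None, "unassigned")


def feature_distribution(
    regions_by_group: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group feature fractions plus pairwise two-proportion tests.

    Returns ``(fractions, tests)``: fractions indexed by group with one
    column per feature class (rows sum to 1; empty groups are all-NaN and
    flagged by that); tests has one row per (group pair, feature) with the
    z statistic and two-sided p-value.
    """
    if len(regions_by_group) < 2:
        raise ValueError("need at least two groups")
    counts: dict[str, dict[str, int]] = {}
    for group, regions in regions_by_group.items():
        c = dict.fromkeys(FEATURES, 0)
        for region in regions:
            c[assign_feature(region, genes, promoter_up, promoter_down).feature] += 1
        counts[group] = c
    frac = pd.DataFrame(counts).T[list(FEATURES)]
    totals = frac.sum(axis=1)
    fractions = frac.div(totals, axis=0)  # empty group -> NaN row

    rows = []
    groups = sorted(counts)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            na, nb = int(totals[a]), int(totals[b])
            if na == 0 or nb == 0:
                continue
            for feat in FEATURES:
                z, p = two_proportion_test(counts[a][feat], na, counts[b][feat], nb)
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "feature": feat,
                        "fraction_a": counts[a][feat] / na,
                        "fraction_b": counts[b][feat] / nb,
                        "z": z,
                        "p_value": p,
                    }
                )
    return fractions, pd.DataFrame(rows)


def tss_distance_histogram(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int,
    nbins: int,
) -> pd.DataFrame:
    """Histogram of signed midpoint-to-nearest-TSS distances.

    Covers ``[-window/2, window/2)``; counts sum to the number of regions
    whose nearest TSS lies within the window.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")
    half = window / 2
    dists = [
        d
        for d in (nearest_tss_distance(r, genes) for r in regions)
        if d is not None and -half <= d < half
    ]
    edges = np.linspace(-half, half, nbins + 1)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "count": counts}
    )
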