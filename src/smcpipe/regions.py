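"""Region classes derived from factor occupancy, and region-to-gene maps.

Enhancers are bases jointly occupied by OCT4, SOX2 and NANOG; promoters by
TBP and POL II; heterochromatin is the union of H3K9me3 and H4K20me3
domains. Gene association uses the nearest TSS within a configurable
distance.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .coverage import OccupancyRegionSet
from .intervals import (
    GeneModel,
    GenomicInterval,
    intersect_all,
    merge_intervals,
    nearest_tss,
)

DEFAULT_COOCCUPANCY_WINDOW = 2500
DEFAULT_GENE_MAX_DISTANCE = 50_000


def define_enhancers(
    oct4: OccupancyRegionSet,
    sox2: OccupancyRegionSet,
    nanog: OccupancyRegionSet,
) -> OccupancyRegionSet:
    """Enhancer regions: bases occupied by OCT4 AND SOX2 AND NANOG."""
    regions = intersect_all([oct4.regions, sox2.regions, nanog.regions])
    return OccupancyRegionSet(factor="OSN", regions=regions)


def define_promoters(
    tbp: OccupancyRegionSet, polii: OccupancyRegionSet
) -> OccupancyRegionSet:
    """Promoter regions: bases occupied by both TBP and POL II."""
    regions = intersect_all([tbp.regions, polii.regions])
    return OccupancyRegionSet(factor="TBP+POLII", regions=regions)


def define_heterochromatin(
    h3k9me3: OccupancyRegionSet, h4k20me3: OccupancyRegionSet
) -> OccupancyRegionSet:
    """Heterochromatin: merged union of H3K9me3 and H4K20me3 domains."""
    regions = merge_intervals(list(h3k9me3.regions) + list(h4k20me3.regions), 0)
    return OccupancyRegionSet(factor="heterochromatin", regions=regions)


def co_occupied_genes(
    caph2: OccupancyRegionSet,
    smc1: OccupancyRegionSet,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_COOCCUPANCY_WINDOW,
) -> set[str]:
    """Genes with both a condensin II and a cohesin region near the TSS.

    A gene qualifies when at least one CAPH2 region AND at least one SMC1
    region lie within ``window`` bp of its TSS (distance 0 if the TSS is
    inside the region).
    """
    if not genes:
        raise ValueError("gene list is empty")

    def near(regions: Sequence[GenomicInterval], g: GeneModel) -> bool:
        return any(
            iv.chrom == g.chrom and iv.distance_to_point(g.tss) <= window
            for iv in regions
        )

    return {
        g.gene_id
        for g in genes
        if near(caph2.regions, g) and near(smc1.regions, g)
    }


def genes_of_enhancers(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_GENE_MAX_DISTANCE,
) -> dict[GenomicInterval, str | None]:
    """Assign each enhancer to its nearest-TSS gene within ``max_distance``.

    Enhancers farther than ``max_distance`` from every TSS map to None.
    Ties break to the lexicographically smaller gene_id.
    """
    return {
        enh: nearest_tss(enh, genes, max_distance) for enh in enhancers
    }


def gene_classes_from_partition(
    se_assignments: Mapping[GenomicInterval, str | None],
    te_assignments: Mapping[GenomicInterval, str | None],
    genes: Sequence[GeneModel],
) -> dict[str, str]:
    """Classify genes as SE-associated, TE-associated or unassociated.

    A gene targeted by any super-enhancer is 'se' (super-enhancer
    association wins over typical); one targeted only by typical enhancers
    is 'te'; the rest are 'none'.
    """
    se_genes = {g for g in se_assignments.values() if g is not None}
    te_genes = {g for g in te_assignments.values() if g is not None}
    out = {}
    for g in genes:
        if g.gene_id in se_genes:
            out[g.gene_id] = "se"
        elif g.gene_id in te_genes:
            out[g.gene_id] = "te"
        else:
            out[g.gene_id] = "none"
    return out
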