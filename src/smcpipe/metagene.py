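"""Metagene profiles and POL II-ranked gene density matrices.

A metagene averages signal density across a set of regions on a common
axis: each region's body is rescaled to a fixed number of equal fractions
(so 700 bp typical enhancers and multi-kb super-enhancers share one axis),
flanked by fixed-bp bins. The ranked gene matrix quantifies density around
every TSS for several factors and orders genes by one factor's density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, _segment_read_count
from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Mean density (RPM/bp) on the rescaled region axis.

    ``values`` has ``2 * flank_bp // bin_size + body_bins`` entries: left
    flank bins, body fractions, right flank bins.
    """

    factor: str
    flank_bp: int
    bin_size: int
    body_bins: int
    values: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        expected = 2 * (self.flank_bp // self.bin_size) + self.body_bins
        if len(self.values) != expected:
            raise ValueError(
                f"profile length {len(self.values)} != expected {expected}"
            )
        if self.n_regions < 1:
            raise ValueError("profile must average at least one region")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: axis position label and mean density per bin."""
        n_flank = self.flank_bp // self.bin_size
        labels = (
            [f"flank_up_{i}" for i in range(n_flank)]
            + [f"body_{i}" for i in range(self.body_bins)]
            + [f"flank_down_{i}" for i in range(n_flank)]
        )
        return pd.DataFrame(
            {"bin": labels, "mean_density_rpm_per_bp": self.values}
        )


def _density(track: CoverageTrack, chrom: str, s: float, e: float) -> float:
    reads = _segment_read_count(track, chrom, s, e)
    return reads * 1e6 / track.total_mapped / (e - s)


def metagene_profile(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    flank_bp: int = 1000,
    body_bins: int = 60,
    factor: str = "",
) -> MetageneProfile:
    """Average density profile across ``regions``.

    Bodies are split into ``body_bins`` equal fractions (pro-rata over the
    underlying coverage bins); flanks use fixed bins of the track's bin
    size. Each region contributes with equal weight regardless of width.
    Regions whose flanks would cross a chromosome edge are dropped and the
    count logged.
    """
    if not regions:
        raise ValueError("empty region list")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if track.total_mapped == 0:
        raise ValueError("track has zero mapped reads")
    bs = track.bin_size
    n_flank = flank_bp // bs
    profiles = []
    dropped = 0
    for region in regions:
        size = track.chrom_sizes.get(region.chrom)
        if size is None or region.start - flank_bp < 0 or region.end + flank_bp > size:
            dropped += 1
            continue
        row = np.empty(2 * n_flank + body_bins)
        for i in range(n_flank):
            s = region.start - flank_bp + i * bs
            row[i] = _density(track, region.chrom, s, s + bs)
        frac = len(region) / body_bins
        for i in range(body_bins):
            s = region.start + i * frac
            row[n_flank + i] = _density(track, region.chrom, s, s + frac)
        for i in range(n_flank):
            s = region.end + i * bs
            row[n_flank + body_bins + i] = _density(track, region.chrom, s, s + bs)
        profiles.append(row)
    if dropped:
        logger.info("metagene: dropped %d region(s) at chromosome edges", dropped)
    if not profiles:
        raise ValueError("no region survived chromosome-edge filtering")
    return MetageneProfile(
        factor=factor,
        flank_bp=flank_bp,
        bin_size=bs,
        body_bins=body_bins,
        values=np.mean(profiles, axis=0),
        n_regions=len(profiles),
    )


def ranked_gene_matrix(
    tracks: Mapping[str, CoverageTrack],
    genes: Sequence[GeneModel],
    window: int = 1000,
    rank_factor: str = "POLII",
) -> pd.DataFrame:
    """Density (RPM/bp) over TSS +/- window per gene and factor, with rows
    sorted by descending ``rank_factor`` density (ties by gene_id).

    Genes on chromosomes missing from the ranking track are skipped with a
    log message; windows are clipped at chromosome edges.
    """
    if rank_factor not in tracks:
        raise ValueError(f"rank factor {rank_factor!r} not among tracks")
    ref = tracks[rank_factor]
    rows = {}
    skipped = 0
    for g in genes:
        if g.chrom not in ref.chrom_sizes:
            skipped += 1
            continue
        size = ref.chrom_sizes[g.chrom]
        s = max(0, g.tss - window)
        e = min(size, g.tss + window)
        rows[g.gene_id] = {
            name: _density(t, g.chrom, s, e) for name, t in tracks.items()
        }
    if skipped:
        logger.info("ranked_gene_matrix: skipped %d gene(s) off-track", skipped)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    df = df.sort_index()  # tie rule: gene_id ascending within equal density
    return df.sort_values(rank_factor, ascending=False, kind="stable")
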