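"""Binned coverage tracks, signal quantification, occupancy calling and
rank normalization.

Quantification follows ChIP-seq convention: reads are extended to the
expected fragment length, counted into fixed-width bins, and signal is
reported in reads per million mapped reads (RPM) or RPM per base pair
(density). Partial bin overlap is pro-rated by the fraction of the bin
inside the query region, so signal is insensitive to bin phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, merge_intervals


@dataclass
class CoverageTrack:
    """Per-chromosome binned counts of (extended) reads.

    ``total_mapped`` is the number of reads the track was built from, not
    the bin sum: an extended read can overlap several bins.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    counts: dict[str, np.ndarray]
    total_mapped: int
    extend_len: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            nbins = -(-size // self.bin_size)
            if chrom not in self.counts:
                self.counts[chrom] = np.zeros(nbins)
            elif len(self.counts[chrom]) != nbins:
                raise ValueError(f"bin vector length mismatch on {chrom}")
            if (self.counts[chrom] < 0).any():
                raise ValueError("negative bin counts")

    def same_binning(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def n_bins(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def copy_with(self, counts: dict[str, np.ndarray]) -> "CoverageTrack":
        return CoverageTrack(
            bin_size=self.bin_size,
            chrom_sizes=dict(self.chrom_sizes),
            counts=counts,
            total_mapped=self.total_mapped,
            extend_len=self.extend_len,
        )


def build_track(
    reads: Iterable[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 50,
    extend_len: int = 200,
) -> CoverageTrack:
    """Bin reads into a :class:`CoverageTrack`.

    Each read is extended to ``extend_len`` bp in its strand direction
    (symmetrically about its midpoint when unstranded), clipped to the
    chromosome, and every bin it overlaps is incremented by 1.
    """
    if bin_size <= 0 or extend_len <= 0:
        raise ValueError("bin_size and extend_len must be positive")
    chrom_sizes = dict(chrom_sizes)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    n_reads = 0
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chrom {r.chrom!r}")
        n_reads += 1
        if r.strand == "+":
            s, e = r.start, r.start + extend_len
        elif r.strand == "-":
            s, e = r.end - extend_len, r.end
        else:
            mid = (r.start + r.end) // 2
            s = mid - extend_len // 2
            e = s + extend_len
        s = max(0, s)
        e = min(chrom_sizes[r.chrom], e)
        if s < e:
            by_chrom[r.chrom].append((s, e))

    counts: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        nbins = -(-size // bin_size)
        vec = np.zeros(nbins)
        spans = by_chrom[chrom]
        if spans:
            arr = np.asarray(spans)
            b0 = arr[:, 0] // bin_size
            b1 = (arr[:, 1] - 1) // bin_size
            width = int((b1 - b0).max()) + 1
            for k in range(width):
                mask = b0 + k <= b1
                np.add.at(vec, (b0 + k)[mask], 1.0)
        counts[chrom] = vec
    return CoverageTrack(
        bin_size=bin_size,
        chrom_sizes=chrom_sizes,
        counts=counts,
        total_mapped=n_reads,
        extend_len=extend_len,
    )


def _segment_read_count(
    track: CoverageTrack, chrom: str, start: float, end: float
) -> float:
    """Pro-rata read count over [start, end); float bounds allowed."""
    vec = track.counts[chrom]
    bs = track.bin_size
    b0 = int(start // bs)
    b1 = int(np.ceil(end / bs))
    total = 0.0
    for b in range(b0, min(b1, len(vec))):
        lo = max(start, b * bs)
        hi = min(end, (b + 1) * bs)
        if hi > lo:
            total += vec[b] * (hi - lo) / bs
    return total


def region_signal(
    track: CoverageTrack,
    region: GenomicInterval,
    mode: str = "total_rpm",
) -> float:
    """Signal over a region: ``total_rpm`` or ``density_rpm_per_bp``.

    total_rpm = pro-rata overlapping reads x 1e6 / total mapped reads;
    density divides further by the region length.
    """
    if track.total_mapped == 0:
        raise ValueError("track has zero mapped reads")
    if region.chrom not in track.counts:
        raise ValueError(f"region chrom {region.chrom!r} not in track")
    if region.end > track.chrom_sizes[region.chrom]:
        raise ValueError("region extends beyond chromosome")
    reads = _segment_read_count(track, region.chrom, region.start, region.end)
    rpm = reads * 1e6 / track.total_mapped
    if mode == "total_rpm":
        return rpm
    if mode == "density_rpm_per_bp":
        return rpm / len(region)
    raise ValueError(f"unknown mode {mode!r}")


def call_occupied_regions(
    track: CoverageTrack,
    control: CoverageTrack,
    p_cutoff: float = 1e-5,
    min_width: int = 100,
    merge_gap: int = 200,
    factor: str = "",
) -> "OccupancyRegionSet":
    """Call factor-occupied regions against a control track.

    Per bin, the treatment count is tested against a Poisson null with
    lambda the depth-scaled control count, floored at the control's
    genome-average bin rate (so sparse control bins do not inflate
    significance). Passing bins are merged within ``merge_gap`` bp and
    regions narrower than ``min_width`` are dropped.
    """
    if not track.same_binning(control):
        raise ValueError("track and control binning differ")
    if control.total_mapped == 0:
        raise ValueError("control track has zero mapped reads")
    scale = track.total_mapped / control.total_mapped
    genome_avg = (
        scale
        * sum(v.sum() for v in control.counts.values())
        / control.n_bins()
    )
    passing: list[GenomicInterval] = []
    for chrom, vec in track.counts.items():
        lam = np.maximum(control.counts[chrom] * scale, genome_avg)
        # upper tail P(X >= k) under Poisson(lam)
        pvals = stats.poisson.sf(vec - 1, lam)
        idx = np.flatnonzero(pvals < p_cutoff)
        size = track.chrom_sizes[chrom]
        for b in idx:
            passing.append(
                GenomicInterval(
                    chrom,
                    int(b) * track.bin_size,
                    min(size, (int(b) + 1) * track.bin_size),
                )
            )
    merged = merge_intervals(passing, merge_gap)
    regions = [iv for iv in merged if len(iv) >= min_width]
    return OccupancyRegionSet(
        factor=factor,
        regions=regions,
        p_cutoff=p_cutoff,
        min_width=min_width,
        merge_gap=merge_gap,
    )


@dataclass
class OccupancyRegionSet:
    """A factor's called (enriched) regions, disjoint and sorted."""

    factor: str
    regions: list[GenomicInterval]
    p_cutoff: float | None = None
    min_width: int | None = None
    merge_gap: int | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.regions, self.regions[1:]):
            if (a.chrom, a.start) > (b.chrom, b.start):
                raise ValueError("regions must be sorted")
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("regions must be disjoint")

    def __len__(self) -> int:
        return len(self.regions)


# ------------------------------------------------------ rank normalization


def _quantile_curve(sorted_vals: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Empirical quantile function: rank k of n sits at quantile (k-0.5)/n."""
    n = len(sorted_vals)
    grid = (np.arange(n) + 0.5) / n
    return np.interp(q, grid, sorted_vals)


def rank_normalize(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    reference: np.ndarray | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Map two tracks onto a shared quantile scale for cross-condition
    comparison.

    Nonzero bins of each track are replaced by the value, at the same
    fractional rank, of a reference distribution. By default the reference
    averages the two samples' empirical quantile functions over their
    nonzero bins (so two identical tracks pass through unchanged); an
    explicit ``reference`` (a sorted value array defining the target
    distribution) makes each output depend on its track only through bin
    ranks, which keeps the normalization invariant under any strictly
    increasing transform of that track's counts. Ties take the mean of
    their rank range. Zero bins stay zero. Display flooring (e.g. at 0.2)
    is applied only at bedGraph export; analysis values are returned
    unfloored.
    """
    if not track_a.same_binning(track_b):
        raise ValueError("tracks must share binning")

    flats = []
    for t in (track_a, track_b):
        flat = np.concatenate([t.counts[c] for c in sorted(t.counts)])
        if not (flat > 0).any():
            raise ValueError("all-zero track cannot be rank normalized")
        flats.append(flat)

    nz = [f[f > 0] for f in flats]
    if reference is not None:
        reference = np.sort(np.asarray(reference, dtype=float))
        m = len(reference)
    else:
        m = max(len(v) for v in nz)
        grid = (np.arange(m) + 0.5) / m
        reference = (
            _quantile_curve(np.sort(nz[0]), grid)
            + _quantile_curve(np.sort(nz[1]), grid)
        ) / 2.0
    grid = (np.arange(m) + 0.5) / m

    outputs = []
    for t, flat in zip((track_a, track_b), flats):
        pos = flat > 0
        ranks = stats.rankdata(flat[pos], method="average")  # ties -> mean rank
        q = (ranks - 0.5) / pos.sum()
        new_flat = np.zeros_like(flat)
        new_flat[pos] = np.interp(q, grid, reference)
        counts: dict[str, np.ndarray] = {}
        offset = 0
        for c in sorted(t.counts):
            n = len(t.counts[c])
            counts[c] = new_flat[offset : offset + n].copy()
            offset += n
        outputs.append(t.copy_with(counts))
    return outputs[0], outputs[1]


def track_to_bedgraph_records(
    track: CoverageTrack,
    values: str = "rpm",
    floor: float | None = None,
) -> list[tuple[GenomicInterval, float]]:
    """Export bins as bedGraph records.

    ``values``: 'rpm' scales counts to reads per million; 'raw' keeps bin
    values as stored (use for rank-normalized tracks). ``floor`` clamps
    displayed values from below (the display-only floor); zero bins are
    omitted.
    """
    if values not in ("rpm", "raw"):
        raise ValueError(f"unknown values mode {values!r}")
    scale = 1.0
    if values == "rpm":
        if track.total_mapped == 0:
            raise ValueError("cannot RPM-scale an empty track")
        scale = 1e6 / track.total_mapped
    records = []
    for chrom in sorted(track.counts):
        vec = track.counts[chrom]
        size = track.chrom_sizes[chrom]
        for b in np.flatnonzero(vec):
            v = vec[b] * scale
            if floor is not None:
                v = max(v, floor)
            records.append(
                (
                    GenomicInterval(
                        chrom,
                        int(b) * track.bin_size,
                        min(size, (int(b) + 1) * track.bin_size),
                    ),
                    float(v),
                )
            )
    return records
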