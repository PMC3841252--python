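"""Super-enhancer identification: stitching, ranking, cutoff, fold stats.

Enhancer constituents within a stitching distance (default 12.5 kb) are
merged into stitched enhancers; each is scored by its
background-subtracted total RPM of coactivator (Mediator) signal; the
ranked signal curve, with both axes scaled to [0, 1], is cut where its
discrete slope first drops to 1 scanning from the top. Entries above the
cutoff are super-enhancers, the rest typical enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack, region_signal
from .intervals import GeneModel, GenomicInterval, merge_intervals

DEFAULT_STITCH_DISTANCE = 12_500


@dataclass
class StitchedEnhancer:
    """A stitched enhancer domain and its constituent enhancers.

    ``signal`` is the background-subtracted total RPM over the span; it may
    be negative and is floored at 0 only for ranking. ``rank`` is ascending
    in ranked signal (0 = weakest).
    """

    span: GenomicInterval
    constituents: list[GenomicInterval]
    signal: float = float("nan")
    rank: int = -1

    def __post_init__(self) -> None:
        for c in self.constituents:
            if not (
                c.chrom == self.span.chrom
                and c.start >= self.span.start
                and c.end <= self.span.end
            ):
                raise ValueError("constituent outside stitched span")

    @property
    def ranking_signal(self) -> float:
        return max(0.0, self.signal)


@dataclass
class SuperEnhancerPartition:
    """Stitched enhancers ranked ascending with a super/typical cutoff.

    Entries with index >= ``cutoff_index`` are super-enhancers.
    """

    ranked: list[StitchedEnhancer]
    cutoff_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff_index <= len(self.ranked):
            raise ValueError("cutoff_index out of range")

    @property
    def super_enhancers(self) -> list[StitchedEnhancer]:
        return self.ranked[self.cutoff_index :]

    @property
    def typical_enhancers(self) -> list[StitchedEnhancer]:
        return self.ranked[: self.cutoff_index]

    @property
    def n_super(self) -> int:
        return len(self.ranked) - self.cutoff_index

    @property
    def n_typical(self) -> int:
        return self.cutoff_index


def stitch_constituents(
    constituents: Sequence[GenomicInterval],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    exclude_tss: bool = False,
    genes: Sequence[GeneModel] | None = None,
    tss_exclusion_window: int = 2000,
) -> list[StitchedEnhancer]:
    """Merge constituents within ``stitch_distance`` into stitched enhancers.

    With ``exclude_tss`` (off by default), constituents whose span lies
    within ``tss_exclusion_window`` bp of any TSS in ``genes`` are removed
    before stitching.
    """
    kept = list(constituents)
    if exclude_tss:
        if genes is None:
            raise ValueError("exclude_tss requires a gene list")
        kept = [
            c
            for c in kept
            if not any(
                g.chrom == c.chrom
                and c.distance_to_point(g.tss) <= tss_exclusion_window
                for g in genes
            )
        ]
    spans = merge_intervals(kept, stitch_distance)
    out = []
    for span in spans:
        members = sorted(c for c in kept if span.overlaps(c))
        out.append(StitchedEnhancer(span=span, constituents=members))
    return out


def rank_by_signal(
    stitched: Sequence[StitchedEnhancer],
    signal_track: CoverageTrack,
    control_track: CoverageTrack,
) -> list[StitchedEnhancer]:
    """Score each stitched enhancer and sort ascending.

    Score = total RPM of the signal track minus total RPM of the control
    over the span (recorded raw; negatives floor to 0 for ranking). Ties
    break by span position for determinism.
    """
    if not signal_track.same_binning(control_track):
        raise ValueError("signal and control tracks must share binning")
    scored = []
    for se in stitched:
        sig = region_signal(signal_track, se.span) - region_signal(
            control_track, se.span
        )
        scored.append(
            StitchedEnhancer(span=se.span, constituents=se.constituents, signal=sig)
        )
    scored.sort(key=lambda se: (se.ranking_signal, se.span.chrom, se.span.start))
    for i, se in enumerate(scored):
        se.rank = i
    return scored


def find_inflection_cutoff(signals: Sequence[float]) -> int:
    """Cutoff index on an ascending ranked-signal curve.

    Both axes are scaled to [0, 1] and the cutoff is placed where a line of
    slope 1 is tangent to the curve — the point past which, scanning from
    the top, the curve rises faster than the diagonal. On the scaled curve
    this is the index minimizing y - x (the discrete slope crosses 1
    there); ties resolve to the topmost such index for determinism.
    Entries strictly above the returned index are super-enhancers. An
    all-equal curve yields cutoff = n (no super-enhancers).
    """
    n = len(signals)
    if n < 2:
        raise ValueError("need at least 2 ranked enhancers")
    y = np.asarray(signals, dtype=float)
    if np.any(np.diff(y) < 0):
        raise ValueError("signals must be ascending")
    lo, hi = y[0], y[-1]
    if hi == lo:
        return n
    ys = (y - lo) / (hi - lo)
    xs = np.arange(n) / (n - 1)
    gap = ys - xs
    elbow = int(np.flatnonzero(gap == gap.min())[-1])
    return elbow + 1


def partition_enhancers(
    ranked: Sequence[StitchedEnhancer],
) -> SuperEnhancerPartition:
    """Split a ranked list into super and typical enhancers."""
    cutoff = find_inflection_cutoff([se.ranking_signal for se in ranked])
    return SuperEnhancerPartition(ranked=list(ranked), cutoff_index=cutoff)


def fold_difference(
    track: CoverageTrack,
    partition: SuperEnhancerPartition,
    mode: str = "enhancers",
) -> float:
    """Super- vs typical-enhancer signal ratio for one factor.

    mode='enhancers': mean total RPM over SE spans divided by mean total
    RPM over TE spans. mode='constituents': mean density (RPM/bp) over SE
    constituents divided by mean density over TE constituents.
    """
    supers = partition.super_enhancers
    typicals = partition.typical_enhancers
    if not supers or not typicals:
        raise ValueError("both classes must be non-empty")
    if mode == "enhancers":
        se_vals = [region_signal(track, se.span) for se in supers]
        te_vals = [region_signal(track, te.span) for te in typicals]
    elif mode == "constituents":
        se_vals = [
            region_signal(track, c, "density_rpm_per_bp")
            for se in supers
            for c in se.constituents
        ]
        te_vals = [
            region_signal(track, c, "density_rpm_per_bp")
            for te in typicals
            for c in te.constituents
        ]
        if not se_vals or not te_vals:
            raise ValueError("a class has no constituents")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = float(np.mean(te_vals))
    if denom == 0:
        raise ValueError("typical-enhancer mean signal is zero")
    return float(np.mean(se_vals)) / denom
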