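import numpy as np
import pytest

from smcpipe import (
    CoverageTrack,
    GeneModel,
    GenomeConfig,
    GenomicInterval,
    make_genome,
)
from smcpipe.simulate import GenomeLayout, default_factor_profiles


@pytest.fixture(scope="session")
def small_layout():
    """A reduced genome for fast end-to-end stages: 4 Mb, 6 SE clusters."""
    return make_genome(
        GenomeConfig(
            chrom_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
            n_se_clusters=6,
            n_typical=40,
            n_extra_genes=10,
            n_heterochromatin=4,
            heterochromatin_width=20_000,
            seed=7,
        )
    )


def make_track(
    bins: dict[str, list[float]],
    bin_size: int = 100,
    total_mapped: int = 1_000_000,
    extend_len: int = 200,
) -> CoverageTrack:
    """Construct a CoverageTrack directly from per-chrom bin vectors."""
    counts = {c: np.asarray(v, dtype=float) for c, v in bins.items()}
    sizes = {c: len(v) * bin_size for c, v in counts.items()}
    return CoverageTrack(
        bin_size=bin_size,
        chrom_sizes=sizes,
        counts=counts,
        total_mapped=total_mapped,
        extend_len=extend_len,
    )


def genes_only_layout(n_se: int, n_te: int, n_none: int) -> GenomeLayout:
    """A layout carrying only genes and class labels (for expression sims)."""
    spacing = 20_000
    n = n_se + n_te + n_none
    genes, classes = [], {}
    for i in range(n):
        tss = 5_000 + i * spacing
        gid = f"g{i:04d}"
        genes.append(
            GeneModel(
                gid, "chr1", "+", tss, GenomicInterval("chr1", tss - 500, tss + 8000, "+")
            )
        )
        classes[gid] = "se" if i < n_se else ("te" if i < n_se + n_te else "none")
    return GenomeLayout(
        chrom_sizes={"chr1": 5_000 + n * spacing + 10_000},
        genes=genes,
        typical_constituents=[],
        se_clusters=[],
        promoters=[],
        heterochromatin=[],
        factor_profiles=default_factor_profiles(),
        gene_classes=classes,
    )


def random_intervals(
    rng: np.random.Generator,
    n_max: int = 100,
    chroms=("chrA", "chrB"),
    span: int = 10_000,
) -> list[GenomicInterval]:
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - 1))
        end = int(rng.integers(start + 1, min(start + 500, span) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return out
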