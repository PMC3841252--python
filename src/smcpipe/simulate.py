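"""Synthetic genome, ChIP-seq read and knockdown RNA-seq simulators.

The generator plants the element classes the downstream analysis is built
to detect: typical-enhancer constituents, clustered super-enhancer
constituents, promoters, gene bodies and heterochromatin domains, on a toy
genome. ChIP-seq reads are emitted as already-aligned fixed-length
intervals drawn from a Poisson model whose rate is the background times a
factor- and class-specific fold enrichment. Knockdown RNA-seq counts are
negative binomial, with super-enhancer-associated genes given larger
knockdown effects than typical-enhancer genes.

Layout uses fixed-width slots (default 50 kb) so planted enhancer entities
are farther apart than the stitching distance and element classes are
disjoint by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .intervals import GeneModel, GenomicInterval

ELEMENT_CLASSES = (
    "typical_enhancer",
    "se_constituent",
    "promoter",
    "gene_body",
    "heterochromatin",
)

GENE_CLASSES = ("se", "te", "none")

#: Knockdown experiment design: a control hairpin, two condensin II (CAPH2)
#: hairpins, and one cohesin (SMC1) hairpin.
CONDITIONS = ("shGFP", "shCAPH2#1", "shCAPH2#2", "shSMC1")


@dataclass(frozen=True)
class EnrichmentRule:
    """Expected ChIP-seq enrichment of one factor over the element classes.

    ``background_rate`` is the expected reads per bp outside any planted
    element (before depth rescaling); ``folds`` multiplies it inside each
    element class. Classes absent from ``folds`` default to fold 1.
    """

    background_rate: float = 0.05
    folds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.background_rate > 0:
            raise ValueError("background_rate must be > 0")
        for cls, f in self.folds.items():
            if cls not in ELEMENT_CLASSES:
                raise ValueError(f"unknown element class {cls!r}")
            if not (np.isfinite(f) and f >= 0):
                raise ValueError(f"fold for {cls} must be finite and >= 0")

    def fold(self, element_class: str) -> float:
        return float(self.folds.get(element_class, 1.0))


def default_factor_profiles() -> dict[str, EnrichmentRule]:
    """Field-realistic enrichment rules per factor.

    MED1 (Mediator) carries the super-enhancer signal used for ranking:
    fold 20 at SE constituents vs 8 at typical constituents plants a
    constituent density ratio of 2.5. OCT4/SOX2/NANOG mark enhancers,
    TBP/POL II mark promoters (POL II also tracks gene bodies),
    H3K9me3/H4K20me3 mark heterochromatin only, and the whole-cell-extract
    (WCE) control is flat.
    """

    def rule(**folds: float) -> EnrichmentRule:
        return EnrichmentRule(folds=folds)

    osn = dict(typical_enhancer=8, se_constituent=16, promoter=2)
    smc = dict(
        typical_enhancer=5,
        se_constituent=12,
        promoter=6,
        heterochromatin=0.2,
    )
    return {
        "MED1": rule(typical_enhancer=8, se_constituent=20, promoter=4),
        "NIPBL": rule(**smc),
        "SMC1": rule(**smc),
        "CAPH2": rule(**smc),
        "OCT4": rule(**osn),
        "SOX2": rule(**osn),
        "NANOG": rule(**osn),
        "TBP": rule(promoter=10),
        "POLII": rule(promoter=10, gene_body=4),
        "H3K9me3": rule(
            heterochromatin=10,
            typical_enhancer=0,
            se_constituent=0,
            promoter=0,
        ),
        "H4K20me3": rule(
            heterochromatin=10,
            typical_enhancer=0,
            se_constituent=0,
            promoter=0,
        ),
        "CTCF": rule(typical_enhancer=2, se_constituent=2, promoter=2),
        "WCE": rule(),
    }


@dataclass(frozen=True)
class GenomeConfig:
    """Layout parameters for :func:`make_genome`.

    The defaults define the demo genome: 20 Mb over two chromosomes,
    20 planted super-enhancer clusters, 300 typical constituents, and a
    gene placed next to every enhancer entity (plus unassociated filler
    genes), packed into 50 kb slots.
    """

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_se_clusters: int = 20
    n_typical: int = 300
    n_extra_genes: int = 60
    constituents_per_cluster: int = 4
    constituent_width: int = 700
    cluster_gap: int = 2000  # within-cluster spacing, must stay < stitch dist
    n_heterochromatin: int = 8
    heterochromatin_width: int = 50_000
    promoter_halfwidth: int = 1000
    gene_body_length: int = 8000
    slot_width: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chrom {chrom} size must be > 0")
        for name in (
            "n_se_clusters",
            "n_typical",
            "n_extra_genes",
            "n_heterochromatin",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GenomeLayout:
    """A toy genome with planted regulatory elements and factor profiles."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    typical_constituents: list[GenomicInterval]
    se_clusters: list[list[GenomicInterval]]
    promoters: list[GenomicInterval]
    heterochromatin: list[GenomicInterval]
    factor_profiles: dict[str, EnrichmentRule]
    gene_classes: dict[str, str] = field(default_factory=dict)

    @property
    def se_constituents(self) -> list[GenomicInterval]:
        return [iv for cluster in self.se_clusters for iv in cluster]

    def elements_by_class(self) -> dict[str, list[GenomicInterval]]:
        gene_bodies = []
        for g in self.genes:
            # body starts 1 kb past the TSS so it never overlaps the promoter
            body_start = g.tss + 1000 if g.strand == "+" else g.span.start
            body_end = g.span.end if g.strand == "+" else g.tss - 1000
            if body_start < body_end:
                gene_bodies.append(GenomicInterval(g.chrom, body_start, body_end))
        return {
            "typical_enhancer": list(self.typical_constituents),
            "se_constituent": self.se_constituents,
            "promoter": list(self.promoters),
            "gene_body": gene_bodies,
            "heterochromatin": list(self.heterochromatin),
        }


class PackingError(ValueError):
    """Raised when the requested elements cannot fit on the genome."""


def make_genome(config: GenomeConfig = GenomeConfig()) -> GenomeLayout:
    """Build a deterministic genome layout from ``config``.

    Heterochromatin domains are carved off the high end of each chromosome;
    the remainder is divided into ``slot_width`` slots. Each slot holds one
    enhancer entity (an SE cluster or a typical constituent) and, for
    enhancer slots, one gene whose TSS sits within nearest-TSS range of the
    enhancer; extra slots hold unassociated genes. Slot identities are
    shuffled with the seeded generator, so layouts are reproducible.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)

    # --- heterochromatin: packed from the top of each chromosome, round robin
    het: list[GenomicInterval] = []
    het_margin = 10_000
    usable_end = {c: config.chrom_sizes[c] for c in chroms}
    for i in range(config.n_heterochromatin):
        chrom = chroms[i % len(chroms)]
        end = usable_end[chrom] - het_margin
        start = end - config.heterochromatin_width
        if start < het_margin:
            raise PackingError("too many heterochromatin domains for genome")
        het.append(GenomicInterval(chrom, start, end))
        usable_end[chrom] = start

    # --- slots over the remaining space
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        n_slots = usable_end[chrom] // config.slot_width
        slots.extend((chrom, s * config.slot_width) for s in range(n_slots))
    n_needed = config.n_se_clusters + config.n_typical + config.n_extra_genes
    if n_needed > len(slots):
        raise PackingError(
            f"need {n_needed} slots but only {len(slots)} fit the genome"
        )
    # slot geometry: gene at the low end (TSS at +10 kb), enhancer entity in
    # the middle (+25 kb), so each enhancer's nearest TSS is its own gene
    # and consecutive enhancer entities are > stitch distance apart
    tss_offset = 10_000
    enh_offset = 25_000
    cluster_span = (
        config.constituents_per_cluster * config.constituent_width
        + max(0, config.constituents_per_cluster - 1) * config.cluster_gap
    )
    if enh_offset + cluster_span + 2000 > config.slot_width:
        raise PackingError("slot_width too small for an SE cluster plus gene")
    if tss_offset + config.gene_body_length + 2000 > enh_offset:
        raise PackingError("gene_body_length too large for slot layout")

    order = rng.permutation(len(slots))
    kinds = (
        ["se"] * config.n_se_clusters
        + ["te"] * config.n_typical
        + ["gene"] * config.n_extra_genes
    )

    genes: list[GeneModel] = []
    gene_classes: dict[str, str] = {}
    typical: list[GenomicInterval] = []
    clusters: list[list[GenomicInterval]] = []
    promoters: list[GenomicInterval] = []

    def add_gene(chrom: str, slot_start: int, idx: int, cls: str) -> None:
        tss = slot_start + tss_offset
        span = GenomicInterval(
            chrom, tss - 500, tss + config.gene_body_length, "+"
        )
        gid = f"gene_{idx:04d}"
        genes.append(GeneModel(gid, chrom, "+", tss, span))
        gene_classes[gid] = cls
        hw = config.promoter_halfwidth
        promoters.append(GenomicInterval(chrom, tss - hw, tss + hw))

    for idx, (kind, oi) in enumerate(zip(kinds, order)):
        chrom, slot_start = slots[oi]
        if kind == "se":
            cluster = []
            pos = slot_start + enh_offset
            for _ in range(config.constituents_per_cluster):
                cluster.append(
                    GenomicInterval(chrom, pos, pos + config.constituent_width)
                )
                pos += config.constituent_width + config.cluster_gap
            clusters.append(cluster)
            add_gene(chrom, slot_start, idx, "se")
        elif kind == "te":
            typical.append(
                GenomicInterval(
                    chrom,
                    slot_start + enh_offset,
                    slot_start + enh_offset + config.constituent_width,
                )
            )
            add_gene(chrom, slot_start, idx, "te")
        else:
            add_gene(chrom, slot_start, idx, "none")

    clusters.sort(key=lambda c: (c[0].chrom, c[0].start))
    typical.sort()
    promoters.sort()
    het.sort()
    genes.sort(key=lambda g: (g.chrom, g.tss))
    return GenomeLayout(
        chrom_sizes=dict(config.chrom_sizes),
        genes=genes,
        typical_constituents=typical,
        se_clusters=clusters,
        promoters=promoters,
        heterochromatin=het,
        factor_profiles=default_factor_profiles(),
        gene_classes=gene_classes,
    )


# ---------------------------------------------------------- ChIP-seq reads


def simulate_chip_reads(
    layout: GenomeLayout,
    factor: str,
    depth: int,
    read_len: int = 36,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Draw ``depth`` expected aligned reads for one factor.

    The genome is segmented into planted elements (rate = background x
    class fold) and background (rate = background); the per-segment rates
    are rescaled so the expected total equals ``depth``, the realized total
    is Poisson, reads fall uniformly within their segment, and strands are
    assigned uniformly. Reads are returned sorted.
    """
    if factor not in layout.factor_profiles:
        raise KeyError(f"no enrichment rule for factor {factor!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    rule = layout.factor_profiles[factor]

    # disjoint segmentation: elements with their fold, gaps with fold 1
    segments: list[tuple[str, int, int, float]] = []
    elements: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in layout.chrom_sizes
    }
    for cls, ivs in layout.elements_by_class().items():
        f = rule.fold(cls)
        for iv in ivs:
            elements[iv.chrom].append((iv.start, iv.end, f))
    for chrom, size in layout.chrom_sizes.items():
        pos = 0
        for start, end, f in sorted(elements[chrom]):
            if start > pos:
                segments.append((chrom, pos, start, 1.0))
            segments.append((chrom, start, end, f))
            pos = end
        if pos < size:
            segments.append((chrom, pos, size, 1.0))

    weights = np.array([(e - s) * f for _, s, e, f in segments])
    total_weight = weights.sum()
    if depth == 0 or total_weight == 0:
        return []
    n_total = rng.poisson(depth)
    if n_total == 0:
        return []
    per_segment = rng.multinomial(n_total, weights / total_weight)

    reads: list[GenomicInterval] = []
    for (chrom, s, e, _f), n in zip(segments, per_segment):
        if n == 0:
            continue
        starts = rng.integers(s, e, size=n)
        strands = rng.integers(0, 2, size=n)
        size = layout.chrom_sizes[chrom]
        for st, sd in zip(starts, strands):
            end = min(int(st) + read_len, size)
            reads.append(
                GenomicInterval(chrom, int(st), end, "+" if sd == 0 else "-")
            )
    reads.sort()
    return reads


# --------------------------------------------------------- RNA-seq counts


@dataclass(frozen=True)
class ExpressionEffects:
    """Per-gene-class knockdown effect model.

    ``log2fc_mean``/``log2fc_sd`` give the distribution of true gene-level
    log2 fold changes per class; ``dispersion`` is the negative-binomial
    dispersion of counts around each mean; ``base_mean`` sets baseline
    expression. Both knockdowns hit the same genes: each gene's cohesin
    (SMC1) effect is its condensin II (CAPH2) effect scaled by
    ``smc1_scale`` (cohesin depletion changes expression somewhat more)
    plus independent noise of sd ``smc1_extra_sd``.
    """

    log2fc_mean: Mapping[str, float] = field(
        default_factory=lambda: {"se": -1.0, "te": -0.3, "none": 0.0}
    )
    log2fc_sd: float = 0.5
    dispersion: float = 0.05
    base_mean: float = 500.0
    smc1_scale: float = 1.3
    smc1_extra_sd: float = 0.3
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.log2fc_sd < 0:
            raise ValueError("log2fc_sd must be >= 0")
        for cls in self.log2fc_mean:
            if cls not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {cls!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_knockdown_expression(
    layout: GenomeLayout,
    effects: ExpressionEffects = ExpressionEffects(),
    seed: int = 0,
) -> "ExpressionTable":
    """Simulate the knockdown RNA-seq experiment.

    Samples: ``n_replicates`` each of shGFP (control), two CAPH2 shRNAs
    (sharing each gene's true condensin II effect) and one SMC1 shRNA.
    Each gene draws a true log2 fold change from its class distribution;
    counts are negative binomial around ``base_mean x 2^log2fc``.
    """
    from .expression import ExpressionTable  # local to avoid cycle

    if not layout.genes:
        raise ValueError("layout has no genes")
    for g in layout.genes:
        if layout.gene_classes.get(g.gene_id) not in GENE_CLASSES:
            raise ValueError(f"gene {g.gene_id} has no class assignment")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in layout.genes]
    n_genes = len(gene_ids)

    mu_class = np.array(
        [effects.log2fc_mean.get(layout.gene_classes[g], 0.0) for g in gene_ids]
    )
    base = effects.base_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    fc_caph2 = rng.normal(mu_class, effects.log2fc_sd)
    fc_smc1 = effects.smc1_scale * fc_caph2 + rng.normal(
        0.0, effects.smc1_extra_sd, size=n_genes
    )

    cond_mean = {
        "shGFP": base,
        "shCAPH2#1": base * 2.0**fc_caph2,
        "shCAPH2#2": base * 2.0**fc_caph2,
        "shSMC1": base * 2.0**fc_smc1,
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in CONDITIONS:
        for rep in range(1, effects.n_replicates + 1):
            name = f"{cond}_rep{rep}"
            columns[name] = _nb_draw(rng, cond_mean[cond], effects.dispersion)
            meta_rows.append((name, cond, rep))
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "condition", "replicate"]
    ).set_index("sample")
    return ExpressionTable(counts=counts, metadata=metadata)


# --------------------------------------------------------------- fixtures


def write_fixture(
    outdir: str | os.PathLike,
    layout: GenomeLayout,
    read_sets: Mapping[str, Sequence[GenomicInterval]] | None = None,
    expression: "ExpressionTable | None" = None,
) -> dict[str, str]:
    """Write a layout (and optional reads/expression) as plain-text files.

    Produces: chrom_sizes.tsv, elements.bed (class in the name field),
    genes.tsv, reads_<factor>.bed per factor, counts.tsv + samples.tsv.
    Everything round-trips through the io module. Returns {label: path}.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    p = os.path.join(outdir, "chrom_sizes.tsv")
    pd.DataFrame(
        sorted(layout.chrom_sizes.items()), columns=["chrom", "size"]
    ).to_csv(p, sep="\t", index=False)
    paths["chrom_sizes"] = p

    elements: list[GenomicInterval] = []
    names: list[str] = []
    for cls, ivs in layout.elements_by_class().items():
        elements.extend(ivs)
        names.extend([cls] * len(ivs))
    p = os.path.join(outdir, "elements.bed")
    gio.write_bed(p, elements, names=names, scores=[0] * len(elements))
    paths["elements"] = p

    p = os.path.join(outdir, "genes.tsv")
    gio.write_gene_table(p, layout.genes)
    paths["genes"] = p

    if layout.gene_classes:
        p = os.path.join(outdir, "gene_classes.tsv")
        pd.DataFrame(
            sorted(layout.gene_classes.items()), columns=["gene_id", "class"]
        ).to_csv(p, sep="\t", index=False)
        paths["gene_classes"] = p

    for factor, reads in (read_sets or {}).items():
        p = os.path.join(outdir, f"reads_{factor}.bed")
        gio.write_bed(
            p,
            reads,
            names=[factor] * len(reads),
            scores=[0] * len(reads),
        )
        paths[f"reads_{factor}"] = p

    if expression is not None:
        p = os.path.join(outdir, "counts.tsv")
        gio.write_counts_table(p, expression.counts)
        paths["counts"] = p
        p = os.path.join(outdir, "samples.tsv")
        expression.metadata.to_csv(p, sep="\t")
        paths["samples"] = p
    return paths
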