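"""End-to-end pipeline: simulate -> tracks -> regions -> metagenes ->
super-enhancers -> expression, with seeded reproducibility and a
machine-readable summary.

Every stage takes its random state from a single master seed, so two runs
with the same config produce byte-identical summaries. All outputs are
declared in a manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from . import io as gio
from .coverage import (
    CoverageTrack,
    build_track,
    call_occupied_regions,
    rank_normalize,
    track_to_bedgraph_records,
)
from .expression import compare_gene_classes, fold_changes, spearman
from .metagene import metagene_profile, ranked_gene_matrix
from .regions import (
    co_occupied_genes,
    define_enhancers,
    define_heterochromatin,
    define_promoters,
    genes_of_enhancers,
)
from .simulate import (
    ExpressionEffects,
    GenomeConfig,
    make_genome,
    simulate_chip_reads,
    simulate_knockdown_expression,
    write_fixture,
)
from .superenhancer import (
    DEFAULT_STITCH_DISTANCE,
    fold_difference,
    partition_enhancers,
    rank_by_signal,
    stitch_constituents,
)

logger = logging.getLogger(__name__)

CHIP_FACTORS = (
    "MED1",
    "NIPBL",
    "SMC1",
    "CAPH2",
    "OCT4",
    "SOX2",
    "NANOG",
    "TBP",
    "POLII",
    "H3K9me3",
    "H4K20me3",
    "WCE",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the demo pipeline, with seeded randomness."""

    seed: int = 0
    outdir: str = "smcpipe_out"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    effects: ExpressionEffects = field(default_factory=ExpressionEffects)
    depth: int = 1_000_000
    read_len: int = 36
    bin_size: int = 50
    extend_len: int = 200
    p_cutoff: float = 1e-5
    min_width: int = 100
    merge_gap: int = 200
    stitch_distance: int = DEFAULT_STITCH_DISTANCE
    gene_max_distance: int = 50_000
    cooccupancy_window: int = 2500
    metagene_flank: int = 3000
    metagene_body_bins: int = 60
    rank_norm_floor: float = 0.2
    write_files: bool = True


def _sub_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run all stages; return the summary dict (also written to disk).

    The summary carries region counts per class, the super/typical
    partition, fold differences per factor, knockdown correlations and the
    class-comparison statistics — every headline number of the analysis.
    """
    cfg = config
    logger.info("stage simulate: genome %s, seed %d", dict(cfg.genome.chrom_sizes), cfg.seed)
    genome_cfg = dataclasses.replace(cfg.genome, seed=_sub_seed(cfg.seed, "genome"))
    layout = make_genome(genome_cfg)

    reads = {
        f: simulate_chip_reads(
            layout, f, cfg.depth, cfg.read_len, seed=_sub_seed(cfg.seed, f"chip:{f}")
        )
        for f in CHIP_FACTORS
    }
    logger.info("stage quantify: %d factors at depth %d", len(reads), cfg.depth)
    tracks: dict[str, CoverageTrack] = {
        f: build_track(r, layout.chrom_sizes, cfg.bin_size, cfg.extend_len)
        for f, r in reads.items()
    }

    logger.info("stage regions: Poisson calling vs WCE, p<%g", cfg.p_cutoff)
    control = tracks["WCE"]
    occupied = {
        f: call_occupied_regions(
            tracks[f], control, cfg.p_cutoff, cfg.min_width, cfg.merge_gap, factor=f
        )
        for f in CHIP_FACTORS
        if f != "WCE"
    }
    enhancers = define_enhancers(occupied["OCT4"], occupied["SOX2"], occupied["NANOG"])
    promoters = define_promoters(occupied["TBP"], occupied["POLII"])
    heterochrom = define_heterochromatin(occupied["H3K9me3"], occupied["H4K20me3"])

    logger.info("stage metagene: flank %d bp, %d body bins", cfg.metagene_flank, cfg.metagene_body_bins)
    se_factors = ("MED1", "NIPBL", "CAPH2", "SMC1")
    enhancer_metagenes = {
        f: metagene_profile(
            tracks[f], enhancers.regions, cfg.metagene_flank, cfg.metagene_body_bins, f
        )
        for f in se_factors
    }

    logger.info("stage superenhancers: stitch %d bp", cfg.stitch_distance)
    stitched = stitch_constituents(enhancers.regions, cfg.stitch_distance)
    ranked = rank_by_signal(stitched, tracks["MED1"], control)
    partition = partition_enhancers(ranked)
    folds = {
        f: {
            "enhancers": fold_difference(tracks[f], partition, "enhancers"),
            "constituents": fold_difference(tracks[f], partition, "constituents"),
        }
        for f in se_factors
    }

    se_map = genes_of_enhancers(
        [se.span for se in partition.super_enhancers],
        layout.genes,
        cfg.gene_max_distance,
    )
    te_map = genes_of_enhancers(
        [te.span for te in partition.typical_enhancers],
        layout.genes,
        cfg.gene_max_distance,
    )
    se_genes = sorted({g for g in se_map.values() if g is not None})
    te_genes = sorted(
        {g for g in te_map.values() if g is not None} - set(se_genes)
    )

    logger.info("stage expression: %d SE genes, %d TE genes", len(se_genes), len(te_genes))
    expr = simulate_knockdown_expression(
        layout, cfg.effects, seed=_sub_seed(cfg.seed, "expression")
    )
    fc_c1 = fold_changes(expr, "shCAPH2#1")
    fc_c2 = fold_changes(expr, "shCAPH2#2")
    fc_caph2 = fold_changes(expr, ["shCAPH2#1", "shCAPH2#2"], pool=True)
    fc_smc1 = fold_changes(expr, "shSMC1")
    cooccupied = co_occupied_genes(
        occupied["CAPH2"], occupied["SMC1"], layout.genes, cfg.cooccupancy_window
    )

    stats_block = {}
    for label, fc in (("CAPH2", fc_caph2), ("SMC1", fc_smc1)):
        box_se, box_te, p = compare_gene_classes(fc, se_genes, te_genes)
        stats_block[label] = {
            "median_se": box_se.median,
            "median_te": box_te.median,
            "p_two_tailed": p,
        }

    planted_spans = [
        (cl[0].chrom, cl[0].start, cl[-1].end) for cl in layout.se_clusters
    ]

    def hits_planted(span) -> bool:
        return any(
            span.chrom == c and span.start < e and s < span.end
            for c, s, e in planted_spans
        )

    n_planted_recovered = sum(
        1 for se in partition.super_enhancers if hits_planted(se.span)
    )

    summary = {
        "seed": cfg.seed,
        "n_genes": len(layout.genes),
        "regions": {
            "enhancers": len(enhancers.regions),
            "promoters": len(promoters.regions),
            "heterochromatin": len(heterochrom.regions),
            **{f: len(occ.regions) for f, occ in occupied.items()},
        },
        "super_enhancers": {
            "n_stitched": len(partition.ranked),
            "n_super": partition.n_super,
            "n_typical": partition.n_typical,
            "n_planted_clusters": len(layout.se_clusters),
            "n_planted_recovered": n_planted_recovered,
        },
        "fold_differences": folds,
        "gene_classes": {"se": len(se_genes), "te": len(te_genes)},
        "n_co_occupied_genes": len(cooccupied),
        "spearman": {
            "caph2_1_vs_2": spearman(fc_c1.values, fc_c2.values),
            "caph2_avg_vs_smc1": spearman(fc_caph2.values, fc_smc1.values),
        },
        "class_comparison": stats_block,
    }

    if cfg.write_files:
        os.makedirs(cfg.outdir, exist_ok=True)
        write_fixture(os.path.join(cfg.outdir, "fixture"), layout, expression=expr)
        gio.write_bed(
            os.path.join(cfg.outdir, "enhancers.bed"),
            enhancers.regions,
            names=["OSN"] * len(enhancers.regions),
            scores=[0] * len(enhancers.regions),
        )
        gio.write_bed(
            os.path.join(cfg.outdir, "stitched_enhancers.bed"),
            [se.span for se in partition.ranked],
            names=[
                ("super" if i >= partition.cutoff_index else "typical")
                for i in range(len(partition.ranked))
            ],
            scores=[se.ranking_signal for se in partition.ranked],
        )
        for f, prof in enhancer_metagenes.items():
            prof.to_frame().to_csv(
                os.path.join(cfg.outdir, f"metagene_{f}.tsv"), sep="\t", index=False
            )
        matrix = ranked_gene_matrix(
            {f: tracks[f] for f in ("POLII", "CAPH2", "SMC1", "NIPBL")},
            layout.genes,
            window=1000,
            rank_factor="POLII",
        )
        matrix.to_csv(os.path.join(cfg.outdir, "ranked_gene_matrix.tsv"), sep="\t")
        norm_a, norm_b = rank_normalize(tracks["CAPH2"], tracks["NIPBL"])
        gio.write_bedgraph(
            os.path.join(cfg.outdir, "CAPH2_ranknorm.bedgraph"),
            track_to_bedgraph_records(norm_a, "raw", floor=cfg.rank_norm_floor),
        )
        fc_table = fc_caph2.to_frame("log2fc_CAPH2")
        fc_table["log2fc_SMC1"] = fc_smc1
        fc_table.to_csv(os.path.join(cfg.outdir, "fold_changes.tsv"), sep="\t")
        with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest = {}
        for root, _dirs, files in os.walk(cfg.outdir):
            for name in sorted(files):
                if name == "manifest.json":
                    continue
                p = os.path.join(root, name)
                manifest[os.path.relpath(p, cfg.outdir)] = _hash_file(p)
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
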