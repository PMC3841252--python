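"""Build a toy genome with planted regulatory elements and write it to disk.

The layout plants super-enhancer clusters (several constituents within
stitching range), isolated typical enhancers, promoters, gene bodies and
heterochromatin domains, then draws ChIP-seq reads whose local rate follows
each factor's enrichment rule.
"""

from smcpipe import GenomeConfig, make_genome, simulate_chip_reads, write_fixture

layout = make_genome(GenomeConfig(seed=11))
reads = {
    f: simulate_chip_reads(layout, f, depth=200_000, seed=11)
    for f in ("MED1", "WCE")
}
paths = write_fixture("example_fixture", layout, reads)

print(f"chromosomes: {layout.chrom_sizes}")
print(f"planted: {len(layout.se_clusters)} super-enhancer clusters, "
      f"{len(layout.typical_constituents)} typical enhancers, "
      f"{len(layout.genes)} genes, "
      f"{len(layout.heterochromatin)} heterochromatin domains")
print(f"MED1 reads drawn: {len(reads['MED1'])} (expected 200,000 +- Poisson)")
print("files:", ", ".join(sorted(paths)))
# The MED1 read count fluctuates around the requested depth because the
# total is itself Poisson; the element counts are exact by construction.
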