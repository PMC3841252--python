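# smcpipe

Occupancy and knockdown-sensitivity analysis of SMC complexes — cohesin
(assayed via its SMC1 subunit) and condensin II (via CAPH2) — at active
enhancers, promoters and super-enhancers, built for embryonic-stem-cell
style regulatory genomics.

The package is a tested, reusable re-implementation of a complete analysis
chain: from aligned ChIP-seq reads (BED) and RNA-seq counts (TSV) through
binned coverage in reads-per-million units, occupied-region calling against
a control, region-class definition by factor co-occupancy, metagene density
profiling, super-enhancer identification, rank normalization across
conditions, and knockdown expression statistics. A first-class synthetic
data module plants all of the structure the pipeline is built to detect, so
every stage is testable without external downloads.

## The analysis

**Quantification.** Reads are extended to the expected fragment length
(default 200 bp), counted into fixed bins (default 50 bp), and signal over
a region *R* is reported as

  RPM(R) = (reads overlapping R) × 10⁶ / (total mapped reads),

with density RPM(R)/|R| in reads per million per base pair. Partial bins
count pro-rata.

**Occupied regions.** Each bin's count *k* is tested against a Poisson null
with λ the depth-scaled control count (floored at the control's
genome-average rate); bins with upper-tail P(X ≥ k) below the cutoff are
merged and width-filtered. Enhancers are bases occupied by OCT4 ∧ SOX2 ∧
NANOG; promoters by TBP ∧ POL II; heterochromatin is the union of H3K9me3
and H4K20me3 domains.

**Super-enhancers.** Enhancer constituents within 12.5 kb are stitched into
domains, scored by control-subtracted Mediator (MED1) RPM, and ranked. With
rank and signal both scaled to [0, 1], the cutoff sits where a unit-slope
line is tangent to the ranked curve (argmin of *y* − *x*); enhancers above
it are super-enhancers. Fold differences compare mean total RPM at
super- vs typical-enhancer spans, and mean density at their constituents.

**Expression sensitivity.** Counts are CPM-normalized; knockdown log₂ fold
changes pool the two CAPH2 shRNAs before the ratio; gene classes
(super-enhancer- vs typical-enhancer-associated, by nearest TSS within
50 kb) are compared with a two-tailed Welch t test and 1.5×IQR box
statistics; cross-knockdown agreement uses Spearman correlation.

## Worked example

```bash
python examples/03_super_enhancers.py
```

```
380 constituents -> 320 stitched enhancers -> 20 super / 300 typical
planted super-enhancer clusters: 20
MED1 fold difference at enhancers: 12.16
MED1 fold difference at constituents: 2.48
```

The simulated genome plants 20 clusters of enhancer constituents and 300
isolated constituents; stitching merges each cluster into one domain and
the tangent cutoff separates exactly the 20 planted clusters. The fold
difference at whole enhancers (12.2) dwarfs the constituent-density fold
(2.48 ≈ the planted Mediator density ratio of 20/8 = 2.5) because
super-enhancer spans are an order of magnitude wider than typical
enhancers. The other examples (`examples/0*.py`) cover fixture simulation,
coverage/region calling, metagene profiles and knockdown expression; each
prints the numbers it computes with a note on what they mean.

A `smcpipe` command exposes the same stages from the shell
(`simulate`, `quantify`, `regions`, `metagene`, `superenhancers`,
`expression`, `run-all`); `smcpipe run-all --seed 1 --outdir out` writes
all exports plus a `summary.json` and a hash manifest.

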