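"""Knockdown expression statistics.

Counts are normalized to counts per million (CPM); knockdown effects are
log2 fold changes of mean CPM versus the control hairpin, optionally
pooling the two condensin II shRNAs; class comparisons (super-enhancer- vs
typical-enhancer-associated genes) use Welch t tests and 1.5x-IQR box
statistics; qPCR fold enrichment uses the standard 2^-ddCt arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionTable:
    """A gene x sample count matrix with per-sample condition metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame  # index: sample; columns: condition, replicate

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.metadata.index):
            raise ValueError("metadata index must match count columns")
        if (self.metadata.groupby("condition").size() < 1).any():
            raise ValueError("every condition needs at least one sample")

    def samples_of(self, condition: str) -> list[str]:
        hit = self.metadata.index[self.metadata["condition"] == condition]
        if len(hit) == 0:
            raise KeyError(f"condition {condition!r} absent")
        return list(hit)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["condition"]))


def normalize_counts(table: ExpressionTable) -> pd.DataFrame:
    """Counts per million per sample: count x 1e6 / library size."""
    lib = table.counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    return table.counts * 1e6 / lib


def fold_changes(
    table: ExpressionTable,
    kd_conditions: str | Sequence[str],
    ctrl_condition: str = "shGFP",
    pool: bool = True,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change of knockdown vs control CPM.

    Replicates are averaged within each condition. With several knockdown
    conditions and ``pool=True``, their mean levels are averaged before the
    ratio (the pooled-shRNA convention); with ``pool=False`` a DataFrame of
    per-condition fold changes is returned instead.
    """
    if isinstance(kd_conditions, str):
        kd_conditions = [kd_conditions]
    cpm = normalize_counts(table)
    ctrl = cpm[table.samples_of(ctrl_condition)].mean(axis=1)
    kd_means = {
        c: cpm[table.samples_of(c)].mean(axis=1) for c in kd_conditions
    }
    if pool or len(kd_conditions) == 1:
        kd = pd.concat(kd_means.values(), axis=1).mean(axis=1)
        return np.log2((kd + pseudocount) / (ctrl + pseudocount)).rename(
            "log2fc"
        )
    return pd.DataFrame(
        {
            c: np.log2((m + pseudocount) / (ctrl + pseudocount))
            for c, m in kd_means.items()
        }
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks on ties).

    Returns NaN for constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def rank_genes_by_avg_fc(
    fc_maps: Sequence[Mapping[str, float]],
    gene_set: Iterable[str],
) -> list[str]:
    """Order genes by ascending mean fold change across shRNA maps.

    Every gene must be present in every map; ties break by gene_id.
    """
    genes = list(gene_set)
    for m in fc_maps:
        missing = [g for g in genes if g not in m]
        if missing:
            raise KeyError(f"genes missing from a fold-change map: {missing[:5]}")
    avg = {g: float(np.mean([m[g] for m in fc_maps])) for g in genes}
    return sorted(genes, key=lambda g: (avg[g], g))


@dataclass(frozen=True)
class BoxStats:
    """Five-number box-plot summary with 1.5x-IQR whiskers.

    Whiskers extend at most 1.5 interquartile ranges beyond the quartiles
    and are clipped to the most extreme data point inside that fence;
    points beyond the fence are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "BoxStats":
        v = np.sort(np.asarray(values, dtype=float))
        if len(v) == 0:
            raise ValueError("empty sample")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
        return cls(
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=outliers,
        )


def compare_gene_classes(
    fc: Mapping[str, float] | pd.Series,
    class_a_genes: Iterable[str],
    class_b_genes: Iterable[str],
    equal_var: bool = False,
) -> tuple[BoxStats, BoxStats, float]:
    """Box statistics per gene class and a two-tailed t-test p-value.

    Welch's unequal-variance t test by default (``equal_var=True`` for the
    pooled-variance variant).
    """
    a = np.asarray([fc[g] for g in class_a_genes], dtype=float)
    b = np.asarray([fc[g] for g in class_b_genes], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 genes")
    if np.array_equal(a, b):
        p = 1.0  # identical samples: no evidence of difference
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return BoxStats.from_values(a), BoxStats.from_values(b), p


def one_tailed_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    direction: str = "greater",
    equal_var: bool = False,
) -> float:
    """One-tailed Welch t-test p-value for sample_a vs sample_b.

    ``direction='greater'`` tests mean(a) > mean(b); 'less' the reverse.
    At t = 0 (equal means) the p-value is 0.5 in either direction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=direction)
    return float(res.pvalue)


def qpcr_relative_quantity(
    ct_target: float,
    ct_reference: float,
    ct_target_ctrl: float,
    ct_reference_ctrl: float,
) -> float:
    """Relative quantity by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) in each condition; the fold value is
    2 to the minus (dCt_treated - dCt_control). One cycle fewer on the
    target doubles the quantity.
    """
    for v in (ct_target, ct_reference, ct_target_ctrl, ct_reference_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_ctrl - ct_reference_ctrl)
    return 2.0**-ddct
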