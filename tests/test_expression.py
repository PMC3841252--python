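"""Expression statistics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smcpipe import (
    BoxStats,
    ExpressionEffects,
    ExpressionTable,
    compare_gene_classes,
    fold_changes,
    normalize_counts,
    one_tailed_t,
    qpcr_relative_quantity,
    rank_genes_by_avg_fc,
    simulate_knockdown_expression,
    spearman,
)

from conftest import genes_only_layout


def table_from(counts: dict, conditions: dict) -> ExpressionTable:
    df = pd.DataFrame(counts, index=pd.Index(
        [f"g{i}" for i in range(len(next(iter(counts.values()))))], name="gene_id"
    ))
    meta = pd.DataFrame(
        {"condition": [conditions[s] for s in df.columns],
         "replicate": range(1, len(df.columns) + 1)},
        index=pd.Index(df.columns, name="sample"),
    )
    return ExpressionTable(counts=df, metadata=meta)


class TestNormalize:
    def test_single_gene_full_library(self):
        t = table_from({"s1": [50]}, {"s1": "shGFP"})
        assert normalize_counts(t).iloc[0, 0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        t1 = table_from({"s1": [10, 30]}, {"s1": "shGFP"})
        t2 = table_from({"s1": [20, 60]}, {"s1": "shGFP"})
        assert normalize_counts(t1).equals(normalize_counts(t2))

    def test_hand_arithmetic_3x2(self):
        t = table_from({"s1": [1, 2, 7], "s2": [5, 0, 5]},
                       {"s1": "shGFP", "s2": "shSMC1"})
        cpm = normalize_counts(t)
        assert np.allclose(cpm["s1"], [1e5, 2e5, 7e5])
        assert np.allclose(cpm["s2"], [5e5, 0, 5e5])

    def test_zero_library_rejected(self):
        t = table_from({"s1": [1], "s2": [0]}, {"s1": "shGFP", "s2": "shSMC1"})
        with pytest.raises(ValueError):
            normalize_counts(t)


class TestFoldChanges:
    def _toy(self):
        return table_from(
            {
                "c1": [100, 50], "c2": [100, 50],
                "k1": [200, 25], "k2": [100, 75],
            },
            {"c1": "shGFP", "c2": "shGFP",
             "k1": "shCAPH2#1", "k2": "shCAPH2#2"},
        )

    def test_kd_equal_ctrl_is_zero(self):
        t = table_from({"c1": [10, 20], "k1": [10, 20]},
                       {"c1": "shGFP", "k1": "shSMC1"})
        fc = fold_changes(t, "shSMC1", pseudocount=0)
        assert np.allclose(fc, 0)

    def test_doubled_level_gives_plus_one(self):
        # gene 0's CPM level doubles at constant library size
        t = table_from({"c1": [10, 90], "k1": [20, 80]},
                       {"c1": "shGFP", "k1": "shSMC1"})
        fc = fold_changes(t, "shSMC1", pseudocount=0)
        assert fc["g0"] == pytest.approx(1.0)

    def test_pooling_averages_levels_before_ratio(self):
        t = self._toy()
        cpm_scale = 1e6  # libraries: c 150, k1 225, k2 175
        k1 = np.array([200 / 225, 25 / 225]) * cpm_scale
        k2 = np.array([100 / 175, 75 / 175]) * cpm_scale
        ctrl = np.array([100 / 150, 50 / 150]) * cpm_scale
        expected = np.log2(((k1 + k2) / 2) / ctrl)
        fc = fold_changes(t, ["shCAPH2#1", "shCAPH2#2"], pool=True, pseudocount=0)
        assert np.allclose(fc, expected)

    def test_antisymmetry(self):
        t = self._toy()
        fwd = fold_changes(t, "shCAPH2#1", "shGFP", pseudocount=0)
        rev = fold_changes(t, "shGFP", "shCAPH2#1", pseudocount=0)
        assert np.allclose(fwd, -rev)

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError):
            fold_changes(self._toy(), "shNIPBL")


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        assert spearman([1, 5, 9], [2, 3, 10]) == pytest.approx(1.0)
        assert spearman([1, 5, 9], [10, 3, 2]) == pytest.approx(-1.0)

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(71)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))

    def test_tied_instance_matches_rank_pearson_oracle(self):
        from scipy.stats import rankdata

        x = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
        y = [2, 7, 1, 8, 2, 8, 1, 8, 2, 8]
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle)

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestRankGenes:
    def test_singleton(self):
        assert rank_genes_by_avg_fc([{"a": 0.5}], ["a"]) == ["a"]

    def test_ascending_order(self):
        maps = [{"up": 1.0, "down": -2.0}, {"up": 1.0, "down": -2.0}]
        assert rank_genes_by_avg_fc(maps, ["up", "down"]) == ["down", "up"]

    def test_matches_sort_by_mean_oracle(self):
        rng = np.random.default_rng(72)
        genes = [f"g{i}" for i in range(100)]
        maps = [{g: float(rng.normal()) for g in genes} for _ in range(3)]
        got = rank_genes_by_avg_fc(maps, genes)
        oracle = sorted(genes, key=lambda g: (np.mean([m[g] for m in maps]), g))
        assert got == oracle

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError):
            rank_genes_by_avg_fc([{"a": 1.0}], ["a", "b"])


class TestBoxStatsAndClassComparison:
    def test_boxstats_quartiles_match_sorted_array_oracle(self):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 50.0]
        bs = BoxStats.from_values(vals)
        v = np.sort(vals)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert (bs.q1, bs.median, bs.q3) == (q1, med, q3)
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        assert bs.whisker_low == inside.min()
        assert bs.whisker_high == inside.max()
        assert bs.outliers == (50.0,)

    def test_identical_classes_give_p_one(self):
        fc = {f"a{i}": v for i, v in enumerate([0.1, 0.2, 0.3])}
        fc.update({f"b{i}": v for i, v in enumerate([0.1, 0.2, 0.3])})
        _, _, p = compare_gene_classes(fc, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert p == pytest.approx(1.0)

    def test_planted_class_difference_detected(self):
        rng = np.random.default_rng(73)
        fc = {f"se{i}": rng.normal(-1.0, 0.5) for i in range(200)}
        fc.update({f"te{i}": rng.normal(-0.3, 0.5) for i in range(200)})
        box_se, box_te, p = compare_gene_classes(
            fc, [f"se{i}" for i in range(200)], [f"te{i}" for i in range(200)]
        )
        assert p < 0.01
        assert box_se.median < box_te.median

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            compare_gene_classes({"a": 1.0, "b": 2.0, "c": 3.0}, ["a"], ["b", "c"])


class TestOneTailedT:
    def test_equal_means_give_half(self):
        assert one_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_direction_symmetry(self):
        a, b = [1.0, 2.0, 2.5, 3.0], [2.0, 3.0, 3.5, 4.5]
        pg = one_tailed_t(a, b, "greater")
        pl = one_tailed_t(a, b, "less")
        assert pg + pl == pytest.approx(1.0)

    def test_matches_exhaustive_permutation_oracle(self):
        a = [4.1, 5.2, 6.3, 5.8, 4.9]
        b = [3.0, 3.8, 4.2, 3.5, 4.6]
        p_t = one_tailed_t(a, b, "greater")

        pooled = a + b
        diff_obs = np.mean(a) - np.mean(b)
        count = total = 0
        for idx in itertools.combinations(range(10), 5):
            sel = np.zeros(10, bool)
            sel[list(idx)] = True
            d = np.mean(np.array(pooled)[sel]) - np.mean(np.array(pooled)[~sel])
            count += d >= diff_obs - 1e-12
            total += 1
        p_perm = count / total
        assert abs(p_t - p_perm) < 0.05


class TestQpcr:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 15, 20, 15), 1.0),   # all dCt equal
            ((19, 15, 20, 15), 2.0),   # one cycle lower -> doubled
            ((20, 15, 22, 15), 4.0),   # hand arithmetic: ddCt = -2
        ],
    )
    def test_ddct_arithmetic(self, cts, expected):
        assert qpcr_relative_quantity(*cts) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            qpcr_relative_quantity(float("nan"), 15, 20, 15)


class TestSimulationRecovery:
    def test_class_mean_fold_changes_recovered_over_seeds(self):
        """Pipeline-facing invariant: class means recovered within 0.1."""
        layout = genes_only_layout(200, 200, 0)
        se = [g for g, c in layout.gene_classes.items() if c == "se"]
        te = [g for g, c in layout.gene_classes.items() if c == "te"]
        for seed in range(3):
            table = simulate_knockdown_expression(
                layout, ExpressionEffects(), seed=seed
            )
            ctrl = table.counts[table.samples_of("shGFP")].mean(axis=1)
            kd = table.counts[
                table.samples_of("shCAPH2#1") + table.samples_of("shCAPH2#2")
            ].mean(axis=1)
            lr = np.log2(kd / ctrl)
            assert abs(lr[se].mean() + 1.0) < 0.1
            assert abs(lr[te].mean() + 0.3) < 0.1
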