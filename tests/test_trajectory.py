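"""Pseudotime analysis: fractions, binning, extreme cells, Welch test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from regulome.simulate import gen_expression_trajectory
from regulome.expression import flag_expressed
from regulome.trajectory import (
    CellAnnotation,
    TrajectoryConfig,
    bin_curve,
    cells_expressing_fraction,
    enrichment_over_pseudotime,
    filter_genes_by_group_expression,
    fraction_expressed,
    fraction_expressed_per_cell,
    select_extreme_cells,
    welch_t_one_tailed,
)


def flags_frame(array, genes=None, cells=None):
    array = np.asarray(array, dtype=bool)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    cells = cells or [f"c{i}" for i in range(array.shape[1])]
    return pd.DataFrame(array, index=genes, columns=cells)


class TestFractionExpressed:
    def test_saturated_and_empty_cells(self):
        flags = flags_frame(np.ones((10, 1)))
        assert fraction_expressed_per_cell(flags, set(flags.index), "c0") == 100.0
        flags = flags_frame(np.zeros((10, 1)))
        assert fraction_expressed_per_cell(flags, set(flags.index), "c0") == 0.0

    def test_matches_naive_count(self, rng):
        flags = flags_frame(rng.random((40, 8)) < 0.3)
        gene_set = {f"g{i}" for i in range(0, 40, 2)}
        out = fraction_expressed(flags, gene_set)
        for cell in flags.columns:
            naive = 100 * sum(flags.at[g, cell] for g in sorted(gene_set)) / len(gene_set)
            assert out[cell] == pytest.approx(naive)

    def test_absent_set_is_an_error(self):
        with pytest.raises(ValueError):
            fraction_expressed(flags_frame(np.ones((2, 2))), {"nope"})


class TestGroupFilter:
    def test_or_semantics_and_boundary(self):
        early = [f"e{i}" for i in range(10)]
        late = [f"l{i}" for i in range(10)]
        flags = pd.DataFrame(False, index=["gA", "gB", "gC"], columns=early + late)
        flags.loc["gA", ["e0", "e1"]] = True  # 2/10 early, 0 late -> kept
        flags.loc["gC", "e0"] = True  # exactly 1/10 -> kept (>=)
        kept = filter_genes_by_group_expression(flags, early, late, 0.10)
        assert kept == {"gA", "gC"}

    def test_empty_group_is_an_error(self):
        flags = flags_frame(np.ones((2, 2)))
        with pytest.raises(ValueError):
            filter_genes_by_group_expression(flags, [], ["c0"], 0.1)


class TestBinCurve:
    def test_sparse_bin_dropped(self):
        pt = pd.Series({"a": 0.01, "b": 0.05, "c": 0.15})
        vals = pd.Series({"a": 10.0, "b": 20.0, "c": 99.0})
        out = bin_curve(pt, vals, bin_width=0.1, min_cells_per_bin=2)
        assert len(out) == 1
        assert out.loc[0, "bin_mid"] == pytest.approx(0.05)
        assert out.loc[0, "mean"] == pytest.approx(15.0)

    def test_single_bin(self):
        pt = pd.Series({"a": 0.02, "b": 0.03})
        out = bin_curve(pt, pd.Series({"a": 1.0, "b": 3.0}))
        assert len(out) == 1 and out.loc[0, "mean"] == 2.0

    def test_matches_naive_grouping(self, rng):
        pt = pd.Series(rng.uniform(0, 1, 200), index=[f"c{i}" for i in range(200)])
        vals = pd.Series(rng.uniform(0, 100, 200), index=pt.index)
        out = bin_curve(pt, vals, 0.1, 2)
        for _, row in out.iterrows():
            members = pt.index[(pt >= row.bin_mid - 0.05 - 1e-12)
                               & (pt < row.bin_mid + 0.05)]
            assert row["n_cells"] == len(members)
            assert row["mean"] == pytest.approx(vals[members].mean())
            lo, hi = vals[members].min(), vals[members].max()
            assert lo <= row["mean"] <= hi

    def test_no_surviving_bin_is_an_error(self):
        pt = pd.Series({"a": 0.01, "b": 0.5})
        with pytest.raises(ValueError):
            bin_curve(pt, pd.Series({"a": 1.0, "b": 2.0}))


class TestSelectExtremeCells:
    def cells(self, pts):
        return [CellAnnotation(cell_id=k, pseudotime=v) for k, v in pts.items()]

    def test_earliest_and_latest(self):
        pts = {f"c{i:02d}": float(i) for i in range(12)}
        cells = self.cells(pts)
        assert select_extreme_cells(cells, 10, "earliest") == \
            [f"c{i:02d}" for i in range(10)]
        assert select_extreme_cells(cells, 10, "latest") == \
            [f"c{i:02d}" for i in range(11, 1, -1)]

    def test_tie_broken_lexicographically(self):
        cells = self.cells({"b": 1.0, "a": 1.0, "c": 0.0})
        assert select_extreme_cells(cells, 2, "earliest") == ["c", "a"]

    def test_order_invariance(self, rng):
        pts = {f"c{i:03d}": float(rng.integers(0, 5)) for i in range(30)}
        cells = self.cells(pts)
        baseline = select_extreme_cells(cells, 10, "earliest")
        for _ in range(5):
            perm = list(cells)
            rng.shuffle(perm)
            assert select_extreme_cells(perm, 10, "earliest") == baseline

    def test_too_few_cells_is_an_error(self):
        with pytest.raises(ValueError):
            select_extreme_cells(self.cells({"a": 0.0}), 2)


class TestWelch:
    def test_identical_samples_give_half_p(self):
        t, df, p = welch_t_one_tailed([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_worked_example_matches_hand_formula(self):
        t, df, p = welch_t_one_tailed([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert t == pytest.approx(1.0)
        assert df == pytest.approx(8.0)
        assert p == pytest.approx(0.1733, abs=5e-5)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(3, 15)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 15)))
            t, df, p = welch_t_one_tailed(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_antisymmetry_and_p_complement(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        t_ab, df_ab, p_ab = welch_t_one_tailed(a, b)
        t_ba, df_ba, p_ba = welch_t_one_tailed(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert df_ab == pytest.approx(df_ba)
        assert p_ab + p_ba == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t_one_tailed([1.0], [1, 2])
        with pytest.raises(ValueError):
            welch_t_one_tailed([2, 2, 2], [3, 3, 3])


class TestEnrichment:
    def make_scenario(self, seed, p_target_early=0.4, p_bg_early=0.2,
                      n_cells=100, n_targets=60, n_bg=300):
        genes = [f"g{i:04d}" for i in range(n_targets + n_bg)]
        matrix, cells, truth = gen_expression_trajectory(
            genes, n_cells=n_cells, target_set=genes[:n_targets],
            p_target_early=p_target_early, p_bg_early=p_bg_early, seed=seed,
        )
        flags = flag_expressed(matrix)
        cfg = TrajectoryConfig(early_max_pseudotime=0.1, late_min_pseudotime=0.9)
        return flags, cells, set(genes[:n_targets]), set(genes[n_targets:]), cfg

    def test_null_plant_fold_near_one(self):
        folds, pvals = [], []
        for seed in range(40):
            flags, cells, targets, non_targets, cfg = self.make_scenario(
                seed, p_target_early=0.2, p_bg_early=0.2
            )
            r = enrichment_over_pseudotime(flags, cells, targets, non_targets,
                                           cfg, apply_filter=False)
            folds.append(r.early.fold)
            pvals.append(r.early.p)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)
        # type-I error at 5% within a 3-SE binomial band around 0.05
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_percentages_bounded_and_curves_cover_both_sets(self):
        flags, cells, targets, non_targets, cfg = self.make_scenario(3)
        r = enrichment_over_pseudotime(flags, cells, targets, non_targets, cfg)
        assert set(r.curves.set_label) == {"target", "non_target"}
        assert ((r.curves.mean_pct >= 0) & (r.curves.mean_pct <= 100)).all()
        assert 0 < r.early.p <= 1 and r.early.df > 0

    def test_overlapping_sets_rejected(self):
        flags, cells, targets, non_targets, cfg = self.make_scenario(3)
        with pytest.raises(ValueError, match="overlap"):
            enrichment_over_pseudotime(flags, cells, targets,
                                       targets | non_targets, cfg)


class TestCellsExpressingFraction:
    def test_saturating_and_empty_groups(self):
        flags = flags_frame([[True, True], [False, False]])
        out = cells_expressing_fraction(flags, {"g0"}, {"all": ["c0", "c1"]})
        assert out["all"] == 100.0
        out = cells_expressing_fraction(flags, {"g1"}, {"all": ["c0", "c1"]})
        assert out["all"] == 0.0

    def test_matches_naive_loop(self, rng):
        flags = flags_frame(rng.random((20, 12)) < 0.2)
        gene_set = {f"g{i}" for i in range(0, 20, 4)}
        groups = {"a": [f"c{i}" for i in range(6)],
                  "b": [f"c{i}" for i in range(6, 12)]}
        out = cells_expressing_fraction(flags, gene_set, groups)
        for name, members in groups.items():
            naive = 100 * np.mean([
                any(flags.at[g, c] for g in sorted(gene_set)) for c in members
            ])
            assert out[name] == pytest.approx(naive)

    def test_empty_group_is_an_error(self):
        flags = flags_frame(np.ones((2, 2)))
        with pytest.raises(ValueError):
            cells_expressing_fraction(flags, {"g0"}, {"empty": []})
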