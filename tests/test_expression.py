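"""Normalization, the DE surrogate, BH adjustment, DEG filtering, outlier
flagging and condition-mean / CV gene selection."""

import numpy as np
import pandas as pd
import pytest

from pahtox.expression import (
    bh_adjust,
    condition_means,
    de_table,
    filter_degs,
    flag_outlier_replicates,
    size_factors,
    top_cv_genes,
)


def bh_brute_force(p):
    """Independent step-up oracle: literal definition, quadratic scan."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]}, index=["g1", "g2"])
        f = size_factors(counts)
        # both rows give ratio 1/sqrt(2) for s1 and sqrt(2) for s2
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]})
        assert size_factors(counts).nunique() == 1

    def test_doubling_one_sample_doubles_only_its_factor(self, rng):
        # factors are defined up to a common scale (the reference geometric
        # mean shifts too), so the invariant is on factor ratios
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(50, 4)), columns=list("abcd")
        )
        f0 = size_factors(counts)
        doubled = counts.copy()
        doubled["c"] = doubled["c"] * 2
        f1 = size_factors(doubled)
        assert f1["c"] / f1["a"] == pytest.approx(2 * f0["c"] / f0["a"])
        assert f1["b"] / f1["a"] == pytest.approx(f0["b"] / f0["a"])
        assert f1["d"] / f1["a"] == pytest.approx(f0["d"] / f0["a"])

    def test_no_reference_genes_is_error(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(counts)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_textbook_equalizing_case(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.max(np.abs(bh_adjust(p) - bh_brute_force(p))) < 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


def _two_group_setup(t_vals, c_vals):
    nt, nc = len(t_vals[0]), len(c_vals[0])
    counts = pd.DataFrame(
        np.column_stack([np.array(t_vals), np.array(c_vals)]).astype(int),
        index=[f"g{i}" for i in range(len(t_vals))],
        columns=[f"t_r{i}" for i in range(nt)] + [f"c_r{i}" for i in range(nc)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "treatment": ["trt"] * nt + ["ctrl"] * nc,
            "day": 1,
            "replicate": list(range(1, nt + 1)) + list(range(1, nc + 1)),
            "is_control": [False] * nt + [True] * nc,
        }
    )
    return counts, meta


class TestDETable:
    def test_exact_doubling_gives_log2fc_one(self):
        t = [[20000, 20000, 20002]] * 3 + [[1000, 1001, 999]]
        c = [[10000, 10001, 9999]] * 3 + [[1000, 1000, 1001]]
        counts, meta = _two_group_setup(t, c)
        # equal size factors by construction are not guaranteed; bypass with unit factors
        de = de_table(counts, meta, "trt", factors=pd.Series(1.0, index=counts.columns))
        assert de.loc["g0", "log2fc"] == pytest.approx(1.0, abs=0.01)
        assert de.loc["g3", "log2fc"] == pytest.approx(0.0, abs=0.01)

    def test_identical_groups_yield_null_table(self, rng):
        base = rng.integers(10, 500, size=(100, 3))
        counts, meta = _two_group_setup(base.tolist(), base.tolist())
        de = de_table(counts, meta, "trt")
        assert np.allclose(de["log2fc"], 0.0)
        assert len(filter_degs(de).genes) == 0

    def test_planted_battery_log2fc_recovered(self, small_study):
        counts, meta, truth = small_study
        de = de_table(counts, meta, "retene")
        battery = truth["battery_genes"]
        assert len(battery) >= 50
        med = float(de.loc[battery, "log2fc"].median())
        assert med == pytest.approx(2.0, abs=0.3)

    def test_absent_treatment_is_error(self, small_study):
        counts, meta, _ = small_study
        with pytest.raises(ValueError, match="absent"):
            de_table(counts, meta, "no-such-treatment")


class TestFilterDEGs:
    def _de(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=["log2fc", "p", "padj"])

    def test_empty_input_empty_set(self):
        assert filter_degs(self._de([])).genes == set()

    def test_threshold_boundary_excludes_just_below(self):
        # log2(1.5) ~ 0.585: 0.58 misses even with tiny padj
        de = self._de([[0.58, 0.001, 0.01]])
        assert filter_degs(de).genes == set()

    def test_reduced_gene_included_by_absolute_value(self):
        de = self._de([[-1.0, 0.01, 0.04]])
        out = filter_degs(de)
        assert out.reduced == {"g0"} and out.elevated == set()

    def test_fc_min_below_one_rejected(self):
        with pytest.raises(ValueError):
            filter_degs(self._de([[1.0, 0.01, 0.01]]), fc_min=0.8)


class TestOutlierFlagging:
    def _study(self, displace=False):
        rng = np.random.default_rng(11)
        # three conditions x 4 replicates with distinct expression *shapes*
        # (depth-only differences are removed by normalization)
        rates = {c: rng.lognormal(np.log(300), 1.0, size=60) for c in "ABC"}
        cols, data, meta_rows = [], [], []
        for cond, rate in rates.items():
            for rep in range(1, 5):
                sid = f"{cond}_r{rep}"
                cols.append(sid)
                data.append(rng.poisson(rate))
                meta_rows.append(
                    {"sample_id": sid, "treatment": cond, "day": 1,
                     "replicate": rep, "is_control": cond == "A"}
                )
        counts = pd.DataFrame(np.array(data).T, columns=cols)
        if displace:
            counts["B_r4"] = rng.poisson(rates["C"])
        meta = pd.DataFrame(meta_rows)
        return counts, meta

    def test_tight_replicates_none_flagged(self):
        counts, meta = self._study()
        keep = flag_outlier_replicates(counts, meta)
        assert keep.all()

    def test_displaced_replicate_is_the_one_flagged(self):
        counts, meta = self._study(displace=True)
        keep = flag_outlier_replicates(counts, meta)
        assert not keep["B_r4"]
        assert keep.drop("B_r4").all()

    def test_invariant_to_sample_column_order(self):
        counts, meta = self._study(displace=True)
        perm = list(counts.columns[::-1])
        keep1 = flag_outlier_replicates(counts, meta)
        keep2 = flag_outlier_replicates(counts[perm], meta)
        assert keep1.sort_index().equals(keep2.sort_index())


class TestConditionMeans:
    def test_replicate_averaging(self):
        counts, meta = _two_group_setup([[2, 4, 3]], [[6, 6, 6]])
        cm = condition_means(counts, meta, factors=pd.Series(1.0, index=counts.columns))
        assert cm.loc["trt", "g0"] == pytest.approx(3.0)
        assert cm.loc["ctrl", "g0"] == pytest.approx(6.0)

    def test_full_design_has_18_condition_rows(self, small_study):
        counts, meta, _ = small_study
        cm = condition_means(counts, meta)
        assert cm.shape[0] == 18

    def test_zero_retained_replicates_is_error(self):
        counts, meta = _two_group_setup([[2, 4, 3]], [[6, 6, 6]])
        keep = pd.Series(
            [False, False, False, True, True, True], index=counts.columns
        )
        with pytest.raises(ValueError, match="zero retained"):
            condition_means(counts, meta, keep=keep)

    def test_means_then_cv_invariant_to_replicate_order(self, small_study):
        counts, meta, _ = small_study
        perm = list(counts.columns[::-1])
        cm1 = condition_means(counts, meta)
        cm2 = condition_means(counts[perm], meta)
        assert top_cv_genes(cm1, 50) == top_cv_genes(cm2, 50)


class TestTopCVGenes:
    def test_hand_computed_ordering(self):
        cm = pd.DataFrame(
            {"gA": [10, 10, 10], "gB": [5, 10, 15], "gC": [1, 1, 10]},
            index=["c1", "c2", "c3"],
        )
        # CVs: gA = 0, gB = 5/10 = 0.5, gC = sqrt(27)/4 ~ 1.299
        assert top_cv_genes(cm, 3) == ["gC", "gB", "gA"]

    def test_constant_gene_ranked_last(self):
        cm = pd.DataFrame({"flat": [7, 7, 7], "var": [1, 5, 9]})
        assert top_cv_genes(cm, 2)[-1] == "flat"

    def test_n_larger_than_gene_count_returns_all_eligible(self):
        cm = pd.DataFrame({"a": [1, 2], "b": [3, 1], "zero": [0, 0]})
        out = top_cv_genes(cm, 10)
        assert set(out) == {"a", "b"}  # zero-mean gene excluded
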