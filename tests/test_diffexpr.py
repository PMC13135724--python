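"""Hurdle DE, exact Wilcoxon rank-sum, proportion pseudobulk, XIST exclusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import loyscan as ls
from loyscan import simulate as sim
from loyscan.diffexpr import avg_log2fc, rank_sum_test


def _norm_frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"c{i}" for i in range(values.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(values.shape[1])])


def _cells(norm, group):
    return pd.DataFrame({"barcode": norm.index, "grp": np.asarray(group, dtype=bool)})


class TestHurdleDE:
    def test_identical_groups_are_null(self, rng):
        half = np.log1p(rng.poisson(3, size=(400, 5)))
        values = np.vstack([half, half])  # the same cells duplicated
        norm = _norm_frame(values)
        grp = np.r_[np.ones(400, bool), np.zeros(400, bool)]
        res = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0)
        assert np.allclose(res.table["avg_log2fc"], 0.0, atol=1e-12)
        assert (res.table["p_hurdle"] > 0.9).all()

    def test_detection_only_signal_is_discrete_driven(self, rng):
        # 50% vs 10% zeros with equal positive means: the discrete part
        # carries the signal; cross-check the discrete LR against a direct
        # binomial-likelihood oracle on the 2x2 detection table
        n = 1000
        pos = rng.gamma(4.0, 0.5, size=2 * n)
        detect = np.r_[rng.random(n) < 0.5, rng.random(n) < 0.9]
        target = np.where(detect, pos, 0.0)
        filler = np.log1p(rng.poisson(2, size=(2 * n, 6)))  # null background
        norm = _norm_frame(np.column_stack([target, filler]))
        grp = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0)
        row = res.table.set_index("gene").loc["g0"]
        assert row["p_adj"] < 0.05
        assert row["p_discrete"] < 1e-10
        # oracle: binomial LR on detection counts alone (no covariate)
        k1, k2 = detect[:n].sum(), detect[n:].sum()
        def bin_llf(k, n_, p):
            p = min(max(p, 1e-12), 1 - 1e-12)
            return k * np.log(p) + (n_ - k) * np.log(1 - p)
        lr_oracle = 2 * (bin_llf(k1, n, k1 / n) + bin_llf(k2, n, k2 / n)
                         - bin_llf(k1, n, (k1 + k2) / (2 * n))
                         - bin_llf(k2, n, (k1 + k2) / (2 * n)))
        p_oracle = scipy.stats.chi2.sf(lr_oracle, 1)
        # detection-rate covariate differs slightly; same order of magnitude
        assert row["p_discrete"] < max(p_oracle * 1e3, 1e-20)

    def test_low_detection_gene_filtered(self, rng):
        n = 1000
        values = np.zeros((2 * n, 2))
        rare = rng.random(2 * n) < 0.005      # 0.5% detection in both groups
        values[rare, 0] = 1.0
        values[:, 1] = np.log1p(rng.poisson(5, size=2 * n))
        norm = _norm_frame(values)
        grp = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0)
        assert "g0" not in set(res.table["gene"])

    def test_each_vs_either_detection_mode(self, rng):
        n = 500
        values = np.zeros((2 * n, 1))
        values[:40, 0] = 2.0  # 8% detection in group1, 0% in group2
        norm = _norm_frame(values)
        grp = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        each = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0)
        either = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0,
                              min_pct_mode="either")
        assert len(each.table) == 0
        assert len(either.table) == 1

    def test_swapping_groups_negates_logfc_preserves_p(self, rng):
        values = np.log1p(rng.poisson(2, size=(600, 8)))
        values[:300] += rng.random((300, 8)) < 0.3
        norm = _norm_frame(values)
        grp = np.r_[np.ones(300, bool), np.zeros(300, bool)]
        a = ls.hurdle_de(norm, _cells(norm, grp), "grp", min_abs_log2fc=0.0).table
        b = ls.hurdle_de(norm, _cells(norm, ~grp), "grp", min_abs_log2fc=0.0).table
        merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
        assert np.allclose(merged["avg_log2fc_a"], -merged["avg_log2fc_b"], atol=1e-9)
        assert np.allclose(merged["p_hurdle_a"], merged["p_hurdle_b"], atol=1e-7)

    def test_hurdle_statistic_is_sum_of_components(self, cohort, normalized):
        res = ls.hurdle_de(normalized, cohort["cells"], "loy", cell_type="mono-c",
                           min_abs_log2fc=0.0)
        t = res.table
        recomputed = scipy.stats.chi2.isf(t["p_discrete"], 1).clip(0) \
            + np.where(t["p_continuous"].notna(),
                       scipy.stats.chi2.isf(t["p_continuous"].fillna(1.0), 1), 0.0)
        assert np.allclose(t["lr_statistic"], recomputed, atol=1e-6)

    def test_bonferroni_uses_tested_gene_count(self, cohort, normalized):
        res = ls.hurdle_de(normalized, cohort["cells"], "loy", cell_type="mono-c")
        assert np.allclose(res.table["p_adj"],
                           np.minimum(1.0, res.table["p_hurdle"] * res.n_tests))

    def test_planted_effect_detected_at_scale(self, rng):
        # IL1B-like downregulation, log2FC -0.22, large groups
        n = 5000
        base = rng.gamma(1.0, 20.0, size=2 * n)
        mean = np.where(np.r_[np.ones(n, bool), np.zeros(n, bool)],
                        base * 2.0 ** -0.22, base)
        counts = rng.poisson(mean)
        target = np.log1p(counts / 1000.0 * 1e4)
        filler = np.log1p(rng.poisson(2, size=(2 * n, 6)))
        norm = _norm_frame(np.column_stack([target, filler]))
        grp = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = ls.hurdle_de(norm, _cells(norm, grp), "grp")
        row = res.table.set_index("gene").loc["g0"]
        assert row["p_adj"] < 0.05
        assert row["avg_log2fc"] < -0.1


class TestRankSum:
    def test_printed_worked_example(self):
        # 4 vs 4 donor proportions, completely separated: exact two-sided
        # p = 2/70 under full enumeration of the C(8,4) rank assignments
        res = rank_sum_test([0.1, 0.12, 0.11, 0.13], [0.3, 0.28, 0.31, 0.29])
        assert res["method"] == "exact_enumeration"
        assert res["p"] == pytest.approx(0.02857142857, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_independent_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, size=2)
        x = np.round(rng.random(n1), 1)  # coarse rounding induces ties
        y = np.round(rng.random(n2), 1)
        res = rank_sum_test(x, y)
        # independent oracle: enumerate group assignments of the pooled data
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        sums = [ranks[list(c)].sum()
                for c in itertools.combinations(range(n1 + n2), n1)]
        sums = np.asarray(sums)
        p_le = np.mean(sums <= w_obs + 1e-9)
        p_ge = np.mean(sums >= w_obs - 1e-9)
        assert res["p"] == pytest.approx(min(1.0, 2 * min(p_le, p_ge)), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(size=7)
            ours = rank_sum_test(x, y)["p"]
            ref = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        x, y = rng.normal(size=50), rng.normal(0.8, size=50)
        res = rank_sum_test(x, y)
        assert res["method"] == "normal_tie_corrected"
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic",
                                       use_continuity=False).pvalue
        assert res["p"] == pytest.approx(ref, rel=1e-6)

    def test_all_tied_degenerates_to_one(self):
        assert rank_sum_test([1, 1, 1], [1, 1])["p"] == 1.0


class TestProportionPseudobulk:
    def _detection_matrix(self, rng, cells, gene_probs):
        values = {g: (rng.random(len(cells)) < p).astype(int)
                  for g, p in gene_probs.items()}
        return pd.DataFrame(values, index=cells["barcode"])

    def test_identical_proportions_give_p_one(self):
        rng = np.random.default_rng(0)
        donors = [f"d{i}" for i in range(6)]
        cells = pd.DataFrame({
            "barcode": [f"c{i}" for i in range(1200)],
            "donor": np.repeat(donors, 200),
            "loy": np.tile([True] * 100 + [False] * 100, 6),
        })
        det = pd.DataFrame({"g0": np.tile([1] * 30 + [0] * 70, 12)},
                           index=cells["barcode"])
        res = ls.proportion_pseudobulk(det > 0, cells, "loy", min_effect=0.0)
        assert res["p"].iloc[0] == 1.0

    def test_planted_proportion_shift_detected(self):
        rng = np.random.default_rng(1)
        donors = [f"d{i}" for i in range(20)]
        cells = pd.DataFrame({
            "barcode": [f"c{i}" for i in range(20 * 200)],
            "donor": np.repeat(donors, 200),
            "loy": np.tile([True] * 100 + [False] * 100, 20),
        })
        p_gene = np.where(cells["loy"], 0.17, 0.22)  # IL1B-like shift
        det = pd.DataFrame({"IL1B": rng.random(len(cells)) < p_gene},
                           index=cells["barcode"])
        res = ls.proportion_pseudobulk(det, cells, "loy", min_effect=0.0)
        row = res.iloc[0]
        assert row["effect"] == pytest.approx(-0.05, abs=0.03)
        assert row["p"] < 0.01

    def test_requires_min_donors_with_both_strata(self):
        cells = pd.DataFrame({
            "barcode": ["c1", "c2", "c3", "c4"],
            "donor": ["d1", "d1", "d2", "d2"],
            "loy": [True, False, True, False],
        })
        det = pd.DataFrame({"g0": [1, 0, 1, 0]}, index=cells["barcode"])
        with pytest.raises(ValueError, match="donors"):
            ls.proportion_pseudobulk(det, cells, "loy")


class TestExcludeXist:
    def test_no_positive_cells_is_identity(self, rng):
        cohort = sim.simulate_cohort(n_donors=3, n_cells_per_donor=30, seed=40)
        m = cohort["expression"]
        j = list(m.gene_ids).index("XIST")
        m.counts[:, j] = 0
        m.counts.eliminate_zeros()
        kept, n_removed = ls.exclude_xist_cells(m, cohort["cells"])
        assert n_removed == 0
        assert len(kept) == len(cohort["cells"])

    def test_counting(self):
        det = pd.DataFrame({"XIST": [0, 3, 0, 1, 0]},
                           index=[f"c{i}" for i in range(5)])
        cells = pd.DataFrame({"barcode": [f"c{i}" for i in range(5)]})
        kept, n_removed = ls.exclude_xist_cells(det, cells)
        assert n_removed == 2
        assert len(kept) == 3

    def test_absent_feature_is_an_error(self):
        det = pd.DataFrame({"OTHER": [0, 1]}, index=["c0", "c1"])
        cells = pd.DataFrame({"barcode": ["c0", "c1"]})
        with pytest.raises(ValueError, match="XIST"):
            ls.exclude_xist_cells(det, cells)

    def test_escape_effects_survive_xist_exclusion(self, cohort, normalized):
        # planted escape-gene upregulation is still detected after dropping
        # XIST-positive cells (the contamination guard)
        cells = cohort["cells"]
        kept, n_removed = ls.exclude_xist_cells(normalized, cells)
        assert n_removed > 0
        res = ls.hurdle_de(normalized, kept, "loy", min_abs_log2fc=0.0)
        esc = res.table[res.table["gene"] == "KDM6A"]
        assert len(esc) == 1
        assert esc["avg_log2fc"].iloc[0] > 0
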