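"""X-gene classification, escape direction stats, dip statistic and test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

import loyscan as ls
from loyscan.io import annotate_gene_table
from loyscan.xci import DipTestResult


# ---------------------------------------------------------------------------
# brute-force oracle: minimax fit of a unimodal CDF to the empirical CDF,
# as a linear program over piecewise-linear CDFs with knots at the unique
# sorted values and one atom allowed at the mode
# ---------------------------------------------------------------------------
def dip_lp_oracle(x):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    k = len(v)
    cum = np.cumsum(counts) / n
    cuml = cum - counts / n
    best = np.inf
    for m in range(k + 1):  # mode at knot m; m == k: virtual mode above all data
        nv = k + 2
        EPS, G0, GL = 0, 1, k + 1
        A_ub, b_ub = [], []

        def row():
            return np.zeros(nv)

        for i in range(k):
            r = row(); r[G0 + i] = 1; r[EPS] = -1; A_ub.append(r); b_ub.append(cum[i])
            r = row(); r[G0 + i] = -1; r[EPS] = -1; A_ub.append(r); b_ub.append(-cum[i])
            lv = GL if i == m else G0 + i
            r = row(); r[lv] = 1; r[EPS] = -1; A_ub.append(r); b_ub.append(cuml[i])
            r = row(); r[lv] = -1; r[EPS] = -1; A_ub.append(r); b_ub.append(-cuml[i])
        for i in range(1, k):
            hi = GL if i == m else G0 + i
            r = row(); r[G0 + i - 1] = 1; r[hi] = -1; A_ub.append(r); b_ub.append(0)
        if m < k:
            r = row(); r[GL] = 1; r[G0 + m] = -1; A_ub.append(r); b_ub.append(0)

        def left_val(i):
            return GL if i == m else G0 + i

        for i in range(min(m, k - 1) - 1):  # convex below the mode
            x0, x1, x2 = v[i], v[i + 1], v[i + 2]
            r = row()
            r[G0 + i] += -1 / (x1 - x0)
            r[left_val(i + 1)] += 1 / (x1 - x0) + 1 / (x2 - x1)
            r[left_val(i + 2)] += -1 / (x2 - x1)
            A_ub.append(r); b_ub.append(0)
        for i in range(m, k - 2):  # concave above the mode
            x0, x1, x2 = v[i], v[i + 1], v[i + 2]
            r = row()
            r[G0 + i] += 1 / (x1 - x0)
            r[G0 + i + 1] += -1 / (x1 - x0) - 1 / (x2 - x1)
            r[G0 + i + 2] += 1 / (x2 - x1)
            A_ub.append(r); b_ub.append(0)
        c_obj = np.zeros(nv); c_obj[EPS] = 1
        res = linprog(c_obj, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(0, None)] + [(0, 1)] * (k + 1), method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestClassifyXGenes:
    @pytest.fixture()
    def annotation(self):
        rows = [
            ("CD99", "X", 2_691_187, 2_741_309, "escape"),       # PAR1 by locus
            ("SPRY3", "X", 155_772_000, 155_782_000, None),      # PAR2 by locus
            ("KDM6A", "X", 44_873_177, 45_112_602, "escape"),
            ("ATRX", "X", 77_504_878, 77_786_269, "inactive"),
            ("TIMP1", "X", 47_582_291, 47_586_789, "variable"),
            ("NOVEL1", "X", 90_000_000, 90_010_000, None),
            ("IL1B", "2", 112_829_751, 112_836_903, None),
        ]
        return annotate_gene_table(pd.DataFrame(
            rows, columns=["gene", "chromosome", "start", "end", "xci_class"]))

    def test_locus_overrides_curated_class(self, annotation):
        classes = ls.classify_x_genes(annotation)
        assert classes["CD99"] == "PAR"       # curated 'escape' beaten by PAR1 locus
        assert classes["SPRY3"] == "PAR"

    def test_curated_classes_and_default(self, annotation):
        classes = ls.classify_x_genes(annotation)
        assert classes["KDM6A"] == "nonPAR-escape"
        assert classes["ATRX"] == "nonPAR-inactive"
        assert classes["TIMP1"] == "nonPAR-variable"
        assert classes["NOVEL1"] == "nonPAR-unclassified"

    def test_partition_and_autosomes_excluded(self, annotation):
        classes = ls.classify_x_genes(annotation)
        assert "IL1B" not in classes.index
        assert classes.isin(["PAR", "nonPAR-escape", "nonPAR-inactive",
                             "nonPAR-variable", "nonPAR-unclassified"]).all()


class TestEscapeDirectionStats:
    def _de_table(self, genes, lfc, padj):
        return pd.DataFrame({"gene": genes, "avg_log2fc": lfc, "p_adj": padj})

    def test_published_rollup_shape(self):
        # 26 significant escape genes across cell types: 23 up-only,
        # 2 in both directions, 1 down-only
        genes = [f"E{i}" for i in range(26)]
        classes = pd.Series("nonPAR-escape", index=genes)
        # ct1: E0..E24 up, E25 down (all significant)
        up_ct1 = self._de_table(genes, [0.4] * 25 + [-0.4], [0.01] * 26)
        # ct2: E23, E24 flip to significant down; E25 not significant
        lfc2 = [0.4] * 23 + [-0.4, -0.4, -0.4]
        padj2 = [0.01] * 25 + [1.0]
        down_ct2 = self._de_table(genes, lfc2, padj2)
        stats = ls.escape_direction_stats({"ct1": up_ct1, "ct2": down_ct2}, classes)
        roll = stats["rollup"]["nonPAR-escape"]
        assert roll == {"up_only": 23, "both": 2, "down_only": 1,
                        "n_significant": 26}

    def test_counts_sum_to_genes_tested(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(40)]
        classes = pd.Series(["nonPAR-escape"] * 20 + ["nonPAR-inactive"] * 20,
                            index=genes)
        tables = {ct: self._de_table(genes, rng.normal(size=40), rng.random(40))
                  for ct in ["a", "b", "c"]}
        stats = ls.escape_direction_stats(tables, classes)
        s = stats["summary"]
        assert ((s["n_up"] + s["n_down"]) <= s["n_genes_tested"]).all()
        assert (s["pct_up"] + s["pct_down"] <= 100.0 + 1e-9).all()

    def test_planted_escape_upregulation(self):
        genes = [f"E{i}" for i in range(10)] + [f"I{i}" for i in range(10)]
        classes = pd.Series(["nonPAR-escape"] * 10 + ["nonPAR-inactive"] * 10,
                            index=genes)
        tables = {}
        rng = np.random.default_rng(1)
        for ct in ["mono-c", "NK", "Treg", "B-in"]:
            lfc = np.r_[np.full(10, 0.3), rng.normal(0, 0.05, 10)]
            padj = np.r_[np.full(10, 0.001), rng.uniform(0.2, 1, 10)]
            tables[ct] = self._de_table(genes, lfc, padj)
        stats = ls.escape_direction_stats(tables, classes)
        s = stats["summary"]
        esc = s[s["gene_class"] == "nonPAR-escape"]
        assert (esc["pct_up"] > esc["pct_down"]).all()
        assert stats["tests"]["nonPAR-escape"]["p"] < 0.05

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match="2 cell types"):
            ls.escape_direction_stats({"only": pd.DataFrame()}, pd.Series(dtype=object))


class TestDipStatistic:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_lp_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        kind = seed % 3
        if kind == 0:
            x = rng.normal(size=n)
        elif kind == 1:
            x = np.concatenate([rng.normal(0, 0.1, n // 2),
                                rng.normal(5, 0.1, n - n // 2)])
        else:
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        assert ls.dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-8)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=200))
    @settings(max_examples=150, deadline=None)
    def test_bounds_hold_for_any_sample(self, values):
        d = ls.dip_statistic(values)
        n = len(values)
        assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        # the unimodal shape class is closed under increasing affine maps,
        # so the dip is exactly location-scale invariant
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        d0 = ls.dip_statistic(x)
        for a, b in [(2.5, 0.0), (0.01, -7.0), (1e4, 3.0)]:
            assert ls.dip_statistic(a * x + b) == pytest.approx(d0, abs=1e-10)

    def test_equally_spaced_sample_attains_lower_bound(self):
        x = np.arange(1, 101, dtype=float)
        assert ls.dip_statistic(x) == pytest.approx(1 / 200, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ls.dip_statistic([1.0, 2.0, 3.0])


class TestDipTest:
    def test_unimodal_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 40
        for rep in range(reps):
            x = rng.normal(size=300)
            rejections += ls.dip_test(x, n_boot=100, seed=rep).p < 0.05
        assert rejections / reps <= 0.10

    def test_bimodal_mixture_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(10, 1, 250)])
        assert ls.dip_test(x, n_boot=200, seed=0).p < 0.01

    def test_reproducible_with_fixed_seed(self, rng):
        x = rng.normal(size=120)
        a = ls.dip_test(x, n_boot=100, seed=7)
        b = ls.dip_test(x, n_boot=100, seed=7)
        assert a.p == b.p and a.dip_statistic == b.dip_statistic

    def test_degenerate_all_equal_flagged(self):
        res = ls.dip_test(np.full(50, 3.0), n_boot=100, seed=0)
        assert res.p == 1.0 and res.degenerate

    def test_both_subsets_returned(self, rng):
        x = np.r_[np.zeros(200), rng.normal(5, 1, 100)]
        res = ls.dip_test(x, n_boot=100, seed=0, subset="both")
        assert set(res) == {"all", "nonzero"}
        assert res["nonzero"].n == 100
        assert isinstance(res["all"], DipTestResult)


class TestXistContrast:
    def _cells(self, n, cell_type="mono-c", loy_frac=0.5):
        return pd.DataFrame({
            "barcode": [f"c{i}" for i in range(n)],
            "cell_type": cell_type,
            "loy": np.arange(n) < int(n * loy_frac),
        })

    def test_detection_percent_arithmetic(self):
        cells = self._cells(20_000)
        xist = np.zeros(20_000)
        xist[:6] = 1.0          # 6 of 10,000 LOY cells
        xist[10_000:10_002] = 1.0  # 2 of 10,000 non-LOY cells
        mat = pd.DataFrame({"XIST": xist}, index=cells["barcode"])
        res = ls.xist_detection_contrast(mat, cells)
        row = res.iloc[0]
        assert row["pct_loy"] == pytest.approx(0.06)
        assert row["pct_nonloy"] == pytest.approx(0.02)

    def test_zero_everywhere_skips_test(self):
        cells = self._cells(100)
        mat = pd.DataFrame({"XIST": np.zeros(100)}, index=cells["barcode"])
        res = ls.xist_detection_contrast(mat, cells)
        assert np.isnan(res["p"].iloc[0])

    def test_planted_activation_significant_in_affected_type_only(self, rng):
        cells = pd.concat([self._cells(4000, "mono-c"),
                           self._cells(4000, "NK")], ignore_index=True)
        cells["barcode"] = [f"c{i}" for i in range(len(cells))]
        xist = np.zeros(len(cells))
        affected = (cells["cell_type"] == "mono-c") & cells["loy"]
        xist[affected.to_numpy() & (rng.random(len(cells)) < 0.10)] = 1.0
        background = rng.random(len(cells)) < 0.002
        xist[background] = 1.0
        mat = pd.DataFrame({"XIST": xist}, index=cells["barcode"])
        res = ls.xist_detection_contrast(mat, cells).set_index("cell_type")
        assert res.loc["mono-c", "p"] < 0.001
        assert res.loc["NK", "p"] > 0.01

    def test_cell_type_without_loy_cells_omitted(self):
        cells = self._cells(100, loy_frac=0.0)
        mat = pd.DataFrame({"XIST": np.zeros(100)}, index=cells["barcode"])
        assert len(ls.xist_detection_contrast(mat, cells)) == 0
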