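"""Differential expression between LOY and non-LOY cells.

Two complementary procedures:

* :class:`HurdleDE` — a two-part hurdle model for zero-inflated single-cell
  expression.  Per gene, a logistic regression models detection
  (count > 0) and a Gaussian regression models magnitude over expressing
  cells; both include the group indicator and a centered per-cell
  detection-rate covariate.  The hurdle p-value comes from the sum of the
  two likelihood-ratio statistics against a chi-square with the combined
  degrees of freedom.  Bonferroni correction over tested genes.

* :func:`proportion_pseudobulk` — a donor-level sensitivity analysis: the
  per-donor fraction of cells expressing each gene is compared between LOY
  and non-LOY strata with a Wilcoxon rank-sum test, making donors (not
  cells) the statistical units.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

__all__ = [
    "HurdleDE", "hurdle_de", "proportion_pseudobulk", "rank_sum_test",
    "exclude_xist_cells", "avg_log2fc",
]


def _values_frame(normalized) -> pd.DataFrame:
    if isinstance(normalized, pd.DataFrame):
        return normalized
    raise TypeError("normalized expression must be a cells x genes DataFrame")


def avg_log2fc(x1: np.ndarray, x2: np.ndarray) -> float:
    """``log2`` ratio of shifted de-logged group means, the single-cell
    convention for log-normalized data: ``log2((mean(expm1 x1)+1) / (mean(expm1 x2)+1))``."""
    return float(np.log2((np.mean(np.expm1(x1)) + 1.0) / (np.mean(np.expm1(x2)) + 1.0)))


def _logistic_llf(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-9) -> float:
    """Maximized Bernoulli log-likelihood by Newton scoring (small designs)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen runaway steps under (near-)separation
        norm = np.max(np.abs(step))
        if norm > 10:
            step *= 10 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _gaussian_lr(X1: np.ndarray, X0: np.ndarray, y: np.ndarray) -> float:
    """LR statistic ``n * ln(RSS0 / RSS1)`` for nested OLS fits."""
    n = len(y)
    rss = []
    for X in (X1, X0):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(float(r @ r))
    rss1, rss0 = rss
    if rss1 <= 0:
        return np.inf if rss0 > rss1 else 0.0
    return max(0.0, n * math.log(rss0 / rss1))


class HurdleDE:
    """Two-part hurdle differential expression model.

    Parameters
    ----------
    normalized : DataFrame
        Log-normalized expression, cells x genes, index = barcodes.
    cells : DataFrame
        Per-cell annotation with a ``barcode`` column and the grouping
        column.
    group_var : str
        Boolean column of ``cells``; group1 = True, group2 = False.
    cell_type : str, optional
        Restrict to one cell type before fitting.
    min_pct : float
        Minimum detection fraction required in each group (``min_pct_mode
        = "each"``) or in at least one (``"either"``).
    min_abs_log2fc : float
        Minimum |average log2 fold change| for a gene to be tested.
    """

    def __init__(self, normalized: pd.DataFrame, cells: pd.DataFrame, group_var: str,
                 cell_type: str | None = None, min_pct: float = 0.01,
                 min_abs_log2fc: float = 0.1, min_pct_mode: str = "each"):
        if min_pct_mode not in ("each", "either"):
            raise ValueError("min_pct_mode must be 'each' or 'either'")
        normalized = _values_frame(normalized)
        cells = cells.set_index("barcode") if "barcode" in cells.columns else cells
        cells = cells.loc[normalized.index.intersection(cells.index)]
        if cell_type is not None:
            cells = cells[cells["cell_type"] == cell_type]
        cells = cells[cells[group_var].notna()]
        self.values = normalized.loc[cells.index]
        self.group = cells[group_var].astype(bool).to_numpy()
        self.cell_type = cell_type
        self.min_pct = min_pct
        self.min_abs_log2fc = min_abs_log2fc
        self.min_pct_mode = min_pct_mode
        self.n1 = int(self.group.sum())
        self.n2 = int((~self.group).sum())
        self.small_groups = min(self.n1, self.n2) < 20

    def fit(self) -> "HurdleDEResults":
        V = self.values.to_numpy(dtype=float)
        g = self.group
        detect = V > 0
        # centered per-cell detection rate, the standard hurdle nuisance
        # covariate; dropped when degenerate (e.g. single-gene matrices)
        cdr = detect.mean(axis=1)
        cdr = cdr - cdr.mean()
        if np.ptp(cdr) > 1e-12 and V.shape[1] >= 3:
            X1 = np.column_stack([np.ones(len(g)), g.astype(float), cdr])
        else:
            X1 = np.column_stack([np.ones(len(g)), g.astype(float)])
        X0 = np.delete(X1, 1, axis=1)

        rows = []
        for j, gene in enumerate(self.values.columns):
            v, d = V[:, j], detect[:, j]
            pct1 = d[g].mean() if self.n1 else 0.0
            pct2 = d[~g].mean() if self.n2 else 0.0
            pct_ok = (min(pct1, pct2) >= self.min_pct if self.min_pct_mode == "each"
                      else max(pct1, pct2) >= self.min_pct)
            if not pct_ok:
                continue
            lfc = avg_log2fc(v[g], v[~g])
            if abs(lfc) < self.min_abs_log2fc:
                continue

            if d.all() or not d.any():
                lr_d, p_d = 0.0, 1.0
            else:
                lr_d = max(0.0, 2.0 * (_logistic_llf(X1, d.astype(float))
                                       - _logistic_llf(X0, d.astype(float))))
                p_d = float(scipy.stats.chi2.sf(lr_d, 1))
            # continuous part only when both groups have >= 2 expressing cells
            if (d & g).sum() >= 2 and (d & ~g).sum() >= 2:
                lr_c = _gaussian_lr(X1[d], X0[d], v[d])
                p_c = float(scipy.stats.chi2.sf(lr_c, 1))
                df = 2
            else:
                lr_c, p_c, df = 0.0, float("nan"), 1
            p_hurdle = float(scipy.stats.chi2.sf(lr_d + lr_c, df))
            rows.append({
                "gene": gene, "cell_type": self.cell_type, "avg_log2fc": lfc,
                "pct_group1": pct1, "pct_group2": pct2,
                "p_discrete": p_d, "p_continuous": p_c, "lr_statistic": lr_d + lr_c,
                "p_hurdle": p_hurdle, "n1": self.n1, "n2": self.n2,
            })
        table = pd.DataFrame(rows)
        n_tests = len(table)
        if n_tests:
            table["p_adj"] = np.minimum(1.0, table["p_hurdle"] * n_tests)
        return HurdleDEResults(table, n_tests, self.small_groups)


class HurdleDEResults:
    """Per-gene hurdle DE table with Bonferroni-adjusted p-values."""

    def __init__(self, table: pd.DataFrame, n_tests: int, small_groups: bool):
        self.table = table
        self.n_tests = n_tests
        self.small_groups = small_groups

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if not len(self.table):
            return self.table
        return self.table[self.table["p_adj"] < alpha]

    def summary(self) -> str:
        n_sig = len(self.significant())
        lines = [
            "Hurdle differential expression (two-part model)",
            f"  genes tested (Bonferroni n): {self.n_tests}",
            f"  significant at p_adj < 0.05: {n_sig}",
        ]
        if self.small_groups:
            lines.append("  warning: a group has fewer than 20 cells")
        return "\n".join(lines)


def hurdle_de(normalized: pd.DataFrame, cells: pd.DataFrame, group_var: str,
              cell_type: str | None = None, **kwargs) -> HurdleDEResults:
    """Fit :class:`HurdleDE` and return its results."""
    return HurdleDE(normalized, cells, group_var, cell_type=cell_type, **kwargs).fit()


def _midranks(values: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(values, method="average")


def rank_sum_test(x, y, exact_max_n: int = 8) -> dict:
    """Two-sample Wilcoxon rank-sum test with midranks for ties.

    Exact enumeration of all rank assignments when ``min(n1, n2) <=
    exact_max_n``; otherwise the normal approximation with tie-corrected
    variance.  Two-sided p = ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return {"statistic": w, "p": 1.0, "method": "degenerate_all_tied"}
    if min(n1, n2) <= exact_max_n and math.comb(n1 + n2, n1) <= 200_000:
        sums = np.array([sum(c) for c in itertools.combinations(ranks, n1)])
        p_le = np.mean(sums <= w + 1e-9)
        p_ge = np.mean(sums >= w - 1e-9)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return {"statistic": w, "p": float(p), "method": "exact_enumeration"}
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (w - mu) / math.sqrt(var)
    p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
    return {"statistic": w, "p": float(p), "method": "normal_tie_corrected"}


def proportion_pseudobulk(matrix, cells: pd.DataFrame, group_var: str = "loy",
                          cell_type: str | None = None, min_pct: float = 0.01,
                          min_effect: float = 0.1, min_donors: int = 3) -> pd.DataFrame:
    """Donor-level proportion-expressing pseudobulk differential test.

    For each gene, the proportion of cells with count > 0 is computed per
    (donor, group) pseudobulk sample; LOY vs non-LOY donor proportions are
    compared with the Wilcoxon rank-sum test (exact for small samples).
    Only donors contributing cells to both strata enter.  Filters: gene
    detected in >= ``min_pct`` of cells in either group, and absolute
    proportion difference >= ``min_effect``.  Bonferroni over tested genes.
    """
    if isinstance(matrix, pd.DataFrame):
        detect = matrix > 0
    else:
        detect = pd.DataFrame(
            (matrix.counts > 0).toarray() if sp.issparse(matrix.counts) else matrix.counts > 0,
            index=matrix.barcodes, columns=matrix.gene_ids)
    ann = cells.set_index("barcode") if "barcode" in cells.columns else cells
    ann = ann.loc[detect.index.intersection(ann.index)]
    if cell_type is not None:
        ann = ann[ann["cell_type"] == cell_type]
    ann = ann[ann[group_var].notna()]
    detect = detect.loc[ann.index]
    grp = ann[group_var].astype(bool)

    both = (
        ann.assign(_g=grp).groupby("donor")["_g"].agg(["min", "max"])
    )
    donors_both = both[(both["min"] == 0) & (both["max"] == 1)].index
    keep = ann["donor"].isin(donors_both).to_numpy()
    ann, detect, grp = ann[keep], detect[keep], grp[keep]
    n_g1 = len(donors_both)
    if n_g1 < min_donors:
        raise ValueError(f"need >= {min_donors} donors contributing both strata, got {n_g1}")

    props = detect.groupby(
        [ann["donor"].to_numpy(), grp.to_numpy()]).mean()  # (donor, group) x genes
    props.index = props.index.set_names(["donor", "group"])
    p1 = props.xs(True, level="group")
    p2 = props.xs(False, level="group")
    cell_pct1 = detect[grp.to_numpy()].mean(axis=0)
    cell_pct2 = detect[~grp.to_numpy()].mean(axis=0)

    rows = []
    for gene in detect.columns:
        if max(cell_pct1[gene], cell_pct2[gene]) < min_pct:
            continue
        m1, m2 = float(p1[gene].mean()), float(p2[gene].mean())
        effect = m1 - m2
        if abs(effect) < min_effect:
            continue
        test = rank_sum_test(p1[gene].to_numpy(), p2[gene].to_numpy())
        rows.append({
            "gene": gene, "cell_type": cell_type,
            "mean_prop_group1": m1, "mean_prop_group2": m2, "effect": effect,
            "p": test["p"], "method": test["method"], "n_donors": n_g1,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
    out.attrs["n_tests"] = len(out)
    return out


def exclude_xist_cells(matrix, cells: pd.DataFrame, gene: str = "XIST") -> tuple[pd.DataFrame, int]:
    """Drop cells with any XIST counts (guards against female contamination).

    Returns the retained cell annotation and the number of removed cells.
    """
    if isinstance(matrix, pd.DataFrame):
        if gene not in matrix.columns:
            raise ValueError(f"feature {gene!r} absent from expression matrix")
        xist = matrix[gene]
    else:
        if gene not in set(matrix.gene_ids):
            raise ValueError(f"feature {gene!r} absent from expression matrix")
        j = list(matrix.gene_ids).index(gene)
        xist = pd.Series(np.asarray(matrix.counts[:, j].todense()).ravel(),
                         index=matrix.barcodes)
    ann = cells.set_index("barcode") if "barcode" in cells.columns else cells
    positive = xist.reindex(ann.index).fillna(0) > 0
    kept = ann[~positive].reset_index()
    return kept, int(positive.sum())
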