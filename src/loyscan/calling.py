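"""Per-cell LOY calling and donor-level clonality statistics.

A male cell is called LOY only when the summed UMI count over the
male-specific-region (MSY) genes is zero in *both* counting sources; a
single stray MSY read in either source blocks the call.  This rule is
maximally specific: ambient contamination can suppress true calls but can
never create a false positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CellGeneMatrix

EXPANDED_CLONALITY_PCT = 10.0  # LOY in >= 10% of a donor's cells


def _msy_totals(matrix: CellGeneMatrix, msy_genes) -> np.ndarray:
    sub = matrix.subset_genes(msy_genes)
    if sub.n_genes == 0:
        raise ValueError("no MSY genes present in matrix")
    return sub.umi_totals()


def call_loy(matrix_a: CellGeneMatrix, matrix_b: CellGeneMatrix,
             annotation: pd.DataFrame, msy_genes=None) -> pd.DataFrame:
    """Fill per-cell LOY flags from dual-source MSY counts.

    Parameters
    ----------
    matrix_a, matrix_b
        Count matrices from the two counting sources, restricted or
        restrictable to MSY genes.  Must share the barcode universe.
    annotation
        Per-cell table with ``barcode`` and ``sex`` columns.
    msy_genes
        Iterable of MSY gene identifiers; defaults to every gene present
        (for matrices already restricted to the MSY).

    Returns the annotation with ``msy_total_a``, ``msy_total_b``, ``loy``
    (nullable boolean; only male cells are assigned) and
    ``excluded_zero_depth`` columns.
    """
    if set(matrix_a.barcodes) != set(matrix_b.barcodes):
        only_a = set(matrix_a.barcodes) - set(matrix_b.barcodes)
        only_b = set(matrix_b.barcodes) - set(matrix_a.barcodes)
        raise ValueError(
            f"barcode universes differ between sources "
            f"({len(only_a)} only in A, {len(only_b)} only in B)"
        )
    if msy_genes is None:
        msy_genes = list(matrix_a.gene_ids)
    tot_a = pd.Series(_msy_totals(matrix_a, msy_genes), index=matrix_a.barcodes)
    tot_b = pd.Series(_msy_totals(matrix_b, msy_genes), index=matrix_b.barcodes)

    out = annotation.copy()
    bc = out["barcode"]
    missing = set(bc) - set(matrix_a.barcodes)
    if missing:
        raise ValueError(f"{len(missing)} annotated barcodes absent from matrices")
    out["msy_total_a"] = tot_a[bc].to_numpy()
    out["msy_total_b"] = tot_b[bc].to_numpy()

    if "umi_total" in out.columns:
        zero_depth = out["umi_total"].to_numpy() == 0
    else:
        zero_depth = np.zeros(len(out), dtype=bool)
    out["excluded_zero_depth"] = zero_depth

    male = (out["sex"] == "M").to_numpy()
    zero_msy = (out["msy_total_a"].to_numpy() + out["msy_total_b"].to_numpy()) == 0
    loy = pd.array([pd.NA] * len(out), dtype="boolean")
    assignable = male & ~zero_depth
    loy[assignable] = zero_msy[assignable]
    out["loy"] = loy
    return out


def donor_prevalence(cells: pd.DataFrame, by_cell_type: bool = False) -> pd.DataFrame:
    """Per-donor LOY prevalence and expanded-clonality flags.

    Expanded clonality is LOY in >= 10% of the donor's assayed cells (the
    10.0% boundary itself counts as expanded).  Donors with very few cells
    are kept but flagged ``degenerate`` (n < 10).
    """
    use = cells[cells["loy"].notna()].copy()
    use["loy"] = use["loy"].astype(bool)
    keys = ["donor", "cell_type"] if by_cell_type else ["donor"]
    grouped = use.groupby(keys, observed=True)["loy"].agg(n_cells="size", n_loy="sum").reset_index()
    grouped["pct_loy"] = 100.0 * grouped["n_loy"] / grouped["n_cells"]
    grouped["expanded"] = grouped["pct_loy"] >= EXPANDED_CLONALITY_PCT
    grouped["degenerate"] = grouped["n_cells"] < 10
    return grouped


def cohort_prevalence(cells: pd.DataFrame) -> dict:
    """Aggregate LOY prevalence over the whole cohort."""
    use = cells[cells["loy"].notna()]
    n, k = len(use), int(use["loy"].astype(bool).sum())
    return {"n_cells": n, "n_loy": k, "pct_loy": 100.0 * k / n if n else float("nan")}


def prevalence_pct(n_loy: int, n_cells: int, decimals: int | None = None) -> float:
    """Percentage of LOY cells, optionally rounded to printed precision."""
    pct = 100.0 * n_loy / n_cells
    return round(pct, decimals) if decimals is not None else pct


def umi_sensitivity_filter(cells: pd.DataFrame, drop_fraction: float) -> tuple[pd.DataFrame, float]:
    """Drop the lowest ``drop_fraction`` of cells by total UMI count.

    Returns the retained cells and the UMI cutoff actually applied (cells
    with ``umi_total`` <= cutoff are removed; ``drop_fraction = 0`` is the
    identity).
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if drop_fraction == 0:
        return cells.copy(), -np.inf
    cutoff = float(np.quantile(cells["umi_total"].to_numpy(), drop_fraction))
    return cells[cells["umi_total"] > cutoff].copy(), cutoff


def empirical_logit(count: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Smoothed logit ``log(p/(1-p))`` with ``p = (x + 0.5) / (n + 1)``.

    Finite for 0% and 100% observations, which occur for real donors.
    """
    p = (np.asarray(count, dtype=float) + 0.5) / (np.asarray(total, dtype=float) + 1.0)
    return np.log(p / (1.0 - p))


class AgeAssociation:
    """Linear model of donor-level LOY burden on age.

    The per-donor LOY percentage is empirical-logit transformed and
    regressed on age plus sequencing pool and the first ten genotype PCs
    when available.  ``fit()`` returns an :class:`AgeAssociationResults`.

    Parameters
    ----------
    clonality : DataFrame from :func:`donor_prevalence` (donor, n_loy, n_cells).
    donors : per-donor covariate table (donor, age[, pool, pc1..pc10]).
    covariates : include pool/PC adjustment (default True when present).
    """

    def __init__(self, clonality: pd.DataFrame, donors: pd.DataFrame, covariates: bool = True):
        merged = clonality.merge(donors, on="donor", how="inner")
        if merged["age"].nunique() < 3:
            raise ValueError("need at least 3 donors with distinct ages")
        self.data = merged
        self.covariates = covariates

    def _design(self) -> tuple[pd.DataFrame, list[str]]:
        d = self.data
        X = pd.DataFrame({"age": d["age"].astype(float)})
        dropped = []
        if self.covariates:
            if "pool" in d.columns and d["pool"].nunique() > 1:
                X = pd.concat([X, pd.get_dummies(d["pool"], prefix="pool",
                                                 drop_first=True, dtype=float)], axis=1)
            pcs = [c for c in d.columns if c.startswith("pc") and c[2:].isdigit()]
            for c in pcs:
                if d[c].nunique() > 1:
                    X[c] = d[c].astype(float)
                else:
                    dropped.append(c)
        return sm.add_constant(X), dropped

    def fit(self) -> "AgeAssociationResults":
        y = empirical_logit(self.data["n_loy"].to_numpy(), self.data["n_cells"].to_numpy())
        X, dropped = self._design()
        # drop collinear columns (reduced model), flag them
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            keep = ["const", "age"]
            Q = X[keep].to_numpy()
            for c in [c for c in X.columns if c not in keep]:
                cand = np.column_stack([Q, X[c].to_numpy()])
                if np.linalg.matrix_rank(cand) > Q.shape[1]:
                    keep.append(c)
                    Q = cand
                else:
                    dropped.append(c)
            X = X[keep]
        res = sm.OLS(y, X).fit()
        return AgeAssociationResults(res, dropped, len(self.data))


class AgeAssociationResults:
    """Slope of logit LOY burden per year of age, with Wald CI and p."""

    def __init__(self, sm_results, dropped_covariates, n_donors):
        self._res = sm_results
        self.dropped_covariates = dropped_covariates
        self.n_donors = n_donors
        self.slope = float(sm_results.params["age"])
        ci = sm_results.conf_int().loc["age"]
        self.conf_int = (float(ci[0]), float(ci[1]))
        self.pvalue = float(sm_results.pvalues["age"])

    def summary(self) -> str:
        lines = [
            "Donor-level LOY ~ age (empirical-logit linear model)",
            f"  n donors:       {self.n_donors}",
            f"  slope per year: {self.slope:.4f}",
            f"  95% CI:         ({self.conf_int[0]:.4f}, {self.conf_int[1]:.4f})",
            f"  p value:        {self.pvalue:.3g}",
        ]
        if self.dropped_covariates:
            lines.append(f"  dropped (collinear/constant): {self.dropped_covariates}")
        return "\n".join(lines)


def age_association(clonality: pd.DataFrame, donors: pd.DataFrame,
                    covariates: bool = True) -> AgeAssociationResults:
    """Convenience wrapper: fit :class:`AgeAssociation` and return results."""
    return AgeAssociation(clonality, donors, covariates=covariates).fit()


def snp_concordance(clonality: pd.DataFrame, donors: pd.DataFrame,
                    by_cell_type: bool = False) -> pd.DataFrame:
    """Pearson correlation between single-cell and SNP-array clonal fractions.

    One row per cell type (or a single ``all`` row), with Fisher-z 95% CI
    and Benjamini-Hochberg FDR across cell types.
    """
    groups = clonality.groupby("cell_type") if by_cell_type else [("all", clonality)]
    rows = []
    for name, grp in groups:
        merged = grp.merge(donors[["donor", "snp_clonal_fraction"]], on="donor").dropna(
            subset=["snp_clonal_fraction"])
        x = merged["pct_loy"].to_numpy() / 100.0
        y = merged["snp_clonal_fraction"].to_numpy()
        if len(x) < 3:
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in clonal fractions for {name!r}")
        r, p = scipy.stats.pearsonr(x, y)
        with np.errstate(divide="ignore"):
            z = np.arctanh(min(max(r, -1.0), 1.0))
        if len(x) > 3 and np.isfinite(z):
            se = 1.0 / np.sqrt(len(x) - 3)
            lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
        else:
            lo, hi = float("nan"), float("nan")
        rows.append({"cell_type": name, "n": len(x), "r": r,
                     "ci_low": lo, "ci_high": hi, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def mca_loy_independence(donor_table: pd.DataFrame, loy_col: str = "loy_flag",
                         mca_col: str = "mca_flag") -> dict:
    """Chi-square test of independence between donor mCA and LOY flags.

    Computed without Yates continuity correction (stated in the output);
    falls back to Fisher's exact test when a margin is empty.
    """
    d = donor_table[[loy_col, mca_col]].dropna().astype(bool)
    table = pd.crosstab(d[loy_col], d[mca_col]).reindex(
        index=[False, True], columns=[False, True], fill_value=0).to_numpy()
    margins_ok = table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0
    if not margins_ok:
        _, p = scipy.stats.fisher_exact(table)
        return {"statistic": float("nan"), "p": float(p), "table": table,
                "method": "fisher_exact_fallback", "continuity_correction": False}
    stat, p, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    return {"statistic": float(stat), "p": float(p), "table": table,
            "method": "chi2", "continuity_correction": False}
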