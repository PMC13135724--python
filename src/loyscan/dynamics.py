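"""Dynamic (pseudotime-dependent) effects of LOY on gene expression.

For each gene, two nested mixed models with a donor random intercept are
compared by likelihood ratio:

* basic:      expr ~ LOY + quantile (+ quantile^2) + age + 10 PCs + (1|donor)
* augmented:  basic + LOY x quantile (+ LOY x quantile^2)

The quantile enters as a single numeric slope (1..6), so the linear form
reports one interaction estimate per gene.  Models are fitted by maximum
likelihood so the nested comparison is a standard LRT; on non-convergence
the fit falls back to donor fixed effects and is flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["InteractionModel", "InteractionResult", "interaction_model", "run_dynamics",
           "quantile_expression_filter"]


def quantile_expression_filter(values: np.ndarray, quantiles: np.ndarray,
                               min_pct: float = 0.01, min_quantiles: int = 3,
                               n_quantiles: int = 6) -> tuple[bool, int]:
    """A gene is testable when detected in >= ``min_pct`` of cells in at
    least ``min_quantiles`` of the ``n_quantiles`` pseudotime bins."""
    detected = np.asarray(values) > 0
    n_expressed = 0
    for q in range(1, n_quantiles + 1):
        m = quantiles == q
        if m.any() and detected[m].mean() >= min_pct:
            n_expressed += 1
    return n_expressed >= min_quantiles, n_expressed


class InteractionModel:
    """Nested mixed-model LRT for one gene's LOY x pseudotime interaction.

    Parameters
    ----------
    values : per-cell expression (log-normalized), aligned with ``cells``.
    cells : per-cell table with ``loy``, ``quantile``, ``donor``.
    donors : per-donor covariates (age, pc1..pc10).
    form : ``"linear"`` or ``"quadratic"``.
    """

    def __init__(self, values: np.ndarray, cells: pd.DataFrame, donors: pd.DataFrame,
                 form: str = "linear", gene: str = "", lineage: str = "",
                 min_pct: float = 0.01, min_quantiles: int = 3):
        if form not in ("linear", "quadratic"):
            raise ValueError("form must be 'linear' or 'quadratic'")
        self.form = form
        self.gene = gene
        self.lineage = lineage
        data = cells[["loy", "quantile", "donor"]].copy()
        data["y"] = np.asarray(values, dtype=float)
        data = data[data["loy"].notna() & data["quantile"].notna()]
        self.data = data.merge(donors, on="donor", how="left")
        ok, n_expr = quantile_expression_filter(
            self.data["y"].to_numpy(), self.data["quantile"].to_numpy(),
            min_pct=min_pct, min_quantiles=min_quantiles)
        self.testable = ok
        self.n_quantiles_expressed = n_expr

    def _designs(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        d = self.data
        loy = d["loy"].astype(float).to_numpy()
        q = d["quantile"].astype(float).to_numpy()
        cols = {"const": np.ones(len(d)), "loy": loy, "quantile": q}
        if self.form == "quadratic":
            cols["quantile2"] = q * q
        if "age" in d.columns:
            cols["age"] = d["age"].astype(float).to_numpy()
        for c in [f"pc{j}" for j in range(1, 11)]:
            if c in d.columns:
                cols[c] = d[c].astype(float).to_numpy()
        basic = np.column_stack(list(cols.values()))
        aug_cols = dict(cols)
        aug_cols["loy:quantile"] = loy * q
        if self.form == "quadratic":
            aug_cols["loy:quantile2"] = loy * q * q
        augmented = np.column_stack(list(aug_cols.values()))
        return basic, augmented, list(aug_cols.keys())

    @staticmethod
    def _fit_mixed(y, X, groups) -> tuple[float, np.ndarray, bool]:
        last_err = None
        for method in ("powell", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(y, X, groups=groups)
                    res = model.fit(reml=False, method=method, maxiter=300)
                if res.converged:
                    return float(res.llf), np.asarray(res.fe_params), np.asarray(res.bse_fe)
                last_err = RuntimeError("mixed model did not converge")
            except Exception as err:  # singular Hessian etc.
                last_err = err
        raise last_err

    @staticmethod
    def _fit_fixed(y, X, groups) -> tuple[float, np.ndarray, np.ndarray]:
        dummies = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float).to_numpy()
        Xf = np.column_stack([X, dummies])
        res = sm.OLS(y, Xf).fit()
        k = X.shape[1]
        return float(res.llf), np.asarray(res.params[:k]), np.asarray(res.bse[:k])

    def fit(self) -> "InteractionResult":
        if not self.testable:
            return InteractionResult(
                gene=self.gene, lineage=self.lineage, form=self.form,
                interaction_estimate=float("nan"), p_lrt=float("nan"),
                n_quantiles_expressed=self.n_quantiles_expressed,
                tested=False, reason="expressed_in_fewer_than_3_quantiles")
        y = self.data["y"].to_numpy(dtype=float)
        groups = self.data["donor"].to_numpy()
        basic, augmented, names = self._designs()
        fallback = False
        try:
            llf0, _, _ = self._fit_mixed(y, basic, groups)
            llf1, params, bse = self._fit_mixed(y, augmented, groups)
        except Exception:
            llf0, _, _ = self._fit_fixed(y, basic, groups)
            llf1, params, bse = self._fit_fixed(y, augmented, groups)
            fallback = True
        df = 2 if self.form == "quadratic" else 1
        lrt = max(0.0, 2.0 * (llf1 - llf0))
        p = float(scipy.stats.chi2.sf(lrt, df))
        i = names.index("loy:quantile")
        return InteractionResult(
            gene=self.gene, lineage=self.lineage, form=self.form,
            interaction_estimate=float(params[i]), p_lrt=p, lrt_statistic=lrt,
            interaction_se=float(bse[i]),
            n_quantiles_expressed=self.n_quantiles_expressed,
            tested=True, fixed_effect_fallback=fallback)


class InteractionResult:
    """LRT result for one (gene, form): interaction estimate and p-value."""

    def __init__(self, gene, lineage, form, interaction_estimate, p_lrt,
                 n_quantiles_expressed, tested, lrt_statistic=float("nan"),
                 interaction_se=float("nan"), fixed_effect_fallback=False, reason=""):
        self.gene = gene
        self.lineage = lineage
        self.form = form
        self.interaction_estimate = interaction_estimate
        self.interaction_se = interaction_se
        self.p_lrt = p_lrt
        self.lrt_statistic = lrt_statistic
        self.n_quantiles_expressed = n_quantiles_expressed
        self.tested = tested
        self.fixed_effect_fallback = fixed_effect_fallback
        self.reason = reason
        z = 1.959963984540054
        if np.isfinite(interaction_se):
            self.conf_int = (interaction_estimate - z * interaction_se,
                             interaction_estimate + z * interaction_se)
        else:
            self.conf_int = (float("nan"), float("nan"))

    def to_row(self) -> dict:
        return {
            "gene": self.gene, "lineage": self.lineage, "form": self.form,
            "interaction_estimate": self.interaction_estimate,
            "lrt_statistic": self.lrt_statistic, "p_lrt": self.p_lrt,
            "n_quantiles_expressed": self.n_quantiles_expressed,
            "tested": self.tested, "fallback": self.fixed_effect_fallback,
            "reason": self.reason,
        }

    def summary(self) -> str:
        if not self.tested:
            return f"{self.gene} [{self.form}]: not tested ({self.reason})"
        return (f"{self.gene} [{self.form}]: interaction = "
                f"{self.interaction_estimate:.4f}, LRT p = {self.p_lrt:.3g}"
                + ("  [fixed-effect fallback]" if self.fixed_effect_fallback else ""))


def interaction_model(values, cells, donors, form="linear", **kwargs) -> InteractionResult:
    """Fit :class:`InteractionModel` and return its result."""
    return InteractionModel(values, cells, donors, form=form, **kwargs).fit()


def run_dynamics(normalized: pd.DataFrame, cells: pd.DataFrame, donors: pd.DataFrame,
                 genes=None, lineage: str = "", forms=("linear", "quadratic"),
                 ) -> pd.DataFrame:
    """Interaction LRTs for a panel of genes, both model forms.

    Bonferroni correction over the tests actually run; the family size is
    recorded in ``table.attrs["n_tests"]``.
    """
    genes = list(genes) if genes is not None else list(normalized.columns)
    if not genes:
        raise ValueError("empty gene list")
    ann = cells.set_index("barcode") if "barcode" in cells.columns else cells
    ann = ann.loc[normalized.index]
    rows = []
    for gene in genes:
        for form in forms:
            res = InteractionModel(
                normalized[gene].to_numpy(), ann.reset_index(), donors,
                form=form, gene=gene, lineage=lineage).fit()
            rows.append(res.to_row())
    table = pd.DataFrame(rows)
    tested = table["tested"].to_numpy()
    n_tests = int(tested.sum())
    table["p_adj"] = np.nan
    table.loc[tested, "p_adj"] = np.minimum(1.0, table.loc[tested, "p_lrt"] * n_tests)
    table.attrs["n_tests"] = n_tests
    return table
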