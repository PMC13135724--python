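"""Pseudotime trajectories and LOY-position logistic models.

Pseudotime is the arclength position of each cell on a principal curve
fitted through a low-dimensional embedding (the embedding itself is
pluggable: supply one, or use any diffusion/manifold method).  Cells are
stratified into six near-equal quantile bins, and logistic regression
relates LOY status to a cell's position — either a binary start/end
subtype indicator or the quantile treated as a single numeric slope, so
each trajectory yields one odds ratio per quantile step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fit_pseudotime", "bin_quantiles", "LoyPositionModel", "LoyPositionResults",
    "loy_position_model", "age_stratified_models", "adjust_family",
]


def _project_to_polyline(points: np.ndarray, curve: np.ndarray,
                         arclen: np.ndarray) -> np.ndarray:
    """Arclength position of each point's nearest projection onto a polyline."""
    a = curve[:-1]                     # segment starts, (s, d)
    d = curve[1:] - a                  # segment vectors
    seg_len2 = np.maximum((d ** 2).sum(axis=1), 1e-30)
    # t[i, s]: projection parameter of point i on segment s
    t = np.clip(((points[:, None, :] - a[None]) * d[None]).sum(-1) / seg_len2, 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    best = dist2.argmin(axis=1)
    rows = np.arange(len(points))
    return arclen[best] + t[rows, best] * np.sqrt(seg_len2[best])


def fit_pseudotime(embedding: np.ndarray, cluster_labels, start_label, end_label,
                   n_iter: int = 10, n_grid: int = 50, smooth_frac: float = 0.3,
                   ) -> np.ndarray:
    """Principal-curve pseudotime on a low-dimensional embedding.

    Iteratively alternates between smoothing each embedding coordinate
    against the current arclength ordering (lowess) and re-projecting cells
    onto the smoothed polyline.  The curve is initialized on the first
    principal component, oriented so the start cluster has the lower mean
    pseudotime, and scaled to [0, 1].
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be 2-D (cells x dims)")
    if len(X) < 10:
        raise ValueError("need at least 10 cells to fit a trajectory")
    labels = np.asarray(cluster_labels)
    if start_label == end_label:
        raise ValueError("start and end labels must differ")
    for lab in (start_label, end_label):
        if lab not in labels:
            raise ValueError(f"cluster label {lab!r} not present")

    from statsmodels.nonparametric.smoothers_lowess import lowess

    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    t = Xc @ Vt[0]
    for _ in range(n_iter):
        order = np.argsort(t, kind="stable")
        grid_idx = np.linspace(0, len(t) - 1, min(n_grid, len(t))).astype(int)
        ts = t[order]
        curve = np.column_stack([
            lowess(Xc[order, j], ts, frac=smooth_frac, return_sorted=True)[grid_idx, 1]
            for j in range(X.shape[1])
        ])
        # drop duplicate consecutive grid points (flat stretches)
        keep = np.r_[True, np.linalg.norm(np.diff(curve, axis=0), axis=1) > 1e-12]
        curve = curve[keep]
        if len(curve) < 2:
            break
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arclen = np.r_[0.0, np.cumsum(seg)]
        t_new = _project_to_polyline(Xc, curve, arclen)
        if np.allclose(t_new, t, atol=1e-10):
            t = t_new
            break
        t = t_new

    if np.mean(t[labels == start_label]) > np.mean(t[labels == end_label]):
        t = -t
    rng_span = t.max() - t.min()
    return (t - t.min()) / rng_span if rng_span > 0 else np.zeros_like(t)


def bin_quantiles(pseudotime: np.ndarray, k: int = 6, barcodes=None) -> np.ndarray:
    """Split cells into ``k`` near-equal quantile bins along pseudotime.

    Labels run 1..k and are non-decreasing in pseudotime.  Ties at bin
    boundaries are broken stably by (pseudotime, barcode) lexicographic
    order, making equal-count bins well defined.
    """
    pt = np.asarray(pseudotime, dtype=float)
    n = len(pt)
    if n < k:
        raise ValueError(f"cannot split {n} cells into {k} quantiles")
    if barcodes is None:
        barcodes = np.arange(n)
    order = np.lexsort((np.asarray(barcodes), pt))
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * k // n + 1
    return labels


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Penalized (Jeffreys-prior) logistic regression, finite under separation.

    Newton scoring on the Firth-adjusted score ``X'(y - p + h (1/2 - p))``
    where ``h`` is the leverage of the weighted hat matrix.  Returns
    (coefficients, standard errors from the penalized information).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        XW = X * w[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        nrm = np.max(np.abs(step))
        if nrm > 5:
            step *= 5 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-10)
    se = np.sqrt(np.diag(np.linalg.inv((X * w[:, None]).T @ X)))
    return beta, se


class LoyPositionModel:
    """Logistic regression of per-cell LOY status on trajectory position.

    Parameters
    ----------
    cells : per-cell table with ``loy``, ``donor`` and the predictor column.
    donors : per-donor covariates (age, pool, pc1..pc10, rs2887399_dosage).
    predictor : ``"quantile"`` (numeric 1..k slope; OR per quantile step) or
        ``"subtype"`` (binary end-vs-start indicator from ``subtype_pair``).
    variant : ``"univariate"``, ``"multivariate"`` (adds age + pool + 10
        PCs) or ``"multivariate+genotype"`` (additionally rs2887399 dosage,
        additive-coded).
    lineage : label carried into the results row.
    """

    _VARIANTS = ("univariate", "multivariate", "multivariate+genotype")

    def __init__(self, cells: pd.DataFrame, donors: pd.DataFrame,
                 predictor: str = "quantile", variant: str = "multivariate",
                 subtype_pair: tuple[str, str] | None = None, lineage: str = ""):
        if variant not in self._VARIANTS:
            raise ValueError(f"variant must be one of {self._VARIANTS}")
        data = cells[cells["loy"].notna()].copy()
        data["loy"] = data["loy"].astype(bool)
        if predictor == "quantile":
            data = data[data["quantile"].notna()]
            data["_x"] = data["quantile"].astype(float)
        elif predictor == "subtype":
            if subtype_pair is None:
                raise ValueError("subtype predictor requires subtype_pair=(start, end)")
            start, end = subtype_pair
            data = data[data["cell_type"].isin([start, end])]
            data["_x"] = (data["cell_type"] == end).astype(float)
        else:
            raise ValueError("predictor must be 'quantile' or 'subtype'")
        self.data = data.merge(donors, on="donor", how="left", suffixes=("", "_donor"))
        self.predictor = predictor
        self.variant = variant
        self.lineage = lineage

    def _design(self) -> pd.DataFrame:
        d = self.data
        X = pd.DataFrame({"position": d["_x"].to_numpy()}, index=d.index)
        if self.variant != "univariate":
            X["age"] = d["age"].astype(float)
            if "pool" in d.columns and d["pool"].nunique() > 1:
                X = pd.concat([X, pd.get_dummies(d["pool"], prefix="pool",
                                                 drop_first=True, dtype=float)], axis=1)
            for c in [f"pc{j}" for j in range(1, 11)]:
                if c in d.columns:
                    X[c] = d[c].astype(float)
        if self.variant == "multivariate+genotype":
            X["rs2887399_dosage"] = d["rs2887399_dosage"].astype(float)
        return sm.add_constant(X)

    def fit(self) -> "LoyPositionResults":
        y = self.data["loy"].to_numpy(dtype=float)
        X = self._design()
        flagged = False
        try:
            with np.errstate(all="ignore"):
                # donor-clustered covariance: cells are nested in donors, and
                # unmodeled donor heterogeneity would otherwise shrink the SEs
                groups = pd.factorize(self.data["donor"])[0]
                res = sm.Logit(y, X.astype(float)).fit(
                    disp=False, maxiter=200, cov_type="cluster",
                    cov_kwds={"groups": groups})
            beta = res.params["position"]
            se = res.bse["position"]
            converged = res.mle_retvals.get("converged", True)
            if not converged or not np.isfinite(se) or se > 50:
                raise ValueError("separation suspected")
        except Exception:
            # penalized-likelihood fallback under (quasi-)separation
            b, s = _firth_logit(X.to_numpy(dtype=float), y)
            pos = list(X.columns).index("position")
            beta, se = b[pos], s[pos]
            flagged = True
        return LoyPositionResults(
            log_or=float(beta), se=float(se), n_cells=len(y),
            predictor=self.predictor, variant=self.variant, lineage=self.lineage,
            penalized=flagged,
        )


class LoyPositionResults:
    """Odds ratio (per quantile step or end-vs-start) with Wald CI and p."""

    def __init__(self, log_or, se, n_cells, predictor, variant, lineage,
                 penalized=False, stratum="all"):
        self.log_or = log_or
        self.se = se
        self.n_cells = n_cells
        self.predictor = predictor
        self.variant = variant
        self.lineage = lineage
        self.penalized = penalized
        self.stratum = stratum
        self.or_estimate = float(np.exp(log_or))
        z = 1.959963984540054
        self.ci_low = float(np.exp(log_or - z * se))
        self.ci_high = float(np.exp(log_or + z * se))
        self.pvalue = float(2 * scipy.stats.norm.sf(abs(log_or / se))) if se > 0 else float("nan")

    def to_row(self) -> dict:
        return {
            "lineage": self.lineage, "predictor": self.predictor,
            "model_variant": self.variant, "stratum": self.stratum,
            "or_estimate": self.or_estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.pvalue, "n_cells": self.n_cells,
            "penalized": self.penalized,
        }

    def summary(self) -> str:
        return (
            f"LOY ~ {self.predictor} [{self.variant}, {self.lineage or 'unnamed'}"
            f", stratum={self.stratum}]\n"
            f"  OR = {self.or_estimate:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})"
            f", p = {self.pvalue:.3g}, n = {self.n_cells}"
            + ("  [penalized fit]" if self.penalized else "")
        )


def loy_position_model(cells, donors, predictor="quantile", variant="multivariate",
                       subtype_pair=None, lineage="") -> LoyPositionResults:
    """Fit :class:`LoyPositionModel` and return its results."""
    return LoyPositionModel(cells, donors, predictor=predictor, variant=variant,
                            subtype_pair=subtype_pair, lineage=lineage).fit()


def age_stratified_models(cells: pd.DataFrame, donors: pd.DataFrame,
                          median_age: float | None = None, **model_kwargs,
                          ) -> list[LoyPositionResults]:
    """Refit the LOY-position model within donor age strata.

    The split is the median age computed over *donors* (not cells) unless
    supplied.  Returns results for the below-median and at-or-above-median
    strata, labeled accordingly; a stratum with no LOY cells is flagged by
    the penalized fallback rather than dropped.
    """
    if median_age is None:
        median_age = float(donors["age"].median())
    out = []
    for name, mask in [("age<median", donors["age"] < median_age),
                       ("age>=median", donors["age"] >= median_age)]:
        sub_donors = donors[mask]
        if len(sub_donors) == 0:
            raise ValueError(f"stratum {name!r} is empty")
        sub_cells = cells[cells["donor"].isin(sub_donors["donor"])]
        res = LoyPositionModel(sub_cells, sub_donors, **model_kwargs).fit()
        res.stratum = name
        out.append(res)
    return out


def adjust_family(results: list[LoyPositionResults]) -> pd.DataFrame:
    """BH-FDR adjustment across a family of trajectory model results."""
    table = pd.DataFrame([r.to_row() for r in results])
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
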