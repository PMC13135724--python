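"""X-inactivation analyses: gene classification, escape-gene direction
statistics, XIST detection contrasts and Hartigan's dip test.

X genes are bucketed by locus (pseudoautosomal PAR1/PAR2 by coordinates,
which overrides any curated class) and, in the non-PAR region, by a curated
inactivation degree: escape, inactive, variable, else unclassified.  The
direction summary asks, per cell type, what share of each bucket's tested
genes is significantly up- vs down-regulated in LOY cells.

The dip statistic measures the maximal distance between the empirical CDF
and the closest unimodal CDF, computed with the greatest-convex-minorant /
least-concave-majorant algorithm on the sorted sample; significance comes
from a uniform-null bootstrap (the classical calibration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import rank_sum_test

__all__ = [
    "classify_x_genes", "escape_direction_stats", "dip_statistic", "dip_test",
    "DipTestResult", "xist_detection_contrast",
]

X_CLASS_ORDER = ["PAR", "nonPAR-escape", "nonPAR-inactive", "nonPAR-variable",
                 "nonPAR-unclassified"]


def classify_x_genes(annotation: pd.DataFrame) -> pd.Series:
    """Assign each X gene exactly one class.

    PAR membership (from coordinates) overrides the curated XCI class —
    the locus fact beats the tissue-derived label; non-PAR genes take their
    curated class, defaulting to unclassified.
    """
    x = annotation[annotation["chromosome"].astype(str).isin(["X", "chrX"])]
    out = {}
    for _, row in x.iterrows():
        if row.get("par_region") in ("PAR1", "PAR2"):
            out[row["gene"]] = "PAR"
        else:
            xci = row.get("xci_class") or "unclassified"
            out[row["gene"]] = f"nonPAR-{xci}"
    return pd.Series(out, name="x_class")


def escape_direction_stats(de_tables: dict[str, pd.DataFrame], classes: pd.Series,
                           alpha: float = 0.05) -> dict:
    """Direction summary of X-gene differential expression across cell types.

    Parameters
    ----------
    de_tables : mapping cell_type -> DE table (gene, avg_log2fc, p_adj).
    classes : gene -> class from :func:`classify_x_genes`.

    Returns a dict with:

    * ``summary`` — per (cell type, class): n tested, % significantly up,
      % significantly down (p_adj < alpha split by log2FC sign);
    * ``tests`` — per class, a Wilcoxon rank-sum comparison of the pct_up
      vs pct_down vectors across cell types (the headline comparison runs
      on PAR / escape / inactive);
    * ``rollup`` — per class, counts of genes up-only / both / down-only
      across cell types.
    """
    if len(de_tables) < 2:
        raise ValueError("need DE tables for at least 2 cell types")
    rows = []
    gene_dir: dict[str, dict[str, set]] = {}
    for ct, table in de_tables.items():
        t = table[table["gene"].isin(classes.index)].copy()
        t["x_class"] = classes[t["gene"]].to_numpy()
        for cls, grp in t.groupby("x_class"):
            sig = grp["p_adj"] < alpha
            up = sig & (grp["avg_log2fc"] > 0)
            down = sig & (grp["avg_log2fc"] < 0)
            rows.append({
                "cell_type": ct, "gene_class": cls, "n_genes_tested": len(grp),
                "n_up": int(up.sum()), "n_down": int(down.sum()),
                "pct_up": 100.0 * up.mean(), "pct_down": 100.0 * down.mean(),
            })
            d = gene_dir.setdefault(cls, {})
            for gene in grp.loc[up, "gene"]:
                d.setdefault(gene, set()).add("up")
            for gene in grp.loc[down, "gene"]:
                d.setdefault(gene, set()).add("down")
    summary = pd.DataFrame(rows)

    tests = {}
    for cls, grp in summary.groupby("gene_class"):
        if len(grp) >= 2:
            res = rank_sum_test(grp["pct_up"].to_numpy(), grp["pct_down"].to_numpy())
            tests[cls] = {"p": res["p"], "statistic": res["statistic"],
                          "mean_pct_up": float(grp["pct_up"].mean()),
                          "mean_pct_down": float(grp["pct_down"].mean())}
    rollup = {}
    for cls, d in gene_dir.items():
        up_only = sum(1 for s in d.values() if s == {"up"})
        down_only = sum(1 for s in d.values() if s == {"down"})
        both = sum(1 for s in d.values() if s == {"up", "down"})
        rollup[cls] = {"up_only": up_only, "both": both, "down_only": down_only,
                       "n_significant": len(d)}
    return {"summary": summary, "tests": tests, "rollup": rollup}


def dip_statistic(values) -> float:
    """Hartigan's dip: max distance from the empirical CDF to the closest
    unimodal CDF.

    Computed with the classical greatest-convex-minorant / least-concave-
    majorant algorithm on the sorted sample: iteratively shrink to the
    modal interval where the two envelopes of the empirical CDF disagree
    most, accumulating the largest deviation of the CDF from either fit
    outside it.  The statistic lies in ``[1/(2n), 1/4]`` and, being
    rank-based, is invariant to strictly monotone transforms of the data.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if x.ndim != 1 or n < 4:
        raise ValueError("need at least 4 one-dimensional values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # x padded to 1-based indexing to mirror the published algorithm
    x = np.concatenate([[np.nan], x])
    N = n
    low, high = 1, N
    dip = 1.0  # in count units; final statistic = dip / (2N) >= 1/(2N)

    # mn[j]: previous touch point of the greatest convex minorant
    mn = np.zeros(N + 1, dtype=int)
    mn[1] = 1
    for j in range(2, N + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[k]: next touch point of the least concave majorant
    mj = np.zeros(N + 1, dtype=int)
    mj[N] = N
    for k in range(N - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == N or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    while True:
        # change points of the GCM from high to low, and the LCM from low to high
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm) - 1
        ig = l_gcm
        ix = l_gcm - 1
        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm) - 1
        ih = l_lcm
        iv = 2

        # largest distance between the envelopes inside [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # largest deviation of the CDF from the convex minorant fit
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            j_, jb = gcm[j], gcm[j + 1]
            if j_ - jb > 1 and x[j_] != x[jb]:
                C = (j_ - jb) / (x[j_] - x[jb])
                for jj in range(jb, j_ + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # largest deviation from the concave majorant fit
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            j_, jb = lcm[j], lcm[j + 1]
            if jb - j_ > 1 and x[jb] != x[j_]:
                C = (jb - j_) / (x[jb] - x[j_])
                for jj in range(j_, jb + 1):
                    t = (x[jj] - x[j_]) * C - (jj - j_ - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return float(dip / (2.0 * N))


class DipTestResult:
    """Dip statistic with a uniform-null bootstrap p-value."""

    def __init__(self, dip: float, p: float, n: int, subset: str,
                 n_boot: int, degenerate: bool = False):
        self.dip_statistic = dip
        self.p = p
        self.n = n
        self.subset = subset
        self.n_boot = n_boot
        self.degenerate = degenerate

    def __repr__(self):
        flag = ", degenerate" if self.degenerate else ""
        return (f"DipTestResult(dip={self.dip_statistic:.4f}, p={self.p:.4f}, "
                f"n={self.n}, subset={self.subset!r}{flag})")


def dip_test(values, n_boot: int = 200, seed: int = 0, subset: str = "all",
             ) -> DipTestResult | dict[str, DipTestResult]:
    """Test unimodality with the dip statistic and a uniform-null bootstrap.

    ``p`` is the fraction of ``n_boot`` uniform(min, max) reference samples
    of the same size whose dip reaches the observed one.  ``subset`` may be
    ``"all"``, ``"nonzero"`` (cells with nonzero expression — the standard
    guard against the zero inflation of single-cell data) or ``"both"``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if subset == "both":
        return {
            "all": dip_test(values, n_boot, seed, "all"),
            "nonzero": dip_test(values, n_boot, seed, "nonzero"),
        }
    x = np.asarray(values, dtype=float)
    if subset == "nonzero":
        x = x[x != 0]
    elif subset != "all":
        raise ValueError("subset must be 'all', 'nonzero' or 'both'")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 values in subset {subset!r}, got {n}")
    if np.all(x == x[0]):
        return DipTestResult(1.0 / (2 * n), 1.0, n, subset, n_boot, degenerate=True)
    obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    lo, hi = x.min(), x.max()
    boot = np.array([
        dip_statistic(rng.uniform(lo, hi, size=n)) for _ in range(n_boot)
    ])
    p = float(np.mean(boot >= obs))
    return DipTestResult(obs, p, n, subset, n_boot)


def xist_detection_contrast(matrix, cells: pd.DataFrame, gene: str = "XIST",
                            ) -> pd.DataFrame:
    """XIST detection percentage in LOY vs non-LOY cells, per cell type.

    Uses a chi-square two-proportion test (without continuity correction)
    per cell type; cell types with zero LOY cells are omitted, and the test
    is skipped (p = NaN) when the gene is detected in neither group.
    """
    if isinstance(matrix, pd.DataFrame):
        if gene not in matrix.columns:
            raise ValueError(f"feature {gene!r} absent")
        det = pd.Series(matrix[gene].to_numpy() > 0, index=matrix.index)
    else:
        if gene not in set(matrix.gene_ids):
            raise ValueError(f"feature {gene!r} absent")
        j = list(matrix.gene_ids).index(gene)
        det = pd.Series(np.asarray(matrix.counts[:, j].todense()).ravel() > 0,
                        index=matrix.barcodes)
    ann = cells.set_index("barcode") if "barcode" in cells.columns else cells
    ann = ann[ann["loy"].notna()]
    det = det.reindex(ann.index).fillna(False)

    rows = []
    for ct, grp in ann.groupby("cell_type"):
        loy = grp["loy"].astype(bool)
        n1, n2 = int(loy.sum()), int((~loy).sum())
        if n1 == 0 or n2 == 0:
            continue
        k1 = int(det[grp.index][loy.to_numpy()].sum())
        k2 = int(det[grp.index][~loy.to_numpy()].sum())
        if k1 + k2 == 0:
            p = float("nan")
        else:
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            _, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        rows.append({
            "cell_type": ct, "n_loy": n1, "n_nonloy": n2,
            "k_loy": k1, "k_nonloy": k2,
            "pct_loy": 100.0 * k1 / n1, "pct_nonloy": 100.0 * k2 / n2,
            "p": p,
        })
    return pd.DataFrame(rows)
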