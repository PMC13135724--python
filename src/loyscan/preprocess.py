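"""Quality control, normalization and cluster validation.

QC metrics (total UMIs, genes detected, mitochondrial fraction) are mapped
to normal scores by their percentile rank, ``Z = Phi^-1((rank - 0.5) / n)``
with midranks for ties; cells with any metric below -3 Z, or a
mitochondrial Z of +2 or more, are removed.  Expression is log-normalized
per cell with a scale factor of 10,000, variable genes are ranked by a
mean-binned normalized dispersion, and the scaled (covariate-adjusted,
clipped) HVG matrix feeds a PCA.  Community detection on the PC graph is a
pluggable contract — any deterministic labeling is accepted — while the
bespoke logic is marker-based validation of the resulting clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .diffexpr import avg_log2fc
from .io import CellGeneMatrix


def rank_normal_scores(values: np.ndarray) -> np.ndarray:
    """Percentile-to-normal mapping ``Z = Phi^-1((rank - 0.5) / n)``.

    Ties share midranks, so a constant vector maps to all-zero scores.
    """
    values = np.asarray(values, dtype=float)
    ranks = scipy.stats.rankdata(values, method="average")
    return scipy.stats.norm.ppf((ranks - 0.5) / len(values))


def qc_metrics(matrix: CellGeneMatrix, gene_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell QC metrics: umi_total, n_genes_detected, mito_fraction."""
    counts = matrix.counts
    umi = matrix.umi_totals()
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    if gene_annotation is not None:
        mito_genes = set(gene_annotation.loc[
            gene_annotation["chromosome"].astype(str).isin(["MT", "chrM", "M"]), "gene"])
    else:
        mito_genes = {g for g in matrix.gene_ids if str(g).startswith("MT-")}
    mito_mask = matrix.features["gene"].isin(mito_genes).to_numpy()
    mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(len(umi))
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
    return pd.DataFrame({
        "umi_total": umi, "n_genes_detected": n_genes, "mito_fraction": mito_frac,
    }, index=matrix.barcodes)


def qc_filter(matrix: CellGeneMatrix, gene_annotation: pd.DataFrame | None = None,
              low_z: float = -3.0, mito_high_z: float = 2.0,
              ) -> tuple[CellGeneMatrix, pd.DataFrame]:
    """Remove outlier cells by rank-normal QC scores.

    Cells with any metric Z < ``low_z`` are outliers; cells with a
    mitochondrial-fraction Z >= ``mito_high_z`` are additionally removed as
    apoptotic.  Returns the filtered matrix and a per-rule removal report.
    """
    metrics = qc_metrics(matrix, gene_annotation)
    z = metrics.apply(rank_normal_scores)
    low = (z < low_z).any(axis=1)
    mito_hi = z["mito_fraction"] >= mito_high_z
    remove = (low | mito_hi).to_numpy()
    if remove.all():
        raise ValueError("QC filter removed every cell")
    report = pd.DataFrame({
        "rule": ["low_outlier", "mito_high", "total_removed", "retained"],
        "n_cells": [int(low.sum()), int(mito_hi.sum()), int(remove.sum()),
                    int((~remove).sum())],
    })
    filtered = CellGeneMatrix(
        counts=matrix.counts[~remove],
        barcodes=matrix.barcodes[~remove],
        features=matrix.features,
        source_label=matrix.source_label,
    )
    return filtered, report


def log_normalize(matrix: CellGeneMatrix, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Per-cell log normalization: ``ln(1 + count / cell_total * scale_factor)``.

    Depends only on within-cell proportions.  Raises on zero-total cells.
    """
    totals = matrix.umi_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError(f"{int((totals == 0).sum())} cells have zero total counts")
    dense = matrix.counts.toarray() if sp.issparse(matrix.counts) else np.asarray(matrix.counts)
    values = np.log1p(dense / totals[:, None] * scale_factor)
    return pd.DataFrame(values, index=matrix.barcodes, columns=matrix.gene_ids)


def select_hvg(normalized: pd.DataFrame, k: int = 500, n_bins: int = 20) -> list:
    """Top-k variable genes by mean-binned normalized dispersion.

    Dispersion = variance / mean of ``expm1`` values, robustly z-scored
    (median / MAD) within bins of similar mean expression — the variance-
    stabilization step, robust so that a dispersed gene cannot mask itself
    by inflating its own bin's spread.  Constant genes rank last.
    """
    if k > normalized.shape[1]:
        raise ValueError(f"k={k} exceeds gene count {normalized.shape[1]}")
    X = np.expm1(normalized.to_numpy())
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean)
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // max(len(mean), 1)
    norm_disp = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        center = np.median(disp[m])
        scale = 1.4826 * np.median(np.abs(disp[m] - center))
        if scale == 0:
            scale = disp[m].std(ddof=0)
        norm_disp[m] = (disp[m] - center) / scale if scale > 0 else 0.0
    constant = var <= 1e-16 * np.maximum(mean, 1.0) ** 2
    norm_disp[constant] = -np.inf  # constant genes can never be "variable"
    top = np.argsort(-norm_disp, kind="stable")[:k]
    return list(normalized.columns[np.sort(top)])


def scale_and_reduce(normalized: pd.DataFrame, covariates: pd.DataFrame | None = None,
                     n_pcs: int = 30, clip: float = 10.0,
                     ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Covariate-adjusted scaling and PCA.

    Each gene is replaced by its residual from a linear regression on the
    covariates (numeric used as-is, categoricals dummy-coded; single-level
    covariates dropped with a warning flag), scaled to unit variance and
    clipped at ``+/- clip``.  Returns (scaled DataFrame, PC scores,
    explained-variance ratios).
    """
    Y = normalized.to_numpy(dtype=float)
    n = Y.shape[0]
    X_cols = [np.ones(n)]
    if covariates is not None:
        for col in covariates.columns:
            v = covariates[col]
            if v.nunique() <= 1:
                continue
            if pd.api.types.is_numeric_dtype(v):
                X_cols.append(v.to_numpy(dtype=float))
            else:
                X_cols.append(pd.get_dummies(v, drop_first=True, dtype=float).to_numpy())
    X = np.column_stack(X_cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes fully explained by covariates stay at (numerically) zero
    scaled = resid / np.where(sd > 1e-8 * np.abs(Y).max(), sd, np.inf)
    scaled = np.clip(scaled, -clip, clip)
    n_pcs = min(n_pcs, min(scaled.shape) - 1)
    # deterministic exact SVD on the centered scaled matrix
    centered = scaled - scaled.mean(axis=0)
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    evr = (S ** 2 / np.sum(S ** 2))[:n_pcs]
    return pd.DataFrame(scaled, index=normalized.index, columns=normalized.columns), pcs, evr


def cluster_cells(pcs: np.ndarray, barcodes, n_neighbors: int = 15,
                  resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Graph community detection on the PC KNN graph (pluggable contract).

    Delegates to scanpy neighbors + Leiden with a fixed seed; any
    deterministic labeling can substitute for this helper downstream.
    """
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.zeros((pcs.shape[0], 1), dtype=np.float32),
                       obs=pd.DataFrame(index=pd.Index(barcodes).astype(str)))
    adata.obsm["X_pca"] = np.asarray(pcs)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X_pca", random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    return pd.Series(adata.obs["leiden"].astype(str).to_numpy(), index=pd.Index(barcodes))


def validate_clusters(cluster_labels: pd.Series, normalized: pd.DataFrame,
                      marker_table: pd.DataFrame,
                      exclusion_markers: list | None = None,
                      alpha: float = 0.05, min_log2fc: float = 0.25,
                      ) -> tuple[pd.Series, list]:
    """Assign cell types to clusters by one-sided marker enrichment.

    Each cluster is tested one-vs-rest per candidate cell type's markers
    (Wilcoxon rank-sum, one-sided up, Bonferroni within cluster over all
    marker tests).  A cluster takes the best-supported type — the candidate
    with the most significantly upregulated markers (mean marker log2FC
    breaks ties) — provided at least one marker is significant; otherwise
    it is excluded.  Clusters significantly enriched for any contamination
    marker are excluded outright.

    Returns (per-cell type labels, with excluded clusters labeled NaN;
    list of excluded cluster ids).
    """
    exclusion_markers = exclusion_markers or []
    labels = pd.Series(cluster_labels, index=normalized.index)
    V = normalized
    assignments: dict[str, str | None] = {}
    excluded = []
    marker_rows = [(r["cell_type"], r["gene"]) for _, r in marker_table.iterrows()
                   if r["gene"] in V.columns]
    n_tests_per_cluster = len(marker_rows) + len([g for g in exclusion_markers if g in V.columns])

    for cl in sorted(labels.unique()):
        in_cl = (labels == cl).to_numpy()
        best: tuple[int, float] | None = None
        best_type = None
        contaminated = False
        for gene in exclusion_markers:
            if gene not in V.columns:
                continue
            stat, p = scipy.stats.mannwhitneyu(V[gene].to_numpy()[in_cl],
                                               V[gene].to_numpy()[~in_cl],
                                               alternative="greater")
            if min(1.0, p * n_tests_per_cluster) < alpha:
                contaminated = True
                break
        if contaminated:
            excluded.append(cl)
            assignments[cl] = None
            continue
        for ct in marker_table["cell_type"].unique():
            genes = [g for t, g in marker_rows if t == ct]
            if not genes:
                continue
            n_sig, lfc_sum = 0, 0.0
            for gene in genes:
                v = V[gene].to_numpy()
                _, p = scipy.stats.mannwhitneyu(v[in_cl], v[~in_cl], alternative="greater")
                lfc = avg_log2fc(v[in_cl], v[~in_cl])
                if min(1.0, p * n_tests_per_cluster) < alpha and lfc >= min_log2fc:
                    n_sig += 1
                    lfc_sum += lfc
            score = (n_sig, lfc_sum)
            if n_sig > 0 and (best is None or score > best):
                best = score
                best_type = ct
        if best_type is None:
            excluded.append(cl)
        assignments[cl] = best_type

    cell_types = labels.map(assignments)
    return cell_types, excluded
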