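"""Synthetic PBMC cohort generator with known ground truth.

Emulates the statistical structure of a multiplexed single-cell study of
mosaic loss of chromosome Y (LOY) in male blood donors:

* donor clonal fractions whose logit is linear in age,
* cell-type-specific LOY frequencies across five immune lineages,
* a monotone LOY gradient along each lineage's pseudotime,
* dual-source MSY read counts in which LOY cells have structurally zero
  true signal (ambient contamination can only create false *negatives*),
* negative-binomial gene expression with designated LOY effect genes,
  escape-gene upregulation, and a bimodal XIST mixture in LOY cells,
* noisy SNP-array clonal fractions with a detection floor.

Every generative parameter lives in :class:`SimTruth` and is recoverable by
the matching downstream estimator; one master seed drives independent child
streams per stage, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .io import CellGeneMatrix, annotate_gene_table

# (cell type, lineage, relative abundance, baseline LOY rate)
# Abundances and rates follow the observed cohort composition of the five
# major PBMC lineages; each lineage is a single start -> end trajectory.
DEFAULT_CELL_TYPES = [
    ("B-in", "b", 20160, 0.123),
    ("B-mem", "b", 13126, 0.084),
    ("mono-c", "mono", 9561, 0.186),
    ("mono-nc", "mono", 3927, 0.171),
    ("NK", "nk", 20750, 0.146),
    ("NKr", "nk", 4366, 0.125),
    ("CD8nc", "cd8", 1809, 0.137),
    ("CD8et", "cd8", 2265, 0.158),
    ("CD4nc", "cd4", 76835, 0.058),
    ("Treg", "cd4", 10615, 0.1257),
]

LINEAGES = {
    "b": ("B-in", "B-mem"),
    "mono": ("mono-c", "mono-nc"),
    "nk": ("NK", "NKr"),
    "cd8": ("CD8nc", "CD8et"),
    "cd4": ("CD4nc", "Treg"),
}

# Odds ratio per pseudotime-quantile step for LOY along each lineage.
DEFAULT_QUANTILE_OR = {
    "b": 0.92,
    "mono": 0.91,
    "nk": 0.93,
    "cd8": 1.08,
    "cd4": 1.04,
}


@dataclasses.dataclass
class SimTruth:
    """Generative parameters of the synthetic cohort.

    The defaults encode the study conditions the generator emulates: a
    logit-scale LOY-prevalence slope of 0.013 per year of age, lineage
    gradients expressed as per-quantile odds ratios, designated LOY effect
    genes (IL1B-like downregulation in classical monocytes, escape-gene
    upregulation), and a two-component XIST mixture active only in LOY
    cells.
    """

    age_logit_slope: float = 0.013
    # intercept and donor spread calibrated so the donor clonal-fraction
    # distribution matches the cohort's printed shape: mean ~ 8.5%,
    # expanded-clonality (>= 10%) share ~ 26%, per-donor range ~ 1%-54%
    age_logit_intercept: float = -3.853
    donor_logit_sd: float = 1.4
    base_loy_rates: dict = dataclasses.field(
        default_factory=lambda: {name: rate for name, _, _, rate in DEFAULT_CELL_TYPES}
    )
    quantile_or: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_QUANTILE_OR))
    xist_bimodal_params: tuple = (0.5, 2.0, 25.0)  # (high-component weight, low mean, high mean)
    xist_active_prob: float = 0.05            # LOY cells with any XIST activity
    ambient_msy_rate: float = 0.0             # stray MSY UMIs per LOY cell per source
    msy_mean_nonloy: float = 5.0              # MSY UMIs per non-LOY cell at median depth
    # array noise sized so corr(array, true fraction) ~ 0.34, the weak
    # cohort-level concordance of whole-blood arrays with single-cell calls
    snp_noise_sd: float = 0.30
    snp_detection_floor: float = 0.02         # below this the array reports nothing
    nb_dispersion: float = 0.5                # expression overdispersion (1/size)
    n_quantiles: int = 6
    realized_quantile_freq: pd.DataFrame | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        rf = d.pop("realized_quantile_freq")
        if rf is not None:
            d["realized_quantile_freq"] = self.realized_quantile_freq.to_dict("list")
        return json.dumps(d, indent=2, default=float)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_donors(n_donors: int, truth: SimTruth | None = None, seed: int = 0,
                    age_range: tuple[int, int] = (19, 93), n_pools: int = 8) -> pd.DataFrame:
    """Draw a donor table with true and array-observed clonal fractions.

    The true clonal fraction satisfies
    ``logit(f) = intercept + slope * age + N(0, donor_logit_sd)``; the
    SNP-array estimate adds truncated Gaussian noise and is censored to
    missing below the array detection floor.
    """
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    truth = truth or SimTruth()
    rng_age, rng_frac, rng_cov, rng_snp = _rngs(seed, 4)
    ages = rng_age.integers(age_range[0], age_range[1] + 1, size=n_donors)
    lo = truth.age_logit_intercept + truth.age_logit_slope * ages
    lo = lo + rng_frac.normal(0.0, truth.donor_logit_sd, size=n_donors)
    frac = np.clip(expit(lo), 1e-6, 1 - 1e-6)

    pcs = rng_cov.normal(size=(n_donors, 10))
    donors = pd.DataFrame({
        "donor": [f"D{i:04d}" for i in range(n_donors)],
        "age": ages,
        "sex": "M",
        "pool": [f"pool{p}" for p in rng_cov.integers(0, n_pools, size=n_donors)],
        **{f"pc{j + 1}": pcs[:, j] for j in range(10)},
        "rs2887399_dosage": rng_cov.binomial(2, 0.25, size=n_donors),
        "mca_flag": rng_cov.random(n_donors) < 0.0625,
        "true_clonal_fraction": frac,
    })
    snp = np.clip(frac + rng_snp.normal(0.0, truth.snp_noise_sd, size=n_donors), 0.0, 1.0)
    snp[snp < truth.snp_detection_floor] = np.nan
    donors["snp_clonal_fraction"] = snp
    return donors


def simulate_cells(donors: pd.DataFrame, truth: SimTruth | None = None,
                   n_cells_per_donor: int = 100, seed: int = 0) -> pd.DataFrame:
    """Draw a per-cell annotation skeleton with ground-truth LOY labels.

    Each cell gets a lineage (weight = lineage abundance), a pseudotime
    ``U(0, 1)``, a cell type from its position along the lineage, a depth,
    and an LOY label from a logistic model: a lineage anchor (matched so
    the realized lineage LOY rate equals the abundance-weighted mean of
    its cell types' baseline rates) plus the donor's clonal-fraction
    offset plus the per-quantile log-odds step.  The quantile gradient is
    therefore loglinear within every lineage, which makes the per-quantile
    odds ratio the exact estimand of the downstream logistic model; a cell
    type with baseline rate 0 never produces LOY cells.  Realized
    per-quantile LOY frequencies are stored in
    ``truth.realized_quantile_freq``.
    """
    if len(donors) == 0:
        raise ValueError("empty donor table")
    truth = truth or SimTruth()
    rng_assign, rng_loy, rng_depth = _rngs(seed + 1_000_003, 3)
    k = truth.n_quantiles

    lineage_names = list(LINEAGES)
    weights = np.array([
        sum(n for _, lin, n, _ in DEFAULT_CELL_TYPES if lin == name) for name in lineage_names
    ], dtype=float)
    weights /= weights.sum()
    start_frac = {}
    for name, (start, end) in LINEAGES.items():
        n_start = next(n for t, _, n, _ in DEFAULT_CELL_TYPES if t == start)
        n_end = next(n for t, _, n, _ in DEFAULT_CELL_TYPES if t == end)
        start_frac[name] = n_start / (n_start + n_end)

    n = len(donors) * n_cells_per_donor
    donor_idx = np.repeat(np.arange(len(donors)), n_cells_per_donor)
    lin = rng_assign.choice(len(lineage_names), size=n, p=weights)
    pt = rng_assign.random(n)
    quantile = np.minimum((pt * k).astype(int) + 1, k)
    lin_names = np.array(lineage_names)[lin]
    is_start = pt < np.array([start_frac[ln] for ln in lin_names])
    cell_type = np.where(
        is_start,
        [LINEAGES[ln][0] for ln in lin_names],
        [LINEAGES[ln][1] for ln in lin_names],
    )

    cells = pd.DataFrame({
        "barcode": [f"C{i:07d}" for i in range(n)],
        "donor": donors["donor"].to_numpy()[donor_idx],
        "sex": donors["sex"].to_numpy()[donor_idx],
        "lineage": lin_names,
        "cell_type": cell_type,
        "pseudotime": pt,
        "quantile": quantile,
    })
    cells["umi_total"] = np.round(np.exp(rng_depth.normal(np.log(2500), 0.45, size=n))).astype(int)

    from scipy.optimize import brentq

    donor_lo = logit(donors["true_clonal_fraction"].to_numpy())
    offs_donor = donor_lo[donor_idx] - donor_lo.mean()
    step = np.log(np.array([truth.quantile_or[ln] for ln in lin_names]))
    offs = offs_donor + step * (quantile - (k + 1) / 2.0)

    type_weights = {t: n_ for t, _, n_, _ in DEFAULT_CELL_TYPES}
    p = np.zeros(n)
    for name in lineage_names:
        start, end = LINEAGES[name]
        w_s, w_e = type_weights[start], type_weights[end]
        anchor = (w_s * truth.base_loy_rates[start]
                  + w_e * truth.base_loy_rates[end]) / (w_s + w_e)
        m = lin_names == name
        if not m.any() or anchor <= 0:
            continue
        # mean-matching intercept: realized lineage LOY rate == anchor
        o = offs[m]
        a = brentq(lambda a_: expit(a_ + o).mean() - anchor, -25.0, 10.0)
        p[m] = expit(a + o)
    # a cell type with baseline rate zero never yields LOY cells
    base = np.array([truth.base_loy_rates[t] for t in cell_type])
    p[base <= 0] = 0.0
    cells["loy"] = rng_loy.random(n) < p
    cells.loc[cells["sex"] != "M", "loy"] = False

    freq = cells.groupby(["lineage", "quantile"])["loy"].mean().rename("loy_freq").reset_index()
    truth.realized_quantile_freq = freq
    return cells


def default_msy_genes() -> pd.DataFrame:
    """A small panel of Y male-specific-region genes (GRCh38 coordinates)."""
    rows = [
        ("RPS4Y1", "Y", 2_841_602, 2_867_268),
        ("ZFY", "Y", 2_935_281, 2_982_506),
        ("USP9Y", "Y", 12_701_231, 12_860_839),
        ("DDX3Y", "Y", 12_904_071, 12_920_478),
        ("UTY", "Y", 13_234_104, 13_480_673),
        ("NLGN4Y", "Y", 14_522_311, 14_845_650),
        ("KDM5D", "Y", 19_703_865, 19_744_939),
        ("EIF1AY", "Y", 20_575_711, 20_593_154),
    ]
    return annotate_gene_table(
        pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
    )


def simulate_msy_counts(cells: pd.DataFrame, truth: SimTruth | None = None, seed: int = 0,
                        msy_genes: pd.DataFrame | None = None,
                        guarantee_positive: bool = False) -> tuple[CellGeneMatrix, CellGeneMatrix]:
    """Draw MSY UMI counts from two independent counting sources.

    Non-LOY male cells draw Poisson totals with a depth-scaled mean (or a
    shifted Poisson guaranteed >= 1 when ``guarantee_positive``); LOY cells
    and female cells draw only ambient Poisson(``ambient_msy_rate``) strays.
    With a zero ambient rate the dual-source zero-read rule is therefore
    perfectly specific and its only errors are Poisson-zero false negatives.
    """
    truth = truth or SimTruth()
    if truth.ambient_msy_rate < 0:
        raise ValueError("ambient MSY rate must be non-negative")
    msy_genes = msy_genes if msy_genes is not None else default_msy_genes()
    if len(msy_genes) == 0:
        raise ValueError("need at least one MSY gene")
    rngs = _rngs(seed + 2_000_003, 2)
    n, g = len(cells), len(msy_genes)
    depth = cells["umi_total"].to_numpy(dtype=float)
    scale = depth / max(np.median(depth), 1.0)
    signal = (cells["sex"].to_numpy() == "M") & (~cells["loy"].to_numpy().astype(bool))

    out = []
    for source, rng in zip(("cellranger", "velocyto"), rngs):
        totals = rng.poisson(truth.ambient_msy_rate, size=n)
        mean = truth.msy_mean_nonloy * scale[signal]
        sig_tot = rng.poisson(mean)
        if guarantee_positive:
            sig_tot = sig_tot + 1
        totals[signal] = totals[signal] + sig_tot
        counts = np.zeros((n, g), dtype=np.int64)
        nz = totals > 0
        if nz.any():
            counts[nz] = rng.multinomial(totals[nz], np.full(g, 1.0 / g))
        out.append(CellGeneMatrix(
            counts=sp.csr_matrix(counts),
            barcodes=pd.Index(cells["barcode"]),
            features=msy_genes[["gene"]].assign(symbol=msy_genes["gene"]),
            source_label=source,
        ))
    return out[0], out[1]


ESCAPE_X_GENES = [
    ("KDM6A", 44_873_177, 45_112_602), ("DDX3X", 41_333_284, 41_364_472),
    ("KDM5C", 53_176_277, 53_225_422), ("ZRSR2", 15_790_556, 15_823_172),
    ("JPX", 73_940_475, 74_063_963), ("RPS4X", 72_256_032, 72_300_361),
    ("EIF1AX", 20_124_518, 20_141_841), ("ESC_NULL1", 48_000_000, 48_010_000),
    ("ESC_NULL2", 49_000_000, 49_010_000),
]
INACTIVE_X_GENES = [
    ("ATRX", 77_504_878, 77_786_269), ("BTK", 101_349_447, 101_390_796),
    ("FOXP3", 49_250_436, 49_264_826), ("INA_NULL1", 90_000_000, 90_010_000),
    ("INA_NULL2", 91_000_000, 91_010_000), ("INA_NULL3", 92_000_000, 92_010_000),
]


def default_gene_panel(n_null: int = 60) -> pd.DataFrame:
    """Gene annotation + expression baselines for the synthetic transcriptome.

    Includes the designated LOY effect genes, X escape/inactive genes, XIST,
    PAR1 CD99, mitochondrial genes for QC, lineage markers, and autosomal
    null genes.
    """
    rows = []  # gene, chromosome, start, end, xci_class, baseline_mean

    def add(gene, chrom, start, end, xci, mean):
        rows.append((gene, chrom, start, end, xci, mean))

    add("XIST", "X", 73_820_651, 73_852_753, "escape", 0.0)  # handled specially
    add("CD99", "X", 2_691_187, 2_741_309, "unclassified", 8.0)
    for g, s, e in ESCAPE_X_GENES:
        add(g, "X", s, e, "escape", 4.0)
    for g, s, e in INACTIVE_X_GENES:
        add(g, "X", s, e, "inactive", 4.0)
    add("TIMP1", "X", 47_582_291, 47_586_789, "variable", 3.0)
    # autosomal effect genes; IL1B's baseline keeps its detection mid-range
    # (~50% of cells) so the LOY mean effect also moves the per-donor
    # proportion of expressing cells, the pseudobulk estimand
    add("IL1B", "2", 112_829_751, 112_836_903, None, 0.8)
    add("LGALS2", "22", 37_565_467, 37_574_170, None, 6.0)
    add("CD86", "3", 122_055_362, 122_121_139, None, 5.0)
    add("MYCL", "1", 39_895_411, 39_901_648, None, 4.0)
    add("TCL1A", "14", 95_714_358, 95_723_557, None, 6.0)
    add("LYPD2", "8", 142_829_706, 142_832_442, None, 8.0)
    add("C1QA", "1", 22_636_565, 22_639_622, None, 8.0)
    add("RNASE2", "14", 20_889_561, 20_890_526, None, 8.0)
    # lineage markers (for cluster validation)
    add("CD14", "5", 140_630_856, 140_633_701, None, 2.0)
    add("LYZ", "12", 69_348_341, 69_354_234, None, 2.0)
    add("FCGR3A", "1", 161_540_759, 161_549_916, None, 2.0)  # CD16
    add("CD3D", "11", 118_339_075, 118_342_704, None, 2.0)
    add("MS4A1", "11", 60_455_845, 60_470_752, None, 2.0)  # CD20
    add("NKG7", "19", 51_371_836, 51_372_961, None, 2.0)
    # mitochondrial genes for QC mito fraction
    add("MT-CO1", "MT", 5_904, 7_445, None, 60.0)
    add("MT-ND1", "MT", 3_307, 4_262, None, 40.0)
    for i in range(n_null):
        add(f"NULL{i:03d}", "1", 1_000_000 + i * 20_000, 1_010_000 + i * 20_000, None, 3.0)

    panel = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end",
                                        "xci_class", "baseline_mean"])
    return annotate_gene_table(panel)


def default_gene_effects() -> pd.DataFrame:
    """Planted LOY effects: (gene, cell_type or 'all', log2 fold change)."""
    rows = [
        ("IL1B", "mono-c", -0.22), ("LGALS2", "mono-c", -0.16),
        ("CD86", "mono-c", -0.30), ("MYCL", "mono-c", -0.55),
        ("CD99", "all", -0.30),
    ]
    rows += [(g, "all", 0.30) for g, _, _ in ESCAPE_X_GENES if not g.startswith("ESC_NULL")]
    return pd.DataFrame(rows, columns=["gene", "cell_type", "log2fc"])


def simulate_expression(cells: pd.DataFrame, truth: SimTruth | None = None,
                        gene_panel: pd.DataFrame | None = None,
                        gene_effects: pd.DataFrame | None = None,
                        seed: int = 0) -> CellGeneMatrix:
    """Draw a negative-binomial expression matrix with planted LOY effects.

    LOY multiplies the mean of each effect gene by ``2**log2fc`` in its
    designated cell types.  Marker genes (CD14/LYZ in monocytes, CD3D in T
    cells, MS4A1 in B cells, NKG7/FCGR3A where expected) are upregulated in
    their home types.  XIST is drawn from a zero-dominated two-component
    Poisson mixture active only in LOY cells, producing a bimodal nonzero
    distribution when the high-component weight is strictly between 0 and 1.
    """
    truth = truth or SimTruth()
    if truth.nb_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    panel = gene_panel if gene_panel is not None else default_gene_panel()
    effects = gene_effects if gene_effects is not None else default_gene_effects()
    rng = np.random.default_rng(np.random.SeedSequence(seed + 3_000_007).spawn(1)[0])

    n, g = len(cells), len(panel)
    depth = cells["umi_total"].to_numpy(dtype=float)
    scale = depth / max(np.median(depth), 1.0)
    loy = cells["loy"].to_numpy().astype(bool)
    ct = cells["cell_type"].to_numpy()

    marker_home = {
        "CD14": ["mono-c"], "LYZ": ["mono-c", "mono-nc"], "FCGR3A": ["mono-nc", "NK", "NKr"],
        "CD3D": ["CD4nc", "Treg", "CD8nc", "CD8et"], "MS4A1": ["B-in", "B-mem"],
        "NKG7": ["NK", "NKr", "CD8et"],
    }

    mean = np.outer(scale, panel["baseline_mean"].to_numpy())
    gene_pos = {gene: j for j, gene in enumerate(panel["gene"])}
    for gene, homes in marker_home.items():
        if gene in gene_pos:
            mean[np.isin(ct, homes), gene_pos[gene]] *= 8.0
    for _, row in effects.iterrows():
        if row["gene"] not in gene_pos:
            continue
        j = gene_pos[row["gene"]]
        mask = loy if row["cell_type"] == "all" else (loy & (ct == row["cell_type"]))
        mean[mask, j] *= 2.0 ** row["log2fc"]

    shape = 1.0 / truth.nb_dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)

    if "XIST" in gene_pos:
        j = gene_pos["XIST"]
        w, mu_low, mu_high = truth.xist_bimodal_params
        xist = rng.poisson(0.0002, size=n)  # stray background in non-LOY males
        active = loy & (rng.random(n) < truth.xist_active_prob)
        hi = active & (rng.random(n) < w)
        lo_ = active & ~hi
        xist[hi] = rng.poisson(mu_high, size=int(hi.sum()))
        xist[lo_] = rng.poisson(mu_low, size=int(lo_.sum()))
        counts[:, j] = xist

    return CellGeneMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=pd.Index(cells["barcode"]),
        features=panel[["gene"]].assign(symbol=panel["gene"]),
        source_label="simulated",
    )


def simulate_embedding(pseudotime: np.ndarray, seed: int = 0,
                       noise_sd: float = 0.0) -> np.ndarray:
    """Embed cells on a noisy 2-D parametric arc ordered by pseudotime."""
    rng = np.random.default_rng(seed)
    t = np.asarray(pseudotime, dtype=float)
    xy = np.column_stack([np.cos(np.pi * (1 - t)), np.sin(np.pi * (1 - t))])
    if noise_sd > 0:
        xy = xy + rng.normal(0.0, noise_sd, size=xy.shape)
    return xy


def simulate_dynamics_response(cells: pd.DataFrame, beta_loy: float = 0.1,
                               beta_quantile: float = 0.05, beta_interaction: float = -0.08,
                               beta_quantile2: float = 0.0, beta_interaction2: float = 0.0,
                               donor_sd: float = 0.2, noise_sd: float = 1.0,
                               seed: int = 0) -> np.ndarray:
    """Draw a continuous expression response from the exact interaction model.

    ``y = b0 + bL*loy + bQ*q + bQ2*q^2 + bI*loy*q + bI2*loy*q^2 + u_donor + eps``
    with a Gaussian donor random intercept — the generative counterpart of
    the pseudotime-interaction mixed model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed + 4_000_037).spawn(1)[0])
    q = cells["quantile"].to_numpy(dtype=float)
    loy = cells["loy"].to_numpy(dtype=float)
    donors = cells["donor"].to_numpy()
    uniq = pd.unique(donors)
    u = pd.Series(rng.normal(0.0, donor_sd, size=len(uniq)), index=uniq)
    y = (1.0 + beta_loy * loy + beta_quantile * q + beta_quantile2 * q * q
         + beta_interaction * loy * q + beta_interaction2 * loy * q * q
         + u[donors].to_numpy() + rng.normal(0.0, noise_sd, size=len(cells)))
    return y


def simulate_cohort(n_donors: int = 40, n_cells_per_donor: int = 150,
                    truth: SimTruth | None = None, seed: int = 0) -> dict:
    """Generate the full synthetic cohort: donors, cells, dual-source MSY
    counts, and an expression matrix.  Returns a dict of the pieces plus the
    (mutated) truth object holding realized quantities."""
    truth = truth or SimTruth()
    donors = simulate_donors(n_donors, truth, seed=seed)
    cells = simulate_cells(donors, truth, n_cells_per_donor=n_cells_per_donor, seed=seed)
    msy_a, msy_b = simulate_msy_counts(cells, truth, seed=seed)
    expr = simulate_expression(cells, truth, seed=seed)
    return {
        "truth": truth,
        "donors": donors,
        "cells": cells,
        "msy_a": msy_a,
        "msy_b": msy_b,
        "expression": expr,
        "gene_panel": default_gene_panel(),
    }


def write_cohort(cohort: dict, out_dir) -> None:
    """Write a simulated cohort to disk: MTX triplets for each counting
    source and the expression matrix, donor and cell TSVs, the gene
    annotation TSV, and the generative truth as JSON."""
    from pathlib import Path

    from .io import write_counts_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_matrix(cohort["msy_a"], out / "msy_cellranger")
    write_counts_matrix(cohort["msy_b"], out / "msy_velocyto")
    write_counts_matrix(cohort["expression"], out / "expression")
    cohort["donors"].to_csv(out / "donors.tsv", sep="\t", index=False)
    cohort["cells"].to_csv(out / "cells.tsv", sep="\t", index=False)
    cohort["gene_panel"].to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(cohort["truth"].to_json() + "\n")
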