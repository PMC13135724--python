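"""Readers and writers for the formats the pipeline touches.

Count matrices travel as MatrixMarket triplets (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``), donor covariates and gene annotation
as TSV, gene sets as GMT.  All genomic coordinates are 1-based inclusive.

The male-specific region (MSY) of chromosome Y and the X pseudoautosomal
regions are fixed GRCh38 intervals; a chrY gene belongs to the MSY only if
it is fully contained in the region (genes straddling a boundary are
excluded — conservative, in keeping with the specificity-first LOY rule).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

# GRCh38 spans, 1-based inclusive.
MSY_REGION = (2_781_480, 56_887_902)        # chrY male-specific region
PAR1_X = (10_001, 2_781_479)                # chrX pseudoautosomal region 1
PAR2_X = (155_701_383, 156_030_895)         # chrX pseudoautosomal region 2

#: Default analysis thresholds, resolvable from a flat key/value config file.
DEFAULT_CONFIG: dict[str, float | int | str] = {
    "msy_start": MSY_REGION[0],
    "msy_end": MSY_REGION[1],
    "par1_start": PAR1_X[0],
    "par1_end": PAR1_X[1],
    "par2_start": PAR2_X[0],
    "par2_end": PAR2_X[1],
    "expanded_clonality_pct": 10.0,
    "de_min_pct": 0.01,
    "de_min_log2fc": 0.1,
    "snp_detection_floor": 0.02,
    "n_quantiles": 6,
    "seed": 0,
}

XCI_CLASSES = frozenset({"escape", "inactive", "variable", "unclassified"})


@dataclasses.dataclass
class CellGeneMatrix:
    """Sparse cells x genes UMI count matrix with sidecar metadata.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Non-negative integer UMI counts, one row per cell.
    barcodes : pandas.Index
        Unique cell identifiers, aligned to rows.
    features : pandas.DataFrame
        One row per gene; must carry a ``gene`` column (identifier), may
        carry ``symbol``.
    source_label : str
        Tag for the counting source (e.g. ``"cellranger"``, ``"velocyto"``).
    """

    counts: sp.csr_matrix
    barcodes: pd.Index
    features: pd.DataFrame
    source_label: str = "unknown"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = pd.Index(self.barcodes)
        if not self.barcodes.is_unique:
            raise ValueError("cell barcodes must be unique within a matrix")
        if len(self.barcodes) != self.counts.shape[0]:
            raise ValueError(
                f"barcode count {len(self.barcodes)} != matrix rows {self.counts.shape[0]}"
            )
        if len(self.features) != self.counts.shape[1]:
            raise ValueError(
                f"feature count {len(self.features)} != matrix columns {self.counts.shape[1]}"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.features["gene"])

    def umi_totals(self) -> np.ndarray:
        """Per-cell total UMI count."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_genes(self, genes) -> "CellGeneMatrix":
        """Restrict to the given gene identifiers (order of appearance kept)."""
        mask = self.features["gene"].isin(set(genes)).to_numpy()
        return CellGeneMatrix(
            counts=self.counts[:, mask],
            barcodes=self.barcodes,
            features=self.features.loc[mask].reset_index(drop=True),
            source_label=self.source_label,
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=self.barcodes.astype(str))
        var = self.features.set_index("gene")
        var.index = var.index.astype(str)
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)


def read_counts_matrix(path, format: str = "mtx", source_label: str = "unknown") -> CellGeneMatrix:
    """Read a cells x genes count matrix.

    ``format="mtx"`` expects a directory with ``matrix.mtx`` (genes x cells,
    CellRanger orientation, transposed on load) or ``matrix.mtx`` already in
    cells x genes if ``barcodes.tsv``/``features.tsv`` lengths say so;
    ``format="tsv"`` expects a dense TSV with barcodes as the index and gene
    identifiers as columns (test-scale convenience).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CellGeneMatrix(
            counts=sp.csr_matrix(df.to_numpy()),
            barcodes=pd.Index(df.index),
            features=pd.DataFrame({"gene": df.columns}),
            source_label=source_label,
        )
    if format != "mtx":
        raise ValueError(f"unknown format: {format!r}")
    mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    features.columns = ["gene", "symbol"][: features.shape[1]]
    if "symbol" not in features.columns:
        features["symbol"] = features["gene"]
    if mat.shape == (len(features), len(barcodes)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T.tocsr()  # genes x cells on disk, cells x genes in memory
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match barcodes ({len(barcodes)}) "
            f"x features ({len(features)})"
        )
    return CellGeneMatrix(
        counts=mat,
        barcodes=pd.Index(barcodes),
        features=features,
        source_label=source_label,
    )


def write_counts_matrix(matrix: CellGeneMatrix, path) -> None:
    """Write an MTX triplet directory (genes x cells on disk, CellRanger style)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.counts.T), field="integer")
    pd.Series(matrix.barcodes).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    feats = matrix.features.copy()
    if "symbol" not in feats.columns:
        feats["symbol"] = feats["gene"]
    feats[["gene", "symbol"]].to_csv(path / "features.tsv", sep="\t", header=False, index=False)


def _par_region(chromosome: str, start: int, end: int) -> str:
    if chromosome not in ("X", "chrX", "Y", "chrY"):
        return "NA"
    if chromosome in ("X", "chrX"):
        if start >= PAR1_X[0] and end <= PAR1_X[1]:
            return "PAR1"
        if start >= PAR2_X[0] and end <= PAR2_X[1]:
            return "PAR2"
        return "nonPAR"
    # chrY: anything outside the MSY is pseudoautosomal; label by which end
    if end < MSY_REGION[0]:
        return "PAR1"
    if start > MSY_REGION[1]:
        return "PAR2"
    return "nonPAR"


def is_msy(chromosome: str, start: int, end: int) -> bool:
    """Whether a gene lies fully inside the Y male-specific region."""
    return chromosome in ("Y", "chrY") and start >= MSY_REGION[0] and end <= MSY_REGION[1]


def annotate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``par_region``, ``msy`` and normalized ``xci_class`` columns."""
    table = table.copy()
    if np.any(table["start"] > table["end"]):
        bad = table.loc[table["start"] > table["end"], "gene"].tolist()
        raise ValueError(f"start > end for genes: {bad}")
    if "xci_class" in table.columns:
        xci = table["xci_class"].fillna("unclassified").astype(str).str.lower()
        unknown = set(xci) - XCI_CLASSES
        if unknown:
            raise ValueError(f"unknown xci_class tokens: {sorted(unknown)}")
        table["xci_class"] = xci
    else:
        table["xci_class"] = "unclassified"
    table["par_region"] = [
        _par_region(c, s, e) for c, s, e in zip(table["chromosome"], table["start"], table["end"])
    ]
    table["msy"] = [
        is_msy(c, s, e) for c, s, e in zip(table["chromosome"], table["start"], table["end"])
    ]
    return table


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, chromosome, start, end[, xci_class]).

    Returns the table with derived ``par_region`` (PAR1/PAR2/nonPAR/NA) and
    boolean ``msy`` columns filled from the GRCh38 coordinate rules.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return annotate_gene_table(table)


def read_donor_table(path) -> pd.DataFrame:
    """Read the per-donor covariate TSV and validate its invariants."""
    table = pd.read_csv(path, sep="\t")
    if "age" in table.columns and np.any(table["age"] <= 0):
        raise ValueError("donor ages must be positive")
    if "rs2887399_dosage" in table.columns:
        dosages = table["rs2887399_dosage"].dropna()
        if not set(dosages.astype(int)) <= {0, 1, 2}:
            raise ValueError("rs2887399 dosage must be additive-coded 0/1/2")
    if "snp_clonal_fraction" in table.columns:
        cf = table["snp_clonal_fraction"].dropna()
        if np.any((cf < 0) | (cf > 1)):
            raise ValueError("snp_clonal_fraction must lie in [0, 1]")
    return table


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into ``{set_name: {genes}}``.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a set are dropped.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = set(g for g in fields[2:] if g)
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_config(path) -> dict:
    """Read a flat ``key = value`` config file, merged over the defaults."""
    config = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            try:
                config[key] = int(value)
            except ValueError:
                try:
                    config[key] = float(value)
                except ValueError:
                    config[key] = value
    return config
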