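"""Input reading, gene filtering, pseudobulk aggregation, and normalization.

Normalization is an autosome-anchored variant of TPM: per-gene counts are
divided by CDS length, and the scale is set so the *autosomal* length-
normalized rates sum to 10^6 within each sample. Because the sex chromosomes
can contribute very differently to male and female transcriptomes, anchoring
the scale on autosomes keeps samples comparable.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread

from .config import DEFAULT_STAGES, REFERENCE_AUTOSOMES


class ParseError(ValueError):
    """Raised for malformed or inconsistent input files."""


def read_count_matrix(
    mtx_path,
    genes_path,
    barcodes_path,
    celltypes_path,
    stages=DEFAULT_STAGES,
) -> AnnData:
    """Read a genes-by-cells MatrixMarket bundle into an AnnData.

    ``genes.tsv`` must carry columns gene_id, chromosome, start, end, strand,
    cds_length; ``barcodes.tsv`` one barcode per row; ``cell_types.tsv``
    columns barcode, cell_type[, replicate]. Cells become ``obs`` (cell_type
    categorical in stage order), genes become ``var``.
    """
    try:
        mat = mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ParseError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if (mat.data < 0).any():
        raise ParseError("negative entries in count matrix")

    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_id" not in genes.columns:
        raise ParseError(f"{genes_path}: missing gene_id column")
    if genes.gene_id.duplicated().any():
        dup = genes.gene_id[genes.gene_id.duplicated()].iloc[0]
        raise ParseError(f"duplicate gene id: {dup}")
    genes = genes.set_index("gene_id")

    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if barcodes.duplicated().any():
        raise ParseError("duplicate barcodes")

    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise ParseError(
            f"dimension mismatch: {len(genes)} genes in {genes_path}, "
            f"{n_genes} rows in matrix")
    if len(barcodes) != n_cells:
        raise ParseError(
            f"dimension mismatch: {len(barcodes)} barcodes in {barcodes_path}, "
            f"{n_cells} columns in matrix")

    ct = pd.read_csv(celltypes_path, sep="\t")
    if not {"barcode", "cell_type"} <= set(ct.columns):
        raise ParseError(f"{celltypes_path}: need barcode and cell_type columns")
    ct = ct.set_index("barcode").reindex(barcodes)
    if ct.cell_type.isna().any():
        missing = barcodes[ct.cell_type.isna().to_numpy()].iloc[0]
        raise ParseError(f"no cell type for barcode {missing}")
    unknown = set(ct.cell_type) - set(stages)
    if unknown:
        raise ParseError(f"unknown cell-type labels: {sorted(unknown)}")

    obs = pd.DataFrame(index=pd.Index(barcodes, name=None))
    obs["cell_type"] = pd.Categorical(ct.cell_type.to_numpy(), categories=list(stages))
    obs["replicate"] = ct["replicate"].to_numpy() if "replicate" in ct else "rep1"
    return AnnData(X=sp.csr_matrix(mat.T), obs=obs, var=genes)


def aggregate_pseudobulk(adata: AnnData) -> pd.DataFrame:
    """Sum counts across cells of the same type: genes x cell_types.

    Conserves the grand total of the matrix; raises if any cell is unlabeled.
    """
    ct = adata.obs["cell_type"]
    if ct.isna().any():
        raise ValueError("unlabeled cells present")
    X = adata.X
    sparse = sp.issparse(X)
    cols = {}
    for stage in ct.cat.categories if hasattr(ct, "cat") else pd.unique(ct):
        mask = (ct == stage).to_numpy()
        if not mask.any():
            continue
        cols[stage] = np.asarray(X[mask].sum(axis=0)).ravel() if sparse \
            else X[mask].sum(axis=0)
    pb = pd.DataFrame(cols, index=adata.var_names)
    return pb.astype(np.int64)


def filter_genes(
    adata: AnnData,
    min_count: int = 5,
    mode: str = "per_type_max",
) -> tuple[AnnData, list]:
    """Drop genes too weakly expressed to be testis-relevant.

    ``per_type_max`` (default) keeps a gene iff its pseudobulk count reaches
    ``min_count`` in at least one cell type; ``total`` keeps it iff the global
    sum reaches ``min_count``. Returns the filtered view (copied) and the
    removed gene ids. Idempotent.
    """
    pb = aggregate_pseudobulk(adata)
    if mode == "per_type_max":
        keep = (pb.max(axis=1) >= min_count).to_numpy()
    elif mode == "total":
        keep = (pb.sum(axis=1) >= min_count).to_numpy()
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    removed = list(adata.var_names[~keep])
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return adata[:, keep].copy(), removed


def modified_tpm(
    counts: pd.DataFrame,
    cds_lengths: pd.Series,
    autosome_genes,
) -> pd.DataFrame:
    """Autosome-anchored TPM.

    value(g) = (c_g / L_g) / sum over autosomal a of (c_a / L_a) * 1e6,
    so within each sample the autosomal values sum to exactly 10^6.

    ``counts`` is genes x samples (nonnegative; real-valued accepted);
    ``cds_lengths`` is indexed by gene id; ``autosome_genes`` designates the
    anchor set (must be nonempty with a nonzero rate sum in every sample).
    """
    autosome_genes = pd.Index(autosome_genes)
    if len(autosome_genes) == 0:
        raise ValueError("autosome gene set is empty")
    missing = autosome_genes.difference(counts.index)
    if len(missing):
        raise ValueError(f"autosome genes absent from counts: {list(missing[:3])}")
    lengths = cds_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = counts.index[lengths.isna() | (lengths <= 0)][0]
        raise ValueError(f"gene {bad} lacks a positive cds_length")

    rate = counts.div(lengths, axis=0)
    denom = rate.loc[autosome_genes].sum(axis=0)
    if (denom <= 0).any():
        bad = denom.index[denom <= 0][0]
        raise ValueError(f"degenerate normalizer: zero autosomal rate in {bad}")
    return rate.div(denom, axis=1) * 1e6


def autosome_reference_genes(annotation: pd.DataFrame,
                             reference=REFERENCE_AUTOSOMES) -> pd.Index:
    """Gene ids on the reference autosomal arms (excludes the former-X dot)."""
    return annotation.index[annotation.chromosome.isin(reference)]


def testes_expressed_subset(tpm, sample=None) -> pd.Index:
    """Genes in the upper half of the testis TPM distribution.

    ``tpm`` is a Series or a one-column selection of an expression table
    (pass ``sample`` to pick a column). The median is taken over all genes in
    the table; genes at or above it are returned, so a fully tied table
    returns every gene.
    """
    if isinstance(tpm, pd.DataFrame):
        if sample is None:
            if tpm.shape[1] != 1:
                raise ValueError("pass sample= to select a testis column")
            tpm = tpm.iloc[:, 0]
        else:
            tpm = tpm[sample]
    if len(tpm) == 0:
        raise ValueError("empty expression table")
    return tpm.index[tpm >= tpm.median()]
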