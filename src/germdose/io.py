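"""Readers and writers for the standard on-disk formats.

Single-cell bundles are MatrixMarket (genes x cells) with TSV sidecars;
annotation goes out as GFF3 (1-based closed, ``muller`` attribute carrying
the chromosome class) and BED (0-based half-open); peaks as BED3; bulk tables
and gametolog trios as TSV; CDS sets as FASTA.
"""
from __future__ import annotations

import os

import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmwrite

ANNOTATION_COLUMNS = ["chromosome", "start", "end", "strand", "cds_length"]


def write_count_bundle(adata, outdir) -> None:
    """Write an AnnData as matrix.mtx + genes/barcodes/cell_types TSVs."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.csr_matrix(adata.X).T  # genes x cells on disk
    mmwrite(os.path.join(outdir, "matrix.mtx"), X.tocoo(), field="integer")
    genes = adata.var[ANNOTATION_COLUMNS].copy()
    genes.index.name = "gene_id"
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False)
    ct = adata.obs[["cell_type", "replicate"]].copy()
    ct.index.name = "barcode"
    ct.to_csv(os.path.join(outdir, "cell_types.tsv"), sep="\t")


def annotation_to_gff3(annotation: pd.DataFrame, path) -> None:
    """GFF3 gene lines; converts internal 0-based half-open to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in annotation.iterrows():
            attrs = f"ID={gid};muller={row.chromosome};cds_length={int(row.cds_length)}"
            fh.write(
                f"{row.chromosome}\tgermdose\tgene\t{int(row.start) + 1}\t"
                f"{int(row.end)}\t.\t{row.strand}\t.\t{attrs}\n")


def read_gff3_annotation(path) -> pd.DataFrame:
    """Read gene features from GFF3 into the internal annotation frame.

    Coordinates convert back to 0-based half-open; the chromosome class is
    taken from the ``muller`` attribute (falling back to the seqid) and CDS
    length from the ``cds_length`` attribute.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        muller = feat.attributes.get("muller", [feat.seqid])[0]
        cds = int(feat.attributes.get("cds_length", [feat.end - feat.start + 1])[0])
        rows.append((gid, muller, feat.start - 1, feat.end, feat.strand, cds))
    return pd.DataFrame(
        rows, columns=["gene_id"] + ANNOTATION_COLUMNS).set_index("gene_id")


def annotation_to_bed(annotation: pd.DataFrame, path, class_map_path=None) -> None:
    """6-column BED (0-based half-open) plus optional chromosome-class map."""
    bed = annotation.reset_index()[
        ["chromosome", "start", "end", "gene_id", "cds_length", "strand"]]
    bed.to_csv(path, sep="\t", header=False, index=False)
    if class_map_path is not None:
        annotation.reset_index()[["gene_id", "chromosome"]].to_csv(
            class_map_path, sep="\t", header=False, index=False)


def peaks_to_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    """Read BED3+ peak intervals (extra columns ignored)."""
    peaks = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = peaks.iloc[:, :3]
    peaks.columns = ["chromosome", "start", "end"]
    return peaks.astype({"start": int, "end": int})


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_id_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_bulk_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_bulk_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
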