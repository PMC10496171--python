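"""Readers and writers for the on-disk formats the pipeline exchanges.

Count matrices travel as 10x-style MTX triplets (matrix.mtx, barcodes.tsv,
features.tsv) via :mod:`scipy.io`; tabular metadata as TSV via pandas;
alignment hits as 21-column PSL text; exon references as GTF.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount",
    "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
    "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd",
    "blockCount", "blockSizes", "qStarts", "tStarts",
]


# --------------------------------------------------------------------------
# 10x-style MTX triplets
# --------------------------------------------------------------------------

def write_mtx(dirpath, matrix, barcodes, features) -> None:
    """Write a barcode x gene matrix as a 10x-style triplet directory.

    The MTX file is stored genes x barcodes (features as rows), matching the
    CellRanger convention.
    """
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    m = sp.csc_matrix(sp.csr_matrix(matrix).T)
    scipy.io.mmwrite(str(d / "matrix.mtx"), m, field="integer")
    pd.Series(list(barcodes)).to_csv(d / "barcodes.tsv", index=False, header=False)
    pd.Series(list(features)).to_csv(d / "features.tsv", index=False, header=False)


def read_mtx(dirpath):
    """Read a triplet directory; returns (barcode x gene CSR, barcodes, features)."""
    d = Path(dirpath)
    m = scipy.io.mmread(str(d / "matrix.mtx"))
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None)[0].astype(str).tolist()
    features = pd.read_csv(d / "features.tsv", header=None)[0].astype(str).tolist()
    mat = sp.csr_matrix(m).T.tocsr()
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match barcodes/features "
            f"({len(barcodes)}, {len(features)})")
    return mat, barcodes, features


def write_tsv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# PSL
# --------------------------------------------------------------------------

def hit_to_psl_row(hit) -> list:
    """Serialise an AlignmentHit to the 21 PSL columns.

    The query name carries ``gene|exon|chrom:start-end`` so the query's own
    locus survives the round trip.
    """
    qname = (f"{hit.query_gene_id}|{hit.query_exon_id}|"
             f"{hit.source_locus[0]}:{hit.source_locus[1]}-{hit.source_locus[2]}")
    aligned = hit.matches + hit.mismatches
    return [
        hit.matches, hit.mismatches, 0, 0,
        1 if hit.query_gap_bases else 0, hit.query_gap_bases,
        1 if hit.target_gap_bases else 0, hit.target_gap_bases,
        hit.strand, qname, hit.query_length, 0, aligned,
        hit.target_chrom, 10**9, hit.target_start, hit.target_end,
        1, f"{aligned},", "0,", f"{hit.target_start},",
    ]


def write_psl(path, hits) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write("\t".join(str(x) for x in hit_to_psl_row(hit)) + "\n")


def read_psl(path):
    """Parse a (headerless or headered) PSL file into AlignmentHit records."""
    from .orthoexons import AlignmentHit

    hits = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 21 or not parts[0].isdigit():
                continue  # header / separator lines
            qname = parts[9]
            gene_id, exon_id, locus = qname.split("|")
            chrom, span = locus.split(":")
            start, end = span.split("-")
            hits.append(AlignmentHit(
                query_exon_id=exon_id,
                query_gene_id=gene_id,
                query_length=int(parts[10]),
                matches=int(parts[0]),
                mismatches=int(parts[1]),
                query_gap_bases=int(parts[5]),
                target_gap_bases=int(parts[7]),
                target_chrom=parts[13],
                target_start=int(parts[15]),
                target_end=int(parts[16]),
                strand=parts[8],
                source_locus=(chrom, int(start), int(end)),
            ))
    return hits


# --------------------------------------------------------------------------
# GTF
# --------------------------------------------------------------------------

def write_gtf(path, records) -> None:
    """Write exon records as GTF (1-based inclusive coordinates).

    ``records``: iterable of dicts with keys chrom, start, end (0-based
    half-open), strand, gene_id, exon_id.
    """
    with open(path, "w") as fh:
        for r in records:
            attrs = f'gene_id "{r["gene_id"]}"; exon_id "{r["exon_id"]}";'
            fh.write("\t".join([
                r["chrom"], "ebcomp", "exon",
                str(r["start"] + 1), str(r["end"]), ".",
                r["strand"], ".", attrs]) + "\n")


def sha256_file(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_tree(path) -> str:
    """Hash a file, or every file under a directory, deterministically."""
    import hashlib
    p = Path(path)
    if p.is_file():
        return sha256_file(p)
    h = hashlib.sha256()
    for f in sorted(p.rglob("*")):
        if f.is_file():
            h.update(os.fspath(f.relative_to(p)).encode())
            h.update(bytes.fromhex(sha256_file(f)))
    return h.hexdigest()
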