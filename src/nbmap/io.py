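"""Readers and writers for the pipeline's plain-text exchange formats.

Single-cell matrices travel as MTX (genes × cells, cellranger orientation)
with genes.tsv / barcodes.tsv / metadata.tsv side files; copy-number
segments as BED plus two copy-number columns; allele counts, annotation and
bulk tables as TSV; smoothed tracks as bedGraph (handled by GenomicTrack).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genotyping import CopyNumberSegment

__all__ = [
    "write_cellmatrix",
    "read_cellmatrix",
    "write_segments_bed",
    "read_segments_bed",
    "write_table",
    "read_table",
]


def write_cellmatrix(adata: ad.AnnData, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def read_cellmatrix(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx")).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes, name=None))
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index.name = None
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name=None)))


def write_segments_bed(segments: list[CopyNumberSegment], path) -> None:
    rows = [
        (s.chrom, s.start, s.end, s.major_cn, s.minor_cn, s.expected_major_fraction)
        for s in segments
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "major_cn", "minor_cn", "expected_major_fraction"],
    ).to_csv(path, sep="\t", index=False, header=False)


def read_segments_bed(path) -> list[CopyNumberSegment]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "major_cn", "minor_cn", "expected_major_fraction"],
    )
    return [
        CopyNumberSegment(
            r.chrom, int(r.start), int(r.end), int(r.major_cn), int(r.minor_cn),
            float(r.expected_major_fraction) if not np.isnan(r.expected_major_fraction) else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
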