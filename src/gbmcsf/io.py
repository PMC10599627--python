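"""File-based exchange formats used between pipeline stages.

Single-cell datasets travel as an MTX triplet (``matrix.mtx`` genes x
cells, ``features.tsv``, ``barcodes.tsv``) plus ``cell_metadata.tsv``;
plate tables, spike tables and score tables as TSV/CSV; gene sets as GMT
(see :mod:`gbmcsf.genesets`).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["write_sc_dataset", "read_sc_dataset"]


def write_sc_dataset(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as an MTX triplet (genes x cells, the 10x convention)
    plus per-cell and per-gene metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    feats = adata.var.reset_index(names="gene")
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.reset_index(names="barcode").to_csv(
        outdir / "cell_metadata.tsv", sep="\t", index=False
    )
    return outdir


def read_sc_dataset(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = spio.mmread(str(indir / "matrix.mtx")).T.tocsr()
    feats = pd.read_csv(indir / "features.tsv", sep="\t")
    obs = pd.read_csv(indir / "cell_metadata.tsv", sep="\t").set_index("barcode")
    var = feats.set_index("gene")
    for col in ("is_mito", "is_housekeeping"):
        if col in var:
            var[col] = var[col].astype(bool)
    adata = ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)
    return adata
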