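"""Normalization, variable-gene selection, and per-cell program scores.

The central primitive is the control-bin module score: per cell, the mean
log-normalized expression of a gene set minus the mean expression of
expression-matched control genes.  Matching works by binning all genes into
``n_bins`` average-expression bins and sampling ``n_ctrl`` control genes
from the bin of each set gene, which cancels the coupling between a cell's
overall expression depth and any raw set average.  Cell-cycle (G1S, G2M),
proliferation (their mean), and quiescence scores with >=0 thresholds give
the Cycling/Quiescent labels.

Log-normalization (total-count scaling to 10,000, natural log1p) and
highly-variable-gene selection (mean-binned, z-scored dispersion) are
delegated to scanpy behind this module's interface.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats

__all__ = [
    "log_normalize",
    "select_hvg",
    "module_score",
    "proliferation_score",
    "cycle_labels",
    "fraction_expressing",
    "score_correlations",
]

LAYER = "lognorm"


def log_normalize(
    adata: ad.AnnData, scale_factor: float = 10_000.0, layer: str = LAYER
) -> ad.AnnData:
    """Total-count normalize and log-transform into ``adata.layers[layer]``.

    Per gene g and cell c: ``ln(1 + scale_factor * count(g,c) / total(c))``.
    A zero-total cell is an error (QC should have removed it).
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = adata.obs_names[np.flatnonzero(totals <= 0)].tolist()
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    tmp = ad.AnnData(X=X.copy(), obs=adata.obs[[]].copy(), var=adata.var[[]].copy())
    sc.pp.normalize_total(tmp, target_sum=scale_factor)
    sc.pp.log1p(tmp)
    adata.layers[layer] = tmp.X
    adata.uns["scale_factor"] = float(scale_factor)
    return adata


def select_hvg(adata: ad.AnnData, n: int = 2000, layer: str = LAYER) -> list[str]:
    """Top ``n`` highly variable genes by mean-binned normalized dispersion
    (20 mean bins, dispersion z-scored within bin), ties broken by gene
    order.  If fewer than ``n`` genes are present, all are returned with a
    warning."""
    if layer not in adata.layers:
        raise ValueError("run log_normalize first")
    if adata.n_vars <= n:
        if adata.n_vars < n:
            warnings.warn(f"only {adata.n_vars} genes available; returning all")
        return adata.var_names.tolist()
    tmp = ad.AnnData(X=adata.layers[layer].copy(), var=adata.var[[]].copy())
    sc.pp.highly_variable_genes(tmp, n_top_genes=n, flavor="seurat", n_bins=20)
    disp = tmp.var["dispersions_norm"].to_numpy()
    # stable sort on -dispersion keeps gene order as the tie-break
    order = np.argsort(-disp, kind="stable")[:n]
    return adata.var_names[np.sort(order)].tolist()


def _dense_layer(adata: ad.AnnData, layer: str) -> np.ndarray:
    X = adata.layers[layer] if layer in adata.layers else adata.X
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def module_score(
    adata: ad.AnnData,
    gene_set: Iterable[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = LAYER,
) -> np.ndarray:
    """Control-bin module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of average
    expression across cells; for each set gene, ``n_ctrl`` control genes
    are sampled from its bin (with replacement when the bin is smaller than
    ``n_ctrl``).  Score(c) = mean expression of the set genes minus mean
    expression of the pooled control draw.  Set genes absent from the
    matrix are dropped with a warning; an empty intersection is an error.
    The sampled controls (hence the score) are reproducible from ``seed``.
    """
    if layer not in adata.layers and layer != "X":
        raise ValueError("run log_normalize first")
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} set genes absent; dropped")
    X = _dense_layer(adata, layer)
    var_index = pd.Index(adata.var_names)
    avg = X.mean(axis=0)
    # equal-frequency binning on average expression (random jitter-free:
    # rank with average ties then integer bins)
    ranks = stats.rankdata(avg, method="average")
    bins = np.minimum((ranks - 1) / len(ranks) * n_bins, n_bins - 1).astype(int)
    rng = np.random.default_rng(seed)
    set_idx = var_index.get_indexer(sorted(present))
    ctrl_idx = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        replace = len(pool) < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_idx)
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def proliferation_score(g1s: np.ndarray, g2m: np.ndarray) -> np.ndarray:
    """Proliferation score: the average of the G1S and G2M scores."""
    return (np.asarray(g1s, float) + np.asarray(g2m, float)) / 2.0


def cycle_labels(
    scores: pd.DataFrame, mode: str = "average"
) -> pd.DataFrame:
    """Cycling / Quiescent labels from per-cell scores.

    ``scores`` needs columns ``G1S``, ``G2M`` and optionally
    ``quiescence``.  Default mode ``"average"``: Cycling iff the
    proliferation score (mean of G1S, G2M) is >= 0.  Alternate mode
    ``"max"``: Cycling iff G1S > 0 or G2M > 0 (strict, so cells with both
    scores exactly 0 fall to NonCycling under this convention).  Quiescent
    iff the quiescence score is >= 0.
    """
    if mode not in ("average", "max"):
        raise ValueError(f"unknown cycling mode {mode!r}")
    out = pd.DataFrame(index=scores.index)
    prolif = proliferation_score(scores["G1S"].to_numpy(), scores["G2M"].to_numpy())
    out["proliferation"] = prolif
    if mode == "average":
        cycling = prolif >= 0
    else:
        cycling = (scores["G1S"].to_numpy() > 0) | (scores["G2M"].to_numpy() > 0)
    out["cycling"] = np.where(cycling, "Cycling", "NonCycling")
    if "quiescence" in scores:
        out["quiescent"] = np.where(
            scores["quiescence"].to_numpy() >= 0, "Quiescent", "NonQuiescent"
        )
    return out


def fraction_expressing(
    adata: ad.AnnData,
    gene: str,
    cells: Sequence[str] | np.ndarray | None = None,
    layer: str = LAYER,
) -> float:
    """Fraction of the group's cells with nonzero (normalized) expression."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present")
    sub = adata if cells is None else adata[list(cells)]
    if sub.n_obs == 0:
        raise ValueError("empty cell group")
    X = sub.layers[layer] if layer in sub.layers else sub.X
    col = X[:, sub.var_names.get_loc(gene)]
    col = col.toarray().ravel() if sparse.issparse(col) else np.asarray(col).ravel()
    return float((col > 0).mean())


def score_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between every pair of score columns.

    Diagonal is 1; a constant column yields NaN entries (undefined rank
    correlation), reported as missing.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 cells")
    cols = list(scores.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            x, y = scores[a].to_numpy(float), scores[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(x, y).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out
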