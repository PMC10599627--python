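"""Single-cell quality control: prefiltering, outlier tagging, balancing.

Three stages mirror the preprocessing of a multi-patient GM/CSF single-cell
experiment:

1. :func:`prefilter` — drop near-empty droplets (cells expressing fewer
   than 200 genes) and genes seen in fewer than 3 cells, iterated to a
   fixed point so the output satisfies both rules simultaneously.
2. :func:`flag_outliers` — tag cells violating any of four per-cell
   criteria: too many reads (default >55,000, per-line overrides allowed),
   too few detected genes, too few detected housekeeping genes (<70 of a
   98-gene list), or too high a mitochondrial read fraction (>20%).
3. :func:`balance_conditions` — within each patient line, subsample the
   larger condition so GM and CSF hold equal cell numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "QCThresholds",
    "annotate_qc_metrics",
    "prefilter",
    "flag_outliers",
    "balance_conditions",
    "qc_report",
]

OUTLIER_CRITERIA = ("reads", "genes", "housekeeping", "mito")


@dataclass
class QCThresholds:
    """Per-cell QC thresholds with optional per-line overrides.

    Defaults are the published values for a whole-transcriptome panel; the
    override maps allow line-specific limits (e.g. a deeper-sequenced line
    tolerating more reads, or a low-complexity line with a lower gene
    floor).
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_reads: int = 55_000
    max_reads_overrides: dict[str, int] = field(default_factory=dict)
    min_genes_outlier: int = 2_000
    min_genes_overrides: dict[str, int] = field(default_factory=dict)
    min_housekeeping: int = 70
    housekeeping_list_size: int = 98
    max_mito_fraction: float = 0.20

    def validate(self, lines: set[str] | None = None) -> None:
        for name in (
            "min_genes_per_cell",
            "min_cells_per_gene",
            "max_reads",
            "min_genes_outlier",
            "min_housekeeping",
            "housekeeping_list_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if lines is not None:
            for omap in (self.max_reads_overrides, self.min_genes_overrides):
                unknown = set(omap) - lines
                if unknown:
                    raise ValueError(
                        f"threshold overrides for unknown lines: {sorted(unknown)}"
                    )


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    return X.tocsr()


def annotate_qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Compute per-cell QC metrics into ``obs``: total reads, detected
    genes, detected housekeeping genes, and mitochondrial read fraction
    (mito counts over total counts, from raw counts)."""
    X = _counts(adata)
    adata.obs["n_reads"] = np.asarray(X.sum(axis=1)).ravel().astype(int)
    adata.obs["n_genes"] = np.asarray((X > 0).sum(axis=1)).ravel().astype(int)
    for col in ("is_mito", "is_housekeeping"):
        if col not in adata.var:
            adata.var[col] = False
    hk = adata.var["is_housekeeping"].to_numpy(bool)
    mito = adata.var["is_mito"].to_numpy(bool)
    adata.obs["n_housekeeping"] = (
        np.asarray((X[:, hk] > 0).sum(axis=1)).ravel().astype(int) if hk.any() else 0
    )
    total = np.maximum(adata.obs["n_reads"].to_numpy(float), 1.0)
    mito_reads = (
        np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
    )
    adata.obs["mito_fraction"] = mito_reads / total
    return adata


def prefilter(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Remove near-empty cells and rarely seen genes.

    Cells are filtered first (>= ``min_genes_per_cell`` detected genes),
    then genes (detected in >= ``min_cells_per_gene`` cells), iterating
    both passes until a fixed point so the returned matrix satisfies both
    rules simultaneously.  An empty result is returned with a warning.
    """
    t = thresholds or QCThresholds()
    out = adata
    while True:
        X = _counts(out)
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
        keep_cells = genes_per_cell >= t.min_genes_per_cell
        out = out[keep_cells].copy() if not keep_cells.all() else out
        X = _counts(out)
        cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
        keep_genes = cells_per_gene >= t.min_cells_per_gene
        changed_genes = not keep_genes.all()
        out = out[:, keep_genes].copy() if changed_genes else out
        if keep_cells.all() and not changed_genes:
            break
        if out.n_obs == 0 or out.n_vars == 0:
            warnings.warn("prefilter removed everything; returning empty matrix")
            break
    return out.copy() if out is adata else out


def flag_outliers(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Tag outlier cells; returns a DataFrame indexed like ``obs`` with a
    boolean ``outlier`` column and a ``reasons`` column listing every
    violated criterion (comma-separated reason codes).

    A cell is an outlier iff it violates ANY of: reads above the (per-line)
    maximum, detected genes below the (per-line) floor, housekeeping genes
    below ``min_housekeeping``, or mito fraction above
    ``max_mito_fraction``.
    """
    t = thresholds or QCThresholds()
    if "line" in adata.obs:
        t.validate(set(adata.obs["line"].astype(str)))
    else:
        t.validate()
    needed = ("n_reads", "n_genes", "n_housekeeping", "mito_fraction")
    if any(c not in adata.obs for c in needed):
        annotate_qc_metrics(adata)
    lines = (
        adata.obs["line"].astype(str).to_numpy()
        if "line" in adata.obs
        else np.array(["?"] * adata.n_obs)
    )
    max_reads = np.array([t.max_reads_overrides.get(l, t.max_reads) for l in lines])
    min_genes = np.array([t.min_genes_overrides.get(l, t.min_genes_outlier) for l in lines])
    viol = {
        "reads": adata.obs["n_reads"].to_numpy() > max_reads,
        "genes": adata.obs["n_genes"].to_numpy() < min_genes,
        "housekeeping": adata.obs["n_housekeeping"].to_numpy() < t.min_housekeeping,
        "mito": adata.obs["mito_fraction"].to_numpy() > t.max_mito_fraction,
    }
    any_viol = np.zeros(adata.n_obs, dtype=bool)
    reasons = [[] for _ in range(adata.n_obs)]
    for code in OUTLIER_CRITERIA:
        any_viol |= viol[code]
        for i in np.flatnonzero(viol[code]):
            reasons[i].append(code)
    return pd.DataFrame(
        {"outlier": any_viol, "reasons": [",".join(r) for r in reasons]},
        index=adata.obs_names,
    )


def balance_conditions(adata: ad.AnnData, seed: int = 0) -> ad.AnnData:
    """Within each line, subsample so GM and CSF hold min(nGM, nCSF) cells
    each, uniformly without replacement; cells' data are never mutated."""
    if "line" not in adata.obs or "condition" not in adata.obs:
        raise ValueError("obs must carry 'line' and 'condition'")
    if adata.n_obs == 0:
        raise ValueError("no cells left to balance")
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for line in sorted(set(adata.obs["line"].astype(str))):
        in_line = adata.obs["line"].astype(str).to_numpy() == line
        idx = {}
        for cond in ("GM", "CSF"):
            sel = np.flatnonzero(
                in_line & (adata.obs["condition"].astype(str).to_numpy() == cond)
            )
            if sel.size == 0:
                raise ValueError(f"line {line!r} has no cells in condition {cond!r}")
            idx[cond] = sel
        n = min(len(idx["GM"]), len(idx["CSF"]))
        for cond in ("GM", "CSF"):
            sel = idx[cond]
            if len(sel) > n:
                sel = rng.choice(sel, size=n, replace=False)
            keep_idx.append(np.sort(sel))
    keep = np.sort(np.concatenate(keep_idx))
    return adata[keep].copy()


def qc_report(
    adata_before: ad.AnnData, adata_after: ad.AnnData, flags: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-line retained-cell counts and outlier reason tallies."""
    rows = []
    for line in sorted(set(adata_before.obs.get("line", pd.Series(["?"])).astype(str))):
        before = (adata_before.obs["line"].astype(str) == line).sum() if "line" in adata_before.obs else adata_before.n_obs
        after = (adata_after.obs["line"].astype(str) == line).sum() if "line" in adata_after.obs else adata_after.n_obs
        row = {"line": line, "cells_before": int(before), "cells_after": int(after)}
        if flags is not None and "line" in adata_before.obs:
            sub = flags.loc[adata_before.obs_names[adata_before.obs["line"].astype(str) == line]]
            for code in OUTLIER_CRITERIA:
                row[f"outlier_{code}"] = int(sub["reasons"].str.contains(code).sum())
        rows.append(row)
    return pd.DataFrame(rows)
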