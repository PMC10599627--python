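"""Two-condition differential expression with balanced downsampling.

The comparison of interest is CSF vs GM on log-normalized expression:

* :func:`downsample_balanced` — exactly ``quota`` cells per condition per
  patient line (700 by default, so a 10-line dataset yields 14,000 cells,
  7,000 per condition), sampled uniformly without replacement.
* :func:`wilcoxon_de` — per-gene two-sided Wilcoxon rank-sum test.  Exact
  enumeration of the rank-sum distribution is used when both groups have
  at most 8 cells; above that, the normal approximation with tie
  correction and continuity correction.  Fold changes follow the
  exponentiated-mean convention with pseudocount 1:
  ``log2(mean(expm1 x_CSF) + 1) - log2(mean(expm1 x_GM) + 1)``.
  P values are Bonferroni-corrected over all tested genes and each gene
  gets a rank score ``sign(log2FC) * -log10(p_adj)`` for preranked GSEA.
* :func:`rank_and_topk` — the top-k genes by log2 fold change in each
  direction, tie-broken by gene id.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "downsample_balanced",
    "wilcoxon_de",
    "rank_and_topk",
    "write_rnk",
    "exact_ranksum_p",
]

EXACT_MAX_N = 8


def downsample_balanced(
    adata: ad.AnnData, per_cell_quota: int = 700, seed: int = 0
) -> ad.AnnData:
    """Uniform, seed-reproducible downsampling to exactly ``per_cell_quota``
    cells per condition per line; a line below quota is an error naming the
    line and its counts."""
    rng = np.random.default_rng(seed)
    lines = sorted(set(adata.obs["line"].astype(str)))
    keep: list[np.ndarray] = []
    line_arr = adata.obs["line"].astype(str).to_numpy()
    cond_arr = adata.obs["condition"].astype(str).to_numpy()
    for line in lines:
        for cond in ("GM", "CSF"):
            sel = np.flatnonzero((line_arr == line) & (cond_arr == cond))
            if sel.size < per_cell_quota:
                raise ValueError(
                    f"line {line!r} has {sel.size} {cond} cells, "
                    f"below the quota of {per_cell_quota}"
                )
            if sel.size > per_cell_quota:
                sel = rng.choice(sel, size=per_cell_quota, replace=False)
            keep.append(np.sort(sel))
    return adata[np.sort(np.concatenate(keep))].copy()


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all rank assignments.

    Midranks handle ties; the p value is the fraction of the
    ``C(n1+n2, n1)`` equally likely subsets whose rank sum deviates from
    its null mean at least as much as the observed one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    t_obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    dev = abs(t_obs - mean) - 1e-9  # tolerance for float midranks
    hits = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= dev:
            hits += 1
    return hits / total


def _ranksum_normal_p(ranksum: np.ndarray, n1: int, n2: int, tie_term: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation p for group-1 rank sums, with tie
    correction and a 0.5 continuity correction."""
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    z = np.zeros_like(ranksum, dtype=float)
    nz = var > 0
    num = np.abs(ranksum - mean) - 0.5
    z[nz] = np.maximum(num[nz], 0.0) / np.sqrt(var[nz])
    p = np.where(nz, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def wilcoxon_de(
    adata: ad.AnnData,
    groupby: str = "condition",
    group: str = "CSF",
    reference: str = "GM",
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene CSF-vs-GM differential expression table.

    Returns a DataFrame indexed by gene with columns ``avg_log2FC``,
    ``pct_csf``/``pct_gm`` (expressing fractions), ``p``, ``p_adj``
    (Bonferroni over tested genes) and ``rank_score``; the number of cells
    per group and of tested genes are stored in ``df.attrs``.
    """
    labels = adata.obs[groupby].astype(str).to_numpy()
    g1 = labels == group
    g2 = labels == reference
    if g1.sum() == 0 or g2.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if min(g1.sum(), g2.sum()) < 3:
        raise ValueError("groups of fewer than 3 cells are not testable")
    X = adata.layers[layer] if layer in adata.layers else adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, float)
    X1, X2 = X[g1], X[g2]
    n1, n2 = X1.shape[0], X2.shape[0]

    expm1_1 = np.expm1(X1).mean(axis=0)
    expm1_2 = np.expm1(X2).mean(axis=0)
    log2fc = np.log2(expm1_1 + 1.0) - np.log2(expm1_2 + 1.0)
    pct1 = (X1 > 0).mean(axis=0)
    pct2 = (X2 > 0).mean(axis=0)

    if max(n1, n2) <= EXACT_MAX_N:
        p = np.array(
            [exact_ranksum_p(X1[:, j], X2[:, j]) for j in range(X.shape[1])]
        )
    else:
        both = np.vstack([X1, X2])
        ranks = stats.rankdata(both, axis=0)
        ranksum = ranks[:n1].sum(axis=0)
        # tie correction: sum of (t^3 - t) over tie groups, per gene
        srt = np.sort(both, axis=0)
        tie_term = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            _, counts = np.unique(srt[:, j], return_counts=True)
            tie_term[j] = (counts**3 - counts).sum()
        p = _ranksum_normal_p(ranksum, n1, n2, tie_term)

    n_tested = X.shape[1]
    p_adj = np.minimum(p * n_tested, 1.0)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(p_adj, 1e-300))
    rank_score = np.sign(log2fc) * neglog

    df = pd.DataFrame(
        {
            "avg_log2FC": log2fc,
            "pct_csf": pct1,
            "pct_gm": pct2,
            "p": p,
            "p_adj": p_adj,
            "rank_score": rank_score,
        },
        index=adata.var_names,
    )
    df.attrs.update({"n_group": int(n1), "n_reference": int(n2), "n_tested": int(n_tested)})
    return df


def rank_and_topk(det: pd.DataFrame, k: int = 20) -> tuple[list[str], list[str]]:
    """Top-k genes by average log2FC in each direction.

    Returns ``(up_in_csf, up_in_gm)``; ties broken by gene id so the lists
    are deterministic.  If ``k`` exceeds the table size, all genes are
    returned with a warning.
    """
    if k > len(det):
        warnings.warn(f"k={k} exceeds {len(det)} genes; returning all")
        k = len(det)
    # stable sort on the secondary key first gives the gene-id tie-break
    byid = det.sort_index(kind="stable")
    up = byid.sort_values("avg_log2FC", ascending=False, kind="stable").index[:k].tolist()
    down = byid.sort_values("avg_log2FC", ascending=True, kind="stable").index[:k].tolist()
    return up, down


def write_rnk(det: pd.DataFrame, path) -> None:
    """Write the 2-column RNK-compatible rank file (gene, rank_score),
    ordered by rank score descending with gene-id tie-break."""
    byid = det.sort_index(kind="stable")
    ordered = byid.sort_values("rank_score", ascending=False, kind="stable")
    ordered["rank_score"].to_csv(path, sep="\t", header=False)
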