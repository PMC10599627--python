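"""Preranked gene-set enrichment analysis (GSEA).

Given a gene list ranked by a signed score (here
``sign(log2FC) * -log10(p_adj)`` from the differential-expression stage)
and a gene set, the weighted enrichment statistic walks the ranked list
accumulating ``|r|^p / N_R`` at set genes (hits, ``N_R`` the sum of
``|r|^p`` over set genes) and ``-1/(N - N_H)`` at non-set genes.  The
enrichment score (ES) is the running sum's maximum signed deviation from
zero; the leading edge contains the set genes at or before the extremum
(at or after it, for negative ES).

Significance comes from gene-set permutations: null ES values of random
same-size sets drawn from the ranked genes.  NES divides ES by the mean
magnitude of same-sign null ES values ("meandiv"); the permutation p uses
the add-one estimator so it is never exactly zero; the FDR q across
multiple sets follows the pooled-NES procedure (Benjamini-Hochberg over
permutation p values is the single-set fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

__all__ = [
    "RankedList",
    "GSEAResult",
    "enrichment_score",
    "permutation_test",
    "gsea_collection",
    "read_rnk",
]


@dataclass
class RankedList:
    """Genes ordered by rank score descending, ties broken by gene id."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores differ in length")
        if len(set(genes.tolist())) != len(genes):
            raise ValueError("duplicate genes in ranked list")
        # deterministic order: score descending, then gene id ascending
        order = np.lexsort((genes, -scores))
        self.genes = genes[order]
        self.scores = scores[order]
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set) -> np.ndarray:
        pos = np.array([self._index[g] for g in gene_set if g in self._index], int)
        return np.sort(pos)


def read_rnk(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return RankedList(df["gene"].to_numpy(object), df["score"].to_numpy(float))


def _es_from_positions(
    pos: np.ndarray, absr: np.ndarray, n: int, weight: float = 1.0,
    degenerate: str = "error",
) -> tuple[float, int]:
    """ES and extremum position for hits at sorted positions ``pos``.

    O(n_hits): between hits the running sum decays linearly, so its
    extrema can only occur just after a hit or just before the next hit.
    A draw whose hits all carry zero rank score has no weighted statistic;
    ``degenerate="uniform"`` falls back to uniform hit weights (the
    unweighted statistic) for such permutation draws.
    """
    k = len(pos)
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = absr[pos] ** weight
    nr = w.sum()
    if nr == 0:
        if degenerate != "uniform":
            raise ValueError("degenerate ranks: all set genes have zero score")
        w = np.ones(k)
        nr = float(k)
    miss = 1.0 / (n - k)
    cum_hit = np.cumsum(w) / nr
    # running sum immediately after hit i (0-based): hits so far minus
    # misses so far; misses before-and-at pos[i] = pos[i] + 1 - (i + 1)
    after = cum_hit - (pos - np.arange(k)) * miss
    # minimum just before hit i: hits before i minus misses before pos[i]
    before = np.concatenate(([0.0], cum_hit[:-1])) - (pos - np.arange(k)) * miss
    candidates = np.concatenate((after, before))
    # list position of each candidate: just after hit i -> pos[i];
    # just before hit i -> pos[i] - 1
    cand_pos = np.concatenate((pos, pos - 1))
    amax = np.abs(candidates).max()
    # ties between the positive and negative extremum are broken by walk
    # order: the extremum reached earliest in the ranked list wins
    tied = np.flatnonzero(np.abs(candidates) >= amax - 1e-12)
    i_ext = int(tied[np.argmin(cand_pos[tied])])
    es = float(candidates[i_ext])
    ext_pos = int(cand_pos[i_ext])
    return es, ext_pos


def enrichment_score(
    rl: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted enrichment score, full running sum, and leading edge.

    Returns ``(ES, running_sum, leading_edge)`` where ``running_sum`` has
    one value per ranked gene (after processing that gene).
    """
    pos = rl.positions(gene_set)
    if len(pos) == 0:
        raise ValueError("gene set has no gene in the ranked list")
    n = len(rl)
    absr = np.abs(rl.scores)
    es, ext = _es_from_positions(pos, absr, n, weight)
    # explicit running sum for traces and tests
    steps = np.full(n, -1.0 / (n - len(pos)))
    w = absr[pos] ** weight
    steps[pos] = w / w.sum()
    running = np.cumsum(steps)
    if es >= 0:
        leading = [g for g in rl.genes[: ext + 1] if g in set(gene_set)]
    else:
        leading = [g for g in rl.genes[ext + 1 :] if g in set(gene_set)]
    return es, running, leading


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    null_es: np.ndarray | None = None


def _null_es(
    rl: RankedList, set_size: int, n_perm: int, seed: int, weight: float = 1.0
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = len(rl)
    absr = np.abs(rl.scores)
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        out[i], _ = _es_from_positions(pos, absr, n, weight, degenerate="uniform")
    return out


def permutation_test(
    rl: RankedList,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    set_name: str = "set",
) -> GSEAResult:
    """Gene-set permutation test for one set.

    Null ES values come from ``n_perm`` random same-size gene sets drawn
    from the ranked genes.  ``NES = ES / mean(|null ES| same sign)``;
    ``p = (1 + #{same-sign |null| >= |ES|}) / (1 + #same-sign)``.  The
    single-set FDR q is the Benjamini-Hochberg fallback (= p here);
    :func:`gsea_collection` replaces it with the pooled-NES q when several
    sets are tested together.
    """
    es, _, leading = enrichment_score(rl, gene_set, weight)
    pos = rl.positions(gene_set)
    null = _null_es(rl, len(pos), n_perm, seed, weight)
    same = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    n_same = int(same.sum())
    if n_same == 0:
        warnings.warn(
            f"{set_name}: no same-sign permutation ES; p reported at floor"
        )
        p = 1.0 / (n_perm + 1)
        nes = np.sign(es) * np.inf if es != 0 else 0.0
    else:
        p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        denom = np.abs(null[same]).mean()
        nes = es / denom if denom > 0 else 0.0
    return GSEAResult(
        set_name=set_name,
        es=float(es),
        nes=float(nes),
        p_perm=float(p),
        fdr_q=float(p),
        leading_edge=leading,
        n_permutations=n_perm,
        null_es=null,
    )


def gsea_collection(
    rl: RankedList,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Run the permutation test for every set in a collection.

    With two or more sets, FDR q values follow the pooled-NES procedure:
    all null ES are normalized to null NES by the same-sign meandiv
    denominators, pooled across sets, and q(set) is the ratio of the null
    tail fraction to the observed tail fraction at |NES(set)|, clipped to
    [0, 1] and made monotone.
    """
    results = [
        permutation_test(
            rl, gsc[name], n_perm=n_perm, seed=seed + i, weight=weight, set_name=name
        )
        for i, name in enumerate(gsc.names())
    ]
    if len(results) >= 2:
        pooled = []
        for r in results:
            null = r.null_es
            for sign in (1.0, -1.0):
                sel = null * sign > 0
                if sel.sum():
                    denom = np.abs(null[sel]).mean()
                    pooled.append(null[sel] / denom)
        pooled = np.abs(np.concatenate(pooled)) if pooled else np.array([])
        obs = np.abs(np.array([r.nes for r in results]))
        for r in results:
            if not np.isfinite(r.nes) or pooled.size == 0:
                r.fdr_q = r.p_perm
                continue
            null_tail = (pooled >= abs(r.nes)).mean()
            obs_tail = (obs >= abs(r.nes)).mean()
            r.fdr_q = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0
        # enforce q non-decreasing as |NES| decreases (BH-style step-up)
        order = np.argsort(-obs)  # descending |NES| = descending significance
        qs = np.array([results[i].fdr_q for i in order])
        qs = np.minimum.accumulate(qs[::-1])[::-1]
        for q, idx in zip(qs, order):
            results[idx].fdr_q = float(q)
    rows = [
        {
            "set": r.set_name,
            "ES": r.es,
            "NES": r.nes,
            "p_perm": r.p_perm,
            "FDR_q": r.fdr_q,
            "n_leading_edge": len(r.leading_edge),
            "leading_edge": ",".join(map(str, r.leading_edge)),
            "n_permutations": r.n_permutations,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("set")
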