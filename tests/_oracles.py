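"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package: exhaustive
enumeration for the rank-sum test, a literal walk of the ranked list for
the enrichment score, and a sliding scan for burst detection.  They are
slow and simple on purpose.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def ranksum_exact_p_oracle(x, y) -> float:
    """Two-sided exact rank-sum p via the Mann-Whitney U statistic.

    Enumerates every group-1 subset of the pooled sample and counts pair
    wins (ties count half); the p value is the fraction of subsets whose U
    deviates from n1*n2/2 at least as much as the observed U.
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n1 = len(x)
    n = len(pooled)
    idx_all = set(range(n))

    def u_stat(g1_idx):
        g1 = pooled[list(g1_idx)]
        g2 = pooled[list(idx_all - set(g1_idx))]
        wins = sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)
        return wins

    u_obs = u_stat(range(n1))
    mean = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mean) - 1e-9
    hits = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(u_stat(comb) - mean) >= dev:
            hits += 1
    return hits / total


def gsea_es_oracle(genes_ranked, scores, gene_set, weight=1.0) -> float:
    """Weighted enrichment score by literally walking the ranked list."""
    gene_set = set(gene_set)
    absr = np.abs(np.asarray(scores, float))
    hit_mask = np.array([g in gene_set for g in genes_ranked])
    nr = (absr[hit_mask] ** weight).sum()
    n_miss = len(genes_ranked) - hit_mask.sum()
    running = 0.0
    best = 0.0
    for i, g in enumerate(genes_ranked):
        if hit_mask[i]:
            running += absr[i] ** weight / nr
        else:
            running -= 1.0 / n_miss
        # tolerance keeps the first-extremum convention stable against
        # float accumulation drift on exact positive/negative ties
        if abs(running) > abs(best) + 1e-12:
            best = running
    return best


def bursts_oracle(ts, min_spikes, max_isi):
    """Maximal qualifying runs by sliding scan: for every spike, try it as
    a run start (only valid if the preceding gap breaks the ISI rule),
    extend greedily, keep runs meeting the size minimum."""
    ts = np.asarray(ts, float)
    out = []
    i = 0
    n = len(ts)
    while i < n:
        if i > 0 and ts[i] - ts[i - 1] <= max_isi:
            i += 1
            continue
        j = i
        while j + 1 < n and ts[j + 1] - ts[j] <= max_isi:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((float(ts[i]), float(ts[j]), j - i + 1))
        i = j + 1
    return out


def spearman_oracle(x, y) -> float:
    """Rank correlation as Pearson correlation of midranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
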