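"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the definition of the statistic, naively and
without sharing code paths with the package.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode


def naive_etm(reactions, normalization="per_enzyme"):
    """ETM by plain accumulation loops: {enzyme: {metabolite: weight}}."""
    per_enzyme: dict[str, list] = {}
    for r in reactions:
        per_enzyme.setdefault(r.ec, []).append(r)
    out: dict[str, dict[str, float]] = {}
    for ec, rxns in per_enzyme.items():
        col: dict[str, float] = {}
        for r in rxns:
            for m, c in r.substrates:
                col[m] = col.get(m, 0.0) + c
            for m, c in r.products:
                col[m] = col.get(m, 0.0) - c
        if normalization == "per_enzyme":
            col = {m: v / len(rxns) for m, v in col.items()}
        out[ec] = col
    return out


def naive_prmt(etm_matrix, norm, reference):
    """PRMT scores by a triple loop over samples, metabolites and enzymes."""
    scores = np.zeros((norm.shape[0], etm_matrix.shape[0]))
    for si in range(norm.shape[0]):
        for mi, met in enumerate(etm_matrix.index):
            total = 0.0
            for e in etm_matrix.columns:
                if e in norm.columns:
                    total += etm_matrix.loc[met, e] * (norm.iloc[si][e] - reference[e])
            scores[si, mi] = total
    return scores


def rankdata_naive(values):
    """Average ranks with ties, from the definition."""
    values = np.asarray(values, float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def kruskal_h_naive(values, labels):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    n = len(values)
    ranks = rankdata_naive(values)
    h = 0.0
    for g in np.unique(labels):
        rg = ranks[labels == g]
        h += len(rg) * (rg.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else np.nan


def anosim_r_naive(dist, labels):
    """ANOSIM R from ranked pairwise distances."""
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = dist.shape[0]
    pairs, within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(dist[i, j])
            within.append(labels[i] == labels[j])
    ranks = rankdata_naive(pairs)
    within = np.asarray(within)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    m = n * (n - 1) / 2
    return (r_b - r_w) / (m / 2.0)


def weighted_unifrac_naive(counts_a, counts_b, taxa, newick, normalized=False):
    """Weighted UniFrac by per-branch summation over the parsed tree."""
    tree = TreeNode.read(io.StringIO(newick))
    pa = np.asarray(counts_a, float)
    pb = np.asarray(counts_b, float)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    abund_a = dict(zip(taxa, pa))
    abund_b = dict(zip(taxa, pb))
    d = 0.0
    denom = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            continue
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        wa = sum(abund_a.get(t, 0.0) for t in tips)
        wb = sum(abund_b.get(t, 0.0) for t in tips)
        d += node.length * abs(wa - wb)
        denom += node.length * (wa + wb)
    return d / denom if normalized else d


def mantel_exhaustive_p(d1, d2):
    """Exact one-tailed Mantel p over all permutations (small n only)."""
    from itertools import permutations

    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)

    def r(a, b):
        return np.corrcoef(a[iu], b[iu])[0, 1]

    r_obs = r(d1, d2)
    count = total = 0
    for perm in permutations(range(n)):
        total += 1
        if r(d1, d2[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    return count / total
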