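"""Community-structure statistics: rarefaction, beta diversity, matrix
correlation, ordination comparison, core extraction and per-feature tests.

Feature tables are samples x features DataFrames of nonnegative counts (or
relative abundances where noted).  Distance computations return
``skbio.DistanceMatrix`` (symmetric, zero-diagonal, validated).  Standard
procedures are delegated to scikit-bio/scipy behind this module's interface;
the wrappers add the input contracts and degenerate-case handling documented
per function.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import mantel as _skbio_mantel

from ._utils import DegenerateInputError, RiversedError, substream, warn


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class BestResult:
    """Best environmental-variable subset (BIO-ENV / BEST)."""

    variables: tuple[str, ...]
    rho: float
    table: pd.DataFrame


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class ProcrustesResult:
    m2: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates restricted to positive-eigenvalue axes."""

    coordinates: pd.DataFrame
    eigenvalues: pd.Series
    negative_fraction: float


@dataclass(frozen=True)
class CoreResult:
    features: tuple[str, ...]
    read_fraction: float


@dataclass(frozen=True)
class ZscoreResult:
    z: pd.DataFrame
    linkage: np.ndarray | None
    leaf_order: tuple[int, ...]
    constant_features: tuple[str, ...]


# ---------------------------------------------------------------------------
# rarefaction and beta diversity

def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample's counts without replacement to an even depth.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    """
    if depth <= 0:
        raise RiversedError(f"rarefaction depth must be > 0, got {depth}")
    rng = substream(seed, "rarefy")
    counts = table.to_numpy()
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise RiversedError("rarefaction requires nonnegative integer counts")
    keep, rows = [], []
    for i, sid in enumerate(table.index):
        total = int(counts[i].sum())
        if total < depth:
            warn(f"sample {sid} has {total} < {depth} reads; dropped")
            continue
        keep.append(sid)
        rows.append(rng.multivariate_hypergeometric(counts[i], depth))
    return pd.DataFrame(np.asarray(rows, dtype=int), index=keep, columns=table.columns)


def hellinger_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between square-rooted relative abundances (<= sqrt 2)."""
    arr = table.to_numpy(float)
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        bad = [str(s) for s, t in zip(table.index, totals) if t <= 0]
        raise RiversedError(f"zero-sum sample(s): {bad}")
    if (arr < 0).any():
        raise RiversedError("negative abundances")
    h = np.sqrt(arr / totals[:, None])
    return DistanceMatrix(squareform(pdist(h, metric="euclidean")), ids=[str(s) for s in table.index])


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode | str, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac distances over a rooted tree with branch lengths.

    Raw by default: ``d(A,B) = sum_b len(b) * |p_A(b) - p_B(b)|`` with ``p``
    the relative abundance descending from branch ``b``; ``normalized=True``
    divides by the abundance-weighted tree depth so distances are <= 1.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(map(str, table.columns)) - leaves)
    if missing:
        raise RiversedError(f"features missing from tree: {missing}")
    return beta_diversity(
        "weighted_unifrac",
        table.to_numpy(float),
        ids=[str(s) for s in table.index],
        taxa=[str(c) for c in table.columns],
        tree=tree,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# matrix correlation

def _upper(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    a = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def _check_pair(d1, d2) -> tuple[DistanceMatrix, DistanceMatrix]:
    if not isinstance(d1, DistanceMatrix):
        d1 = DistanceMatrix(np.asarray(d1, float))
    if not isinstance(d2, DistanceMatrix):
        d2 = DistanceMatrix(np.asarray(d2, float))
    if list(d1.ids) != list(d2.ids) or d1.shape != d2.shape:
        raise RiversedError("distance matrices have mismatched sample ids")
    return d1, d2


def mantel(d1, d2, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """One-tailed Mantel test (Pearson r of upper triangles, permutation p).

    p uses the conservative +1 correction; permutations shuffle rows and
    columns of the second matrix simultaneously.
    """
    if n_perm < 99:
        raise RiversedError("n_perm must be >= 99")
    d1, d2 = _check_pair(d1, d2)
    for d in (d1, d2):
        if np.std(_upper(d)) == 0:
            raise DegenerateInputError("distance matrix has zero variance")
    r, p, _ = _skbio_mantel(
        d1, d2, method="pearson", permutations=n_perm, alternative="greater", seed=seed
    )
    return MantelResult(r=float(r), p=float(p), n_perm=n_perm)


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    if 1 - rxz**2 <= 1e-15:
        # x is (anti)collinear with the control: nothing left to correlate
        raise DegenerateInputError("first matrix is collinear with the control matrix")
    if 1 - ryz**2 <= 1e-15:
        # controlling for a copy of y removes all of y's signal
        return 0.0
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def partial_mantel(d1, d2, d_control, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """Partial Mantel: correlation of d1 and d2 controlling for a third matrix.

    First-order partial Pearson correlation of upper triangles; the null
    distribution permutes rows/columns of ``d2``.
    """
    if n_perm < 99:
        raise RiversedError("n_perm must be >= 99")
    d1, d2 = _check_pair(d1, d2)
    d1, dc = _check_pair(d1, d_control)
    for d in (d1, d2, dc):
        if np.std(_upper(d)) == 0:
            raise DegenerateInputError("distance matrix has zero variance")
    x, z = _upper(d1), _upper(dc)
    r_obs = _partial_r(x, _upper(d2), z)
    rng = substream(0 if seed is None else seed, "partial_mantel")
    n = d2.shape[0]
    a2 = d2.data
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = a2[np.ix_(perm, perm)]
        if _partial_r(x, _upper(DistanceMatrix(yp)), z) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=float(r_obs), p=float(p), n_perm=n_perm)


def best_env(d_community, env: pd.DataFrame) -> BestResult:
    """BEST / BIO-ENV: exhaustive environmental-variable subset search.

    Variables are z-scored, each non-empty subset converted to a Euclidean
    distance matrix, and the subset whose distances best Spearman-rank
    correlate with the community distances is returned together with the full
    per-subset table.  Ties prefer smaller subsets.
    """
    if not isinstance(d_community, DistanceMatrix):
        d_community = DistanceMatrix(np.asarray(d_community, float))
    if env.shape[1] < 1:
        raise RiversedError("need at least one environmental variable")
    if env.shape[1] > 20:
        raise RiversedError("refusing exhaustive search over > 20 variables")
    if env.shape[0] != d_community.shape[0]:
        raise RiversedError("environmental table and distance matrix differ in samples")
    z = (env - env.mean()) / env.std(ddof=1)
    if z.isna().to_numpy().any():
        bad = [c for c in env.columns if env[c].std(ddof=1) == 0]
        raise DegenerateInputError(f"constant environmental variable(s): {bad}")
    comm = _upper(d_community)
    rows = []
    cols = list(env.columns)
    for k in range(1, len(cols) + 1):
        for subset in combinations(cols, k):
            ed = pdist(z[list(subset)].to_numpy(float), metric="euclidean")
            rho = stats.spearmanr(comm, ed).statistic
            rows.append(dict(variables=",".join(subset), size=k, rho=float(rho)))
    table = pd.DataFrame(rows)
    best = table.sort_values(["rho", "size"], ascending=[False, True], kind="mergesort").iloc[0]
    return BestResult(
        variables=tuple(best["variables"].split(",")),
        rho=float(best["rho"]),
        table=table.sort_values("rho", ascending=False, kind="mergesort").reset_index(drop=True),
    )


def anosim(d, groups, n_perm: int = 999, seed: int | None = None) -> AnosimResult:
    """ANOSIM R (rank-based between- vs within-group contrast) with permutation p."""
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d, float))
    groups = list(groups)
    if len(groups) != d.shape[0]:
        raise RiversedError("one group label per sample required")
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise DegenerateInputError("ANOSIM requires >= 2 groups")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise DegenerateInputError(f"singleton group(s): {small}")
    res = _skbio_anosim(d, groups, permutations=n_perm, seed=seed)
    return AnosimResult(R=float(res["test statistic"]), p=float(res["p-value"]), n_perm=n_perm)


# ---------------------------------------------------------------------------
# ordination

def pcoa(d) -> PCoAResult:
    """Principal coordinates (Gower-centred eigendecomposition).

    Axes with negative eigenvalues are dropped with a warning recording the
    fraction of (absolute) variance lost; no Lingoes/Cailliez correction.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d, float))
    a = -0.5 * d.data**2
    n = a.shape[0]
    center = np.eye(n) - np.full((n, n), 1.0 / n)
    b = center @ a @ center
    eig, vec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    tol = 1e-12 * max(1.0, np.abs(eig).max())
    pos = eig > tol
    total = np.abs(eig[np.abs(eig) > tol]).sum()
    neg_frac = float(np.abs(eig[eig < -tol]).sum() / total) if total else 0.0
    if neg_frac > 0:
        warn(f"dropped negative-eigenvalue axes; lost variance fraction {neg_frac:.4f}")
    coords = vec[:, pos] * np.sqrt(eig[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=axes),
        eigenvalues=pd.Series(eig[pos], index=axes),
        negative_fraction=neg_frac,
    )


def procrustes(
    x: pd.DataFrame, y: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> ProcrustesResult:
    """Procrustes superimposition with a PROTEST-style permutation test.

    M2 is the residual sum of squares after translating, scaling and
    rotating/reflecting the unit-trace configurations; p permutes the row
    order of ``y`` and counts permutations with M2 at least as small.
    """
    xi = list(map(str, x.index))
    yi = list(map(str, y.index))
    if set(xi) != set(yi):
        raise RiversedError("ordinations cover different sample ids")
    y = y.loc[[i for i in x.index]] if xi != yi else y
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape[0] < 3:
        raise RiversedError("Procrustes needs >= 3 samples")
    k = max(xa.shape[1], ya.shape[1])
    xa = np.pad(xa, ((0, 0), (0, k - xa.shape[1])))
    ya = np.pad(ya, ((0, 0), (0, k - ya.shape[1])))
    _, _, m2 = _scipy_procrustes(xa, ya)
    rng = substream(0 if seed is None else seed, "procrustes")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(xa.shape[0])
        _, _, m2p = _scipy_procrustes(xa, ya[perm])
        if m2p <= m2:
            count += 1
    return ProcrustesResult(m2=float(m2), p=(1 + count) / (1 + n_perm), n_perm=n_perm)


# ---------------------------------------------------------------------------
# core community, per-feature tests, profiles

def core_features(
    table: pd.DataFrame, min_total_reads: int = 200, per_sample: bool = False
) -> CoreResult:
    """Features present in every sample and abundant above a read threshold.

    Default rule: nonzero in all samples and total count across the dataset
    strictly greater than ``min_total_reads``.  With ``per_sample=True`` the
    threshold applies to every sample's count instead of the total.
    """
    present = (table > 0).all(axis=0)
    if per_sample:
        abundant = (table > min_total_reads).all(axis=0)
    else:
        abundant = table.sum(axis=0) > min_total_reads
    mask = present & abundant
    feats = tuple(table.columns[mask])
    total = float(table.to_numpy().sum())
    frac = float(table.loc[:, mask].to_numpy().sum() / total) if total else 0.0
    return CoreResult(features=feats, read_fraction=frac)


def per_feature_anova(
    table: pd.DataFrame,
    groups,
    relative: bool = False,
    min_total_reads: int | None = None,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature with Bonferroni correction.

    Bonferroni multiplies raw p by the number of features actually tested
    (after the optional minimum-total-reads filter).  Features whose groups
    all have zero within-group variance get NA p-values and a degenerate
    flag.
    """
    labels = np.asarray(list(groups))
    if len(labels) != table.shape[0]:
        raise RiversedError("one group label per sample required")
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise DegenerateInputError("ANOVA requires >= 2 groups with >= 2 members each")
    data = table.copy()
    if min_total_reads is not None:
        data = data.loc[:, data.sum(axis=0) > min_total_reads]
    if relative:
        data = data.div(table.sum(axis=1), axis=0)
    n_tested = data.shape[1]
    uniq = pd.unique(labels)
    rows = []
    for feat in data.columns:
        v = data[feat].to_numpy(float)
        gs = [v[labels == g] for g in uniq]
        if all(np.var(g) == 0 for g in gs):
            rows.append(dict(feature=feat, F=np.nan, p=np.nan, degenerate=True))
            continue
        res = stats.f_oneway(*gs)
        rows.append(dict(feature=feat, F=float(res.statistic), p=float(res.pvalue), degenerate=False))
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * n_tested, 1.0)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out.sort_values("p", kind="mergesort", na_position="last").reset_index(drop=True)


def zscore_profiles(site_means: pd.DataFrame) -> ZscoreResult:
    """Z-score each feature's profile across sites and cluster the profiles.

    Rows are features, columns sites.  Z uses the sample standard deviation
    (ddof=1); constant profiles become rows of zeros and are flagged.
    Clustering is average-linkage on Euclidean distances between Z-profiles.
    """
    if site_means.shape[1] < 2:
        raise RiversedError("z-scoring needs >= 2 sites per feature")
    arr = site_means.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (arr - mean) / sd
    z[constant] = 0.0
    flagged = tuple(site_means.index[constant])
    if flagged:
        warn(f"{len(flagged)} constant feature profile(s) z-scored to zeros")
    zdf = pd.DataFrame(z, index=site_means.index, columns=site_means.columns)
    if zdf.shape[0] >= 2:
        link = hierarchy.linkage(z, method="average", metric="euclidean")
        order = tuple(int(i) for i in hierarchy.leaves_list(link))
    else:
        link, order = None, (0,)
    return ZscoreResult(z=zdf, linkage=link, leaf_order=order, constant_features=flagged)
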