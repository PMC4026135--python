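"""Pathway-level aggregation of PRMT scores and group testing.

For each analysis unit and pathway, positive member-metabolite scores are
summed into a 'net positive' value (predicted consumption), negative scores
into a 'net negative' value (predicted accumulation), and their sum is the
'net flow'.  Group differences in net flow are tested per pathway with a
Kruskal-Wallis rank test; p-values are unadjusted by default (a
Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import DegenerateInputError, RiversedError, warn
from .reactions import PathwayMap


def pathway_flows(scores: pd.DataFrame, pmap: PathwayMap) -> pd.DataFrame:
    """Aggregate unit x metabolite scores into per-pathway flow records.

    Returns a tidy frame with columns ``pathway, unit, net_positive,
    net_negative, net_flow``.  A metabolite in k pathways contributes to all
    k; pathways with no scored metabolite are omitted with a warning.
    """
    if len(pmap) == 0:
        raise RiversedError("pathway map is empty")
    scored = set(scores.columns)
    records = []
    for pw in pmap.pathways:
        members = [m for m in pmap.members(pw) if m in scored]
        if not members:
            warn(f"pathway {pw} has no scored metabolites; omitted")
            continue
        sub = scores[members].to_numpy(float)
        pos = np.where(sub > 0, sub, 0.0).sum(axis=1)
        neg = np.where(sub < 0, sub, 0.0).sum(axis=1)
        for unit, p, n in zip(scores.index, pos, neg):
            records.append(
                dict(pathway=pw, unit=unit, net_positive=p, net_negative=n, net_flow=p + n)
            )
    return pd.DataFrame.from_records(
        records, columns=["pathway", "unit", "net_positive", "net_negative", "net_flow"]
    )


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical values return ``(0.0, 1.0)`` (no evidence of difference);
    a single group is an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise RiversedError("values and labels must have equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise DegenerateInputError("Kruskal-Wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DegenerateInputError("every group needs >= 1 value")
    if np.all(values == values[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _kw_h(values: np.ndarray, labels: np.ndarray) -> float:
    """H statistic alone (tie-corrected), tolerant of all-ties."""
    if np.all(values == values[0]):
        return 0.0
    groups = [values[labels == g] for g in pd.unique(labels)]
    return float(stats.kruskal(*groups).statistic)


def _exact_kw_pvalue(values: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p-value of H over all label arrangements (n <= 10)."""
    n = len(values)
    if n > 10:
        raise RiversedError("exact Kruskal-Wallis limited to n <= 10")
    h_obs = _kw_h(values, labels)
    count = 0
    total = 0
    for perm in set(permutations(labels.tolist())):
        total += 1
        if _kw_h(values, np.asarray(perm)) >= h_obs - 1e-12:
            count += 1
    return count / total


def group_pathway_tests(
    flows: pd.DataFrame,
    site_groups: dict[str, str],
    alpha: float = 0.05,
    adjust: str | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-pathway Kruskal-Wallis on unit net-flow values across groups.

    ``site_groups`` maps each unit's site (the prefix of the unit id before
    the first '.') or the unit id itself to a group label.  Results are
    sorted by p-value; ``adjust='bh'`` adds Benjamini-Hochberg q-values
    (significance then uses the adjusted value).
    """
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment '{adjust}'")
    units = flows["unit"].unique()

    def unit_group(u: str) -> str:
        if u in site_groups:
            return site_groups[u]
        site = str(u).split(".", 1)[0]
        if site not in site_groups:
            raise RiversedError(f"unit '{u}' has no group assignment")
        return site_groups[site]

    glabels = {u: unit_group(u) for u in units}
    counts = pd.Series(list(glabels.values())).value_counts()
    for g in set(site_groups.values()):
        if g not in counts.index:
            raise RiversedError(f"group '{g}' has zero units")
    rows = []
    for pw, sub in flows.groupby("pathway", sort=True):
        vals = sub["net_flow"].to_numpy(float)
        labs = np.asarray([glabels[u] for u in sub["unit"]])
        h, p = kruskal_wallis(vals, labs)
        if exact:
            p = _exact_kw_pvalue(vals, labs)
        row = dict(pathway=pw, H=h, p=p)
        for g in sorted(set(labs)):
            row[f"mean_flow_{g}"] = float(vals[labs == g].mean())
        rows.append(row)
    res = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    if adjust == "bh":
        res["p_adjusted"] = _bh_adjust(res["p"].to_numpy())
        res["significant"] = res["p_adjusted"] < alpha
    else:
        res["significant"] = res["p"] < alpha
    return res


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_flow_results(
    tests: pd.DataFrame, flows: pd.DataFrame, site_groups: dict[str, str],
    results_path, edges_path,
) -> None:
    """Write the group-test table and a group/pathway edge list (mean flow, p)."""
    tests.to_csv(results_path, sep="\t", index=False, float_format="%.10g")
    glab = {
        u: site_groups.get(u, site_groups.get(str(u).split(".", 1)[0], "NA"))
        for u in flows["unit"].unique()
    }
    fl = flows.assign(group=flows["unit"].map(glab))
    edges = (
        fl.groupby(["group", "pathway"])["net_flow"].mean().rename("mean_flow").reset_index()
    )
    edges = edges.merge(tests[["pathway", "p"]], on="pathway", how="left")
    edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
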