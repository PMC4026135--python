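"""Synthetic study generator with planted, recoverable structure.

Emulates the data shapes of a river-sediment survey: a sample metadata table
with an environmental gradient, an OTU count table whose community similarity
decays with along-river distance, a random phylogeny, an offline reaction
catalogue with pathway annotations, and enzyme-gene (EC) abundance tables with
group-specific log2 shifts that induce known pathway flows.

All generators are deterministic given their seed; randomness is drawn from
named substreams of a single root seed so stages are individually
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import InfeasibleCoreError, RiversedError, substream, warn
from .design import SEASONS, EnzymeShift, PlantedEffects, StudyDesign
from .reactions import ETM, PathwayMap, Reaction, ReactionSet, build_etm

METADATA_COLUMNS = (
    "site",
    "group",
    "season",
    "year",
    "replicate",
    "date_index",
    "position_km",
    "salinity",
    "temperature",
    "do",
    "ph",
    "conductivity",
)

# seasonal water temperature baselines (deg C)
_SEASON_TEMP = {"spring": 9.0, "fall": 11.0}


def generate_metadata(design: StudyDesign, effects: PlantedEffects) -> pd.DataFrame:
    """One metadata record per sample, with a planted salinity gradient.

    Salinity is ``baseline + slope * position + N(0, sd)``; temperature has a
    seasonal baseline; dissolved oxygen, pH and conductivity are plausible
    covariates (conductivity tracks salinity).  The along-transect distance
    matrix is derivable from ``position_km`` (see ``StudyDesign.site_distances``).
    """
    rng = substream(design.seed, "metadata")
    rows = []
    for si, site in enumerate(design.site_ids):
        pos = design.site_positions_km[si]
        for year in range(1, design.n_years + 1):
            for sj in range(design.n_seasons):
                season = SEASONS[sj]
                for rep in range(1, design.n_replicates + 1):
                    sid = f"{site}.Y{year}.{season}.R{rep}"
                    sal = (
                        effects.salinity_baseline
                        + effects.salinity_slope_per_km * pos
                        + rng.normal(0.0, effects.salinity_noise_sd)
                    )
                    temp = _SEASON_TEMP[season] + rng.normal(0.0, 2.0)
                    do = rng.normal(9.0, 0.8)
                    ph = rng.normal(8.0, 0.15)
                    cond = 500.0 + 1200.0 * sal + rng.normal(0.0, 30.0)
                    rows.append(
                        dict(
                            sample_id=sid,
                            site=site,
                            group=design.site_groups[si],
                            season=season,
                            year=year,
                            replicate=rep,
                            date_index=(year - 1) * design.n_seasons + sj,
                            position_km=pos,
                            salinity=sal,
                            temperature=temp,
                            do=do,
                            ph=ph,
                            conductivity=cond,
                        )
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta[list(METADATA_COLUMNS)]


def _random_tree_newick(leaf_names: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary tree via sequential joining, Exp(1) branch lengths."""
    nodes = [f"{name}" for name in leaf_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        bi, bj = rng.exponential(1.0, size=2)
        merged = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def generate_community(
    meta: pd.DataFrame,
    n_otus: int,
    effects: PlantedEffects,
    depth: int,
    seed: int,
    n_core: int | None = None,
    log_abundance_sd: float = 1.5,
    deviation_sd: float = 1.0,
    nugget: float = 0.15,
) -> tuple[pd.DataFrame, str]:
    """Simulate an OTU count table (samples x OTUs) and a random phylogeny.

    Per-OTU mean log-abundances are Gaussian (log-normal abundance law),
    producing an abundant core and a long rare tail.  Per-sample log-abundance
    deviations are correlated across samples with correlation
    ``(1 - nugget) * exp(-rate * d_km) + nugget * 1[same sample]`` so community
    similarity decays with along-transect distance at the planted rate.  Counts
    are a multinomial draw of ``depth`` reads per sample; designated core OTUs
    are guaranteed present in every sample.

    Returns the count table and a newick string over OTU leaf names.
    """
    if n_otus < 10:
        raise RiversedError(f"n_otus must be >= 10, got {n_otus}")
    if depth < 100:
        raise RiversedError(f"depth must be >= 100, got {depth}")
    if n_core is None:
        n_core = max(3, n_otus // 10)
    if depth < n_core:
        raise InfeasibleCoreError(
            f"depth {depth} cannot guarantee presence of {n_core} core taxa"
        )
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    samples = list(meta.index)
    n_samples = len(samples)

    mu = rng.normal(0.0, log_abundance_sd, size=n_otus)
    core_idx = np.arange(n_core)
    # calibrate core mean log-abundance so the expected core read share
    # equals core_fraction: E[w_i] = exp(mu_i + dev_sd^2 / 2)
    ew = np.exp(mu + 0.5 * deviation_sd**2)
    f = effects.core_fraction
    core_sum = ew[core_idx].sum()
    tail_sum = ew.sum() - core_sum
    if 0.0 < f < 1.0 and core_sum > 0 and tail_sum > 0:
        mu[core_idx] += np.log(f / (1.0 - f) * tail_sum / core_sum)

    pos = meta["position_km"].to_numpy(float)
    d = np.abs(pos[:, None] - pos[None, :])
    corr = (1.0 - nugget) * np.exp(-effects.distance_decay_rate * d) + nugget * np.eye(n_samples)
    chol = np.linalg.cholesky(corr + 1e-9 * np.eye(n_samples))
    z = chol @ rng.standard_normal((n_samples, n_otus))

    logw = mu[None, :] + deviation_sd * z
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p[s]) for s in range(n_samples)])

    # guarantee core presence: move one read from the sample's deepest OTU
    for s in range(n_samples):
        for i in core_idx:
            if counts[s, i] == 0:
                donor = int(np.argmax(counts[s]))
                counts[s, donor] -= 1
                counts[s, i] = 1

    table = pd.DataFrame(counts, index=samples, columns=otu_ids)
    table.attrs["core_otus"] = [otu_ids[i] for i in core_idx]
    newick = _random_tree_newick(otu_ids, rng)
    return table, newick


def _ec_number(i: int) -> str:
    return f"{1 + i % 6}.{1 + (i // 6) % 12}.{1 + (i // 72) % 12}.{1 + i}"


def generate_reaction_network(
    n_metabolites: int,
    n_enzymes: int,
    n_pathways: int,
    seed: int,
    extra_reaction_fraction: float = 0.3,
    reversible_fraction: float = 0.2,
    multi_pathway_fraction: float = 0.1,
) -> tuple[ReactionSet, PathwayMap]:
    """Random connected reaction network with block-structured pathways.

    A substrate->product chain over all metabolites guarantees connectivity;
    extra random reactions add branching.  Each enzyme (EC) catalyses at least
    one reaction, stoichiometric coefficients are integers in 1..3, and every
    metabolite belongs to at least one pathway (contiguous blocks along the
    chain, plus a fraction with a second random membership).
    """
    if n_metabolites < 2:
        raise RiversedError("n_metabolites must be >= 2")
    if n_enzymes < 1:
        raise RiversedError("n_enzymes must be >= 1")
    if not 1 <= n_pathways <= n_metabolites:
        raise RiversedError("n_pathways must be in [1, n_metabolites]")
    rng = np.random.default_rng(seed)
    mets = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    enzymes = [_ec_number(i) for i in range(n_enzymes)]

    n_chain = n_metabolites - 1
    n_base = max(n_chain, n_enzymes)
    n_extra = int(round(extra_reaction_fraction * n_base))
    specs: list[tuple[str, str]] = []  # (substrate, product)
    for k in range(n_chain):
        specs.append((mets[k], mets[k + 1]))
    while len(specs) < n_base + n_extra:
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        specs.append((mets[int(a)], mets[int(b)]))

    reactions = []
    for k, (sub, prod) in enumerate(specs):
        ec = enzymes[k] if k < n_enzymes else enzymes[int(rng.integers(n_enzymes))]
        subs = [(sub, float(rng.integers(1, 4)))]
        prods = [(prod, float(rng.integers(1, 4)))]
        # occasional co-substrate / co-product, avoiding both-sides overlap
        if n_metabolites > 2 and rng.random() < 0.3:
            used = {sub, prod}
            cand = [m for m in mets if m not in used]
            extra = cand[int(rng.integers(len(cand)))]
            if rng.random() < 0.5:
                subs.append((extra, float(rng.integers(1, 4))))
            else:
                prods.append((extra, float(rng.integers(1, 4))))
        reactions.append(
            Reaction(
                reaction_id=f"R{k + 1:04d}",
                ec=ec,
                substrates=tuple(subs),
                products=tuple(prods),
                reversible=bool(rng.random() < reversible_fraction),
            )
        )
    rset = ReactionSet(tuple(reactions))

    mapping: dict[str, set[str]] = {}
    blocks = np.array_split(np.arange(n_metabolites), n_pathways)
    pathway_ids = [f"P{j + 1:03d}" for j in range(n_pathways)]
    for pw, block in zip(pathway_ids, blocks):
        for i in block:
            mapping.setdefault(mets[int(i)], set()).add(pw)
    if n_pathways > 1:
        n_multi = int(round(multi_pathway_fraction * n_metabolites))
        for i in rng.choice(n_metabolites, size=n_multi, replace=False):
            mapping[mets[int(i)]].add(pathway_ids[int(rng.integers(n_pathways))])
    return rset, PathwayMap(mapping)


def generate_functional_table(
    meta: pd.DataFrame,
    reactions: ReactionSet,
    effects: PlantedEffects,
    depth: int,
    seed: int,
    noise_sd: float = 0.25,
    log_abundance_sd: float = 1.0,
) -> pd.DataFrame:
    """Enzyme-gene (EC) count table (samples x enzymes) with planted shifts.

    Baseline enzyme abundances are log-normal and shared across samples up to
    i.i.d. log-scale noise; samples whose metadata group carries a planted
    shift have ``log2_shift`` added to the stated enzymes' log2 abundance
    before a multinomial draw of ``depth`` reads.
    """
    if depth < 1:
        raise RiversedError("depth must be >= 1")
    enzymes = reactions.enzymes
    known_groups = set(meta["group"])
    for s in effects.enzyme_shifts:
        if s.group not in known_groups:
            raise RiversedError(f"planted shift references unknown group '{s.group}'")
        if s.enzyme not in enzymes:
            raise RiversedError(f"planted shift references unknown enzyme '{s.enzyme}'")
    rng = np.random.default_rng(seed)
    e_index = {e: i for i, e in enumerate(enzymes)}
    mu = rng.normal(0.0, log_abundance_sd, size=len(enzymes))
    counts = np.zeros((len(meta), len(enzymes)), dtype=int)
    ln2 = np.log(2.0)
    for r, (sid, row) in enumerate(meta.iterrows()):
        logw = mu + rng.normal(0.0, noise_sd, size=len(enzymes))
        for enz, shift in effects.shifts_for_group(row["group"]).items():
            logw[e_index[enz]] += shift * ln2
        w = np.exp(logw - logw.max())
        counts[r] = rng.multinomial(depth, w / w.sum())
    return pd.DataFrame(counts, index=list(meta.index), columns=enzymes)


def _interior_consumers(
    reactions: ReactionSet, pmap: PathwayMap, pathway: str, etm: ETM
) -> list[str]:
    members = set(pmap.members(pathway))
    present = sorted(members & set(etm.metabolites))
    if not present:
        return []
    touched: dict[str, set[str]] = {}
    for r in reactions:
        touched.setdefault(r.ec, set()).update(r.metabolites)
    w = etm.matrix.loc[present].sum(axis=0)
    return [e for e, ms in touched.items() if ms <= members and w[e] > 0]


def choose_target_pathway(
    reactions: ReactionSet, pmap: PathwayMap, etm: ETM | None = None
) -> str:
    """The pathway with the most interior consuming enzymes.

    A convenient target for planting a clean, recoverable flow shift: shifting
    its interior enzymes changes metabolites of this pathway only.
    """
    if etm is None:
        etm = build_etm(reactions)
    return max(pmap.pathways, key=lambda p: len(_interior_consumers(reactions, pmap, p, etm)))


def plant_pathway_shift(
    reactions: ReactionSet,
    pmap: PathwayMap,
    pathway: str,
    group: str,
    log2_shift: float = 2.0,
    interior_only: bool = True,
    normalization: str = "per_enzyme",
    etm: ETM | None = None,
) -> tuple[EnzymeShift, ...]:
    """Choose enzyme shifts that raise a target pathway's net flow in a group.

    Selects enzymes with positive net ETM weight onto the pathway's member
    metabolites (i.e. enzymes whose up-shift increases predicted consumption
    within the pathway).  With ``interior_only`` the choice is restricted to
    enzymes all of whose reaction metabolites lie inside the pathway, keeping
    the planted signal from bleeding into neighbouring pathways; if no such
    enzyme exists the restriction is relaxed with a warning.
    """
    members = set(pmap.members(pathway))
    if not members:
        raise RiversedError(f"pathway '{pathway}' has no member metabolites")
    if etm is None:
        etm = build_etm(reactions, normalization=normalization)
    present = sorted(members & set(etm.metabolites))
    weights = etm.matrix.loc[present].sum(axis=0)
    candidates = [e for e in etm.enzymes if weights[e] > 0]
    if interior_only:
        interior = _interior_consumers(reactions, pmap, pathway, etm)
        if interior:
            candidates = interior
        else:
            warn(f"no interior enzyme for pathway {pathway}; using boundary enzymes")
    if not candidates:
        raise RiversedError(f"no enzyme with positive net weight onto pathway '{pathway}'")
    return tuple(EnzymeShift(group, e, log2_shift) for e in sorted(candidates))
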