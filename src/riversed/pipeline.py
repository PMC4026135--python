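"""End-to-end orchestration of the functional and community analyses.

A single ``RunConfig`` (YAML-friendly) drives both pipelines.  All randomness
flows from one root seed through named substreams, so reruns with the same
config and seed are byte-identical, and individual stages are reproducible in
isolation.  Warnings are emitted on the package logger with a ``WARN:``
prefix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as cs
from . import io as rio
from ._utils import PipelineStageError, RiversedError, substream, warn
from .design import EnzymeShift, PlantedEffects, StudyDesign
from .flows import group_pathway_tests, pathway_flows, write_flow_results
from .prmt import PRMTScorer, average_replicates
from .reactions import build_etm, parse_pathway_map, parse_reactions
from .simulate import (
    generate_community,
    generate_functional_table,
    generate_metadata,
    generate_reaction_network,
    plant_pathway_shift,
)

DEFAULT_SIMULATION = dict(
    n_sites=6,
    site_positions_km=[0.0, 27.0, 54.0, 80.0, 107.0, 134.0],
    n_seasons=2,
    n_years=2,
    n_replicates=2,
    n_otus=200,
    community_depth=20000,
    n_metabolites=200,
    n_enzymes=120,
    n_pathways=24,
    functional_depth=100000,
    effects={},
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` (simulation parameters) or ``inputs`` (paths
    to tables/tree/metadata/reactions/pathway map) must be provided.
    """

    seed: int = 0
    outdir: str = "riversed_out"
    simulate: dict | None = None
    inputs: dict | None = None
    rarefaction_depth: int | None = None
    pseudocount: float = 1.0
    etm_normalization: str = "per_enzyme"
    permutations: int = 999
    alpha: float = 0.05
    core_min_total_reads: int = 200

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise RiversedError("config needs exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


@dataclass
class DataBundle:
    """Materialized inputs shared by both pipelines."""

    meta: pd.DataFrame
    otu_table: pd.DataFrame | None = None
    tree: str | None = None
    functional_table: pd.DataFrame | None = None
    reactions: object | None = None
    pathway_map: object | None = None
    site_groups: dict = field(default_factory=dict)


def _seed32(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def materialize(config: RunConfig) -> DataBundle:
    """Load inputs from paths or simulate them, per the config."""
    if config.inputs is not None:
        ip = config.inputs
        meta = rio.read_metadata(ip["metadata"])
        bundle = DataBundle(meta=meta)
        if "otu_table" in ip:
            bundle.otu_table = rio.read_feature_table(ip["otu_table"])
        if "tree" in ip:
            bundle.tree = rio.read_newick(ip["tree"])
        if "functional_table" in ip:
            bundle.functional_table = rio.read_feature_table(ip["functional_table"])
        if "reactions" in ip:
            bundle.reactions = parse_reactions(ip["reactions"])
        if "pathway_map" in ip:
            bundle.pathway_map = parse_pathway_map(ip["pathway_map"])
        bundle.site_groups = dict(
            zip(meta["site"].astype(str), meta["group"].astype(str))
        )
        return bundle

    sim = {**DEFAULT_SIMULATION, **config.simulate}
    eff_raw = dict(sim.get("effects") or {})
    plant = eff_raw.pop("plant", None)
    shifts = tuple(
        EnzymeShift(str(g), str(e), float(s))
        for g, e, s in eff_raw.pop("enzyme_shifts", [])
    )
    design = StudyDesign(
        n_sites=sim["n_sites"],
        site_positions_km=tuple(sim["site_positions_km"]),
        n_seasons=sim["n_seasons"],
        n_years=sim["n_years"],
        n_replicates=sim["n_replicates"],
        site_groups=tuple(sim.get("site_groups", ())),
        seed=config.seed,
    )
    effects = PlantedEffects(enzyme_shifts=shifts, **eff_raw)
    meta = generate_metadata(design, effects)
    reactions, pmap = generate_reaction_network(
        sim["n_metabolites"], sim["n_enzymes"], sim["n_pathways"],
        seed=_seed32(substream(config.seed, "network")),
    )
    if plant is not None:
        extra = plant_pathway_shift(
            reactions, pmap,
            pathway=str(plant["pathway"]), group=str(plant["group"]),
            log2_shift=float(plant.get("log2_shift", 2.0)),
            normalization=config.etm_normalization,
        )
        effects = PlantedEffects(
            enzyme_shifts=effects.enzyme_shifts + extra,
            **{k: getattr(effects, k) for k in (
                "distance_decay_rate", "salinity_baseline", "salinity_slope_per_km",
                "salinity_noise_sd", "core_fraction")},
        )
    otu_table, tree = generate_community(
        meta, sim["n_otus"], effects, depth=sim["community_depth"],
        seed=_seed32(substream(config.seed, "community")),
    )
    functional = generate_functional_table(
        meta, reactions, effects, depth=sim["functional_depth"],
        seed=_seed32(substream(config.seed, "functional")),
    )
    return DataBundle(
        meta=meta, otu_table=otu_table, tree=tree, functional_table=functional,
        reactions=reactions, pathway_map=pmap,
        site_groups=dict(zip(design.site_ids, design.site_groups)),
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RiversedError as e:
                raise PipelineStageError(name, e) from e
        return wrapped
    return deco


def run_functional_pipeline(config: RunConfig, bundle: DataBundle | None = None) -> dict:
    """Quantile-normalize -> log2 -> reference -> PRMT -> replicate-average ->
    pathway flows -> group Kruskal-Wallis tests.  Writes every intermediate
    artifact into ``outdir`` and returns the result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    if bundle is None:
        bundle = _stage("materialize")(materialize)(config)
    if bundle.functional_table is None or bundle.reactions is None:
        raise PipelineStageError("materialize", RiversedError(
            "functional pipeline needs a functional table and a reaction catalogue"))

    etm = _stage("build_etm")(build_etm)(bundle.reactions, config.etm_normalization)
    scorer = PRMTScorer(etm, pseudocount=config.pseudocount)
    scores = _stage("prmt_scores")(scorer.fit_transform)(bundle.functional_table)
    norm = scorer._pretransform(bundle.functional_table, fit=False)
    unit_scores = _stage("average_replicates")(average_replicates)(scores, bundle.meta)
    if bundle.pathway_map is None:
        raise PipelineStageError("pathway_flows", RiversedError(
            "no pathway map provided; cannot aggregate PRMT scores into pathways"))
    flows = _stage("pathway_flows")(pathway_flows)(unit_scores, bundle.pathway_map)
    tests = _stage("group_tests")(group_pathway_tests)(
        flows, bundle.site_groups, alpha=config.alpha)

    rio.write_feature_table(norm, outdir / "normalized_abundance.tsv", prov)
    rio.write_feature_table(scores, outdir / "prmt_scores.tsv", {
        **prov, "pseudocount": config.pseudocount,
        "normalization": "quantile+log2", "reference": "mean of all samples"})
    rio.write_feature_table(unit_scores, outdir / "prmt_scores_units.tsv", prov)
    rio.write_tidy(flows, outdir / "pathway_flows.tsv", prov)
    write_flow_results(tests, flows, bundle.site_groups,
                       outdir / "group_tests.tsv", outdir / "flow_edges.tsv")
    return dict(etm=etm, scores=scores, unit_scores=unit_scores,
                flows=flows, tests=tests, bundle=bundle)


def run_community_pipeline(config: RunConfig, bundle: DataBundle | None = None) -> dict:
    """Rarefy -> beta diversity -> Mantel/partial Mantel -> BEST -> ANOSIM ->
    PCoA -> Procrustes -> core extraction -> per-feature ANOVA -> Z profiles."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    if bundle is None:
        bundle = _stage("materialize")(materialize)(config)
    if bundle.otu_table is None:
        raise PipelineStageError("materialize", RiversedError(
            "community pipeline needs an OTU table"))
    meta = bundle.meta
    table = bundle.otu_table
    if config.rarefaction_depth:
        table = _stage("rarefy")(cs.rarefy)(
            table, config.rarefaction_depth, seed=_seed32(substream(config.seed, "rarefy")))
        meta = meta.loc[table.index]
    rio.write_feature_table(table, outdir / "rarefied_table.tsv", prov)

    hell = _stage("hellinger")(cs.hellinger_distance)(table)
    rio.write_distance_matrix(hell, outdir / "hellinger.tsv", prov)
    if bundle.tree is not None:
        uni = _stage("weighted_unifrac")(cs.weighted_unifrac)(table, bundle.tree)
        rio.write_distance_matrix(uni, outdir / "weighted_unifrac.tsv", prov)
        comm = uni
    else:
        comm = hell

    from skbio import DistanceMatrix

    ids = [str(s) for s in table.index]
    pos = meta["position_km"].to_numpy(float)
    d_space = DistanceMatrix(np.abs(pos[:, None] - pos[None, :]), ids=ids)
    sal = meta["salinity"].to_numpy(float)
    d_sal = DistanceMatrix(np.abs(sal[:, None] - sal[None, :]), ids=ids)

    nperm = config.permutations
    sseed = _seed32(substream(config.seed, "stats"))
    mantel_rows = []
    m_dist = _stage("mantel")(cs.mantel)(comm, d_space, n_perm=nperm, seed=sseed)
    mantel_rows.append(dict(comparison="community_vs_distance", r=m_dist.r, p=m_dist.p,
                            n_perm=nperm))
    m_sal = _stage("mantel")(cs.mantel)(comm, d_sal, n_perm=nperm, seed=sseed)
    mantel_rows.append(dict(comparison="community_vs_salinity", r=m_sal.r, p=m_sal.p,
                            n_perm=nperm))
    pm = _stage("partial_mantel")(cs.partial_mantel)(comm, d_space, d_sal,
                                                     n_perm=nperm, seed=sseed)
    mantel_rows.append(dict(comparison="community_vs_distance_controlling_salinity",
                            r=pm.r, p=pm.p, n_perm=nperm))
    mantel_df = pd.DataFrame(mantel_rows)
    rio.write_tidy(mantel_df, outdir / "mantel_results.tsv", prov)

    env = meta[["position_km", "salinity", "temperature", "do", "ph", "conductivity"]]
    best = _stage("best_env")(cs.best_env)(comm, env)
    rio.write_tidy(best.table, outdir / "best_results.tsv", prov)

    anosim_rows = []
    for var in ("season", "site"):
        if meta[var].nunique() < 2 or meta[var].value_counts().min() < 2:
            warn(f"skipping ANOSIM on '{var}': not enough groups/members")
            continue
        a = _stage("anosim")(cs.anosim)(comm, meta[var].astype(str).tolist(),
                                        n_perm=nperm, seed=sseed)
        anosim_rows.append(dict(variable=var, R=a.R, p=a.p, n_perm=nperm))
    anosim_df = pd.DataFrame(anosim_rows)
    rio.write_tidy(anosim_df, outdir / "anosim_results.tsv", prov)

    ord_full = _stage("pcoa")(cs.pcoa)(comm)
    rio.write_tidy(ord_full.coordinates, outdir / "pcoa_coordinates.tsv", prov, index=True)

    core = _stage("core_features")(cs.core_features)(
        table, min_total_reads=config.core_min_total_reads)
    rio.write_tidy(pd.DataFrame({"feature": list(core.features)}),
                   outdir / "core_features.tsv",
                   {**prov, "read_fraction": f"{core.read_fraction:.6f}"})

    proc_rows = []
    if core.features:
        hell_core = cs.hellinger_distance(table[list(core.features)])
        ord_core = cs.pcoa(hell_core)
        ord_hell = cs.pcoa(hell)
        pr = _stage("procrustes")(cs.procrustes)(
            ord_hell.coordinates, ord_core.coordinates, n_perm=nperm, seed=sseed)
        proc_rows.append(dict(comparison="core_vs_full", m2=pr.m2, p=pr.p, n_perm=nperm))
    if bundle.functional_table is not None:
        func = bundle.functional_table.loc[table.index]
        ord_func = cs.pcoa(cs.hellinger_distance(func))
        ord_comm = cs.pcoa(comm)
        pr = _stage("procrustes")(cs.procrustes)(
            ord_comm.coordinates, ord_func.coordinates, n_perm=nperm, seed=sseed)
        proc_rows.append(dict(comparison="taxonomic_vs_functional", m2=pr.m2, p=pr.p,
                              n_perm=nperm))
    rio.write_tidy(pd.DataFrame(proc_rows), outdir / "procrustes_results.tsv", prov)

    anova = _stage("per_feature_anova")(cs.per_feature_anova)(
        table, meta["site"].astype(str).tolist())
    rio.write_tidy(anova, outdir / "feature_anova.tsv", prov)

    sig = anova.loc[anova["significant"] == True, "feature"]  # noqa: E712
    feats = list(sig) if len(sig) >= 2 else list(table.sum(axis=0).nlargest(20).index)
    site_means = table[feats].groupby(meta["site"]).mean().T
    zres = _stage("zscore_profiles")(cs.zscore_profiles)(site_means)
    ordered = zres.z.iloc[list(zres.leaf_order)]
    rio.write_tidy(ordered, outdir / "zscore_profiles.tsv", prov, index=True)

    return dict(
        distances=dict(hellinger=hell, community=comm),
        mantel=mantel_df, best=best, anosim=anosim_df, pcoa=ord_full,
        core=core, procrustes=pd.DataFrame(proc_rows), anova=anova, zscores=zres,
        bundle=bundle,
    )
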