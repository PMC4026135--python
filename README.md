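# riversed

Predicted relative metabolic turnover (PRMT) scoring and community-structure
statistics for environmental metagenomics, packaged with a synthetic-study
generator that plants known, recoverable effects.

## Who this is for

Microbial ecologists analysing paired amplicon (16S rRNA OTU tables plus a
phylogeny) and shotgun-metagenome (enzyme-gene abundance) surveys of
environmental samples — the motivating setting is sediment communities sampled
along a river transect with site groups defined by land use. The package
answers two kinds of questions:

1. **Function**: given enzyme-gene (EC) abundances and a reaction catalogue,
   which metabolites does each community have relatively more capacity to
   consume or accumulate, which metabolic pathways carry that signal, and do
   pathway-level flows differ between site groups?
2. **Structure**: is community composition shaped by space, environment or
   season (distance decay, environmental drivers, core community), and is
   taxonomic structure coupled to functional potential?

## The model

**PRMT.** Reaction stoichiometry is folded into an environmental
transformation matrix *E* (metabolites × enzymes): a substrate of an enzyme's
reactions contributes +coefficient, a product −coefficient, and each enzyme
column is divided by its number of reactions. Enzyme-gene abundances *x* are
quantile-normalized and log2-transformed, and each sample is scored against
the average of all samples (the "reference"):

    score(s, m) = Σ_e E[m, e] · (x[s, e] − x̄[e])

A positive score means relative consumption capacity for metabolite *m* in
sample *s*, a negative score relative accumulation. Scores are relative flux
only — the reference is the average metagenome, so they say nothing about
absolute production or consumption. Per pathway, positive member-metabolite
scores sum to a *net positive* value, negative ones to a *net negative*
value, and their sum is the *net flow*; group differences in net flow are
tested per pathway with a Kruskal–Wallis rank test on replicate-averaged
site×season×year units.

**Community statistics.** Rarefaction (sampling without replacement),
Hellinger and weighted-UniFrac beta diversity, Mantel and partial Mantel
matrix correlation, BEST/BIO-ENV environmental subset search (Spearman),
ANOSIM, principal coordinates, Procrustes/PROTEST ordination comparison,
core-community extraction (present in every sample and abundant), per-feature
ANOVA with Bonferroni correction, and Z-scored abundance profiles with
hierarchical clustering.

The transform-shaped steps are scikit-learn estimators (`QuantileNormalizer`,
`PRMTScorer`) and compose with sklearn pipelines; the statistical tests are
plain functions returning small result objects.

## Worked example

Simulate a 24-sample study (6 sites along 134 km, two years, two replicates)
with a +2 log2 enzyme-gene shift planted on pathway `P001` in site group
`G1`, then run both pipelines:

```yaml
# config.yaml
seed: 42
outdir: out
permutations: 999
simulate:
  n_seasons: 1
  n_years: 2
  n_replicates: 2
  effects:
    plant: {pathway: P001, group: G1, log2_shift: 2.0}
```

```sh
riversed simulate  --config config.yaml
riversed functional --config config.yaml
riversed community  --config config.yaml
```

prints

```
simulated study written to out
1 significant pathway(s) at alpha=0.05; results in out
Mantel (community vs distance): r=0.666 p=0.0010; core features: 114; results in out
```

and the top of `out/group_tests.tsv` shows the planted pathway recovered with
the highest net flow in the shifted group:

```
pathway  H            p              mean_flow_G1  mean_flow_G2  mean_flow_G3  significant
P001     8            0.01831563889  2.637823589   -1.664416795  -0.9734067933 True
P018     5.692307692  0.05806722742  0.5477831114  -0.9846570761 0.4368739647  False
```

Reading: the Kruskal–Wallis test flags only the planted pathway (p ≈ 0.018),
its mean net flow is most positive in `G1` (extra consumption capacity from
the up-shifted enzymes), and the community pipeline detects the planted
spatial distance decay (Mantel r = 0.666, p = 0.001).

The same analyses run on your own files (`riversed functional --config ...`
with an `inputs:` block of TSV/newick paths, or the per-statistic subcommands
`rarefy`, `betadiv`, `mantel`, `best`, `anosim`, `procrustes`, `core`,
`feature-anova`).

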