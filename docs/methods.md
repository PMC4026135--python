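# Methods

This note documents the models implemented by `riversed`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## PRMT scoring

The environmental transformation matrix (ETM) *E* is built from a reaction
catalogue. For every reaction of enzyme *e* (identified by its EC number),
each substrate metabolite *m* adds +coefficient to *E[m, e]* and each product
adds −coefficient; metabolites appearing on both sides enter with their net
coefficient (zero-net entries are dropped at reaction construction).
Reversible reactions contribute in their written direction only: without
thermodynamic information the operative direction is unknowable, and
including both directions would cancel every reversible reaction to zero
signal. Columns are normalized by the enzyme's reaction count
(`normalization="per_enzyme"`, the default) so that promiscuous enzymes do
not dominate the projection; `"none"` keeps raw sums for comparison.

Enzyme abundance tables are quantile-normalized (target distribution = mean
of the rank-k values across samples; ties receive the mean of their tied-rank
targets) and then log2-transformed with a pseudocount of 1 — the conventional
count pseudocount, configurable via `pseudocount`. The order
(quantile-normalize raw counts, then log) is fixed by the `log_first=False`
default and can be switched. The reference is the per-enzyme mean of the
*normalized, log-scale* table, which makes two identities exact: the
reference sample scores zero for every metabolite, and scores sum to zero
over the fitted samples for every metabolite. ETM enzymes absent from the
table contribute nothing (their delta is zero); table enzymes absent from the
ETM are excluded with a warning, since annotation tables never cover a full
catalogue.

Sign convention: substrates get positive ETM weight, so a positive PRMT score
means relative *consumption* capacity and a negative score relative
*accumulation*. Scores are replicate-averaged to one unit per
site×season×year before any group comparison.

## Pathway flows and group tests

Per unit and pathway, positive member-metabolite scores sum to `net_positive`
(≥ 0), negative ones to `net_negative` (≤ 0), and `net_flow` is their sum
(an exact identity on every record). Metabolites belonging to several
pathways contribute to each of them; pathways with no scored metabolite are
omitted with a warning.

Group differences in `net_flow` are tested per pathway with a tie-corrected
Kruskal–Wallis test; p-values come from the chi-square approximation with
(groups − 1) degrees of freedom, as standard implementations do even at small
n, with an exact-permutation option for n ≤ 10. Units are the
replicate-averaged site×season×year values, so a 6-site, 2-year, 1-season
design with three site groups of two sites yields four units per group. No
multiple-testing correction is applied across pathways by default;
Benjamini–Hochberg is available (`adjust="bh"`) but off, since the pathway
screen is intended as a descriptive ranking at a nominal per-pathway level.
At nominal α = 0.05 the realized per-pathway type-I rate of this unit scheme
is about 0.03–0.05 (the chi-square approximation is slightly conservative at
n = 12), which the null-calibration test checks end to end through the
generator, normalization and scoring.

## Community statistics

* **Rarefaction** draws without replacement via the multivariate
  hypergeometric distribution; retained samples sum exactly to the requested
  depth and shallower samples are dropped with a warning.
* **Hellinger distance** is the Euclidean distance between square-rooted
  relative abundance vectors (bounded by √2, compositionally invariant).
* **Weighted UniFrac** sums branch lengths times the absolute difference in
  descendant relative abundance. The default is the raw (non-normalized)
  variant; `normalized=True` divides by the abundance-weighted tree depth,
  bounding distances by 1.
* **Mantel** uses the Pearson correlation of upper triangles with a
  one-tailed permutation p-value and the conservative +1 correction.
  **Partial Mantel** uses the first-order partial correlation and permutes
  the second matrix. Controlling for a matrix identical to the second one
  returns r = 0 (nothing left to correlate); a control collinear with the
  *first* matrix is degenerate and raises.
* **BEST/BIO-ENV** z-scores the environmental variables (sd with ddof = 1),
  evaluates every non-empty subset (guarded at 20 variables), and ranks
  subsets by the Spearman correlation between Euclidean environmental
  distances and the community distances; ties prefer smaller subsets.
* **ANOSIM** is the standard rank-based between/within contrast; groups need
  at least two members.
* **PCoA** Gower-centres −d²/2 and eigendecomposes; axes with negative
  eigenvalues are dropped (no Lingoes/Cailliez correction) and the lost
  absolute-variance fraction is logged.
* **Procrustes** optimally translates, scales and rotates/reflects the
  unit-trace configurations (dimensions harmonized by zero-padding) and
  reports the residual M²; the PROTEST p-value permutes the row order of the
  second configuration, one-tailed on small M².
* **Core community**: features with nonzero counts in every sample and total
  count strictly above a threshold (default 200 reads, attached to the
  feature's dataset-wide total; a per-sample interpretation is available by
  flag).
* **Per-feature ANOVA** is a one-way fixed-effects F per feature with
  Bonferroni correction over the features actually tested (after the
  optional minimum-abundance filter). Features whose groups all have zero
  within-group variance are reported as NA and flagged.
* **Z-profiles** standardize each feature across sites to mean 0, sd 1
  (ddof = 1; constant profiles become zero rows and are flagged) and cluster
  profiles by average-linkage on Euclidean distances.

Permutation defaults are 999 permutations, seedable; all tests are one-tailed
as conventional for Mantel/ANOSIM/PROTEST.

## Synthetic-study generator

The generator emulates the data shapes of a replicated river-transect
survey; its defaults are the package's study conditions.

* **Design**: 6 sites at 0–134 km along a one-dimensional transect, 2
  seasons × 2 years × 2 replicates (48 samples), sites partitioned into three
  contiguous land-use groups G1/G2/G3.
* **Metadata**: salinity = 0.2 ppt + 0.003 ppt/km · position + N(0, 0.05);
  temperature has seasonal baselines (9 °C spring, 11 °C fall, sd 2);
  dissolved oxygen, pH and conductivity are plausible covariates, with
  conductivity tracking salinity.
* **Community**: per-OTU mean log-abundances are Gaussian (sd 1.5), giving a
  log-normal abundance law with an abundant core and a rare tail. A
  designated core subset (10% of OTUs) is recalibrated so its expected read
  share equals `core_fraction` (default 0.5) and is guaranteed present in
  every sample. Per-sample log-abundance deviations are correlated across
  samples with correlation (1 − nugget)·exp(−rate·d) + nugget·1[same sample]
  (rate default 0.02/km, nugget 0.15), so community similarity decays with
  distance at a single planted rate testable by Mantel. Counts are a
  multinomial draw at fixed depth (default 20,000 reads/sample), so
  rarefaction is exercised realistically. The phylogeny is a random
  sequential-join binary tree with Exp(1) branch lengths — adequate for
  exercising UniFrac, with no birth–death realism.
* **Reaction catalogue**: default 200 metabolites, 120 enzymes, 24 pathways —
  the proportions of a genome-scale catalogue (roughly 2000 metabolites, 600
  enzymes, 260 pathways) at desk scale. A substrate→product chain guarantees
  a connected network; pathways are contiguous blocks along the chain with
  ~10% of metabolites holding a second membership. `plant_pathway_shift`
  selects enzymes with positive net ETM weight onto a target pathway,
  preferring "interior" enzymes (all of whose reaction metabolites lie inside
  the pathway) so the planted signal does not bleed into neighbours.
* **Functional table**: log-normal baseline enzyme abundances (sd 1.0) with
  i.i.d. per-sample log-noise (sd 0.25); planted group shifts add
  `log2_shift` to the stated enzymes before a multinomial draw (default
  100,000 reads/sample).

What the generator does *not* emulate: read-level artefacts (sequencing
error, chimeras), realistic taxonomy, phylogenetic signal in abundances
(OTU abundances are exchangeable across the tree), seasonal community
structure (seasons differ only through sampling noise, making season a
built-in negative control), and any coupling between the OTU table and the
functional table beyond shared metadata. Passing tests therefore demonstrate
that the statistics recover the specific planted effects — distance decay,
salinity gradients, group-specific enzyme shifts, a read-share-calibrated
core — not that they would behave identically on real sediment data, where
effect sizes are smaller and confounded.

## Reproducibility and problem sizes

All randomness flows from a single root seed through named substreams (seed
sequence mixed with a CRC32 of the stage name), so stages are individually
reproducible and pipeline reruns with the same config and seed are
byte-identical (floats are written with a fixed `%.10g` format, and output
headers carry the config hash and seed but no timestamps). The acceptance
experiments use deliberately small problem sizes — 24-sample studies, a
120-enzyme catalogue, 25–100 replicate seeds, 199–999 permutations — chosen
so the full battery runs in minutes on one core while keeping every
statistical check well-powered; the power checks (planted recovery,
distance-decay detection) were sized so the planted effects are strong
relative to sampling noise at those depths.

In the distance-decay/BEST recovery experiment the salinity gradient is set
to zero so that the planted spatial driver is the unique true driver: with
the default gradient, salinity is an almost noiseless monotone function of
position and the "correct" variable subset would be ambiguous by
construction.

## Known limitations

* The ETM weighting of the original turnover method is not uniquely
  standardized; per-enzyme normalization is one defensible choice and is
  therefore exposed as an option rather than hard-coded.
* Reversible reactions in their written direction only is a modelling
  convention, not chemistry.
* The Kruskal–Wallis chi-square approximation is coarse at 3×4 units; the
  exact-permutation option exists but is limited to n ≤ 10.
* BEST p-values are not computed (the subset search is descriptive); the
  exhaustive search is exponential and guarded at 20 variables.
* PCoA drops negative-eigenvalue axes instead of correcting them, which can
  discard a small variance fraction for strongly non-Euclidean matrices
  (the fraction is logged).
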