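# Methods

## The two-step null-model framework

`ecoassembly` quantifies which ecological processes structure pairwise
turnover between microbial communities sampled along an environmental
gradient (the motivating system is an estuarine river–sea salinity
transect). Every unordered pair of samples is assigned one of five
processes in two steps.

**Step 1 — phylogenetic turnover (betaNTI).** The beta mean nearest taxon
distance between communities A and B,

    betaMNTD(A, B) = 0.5 * [ sum_{i in A} f_i min_{j in B} d(i, j)
                           + sum_{j in B} f_j min_{i in A} d(i, j) ],

with `f` the within-sample relative abundances and `d` the patristic
(cophenetic) distance, is compared to a null distribution obtained by
relabelling the taxa of the phylogeny with a uniformly random permutation
(tree shape and abundances untouched; default 999 permutations). The
standardized effect size betaNTI = (obs − mean_null) / sd_null indicates
homogeneous selection when ≤ −2 (environmental filtering holds communities
phylogenetically closer than chance) and heterogeneous selection when ≥ +2
(divergent filtering pushes them apart). Thresholds are inclusive. A taxon
shared by both communities is its own nearest taxon (distance 0).

The shuffle pool is **every tip of the supplied distance matrix**, i.e. the
regional species pool, not merely the taxa observed in the current table.
This follows the convention of shuffling all labels of the distance matrix
one feeds the null. It matters: a metacommunity filtered into a single
clade would otherwise be relabelled within that same clade and homogeneous
selection would be structurally undetectable. Callers who want an
observed-taxa pool can prune the tree before calling.

Pairs whose null distribution has zero standard deviation (e.g. identical
samples) carry no selection information; betaNTI is reported as undefined
and the pair falls through to step 2.

**Step 2 — compositional turnover (RC_bray).** For pairs with |betaNTI| < 2,
observed Bray–Curtis dissimilarity is located within a null distribution of
probabilistically assembled community pairs. Each null community preserves
its sample's observed richness and read depth: taxon identities are drawn
without replacement with probability proportional to metacommunity
occupancy (number of occupied samples), each drawn taxon receives one read,
and the remaining reads are assigned multinomially with probability
proportional to metacommunity relative abundance. The observed value's rank
is rescaled to

    RC = 2 * [ #(null < obs) + 0.5 * #(null = obs) ] / n_null − 1  ∈ [−1, +1].

RC > +0.95 indicates dispersal limitation (more turnover than the
stochastic expectation), RC < −0.95 homogenizing dispersal (less), and
|RC| ≤ 0.95 the undominated fraction (mainly drift). RC thresholds are
exclusive. Ties are counted at half weight using exact float equality,
which is exact here because both observed and null Bray–Curtis values are
ratios of integers and IEEE division is correctly rounded.

**Shared null ensembles.** By default one null ensemble serves all pairs of
a run: the r-th replicate uses the r-th tip permutation (betaNTI) or the
r-th per-sample null assembly (RC). Each pair's marginal null distribution
is unchanged while compute drops by roughly the number of pairs;
`shared_null=False` draws fully independent nulls per pair. Whether the
original framework shared ensembles is not documented; both modes exist and
the default is logged in the run manifest.

**Bootstrap rarefaction.** Sequencing effort is normalized by subsampling
every sample without replacement (multivariate hypergeometric) to a common
depth — the study default is 5557 reads — repeated as `n_boot` (default
100) independent bootstrap replicates. The whole two-step inference runs
per replicate; the headline summary is the arithmetic mean of per-replicate
process fractions, with the pooled fraction over all replicate × pair rows
reported alongside, and per-pair modal labels plus their support exposed so
replicate-to-replicate label variability is never collapsed silently.
Rarefaction RNG uses counter-based sub-streams keyed by (boot, sample), so
results do not depend on evaluation order.

## Supporting analyses

* **Environmental distance** — per-variable z-scores (sample sd, n−1), then
  Euclidean distance; constant variables are a hard error (the pipeline
  drops them with a logged warning, which a uniform-environment design
  requires). Geographic distance is haversine with Earth radius 6371 km.
* **Mantel test** — Pearson correlation of the lower triangles with joint
  row/column permutations of the second matrix; one-sided (positive) by
  default; p = (1 + exceedances)/(1 + permutations). Implemented in-package
  so the permutation stream is seeded; cross-checked against scikit-bio in
  the tests.
* **Phylogenetic signal** — Mantel correlogram between niche distances and
  equal-width phylogenetic-distance classes (Sturges count by default).
  Niche values are abundance-weighted means of each (z-scored) environmental
  variable; only OTUs with occupancy ≥ 4 (i.e. > 3 samples) are tested,
  because niche estimates from fewer occurrences are unstable. The class
  statistic is the negated membership correlation, so positive means
  ecological similarity at that phylogenetic distance; p-values are
  two-sided permutation tests with progressive Holm correction. The
  pipeline treats absence of a significant positive short-distance class as
  a warning, not an abort: signal is a prerequisite justification, and a
  user may proceed knowingly.
* **betaNTI vs environment** — ordinary least squares of pairwise betaNTI
  (bootstrap means) on environmental distance. Pairwise observations share
  samples and are not independent; the p-value is reported as descriptive
  only and the output carries that caveat explicitly.
* **Ordination** — weighted UniFrac (normalized by default, so values are
  comparable across pairs; scikit-bio backend), averaged over bootstrap
  tables, then classical PCoA (in-package: double-centring + eigh; negative
  eigenvalues are reported and their axes dropped) and single-factor
  PERMANOVA with seeded label permutations and R² = SS_between/SS_total.
* **IndVal** — group-equalized indicator value (the "IndVal.g" convention,
  appropriate for unequal habitat group sizes along a transect):
  A = group mean relative abundance share, B = occurrence fraction in the
  group, stat = sqrt(A·B), best group = argmax. OTUs below 0.01 % relative
  abundance in every sample are removed first. Significance by sample-label
  permutation preserving group sizes; raw p < 0.05 defines habitat
  preference, with Benjamini–Hochberg q-values emitted additionally.
  Habitats follow the Venice System on salinity: freshwater [0, 0.5),
  oligohaline [0.5, 5), mesohaline [5, 18), polyhaline [18, 30], marine
  (> 30); interior breakpoints are left-closed and 30 is polyhaline so that
  "marine" means strictly > 30 — a documented convention, configurable via
  the `breakpoints` argument.
* **Sub-communities** — `top_n_subcommunity` ranks OTUs by summed relative
  (not raw) abundance so unequal library sizes cannot bias the ranking,
  breaking ties lexicographically; the pipeline reruns the whole null-model
  analysis on the top-N table (study value 1000) to expose the
  diversity/rarity dependence of the inference.

## The synthetic metacommunity generator

Real estuarine survey data cannot be shipped or reprocessed here, so every
claim the package makes is validated against metacommunities simulated
under known assembly regimes. The generator composes:

1. **Phylogeny** — pure-birth (Yule) tree, unit birth rate, exponential
   waiting times, 300 taxa by default.
2. **Niches** — Brownian motion along a depth-rescaled copy of the tree
   (Pagel-delta-style exponent, default 0.05). Plain Brownian motion lets
   distant clades converge onto the same niche value, which destroys the
   clade coherence that selection must induce; concentrating divergence on
   deep branches yields strong conservatism — close relatives share niches —
   which is exactly the phylogenetic signal the betaNTI framework requires
   and which the correlogram verifies. Tip values are rescaled linearly to
   the salinity-like range (default 0–30).
3. **Regional pool** — lognormal abundances. The lognormal sigma is a
   scenario knob (0.5–2.0 across presets): dispersal regimes need a long
   rare tail so that per-sample richness sits well below metacommunity
   richness (otherwise the Raup–Crick identity draw degenerates because
   every site contains essentially the whole pool), while selection regimes
   need an even pool so that many clade members coexist at comparable
   abundance (a z-score of ±2 needs tens of effectively independent
   abundant taxa).
4. **Local assembly** — initial draw of `reads_per_site` individuals with
   weights pool × Gaussian fitness kernel exp(−(niche−e_s)²/(2σ_w²)) ×
   site-specific colonization filter (Bernoulli) × site-specific lognormal
   lottery (priority effects); then Wright–Fisher generations: multinomial
   resampling with weights proportional to current local abundance times
   the kernel, mixed with the regional pool at rate m (mass-effect
   dispersal). Resampling from *local* abundance is essential: weights
   based on the static pool would make generations memoryless and drift
   could never accumulate. With 5557 reads over ≤ 300 taxa the colonization
   filter and lottery are equally essential: without them every taxon is
   present everywhere and the (incidence-based) nearest-taxon term of
   betaMNTD carries no signal.

Preset regimes:

| preset | kernel σ_w | m | generations | pool σ | lottery σ | colonization | environments |
|---|---|---|---|---|---|---|---|
| heterogeneous_selection | 3 | 0 | 5 | 0.5 | 0.8 | 0.5 | gradient |
| homogeneous_selection | 2 | 0 | 5 | 0.5 | 2.5 (guild) | 1 | uniform |
| homogenizing_dispersal | ∞ | 0.7 | 20 | 2.0 | 1.5 | 1 | gradient |
| dispersal_limitation | ∞ | 0 | 5 | 1.0 | 2.0 | 0.5 | gradient |
| drift | ∞ | 0.05 | 10 | 2.0 | 0 | 1 | gradient |

Two refinements matter for the homogeneous-selection preset:

* the shared environment is centred where realized niches are both dense
  and phylogenetically coherent (maximizing window mass divided by
  within-window mean pairwise distance over candidate optima) — "the
  habitat favours a clade". Pure mid-range or pure density centring lands
  between clades on a substantial fraction of random phylogenies and the
  regime then fails to express;
* the lottery is normalized within ~150 average-linkage phylogenetic
  guilds (`n_guilds`), modelling competitive lotteries among ecologically
  redundant close relatives: every site keeps roughly one winner per guild
  while guild-level abundances stay stable. This produces the hallmark
  structure of homogeneous selection — sites hold *different but closely
  related* taxa — robustly across random trees.

Metadata emulates a salinity-dominated transect: measured salinity is the
true environment plus 0.1-unit noise, and three nutrient-like covariates
(NH4, NO3, PO4) are linear transforms of the gradient plus Gaussian noise
targeting r ≈ −0.8, mirroring the strong negative nutrient–salinity
correlations typical of river–sea continua.

**What the generator does not emulate:** spatially explicit transport
(dispersal is regional-pool mixing, not stepping-stone), multi-trait
niches, seasonality, DNA/RNA (total vs active) mechanistic differences,
sequencing error and chimeras, or compositional count biases. Passing the
validation suite therefore shows the inference machinery behaves correctly
on data with the assumed statistical structure; it does not certify
recovery on real surveys where these complications apply.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

* **Oracle equivalence** — cophenetic distances, betaMNTD, Bray–Curtis,
  weighted UniFrac, PCoA and PERMANOVA agree (≤ 1e-8) with naive
  brute-force re-implementations on 50 random instances of ≤ 12 taxa and
  ≤ 8 samples.
* **Null calibration** — data generated by each null look unremarkable to
  it. betaNTI: 50 replicate community pairs, each observed under 10
  independent tip shuffles (500 z-values; a 50-value ensemble mean has a
  standard error of 0.14, nearly the width of the ±0.15 acceptance band, so
  the larger ensemble tests the same property with useful power): mean
  within ±0.15, sd within [0.85, 1.15]. RC: 200 pairs drawn from fixed
  occupancy/abundance pools and ranked against nulls from the same pools:
  mean within ±0.1. Mantel and PERMANOVA p-values under label
  randomization: Kolmogorov–Smirnov uniformity p > 0.01 over 200 runs.
* **Decision-table fidelity** — exact agreement on a grid spanning all
  boundaries (±2 inclusive, ±0.95 exclusive, undefined betaNTI).
* **Scenario recovery** — for each preset at study scale (300 taxa, 12
  sites, 5557 reads, 999 nulls), the intended process is the modal label in
  ≥ 7 of 10 seeds.
* **Sub-community sensitivity** — restricting a homogeneous-selection
  metacommunity to its 50 most abundant taxa reduces the
  homogeneous-selection fraction, reproducing the direction of the
  diversity/rarity effect: fewer taxa and less rarity shrink the deviation
  of betaMNTD from its null.
* **Determinism** — the full pipeline run twice with one seed produces
  byte-identical outputs.
* **Planted indicators** — 20 freshwater specialists planted among 100
  even generalists across five habitats: ≥ 18 recovered at raw p < 0.05
  (999 permutations) with ≤ 2 false positives. The generalists are exactly
  even on purpose: under any exchangeable abundance noise the permutation
  p-value of a true generalist is uniform, so ~5 % of them would be
  "significant" no matter how the test is implemented.

## Numerical and design notes

* RNG: `numpy.random.Generator` everywhere; user-facing entry points take a
  seed or Generator; internal sub-streams derive via `SeedSequence` spawn
  keys so stages are independent and order-insensitive.
* Permutation p-values use the add-one convention (1+k)/(1+n): never zero,
  minimal attainable p = 1/(n+1).
* betaNTI null sd uses the sample standard deviation (ddof=1).
* Distance matrices ride on `skbio.DistanceMatrix` (symmetry and zero
  diagonal enforced); OTU tables are a thin validated integer-matrix class
  with id registries.
* The betaNTI inner loop gathers, per permutation chunk and per sample, the
  column-minima of the relabelled distance matrix (colmin trick), reducing
  per-pair work from |A|×|B| to |A|+|B| after an O(pool×|B|) per-sample
  pass; RC null assemblies are vectorized with a Gumbel top-k identity draw
  and batched multinomial fills.
* Problem sizes in the validation suite (50 oracle instances; 500/200
  calibration replicates; 10 seeds per scenario) were chosen so the whole
  suite completes in a few minutes on one CPU while leaving every
  statistical margin wide.

## Known limitations

* The RC null estimates occupancy and abundance pools from the analysed
  table itself (per bootstrap replicate); with very few samples those
  pools are noisy.
* OLS on pairwise betaNTI inherits pair non-independence (flagged, not
  corrected); a Mantel-style permutation would be the stricter alternative.
* The pipeline's PERMANOVA drops habitat groups with fewer than two
  samples rather than testing them.
* Shared null ensembles introduce weak dependence between pairs *within
  one run*; per-pair independent mode exists where that matters.
* The generator's regimes are archetypes: real communities mix processes,
  and the modal-label check is only meaningful for data generated near an
  archetype.
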