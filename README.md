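# ecoassembly

Null-model quantification of ecological assembly processes in microbial
metacommunities.

Microbial communities along strong environmental gradients — the motivating
system is a river–sea estuarine continuum spanning freshwater to marine
salinities — are shaped by a mix of deterministic selection and stochastic
dispersal and drift. `ecoassembly` implements the two-step phylogenetic /
compositional null-model framework that partitions every pair of
communities among five processes, together with the supporting statistics a
survey of this kind needs, and a synthetic metacommunity generator with
known assembly regimes so the whole pipeline is testable end to end without
any sequencing data.

**Step 1.** Phylogenetic turnover between samples A and B is measured by the
abundance-weighted beta mean nearest taxon distance

> betaMNTD(A, B) = ½ [ Σ_{i∈A} f_i min_{j∈B} d(i,j) + Σ_{j∈B} f_j min_{i∈A} d(i,j) ]

and standardized against a null in which taxa are shuffled across the tips
of the phylogeny (999 randomizations):

> betaNTI = (betaMNTD_obs − mean_null) / sd_null.

betaNTI ≥ +2 ⇒ **heterogeneous selection**; betaNTI ≤ −2 ⇒ **homogeneous
selection**.

**Step 2.** For pairs with |betaNTI| < 2, the Raup–Crick metric on
Bray–Curtis dissimilarity (RC_bray ∈ [−1, +1]) locates observed
compositional turnover within a null of probabilistically assembled
communities that preserve each sample's richness and depth (identities
drawn by metacommunity occupancy, reads filled by metacommunity relative
abundance). RC > +0.95 ⇒ **dispersal limitation**; RC < −0.95 ⇒
**homogenizing dispersal**; otherwise the pair is **undominated** (mainly
drift).

The surrounding toolkit covers bootstrap rarefaction (default: 100
resamplings to the minimum depth), phylogenetic-signal Mantel correlograms
(occupancy > 3 filter), environmental and geographic distances with Mantel
tests, betaNTI-vs-environment regression, weighted UniFrac + PCoA +
PERMANOVA, Venice-System habitat classification from salinity, and IndVal
indicator-species analysis with a 0.01 % rarity pre-filter. See
[docs/methods.md](docs/methods.md) for the full model description,
parameter meanings and limitations.

## Worked example

Generate a synthetic metacommunity assembled under heterogeneous selection
(a salinity-like gradient with phylogenetically conserved niches), then run
the full analysis:

```bash
ecoassembly simulate heterogeneous_selection --seed 2 --out-dir sim
ecoassembly run-all sim/otu_table.tsv sim/tree.nwk sim/metadata.tsv \
    --n-null 999 --n-boot 10 --depth 5000 --seed 7 --out-dir out
```

`out/all/process_fractions.tsv` then contains (this exact output, seed 7):

```
process	mean_fraction	sd_fraction	pooled_fraction
heterogeneous_selection	0.7727272727	0	0.7727272727
homogeneous_selection	0.07575757576	1.462847279e-17	0.07575757576
dispersal_limitation	0.06060606061	1.462847279e-17	0.06060606061
homogenizing_dispersal	0	0	0
undominated	0.09090909091	0	0.09090909091
```

Reading it: across the 66 sample pairs, heterogeneous selection is the
dominant assembly process (77 % of pairs; the per-pair labels are so
stable here that the sd across the 10 bootstrap rarefactions is zero) — as
it should be, since the generator imposed strong divergent environmental
filtering along the gradient. Homogeneous selection (8 %) appears among
the nearest site pairs, which share an environment, and the undominated
fraction (9 %) among intermediate ones, mirroring the expected progression
of processes with environmental distance. `environment_summary.tsv` from
the same run reports Mantel r = 0.92 (p = 0.001) between environmental and
geographic distances and a positive betaNTI-vs-environmental-distance
regression (slope 2.52, R² = 0.29), the signature of selection
strengthening along the gradient. The same directory holds the per-pair per-bootstrap labels (`per_pair.tsv`), modal
labels with bootstrap support, the phylogenetic-signal correlogram, the
environment summary (Mantel r of environmental vs geographic distance,
betaNTI–environment regression), IndVal habitat preferences, PCoA
coordinates and the habitat PERMANOVA, plus `manifest.json` with the
configuration, input checksums and per-stage timings.

The library mirrors the CLI one-to-one (`ecoassembly.beta_nti_matrix`,
`rc_bray_matrix`, `bootstrap_process_fractions`, `indval`, ...) for use
from Python.

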