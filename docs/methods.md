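# Methods

`linkerscape` implements a landscape-genetic analysis chain for a
plant–pollinator system in agricultural mosaics: landscape composition →
among-patch movement of a bumblebee (the *genetic linker*) → population
genetic structure of an insect-pollinated, partially clonal forest herb.
This note records the models, the synthetic study system, the numerical
choices, and the places where the design was genuinely open.

## Study design emulated by the synthetic generator

The generator (`linkerscape.synthetic`) reproduces the sampling design of a
three-window field study: 5 × 5 km landscape windows on a 10 m categorical
grid, six deciduous-forest study patches per window, ~20 herb genotypes per
patch at 6 microsatellite loci (allele pools summing to 134 alleles) and
14–36 bumblebee workers per patch at 8 loci (148 alleles).  Windows carry
nine area-based land-use classes, three crop types as 10-year presence
histories over arable fields (so per-cell *crop dominance* = fraction of
years grown), and four linear-element classes as polylines.

**Mosaic model.** Land-use maps are generated by seeded nucleation + region
growing: ~900 nuclei per window (mean parcel ≈ 2.8 ha, a typical Central
European field grain) are assigned classes by largest-remainder allocation
of the target proportions and every cell joins its nearest nucleus.
Largest-remainder allocation keeps realized covers within ~1–2 percentage
points of the targets on a 500 × 500 grid; a Voronoi mosaic is the simplest
reproducible model with contiguous parcels.  The parcel grain matters: with
coarse parcels (~11 ha) the 125 m buffer around a patch often samples a
single parcel and small-scale heterogeneity (LANDHET125) degenerates to a
near-constant.  Study patches are forced circles (default radius 90 m,
≈ 2.5 ha) with ≥ 1100 m centre separation; the radius is deliberately below
the smallest buffer radius so even the 125 m buffer samples the surrounding
mosaic.

**Bee model.** Nests are queen × single male (monogamy); males are haploid,
as in *Bombus*, so all workers of a nest share the paternal allele at every
locus.  Nests sit on the fringes of the study patches (≈ 14 nests per km of
fringe).  Restricting nests to the identical-geometry study fringes — rather
than every forest boundary in the window — keeps the local nest pool equal
across patches; with nests on all boundaries, the pool size covaries with
forest cover and hence with crop covers, which confounds null experiments
(the no-effect regression of NESTS_shared on maize cover is then not centred
on zero).

**Movement model.** A patch catches workers from nest *i* with probability
∝ exp(−d_i / κ_i), where the nest-specific foraging range is
κ_i = `kernel_scale_m` × exp(*s*) and *s* is the landscape-effect score of
the nest's nearest patch: configured coefficients times the within-window
z-scores of maize dominance (2000 m buffer), semi-natural grassland cover
(2000 m) and landscape heterogeneity (125 m).  Attaching the effect to the
*nest* rather than to the capturing patch is essential: a patch-level
multiplier rescales every nest's weight at that patch equally and leaves the
composition of the catch — and therefore every sharing indicator —
unchanged.  Making forage-poor (maize-rich) surroundings *lengthen* trips
realises the "relative value of floral resources" mechanism: those nests'
workers appear in several patches and raise among-patch nest sharing where
the effect metric is high.

Calibration of the injected effects (chosen once, before the test suite was
frozen): a single effect of ±0.8 on the log-range scale is "large" — it is
reliably recovered — while ±1.6 *over-saturates* (extreme kernels make
NESTS_shared bimodal 0/1 and the monotone signal collapses).  The combined
study preset (`STUDY_PRESET`) therefore uses +0.6 (maize) and +0.35
(heterogeneity) with a 350 m baseline range; grassland is left at zero in
the combined preset because grass and maize covers are *positively* coupled
through compositional closure in these mosaics, so opposite-signed effects
largely cancel each other's single-metric signal.  The grassland effect is
exercised in its own single-effect experiments instead.

**Plant model.** Each patch has a parent-genet pool whose size shrinks with
`pollen_donor_skew`; sampled ramets are clones of an already-sampled genet
with probability `clonality_rate`, otherwise offspring of a random mother ×
a random *different* parent (the herb is strictly outcrossing — allowing
selfing here would cancel most of the heterozygote excess).  Few effective
parents plus clonality produce Ho > He (negative F), the classic state of
small, partially clonal populations; at skew 0.9 essentially all populations
show excess with mean F ≈ −0.17, while skew 0 with many parents gives mean
F ≈ 0 (Hardy–Weinberg).  Optionally (`plant_coupling` > 0) pollen donors are
drawn from other patches via an island-model migration matrix proportional
to realized shared-nest counts, which is how linker movement feeds back into
herb genetic structure (more immigration → more alleles, F pulled toward 0).
The generative plant model is an admissible choice, not a fitted one; no
claim is made that real *Polygonatum* demography follows it.

**What the generator does not emulate:** colony dynamics and phenology,
year-to-year landscape change, genotyping artefacts beyond a uniform
mistyping rate, spatially autocorrelated allele frequencies within windows,
and seed dispersal.  Tests passing on these data show the *pipeline*
recovers what it is supposed to recover under its own assumptions — not that
the biological conclusions transfer to any particular field system.

## Landscape metrics

Node-level zones are circular buffers (125/250/500/1000/2000 m) around
patch centroids; link-level zones are rectangles joining two centroids,
length = centre distance, width = ratio × length
(1:7, 1:5, 1:3, 1:2, 2:3), unclipped at the patches.  Cell membership uses
the cell-centre-in-zone rule; raster metrics use the member-cell area as
denominator, linear-element metrics use exact polyline clipping and the
polygon area.  Shannon heterogeneity uses natural log over area classes
present; edge density counts internal unlike rook-neighbour edges only (one
cell side each, zone border excluded).  Crop metrics (MAIZE, RAPESEED,
CEREAL) are the zone mean of per-cell dominance.  Buffers reaching beyond
the window are computed on the clipped zone with a warning.  Pairwise
geographic distance joins the link-level candidate set as one scale-free
metric.

## Genetic measures

Per population: Ho (mean fraction heterozygous over loci), unbiased He
((2n/(2n−1))(1−Σp²), averaged over loci), allelic richness by gene-copy
rarefaction (hypergeometric expectation; g defaults to the smallest
population × locus copy count in the table), and F = 1 − Ho/He.  The ratio
convention He/Ho is available behind a flag but cannot express the negative
values that heterozygote excess requires, which is why the difference form
is the default.  D_PS (herb: PolD_PS; bee: BomD_PS) is 1 − mean over loci of
Σ_k min(p_kA, p_kB) on population allele-frequency profiles; an
individual-pairwise variant is provided as an option.  Missing data are
handled per-locus complete-case; loci with fewer than two complete genotypes
in a population are skipped with a warning.

## Sibship reconstruction

Under monogamy a nest is one full-sib family.  The partition likelihood is
the product over families of the family likelihood: per locus, a sum over
the unobserved queen × male genotype pair of Hardy–Weinberg parental priors
× Mendelian transmission of each worker's genotype, with mistyping smeared
toward population frequencies at rate `err`.  Parental allele support per
family is the set of alleles observed in that family plus one pooled
"any other allele" class — exact at err = 0 by exchangeability of unobserved
alleles, a close approximation at small err.  Frequencies come from the
block's workers; observed alleles with zero reference frequency are floored
at 1/(2N+1).

Search: greedy best-first pair merging from the all-singletons partition,
restricted to *candidate* pairs (sharing an allele at ≥ 75% of comparable
loci — full sibs with a haploid father always share one), followed by
simulated annealing (move / merge / split, geometric cooling, default 15
moves per worker).  The candidate screen only prunes the greedy agenda;
annealing moves can join any pair.  Per-pair support = co-assignment
frequency across restarts; two independently seeded runs are combined by the
consensus rule (support > 0.8 in both), and consensus families are connected
components of accepted pairs.  Each (window, year) block is analysed
separately.  On default-size data (8 loci, ~148 alleles, err = 0) the
consensus reconstruction reaches pairwise precision and recall ≥ 0.99;
support values are nearly degenerate at 0/1 because the likelihood surface
is sharply peaked, so the analysis drivers use 1–2 restarts per run (a
search-effort choice documented here; the default remains 20).

Movement indicators from consensus families: a nest is assigned to every
patch where ≥ 1 of its workers was caught; NESTS_shared(i) = share of i's
nests also assigned elsewhere; FOREST_PATCHES_shared(i) = number of other
patches sharing ≥ 1 nest with i.

## Mixed models

All variables (responses and metrics) are Box-Cox transformed (λ by profile
likelihood on a grid [−3, 3] step 0.05; shift 1 − min(x) for non-positive
variables) and standardized to mean 0, SD 1, so coefficients are
standardized.  Node-level models have a landscape-window random intercept;
link-level models add the MLPE residual correlation: cov = σ²(I + ρS) with
S_pq = 1 when two pairs share exactly one population (ρ searched in
[0, 0.5)).  Estimation is maximum likelihood throughout (not REML) so AICc
is comparable across fixed-effect structures; β and σ² are profiled in
closed form (Cholesky GLS) and the remaining one or two variance parameters
optimised numerically (bounded scalar search / L-BFGS-B with a small
deterministic multistart), making every fit deterministic.  Wald t tests
(df = n − k) give coefficient p-values; likelihood-ratio tests compare
nested fits; AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects
*and* variance parameters (the convention is constant within any comparison
set, so rankings do not depend on it); r² follows the
Nakagawa–Schielzeth variance decomposition.

## Four-step selection

Step 1 (movement indicators as responses): per metric, fit the single-metric
model at all five scales, linear and with an added quadratic, keep the
lowest-AICc variant (ties → smaller scale, lower degree); retain metrics
whose chosen variant beats the intercept-only model in an LRT at α = 0.15;
then search all subsets of retained metrics (≤ 2 distinct metrics node-level,
≤ 4 link-level; |Pearson r| ≥ 0.7 pairs excluded, screened on the
transformed columns) and keep the ΔAICc < 2 band.  Term limits count
*distinct metrics*; a quadratic term rides along with its linear term
without consuming a slot.  Step 2 refits the Step-1 term sets with the herb
measures (A_r, He, Ho, F; PolD_PS at link level) as responses.  Step 3
enumerates models over *all* metrics × *all* scales under the same rules
(quadratics free, but only together with their linear term — applied to any
metric, not only those quadratic-preferred in Step 1); the link-level
universe is combinatorially large, so a seeded uniform subsample
(`max_models`, default cap 1200 in the drivers) stands in for the full
enumeration, with the cap recorded in the output.  Step 4 computes, per
Step-2 model, the fraction of Step-3 AICc values *strictly* greater (ties
count as not exceeded; the Step-2 model itself is excluded from the
distribution) and flags ≥ 95% as a pass.

Degenerate inputs: empty preselection yields an empty model table and the
downstream steps skip with a report entry; convergence failures and singular
designs are dropped from every enumeration, mirroring how unfittable models
are excluded in practice.

## Problem sizes in the shipped drivers and checks

The analysis drivers and the acceptance script run the full three-window
design (18 patches, ~430 workers, ~360 plants).  Replicated experiments use
the sizes a single CPU handles in minutes: 20–50 replicates for
effect-sign recovery (regenerating bees on a fixed landscape, 1 restart per
reconstruction run), 60–100 simulations for MLPE parameter recovery, and a
1200-model subsample for each Step-3 distribution.  These sizes are
package choices recorded here; all thresholds (80% consensus, α = 0.15,
|r| ≥ 0.7, ΔAICc < 2, 95% percentile) are study constants and are not
scaled.

## Known limitations

- The sibship "support" is a co-assignment frequency across restarts, not a
  posterior pair probability; with a sharply peaked likelihood it is nearly
  binary.  The 0.8 consensus threshold therefore behaves like an agreement
  rule between two runs rather than a calibrated probability cut.
- The MLPE fit searches ρ ∈ [0, 0.5); negatively correlated pair structures
  are flagged at the boundary rather than estimated.
- Step-3 subsampling yields a Monte-Carlo percentile; at the default cap its
  standard error is < 1 percentage point near the 95% boundary.
- The landscape generator produces stationary mosaics; it cannot emulate
  historical land-use change, so "dominance" variation comes from crop
  rotation persistence only.
- FOREST_PATCHES_shared is bounded by the five possible partner patches and
  saturates in high-sharing regimes; NESTS_shared is the more informative
  indicator under the shipped presets.
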