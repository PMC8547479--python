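# Methods

This note documents the statistical machinery implemented in
`assemblage`, the conventions and tunable parameters that affect its
numbers, what the synthetic metacommunity generator does and does not
emulate, and the design choices made where more than one defensible
option existed.

## Null models

### βMNTD / βNTI

The between-sample statistic is the abundance-weighted β-mean nearest
taxon distance: for each taxon present in one sample, the patristic
distance to its nearest relative in the other sample, averaged with
within-sample relative-abundance weights and symmetrised with the 1/2
factor. Taxa present in both samples contribute distance zero.

The null shuffles taxon labels across the **full** patristic distance
matrix of the aligned dataset (the `taxa.labels` convention), not just
the taxa present in the pair: restricting the shuffle to the pair's own
taxa would shrink the null and bias scores toward zero. One shared
shuffle per replicate is applied to all pairs. Marginally this is
identical to independent per-pair shuffles — each pair's null draw is a
uniformly random relabelling — but it is much faster and makes the
whole matrix reproducible from one seed stream.

Conventions that affect the numbers:

* **Replicates** default to 999. The oracle tests check that at 10,000
  replicates the Monte-Carlo null mean and standard deviation agree
  with exhaustive enumeration of all tip-label permutations on trees of
  up to 6 tips, within three standard errors.
* **Standard deviation** uses the population form (denominator = reps),
  so scores are reproducible bit for bit given a seed; at 999 reps the
  difference from the sample form is far below the ±2 threshold's
  resolution.
* **Degenerate pairs** (null sd numerically zero, e.g. two identical
  communities containing every taxon) get a NaN score and are counted
  as *excluded* in fraction summaries, never silently dropped; a
  warning reports how many.
* **NTI** is the within-sample analogue, negated so that phylogenetic
  clustering (observed MNTD below the null mean) is positive.

### RC<sub>bray</sub>

For each replicate both communities are rebuilt independently from a
metacommunity profile estimated from the aligned count table:
occurrence frequency (fraction of samples containing each taxon) and
mean within-sample relative abundance. A simulated sample draws its
observed richness S without replacement with probability ∝ occurrence
frequency (Gumbel-top-k weighted sampling), seeds each drawn taxon with
one individual, and distributes the remaining N − S individuals
multinomially ∝ mean relative abundance restricted to the drawn taxa —
so simulated richness and total abundance match the observed sample
exactly. N is the sample's observed total by default; an optional
rarefied mode subsamples all samples to the minimum depth first.

The observed Bray–Curtis dissimilarity is ranked within the null:
RC_raw = (#{null < obs} + ½·#{null = obs}) / reps, rescaled to
2·RC_raw − 1 ∈ [−1, 1]; ties (within 10⁻¹⁰) count half, so a fully
degenerate null scores exactly 0. Bray–Curtis is computed on relative
abundances on both the observed and the simulated side.

Per-pair RNG substreams are derived from the master seed and the
CRC-32 of the sorted sample-ID pair, so any subset of pairs — computed
lazily, in any order, or in parallel — yields bit-identical scores.

Self-null calibration (observed pairs generated by the null procedure
itself) yields |RC| > 0.95 at ≈5% and a mean score within ±0.05 of
zero; the βNTI tip-shuffle null yields |βNTI| > 2 at ≈4.6%. Both rates
are checked in the acceptance suite with 99% binomial bands over ≥500
pairs.

## Classification and fractions

Thresholds are strict inequalities: a pair at exactly βNTI = 2 or
RC<sub>bray</sub> = 0.95 falls to the less-significant category.
RC<sub>bray</sub> is never consulted when |βNTI| > 2, which is why the
pipeline computes it lazily for non-significant pairs only (a `full_rc`
switch produces complete matrices; classifications are provably
identical either way and a test asserts it).

pH well categories default to breaks at 9 and 10.5 with bounds
7.5–12 (neutral / moderate / extreme), assigned on the mean of all pH
measurements per well; an explicit well→category map takes precedence
when reproducing a published grouping. Category fractions pool within-
and between-well pairs among that category's wells.

## Supporting statistics

* **Shannon H** uses the natural log; **Pielou J = H / ln S** (NaN for
  single-taxon samples). Some papers describe J loosely as Shannon
  "divided by richness"; this package follows Pielou's definition.
* **Mantel** is the Pearson correlation of lower triangles with a
  two-sided permutation p-value, (1 + #{|r_perm| ≥ |r_obs|}) / (1 + P).
  Samples with missing values are removed listwise (greedy removal of
  the sample causing the most missing pairs), never imputed.
* **Niche values** are abundance-weighted means of an environmental
  variable per taxon; taxa with zero total abundance are excluded with
  a report.
* **Mantel correlogram**: equal-width phylogenetic distance classes
  spanning (0, max]; Sturges' rule sets the class count when unset. The
  per-class statistic is the correlation between the class indicator
  and the niche-difference matrix, sign-flipped so that *positive*
  values at short distances mean close relatives have similar niches.
  Progressive Bonferroni tests class k at α/k. Brownian traits trip the
  class-1 test in ≥90% of replicates, permuted traits in ≤10% — the
  precondition for using nearest-taxon metrics at all.
* **PERMANOVA** partitions the Gower-centred total sum of squares
  sequentially (Type I) in the user-given term order, with pseudo-F
  against the residual and p by permutation of raw sample identities.
  It reproduces vegan `adonis2(..., by="terms")` to 8 significant
  digits on test fixtures (categorical terms are dummy-coded; rank is
  tracked through a QR decomposition so aliased terms get df 0 and a
  warning).

## Synthetic metacommunities

The generator emulates the data-generating structure the analysis
assumes: a Yule phylogeny rescaled to height 1; a niche trait evolved
by Brownian motion along it (σ = 1 per unit height by default, so tip
traits have unit variance and strong phylogenetic signal); a lognormal
regional abundance pool; and local communities of fixed size N
assembled by a multinomial colonisation draw from the
environmentally-filtered pool, followed by Wright–Fisher resampling
with migration. Environmental filtering multiplies pool abundances by
exp(−(trait − env)² / 2σ²_sel); migration mixes relative abundances
toward the filtered pool (effective dispersal — arrivals that establish
under local conditions). Site environments are stored as a pH column
(pH = 9 + env) so downstream pH groupings run unchanged.

Two generator-level choices matter enough to call out:

* **The tree is the label frame.** Taxa never observed in any sample
  are kept as structural zero columns, because the simulated tree *is*
  the known regional pool and the tip-shuffle null needs the full label
  frame to have phylogenetic range. In real 16S workflows the frame is
  instead defined by the observed table — which spans the tree because
  real datasets pool many environments. A simulated dataset whose
  samples all come from one filtered clade would otherwise make
  homogeneous selection undetectable by construction, a property of the
  data frame, not of the statistic.
* **Migration delivers filtered settlers.** A variant in which migrants
  arrive from the unfiltered pool and are removed by viability
  selection in later generations was tested and rejected: the transient
  scattered migrants place a relative of every taxon everywhere,
  collapsing nearest-taxon distances and destroying the βNTI signal for
  every selection scenario.

### Scenario presets

Presets were calibrated so that the full pipeline recovers each
generative process as the modal call among between-site pairs robustly
across seeds (measured 20/20 for every scenario at 199 null
replicates); they are configuration, not empirical claims. All use 6
sites × 3 time points.

| scenario | n_taxa | N | σ_sel | m | drift gens | env |
|---|---|---|---|---|---|---|
| homogeneous_selection | 800 | 1,000 | 0.15 | 0.10 | 200 | all at the 0.85 trait quantile |
| variable_selection | 300 | 1,000 | 0.25 | 0.30 | 15 | trait quantiles 0.05–0.95 |
| dispersal_limitation | 120 | 1,000 | ∞ (none) | 0.01 | 1,500 | median trait |
| homogenizing_dispersal | 300 | 8,000 | ∞ (none) | 0.95 | 800 (isolated site) | median trait |
| neutral | 120 | 1,000 | ∞ (none) | 0.30 | 30 | median trait |

Why these shapes:

* *Homogeneous selection* needs a filter much narrower than the trait
  spread, an environment in the distribution's tail (so the tolerant
  taxa form a phylogenetically coherent subset), a large taxon pool
  (null range), and enough drift that sites turn over membership
  *within* the clade — identical communities carry no signal because
  shared taxa are invariant under the tip shuffle.
* *Dispersal limitation* needs drift on the scale of the community
  size (1,500 generations between samples at N = 1,000) with a trickle
  of migration that keeps richness up without re-homogenising.
* *Homogenizing dispersal* couples five sites to one freely-mixing
  shared community and lets a sixth drift in isolation. The isolated
  site is essential: RC<sub>bray</sub> measures similarity relative to
  a null built from the dataset itself, so a dataset in which *every*
  sample is near-identical reproduces its own similarity under the
  null and no pair can cross −0.95. Heterogeneity outside the mixed
  group is what makes the coupled pairs measurably *more* similar than
  expected — matching the field situation where mixing wells sit
  inside an otherwise heterogeneous site.
* *Neutral* communities hover at a migration–drift balance around the
  pool, so both metrics stay within their null bands and pairs are
  undominated.

Environments default to quantiles of the realised trait distribution
rather than fixed values, which removes dependence on any particular
Brownian realisation.

What the generator does **not** emulate: sequencing error, chimeras and
compositional read-depth variation (totals are exactly N); speciation;
temporal autocorrelation in the environment; interactions between taxa
beyond shared filtering. Passing recovery tests therefore demonstrates
that the inference machinery is correct under the model's own
assumptions — not that real communities satisfy them.

## Numerical conventions and degenerate inputs

* Count tables must have positive sample totals; all-zero taxa are
  allowed (structural zeros) and are excluded from the Raup–Crick
  profile automatically.
* Square-matrix I/O is CSV with an ID header row and ID first column,
  12-significant-digit round-trip, symmetry enforced at 10⁻⁸, NaN
  diagonals permitted for score matrices.
* Strict alignment is the default: a count-table taxon missing from
  the tree is an error; permissive mode drops and reports. Alignment is
  idempotent.
* Null sds below 10⁻¹⁰ (relative) are treated as zero → degenerate.
* Every stochastic routine takes an explicit seed; pipeline substreams
  are derived deterministically, and the manifest records seeds,
  parameters and a parameter hash sufficient to reproduce every output.

## Problem sizes used in the test and acceptance runs

Calibration runs use 33 samples (528 pairs) with 999 null replicates;
scenario-recovery runs use the preset sizes above with 199 replicates
and 20 seeds per scenario; correlogram calibration uses 100 replicates
of 50-taxon trees with 199 permutations. These sizes give the binomial
bands quoted above while keeping a full run in the minutes range on a
single CPU.

## Known limitations

* The two-stage decision rule inherits the framework's blind spot: a
  pair influenced by counteracting processes lands in *undominated*.
* RC<sub>bray</sub> depends on the dataset used to build the profile;
  adding or removing samples changes every score. The package
  recomputes the profile from the aligned table by default and lets
  callers pass a fixed profile explicitly.
* Mantel tests on βNTI matrices treat scores as distances after
  zeroing the diagonal; βNTI is not a metric, so these are correlation
  summaries, not distance-based inference.
* The simulator's Wright–Fisher drift has no overlapping generations
  and its migration is island-model; both are the minimal standard
  choices, not mechanistic claims about any aquifer.
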