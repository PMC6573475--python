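# Methods

## Data model

A `HaplotypeAlignment` stores, for each sample, the states at the
polymorphic sites of one non-recombining haploid locus, plus the total
surveyed length `locus_length_bp`. Monomorphic positions are never stored:
they matter only for per-bp rates, not for any statistic computed here.
States are nucleotides (`A/C/G/T`, `N` missing) or `0/1`
ancestral/derived when the alignment is polarized. Haplotype identity must
be defined on a common site set, so haplotype collapsing and the
AMOVA-family statistics use *complete deletion* (drop any column with a
missing state) by default; MPD may alternatively use pairwise deletion,
under which the triangle inequality of the difference matrix is not
guaranteed. Readers are pure functions of the file bytes.

## Within-population statistics

* **Haplotype / haplogroup diversity** uses Nei's unbiased estimator
  h = n(1 − Σpᵢ²)/(n − 1). The n/(n − 1) correction is the convention of the
  standard population-genetics packages this module mirrors, and makes the
  two diversity indices comparable across sample sizes.
* **MPD** is the mean of all C(n,2) pairwise difference counts.
* **Tajima's D** contrasts π (here MPD under complete deletion) with S/a₁,
  with S counted on the same site set so both θ estimators see identical
  data. D is undefined (NaN, flagged not raised) when S = 0.
* **Significance of D** is simulation-based: neutral constant-size
  coalescent genealogies with exactly S mutations placed multinomially on
  branches in proportion to length (a fixed-S null, so no θ needs to be
  assumed); the two-sided p-value is the add-one-corrected fraction of
  replicates with |D| ≥ |D_obs|. Default 10,000 replicates, configurable —
  the beta-distribution approximation is deliberately not used.

## Between-population structure

**AMOVA** decomposes the sum of squared inter-haplotype distances with the
nested moment estimators of Excoffier, Smouse & Quattro (1992). The distance
entering the sums of squares is, by default, the *square* of the pairwise
difference count (`distance="squared"`); the plain count is selectable
(`"plain"`), since tools differ in whether the difference count is treated
as the distance or as its square. Variance components can be negative and
are reported as-is; percentages are computed on the signed sum, so they
always total 100 even when a component is negative. Permutation schemes per
level: within-population component — individuals permuted among populations
across all groups (tests Φst); among-populations-within-groups — individuals
permuted among populations within their group (Φsc); among-groups — whole
populations permuted among groups (Φct). p-values are add-one corrected;
default 10,000 permutations (9,999 for Mantel). Pairwise Φst is the
two-population special case, permuting individuals between the two
populations. When every population is its own group the
among-populations-within-groups stratum is empty and σ²_b is 0 by
construction.

**Nei's net divergence** d_A = π_XY − (π_X + π_Y)/2 uses pair means, so for
small samples with identical composition the estimate need not be exactly 0
(it is 0 in expectation and exactly 0 for identical monomorphic
populations).

**Mantel** correlates off-diagonal upper triangles and permutes rows and
columns of the second matrix jointly. Geographic distances are haversine
great-circle distances on a sphere of radius 6371.0088 km; resistance or
least-cost distances can be supplied as external matrices.

**NMDS** minimizes Kruskal stress-1 by iterative majorization (Guttman
transform) alternated with isotonic regression of configuration distances on
the input dissimilarities (scikit-learn's isotonic solver; ties handled by
averaging). Negative input values — possible for Φst — are clamped to zero
with a warning. Default k = 2 with 20 random restarts; the best restart is
returned with a convergence flag, coordinates centered at the origin.
A hand-written SMACOF is used rather than an off-the-shelf one so that the
stress-1 value and the convergence tolerance (1e-9 change in stress) are
exactly the quantities contracted by the tests.

**Rank contrasts** report Mann–Whitney U (for group 1), the tie-corrected
normal Z without continuity correction, and a two-sided p-value — exact
when n₁·n₂ ≤ 400 and untied, normal approximation otherwise. The residence
report applies this to h, MPD and haplogroup diversity across
patrilocal/matrilocal classes and to off-diagonal Φst entries within each
class, with direction-of-effect flags (patrilocality predicts lower
within-population diversity and higher among-population differentiation for
a paternally inherited locus).

## Structured coalescent

The simulator runs the Hudson structured coalescent backward in time in
generations: within a deme holding k lineages, coalescence at rate
k(k−1)/(2Ne) (haploid Ne); per-lineage migration between demes at the
configured rates; at fixed split times all lineages of a daughter deme
relocate into its parent, which keeps its own size. One genealogy per
simulation — the locus does not recombine, so the surveyed length enters
only through the mutation rate. Mutations are infinite-sites: a Poisson
number with mean (total branch length) × μ·g·L, each on a fresh site on a
branch chosen proportionally to length, giving a polarized 0/1 alignment
and per-deme unfolded SFS (frequency classes 1..n_d − 1; classes 0 and n_d
excluded per deme; `total_S` counts sites segregating in the total sample).

Scenario topologies: under *demic* and *continuous migration* the TARGET
deme merges into DAI at `t_target`, under *cultural* into AA; DAI merges
into AA at `t_root`. *Continuous migration* adds symmetric TARGET↔AA
migration active only more recently than `t_target`. Parameters not fixed
are drawn from independent uniform priors.

Defaults (all configurable): μ = 8.71 × 10⁻¹⁰ substitutions/bp/year,
L = 2,364,048 bp, generation time g = 30 years, t_target = 2,000 years,
t_root = 4,500 years (Bronze-Age-scale splits), Ne ~ U(10³, 10⁵) haploid per
deme, m ~ U(10⁻⁵, 10⁻²) per generation per lineage. After a merge the
ancestral deme keeps the parent deme's size. Observed data are polarized
alignments; the observed SFS subsamples each deme without replacement to the
model's sample size (matching a design that simulates the lowest sample size
among the populations in the model), dropping unpolarizable sites with a
logged count.

## ABC random forests

Model choice follows Pudlo et al. (2016). A classification forest (default
500 trees) is trained on the reference table of flattened summaries
(concatenated per-deme unfolded SFS + total_S; pairwise d_A between demes is
available as an optional addition but off by default). The reported
quantities are: the fraction of trees voting for each scenario at the
observed summary (ties broken in the fixed order demic < cultural <
continuous migration), the out-of-bag misclassification rate ("prior error
rate") with its confusion matrix, and the posterior probability of the
selected scenario — a regression forest trained on the out-of-bag
classification-success indicator, evaluated at the observed point and
clipped to [0, 1]. Parameter estimation uses quantile regression forests
(Meinshausen 2006): point estimate = forest mean; 5/50/95% quantiles from
the leaf-co-occupancy-weighted distribution of training responses; a
flatness diagnostic divides the posterior 5–95% width by the prior's
(0.9 × range for a uniform prior) — values near 1 mean the summaries carry
little information about that parameter. Forests are deterministic given
(table, seed, number of trees). Reference tables default to 2,000 rows per
model for desk-scale work; 50,000 per model is the flag-selectable
full-scale setting. Row i of model j is seeded `base_seed + j·n + i`, so
any row is reproducible in isolation.

### Separability and the separated test regime

Under the default Bronze-Age-scale times (67 and 150 generations at g = 30)
and wide Ne priors, the three scenarios are close to indistinguishable from
marginal SFS summaries: the splits are far too recent relative to
coalescent timescales for topology to mark the spectra, and the random
forest's out-of-bag error approaches the 2/3 chance level. This is a real
property of the inference problem at these timescales, not an implementation
artifact. Recovery tests therefore use a documented *separated regime*:
disjoint source-size priors (AA ~ U(10³, 5×10³), DAI ~ U(5×10⁴, 10⁵),
TARGET ~ U(5×10³, 2×10⁴)), split times deep relative to deme sizes
(t_target = 30 kyr, t_root = 300 kyr), L = 500 kb, migration prior
U(5×10⁻³, 5×10⁻²), n = 10 per deme. In this regime the classifier's
out-of-bag error is ≈ 5% and true scenarios are recovered from
pseudo-observed data ≥ 90% of the time. Conversely, shrinking the migration
prior's upper bound toward zero makes continuous migration converge to
demic (they are the same process at m = 0) and classification accuracy
falls — a monotonicity the tests check.

## Synthetic study generator

`generate_study` emulates the statistical shape of a multi-population
haploid survey: three language-family blocks, each an island model
(symmetric migration among its populations) run through the same coalescent
engine. The AA-like block uses small deme sizes (Ne = 1,500) and low
migration (10⁻⁴/generation), the TK- and ST-like blocks larger sizes
(6,000) and high migration (2×10⁻³), which produces the designed contrasts:
lower within-population diversity and higher among-population heterogeneity
in the AA-like block. Residence labels default to patrilocal for the
AA-like and matrilocal for the ST-like block, so the residence contrasts
have a known construction direction. Blocks are simulated independently and
carry disjoint polymorphic-site sets (other blocks remain ancestral at
them); coordinates are block centers with Gaussian jitter. Defaults are
desk-scale — 12 populations (5 AA-like, 5 TK-like, 2 ST-like), n = 15,
L = 50 kb — and run in seconds. All randomness descends from the single
design seed through spawned per-block streams, and a truth manifest records
every generating parameter.

What the generator does **not** emulate: shared ancestry between blocks
(blocks are independent; real language families share deep history),
haplogroup-specific mutation processes, missing data, sequencing error, or
uneven sample sizes. Passing tests on this data demonstrate that the
statistics and the inference machinery behave correctly under their own
model assumptions; they do not validate the historical conclusions one
would draw from real data.

Clade-based haplogroup labels for testing haplogroup diversity come from
cutting a genealogy at an age threshold: every subtree hanging from a branch
crossing the threshold gets one label.

## Numerical and design choices

* Add-one permutation p-values everywhere: p = (b + 1)/(B + 1).
* Negative AMOVA components retained; percentage normalization on the
  signed sum.
* Tajima's D returns NaN for S = 0 rather than raising, so population
  tables can include monomorphic populations.
* NMDS restarts share one seeded generator, so the whole ordination is
  reproducible from a single seed.
* Pipeline runs derive one sub-seed per stage from the master seed; every
  consumed seed is recorded in the run manifest, and two runs from the same
  config are value-identical (timings excluded).
* Test problem sizes: simulation-based checks use 2,000 replicates for
  coalescent expectations, 200 seeded null datasets (199 permutations each)
  for p-value calibration, 200 replicates per grid point for the
  split-time/migration monotonicity checks, 2,000-row-per-model reference
  tables with 500 trees and 100 pseudo-observed datasets per scenario for
  scenario recovery, and 50 replicates for parameter recovery — sizes chosen
  to keep Monte-Carlo error comfortably below the tested margins while the
  full suite runs in a few minutes.

## Known limitations

* The coalescent engine is continuous-time (no discrete-generation
  Wright–Fisher correction); for the small per-generation rates used here
  the approximation error is negligible.
* Marginal per-deme SFS summaries discard cross-deme allele sharing, which
  is the main signal distinguishing split topologies at recent timescales;
  adding d_A summaries (available as an option) or joint spectra would
  sharpen scenario choice.
* The exact-U path of the rank test is used only for untied data; tied
  small-sample p-values fall back to the tie-corrected normal
  approximation.
* No recombination, selection, or within-branch growth; at most three demes
  in the scenario models.
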