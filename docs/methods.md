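# Methods

This note documents the statistical model behind `standscape`, the
estimator and design choices where more than one convention exists, the
simulator that the validation suite runs against, and what the passing
tests do and do not establish about real field data.

## The system being modelled

The target data are dense SNP surveys of an annual, self-compatible,
predominantly selfing plant sampled from many small stands in one region.
A *stand* is a contiguous cluster of plants treated as the population
unit; stands sit tens of meters to tens of kilometers apart. Genotypes are
biallelic dosages (0/1/2 copies of allele b, −1 missing) at a few hundred
markers spread over five chromosomes — about one marker per 250 kb at the
default density, enough to see individual recombination events as changes
of mosaic block state.

Under near-complete selfing, heterozygosity halves every selfed
generation, so almost all standing variation is between fully homozygous
lines. Outcrossing at per-ovule rate `t` regenerates heterozygotes; at
equilibrium with unrelated partners the within-stand inbreeding
coefficient satisfies F = (1−t)/(1+t). Inverting this gives the
*effective outcrossing rate*

    OC = 1 − 2F_IS/(1+F_IS) = (1−F_IS)/(1+F_IS),

"effective" because anything that removes heterozygotes relative to
Hardy–Weinberg — true selfing, mating among relatives, fine-scale spatial
structure (the Wahlund effect) — raises F_IS and depresses OC below the
true mating rate. The package therefore treats OC strictly as a
heterozygote-generation rate, and quantifies the Wahlund contribution
separately via the transect statistics (below).

## Estimators

**Gene diversity (He).** Nei & Chesser's (1983) unbiased estimator per
marker, `He = n/(n−1) · (1 − Σ p̂² − Ho/(2n))` with `n` called
individuals. The more common `2n/(2n−1) · (1 − Σ p̂²)` correction assumes
the 2n alleles are independent draws; under selfing the two alleles of a
plant are nearly always identical by descent, which leaves that correction
with an n-dependent bias of several percent — enough to make a 10-plant
subsample systematically disagree with a 30-plant full sample on the same
stand. The Nei–Chesser form conditions on the observed heterozygosity and
is unbiased at any inbreeding level; the validation suite checks this by
comparing the subsampling procedure with full-sample estimates over 200
simulated selfing stands. Monomorphic markers contribute He = 0 to the
genome mean (a monotypic stand has He = 0 by definition).

**1−Q.** Q is the probability that one allele drawn from each of two
distinct plants of a stand is identical, computed per marker from the
per-individual allele frequencies (0, ½, 1) over ordered pairs, then
averaged across markers. It is a pure identity measure with no
Hardy–Weinberg reference, which makes it a useful companion to He in
highly inbred material.

**F-statistics.** Weir & Cockerham's (1984) variance components, per
locus: `a` (among stands), `b` (among plants within stands), `c` (within
plants, = half the observed heterozygote frequency). Multilocus statistics
are ratios of component sums over loci — F_IS = 1 − Σc/Σ(b+c),
F_ST = Σa/Σ(a+b+c) — the standard small-sample-robust combination. Loci
monomorphic across the analysed units are excluded from these ratios (they
carry no information about heterozygote deficit or differentiation). A
single stand uses the r=1 reduction of the same components. The
implementation is verified against an independently coded gametic-ANOVA
oracle to 1e−12 on randomized instances: the two derivations are
algebraically identical, so any discrepancy would be a coding error.

**Size-corrected stand statistics.** Stands differ greatly in sample size
(1–30 plants), and diversity estimates at different n are not directly
comparable. For every stand with ≥10 plants the package draws random
subsamples of 10 without replacement, computes per-marker He and
variance components, repeats 100 times, averages per marker and then
across the genome; the stand F_IS is the ratio of rep-averaged component
sums. 95% CIs come from bootstrapping loci (1,000 draws) on the
rep-averaged per-marker values. A caveat stated once and relied on
nowhere: under selfing, loci are strongly correlated through identity
disequilibrium (a recently outcrossed plant is heterozygous at many loci
at once), so locus-bootstrap CIs on F_IS are anti-conservative for small
stands; where the validation suite needs a calibrated interval for a
pooled estimate it resamples stands, the independent units, instead.

**Year-to-year F_ST.** Two samples of the same stand in successive years
are compared by subsampling the larger down to the size of the smaller,
computing pairwise theta, and averaging over 100 replicates, so that
sample-size asymmetry does not masquerade as differentiation.

## Spatial statistics

**Correlograms.** Pairs of plants are binned into contiguous geographic
distance classes (defaults mirror a ~40 km survey: 10 classes of 3.84 km,
or 30 of 0.5 km). Per class, Moran's I is computed on per-individual
allele scores y ∈ {0, ½, 1} with equal (binary) weights within the class,
averaged over polymorphic markers; for biallelic markers the two alleles
give the same I, so each marker enters once. The distogram uses the
Gregorius distance, which for dosage data reduces to |y_i − y_j| averaged
over loci. Confidence envelopes come from permuting which plant sits at
which sampled location (500 permutations by default); the permutation
unit is the individual. The analytic null mean of Moran's I, −1/(n−1), is
used as a correctness check on the permutation machinery. The exact
weighting and permutation conventions of legacy spatial-genetics software
are not published; these choices are documented here and validated against
their own oracles rather than against any particular program's output.

**Aggregation.** The Clark–Evans ratio R = (mean nearest-neighbor
distance)/(0.5/√(n/area)), with Monte-Carlo significance from uniform
placements in a square of equal area. R < 1 indicates clumping; R = 0
coincident points. For stand-structured surveys R is dominated by the
stand structure itself and is reported as a descriptive index.

**Transect statistics.** For stands sampled along a line, C2 is the
proportion of plants with at least one identical (same-MLG) neighbor,
computed over all n plants; C3 is the proportion flanked by two identical
neighbors, computed over the n−2 interior plants. 0 ≤ C3 ≤ C2 ≤ 1, with
equality at 1 exactly for a monotypic transect. Regressing stand F_IS on
C3 quantifies how much of the homozygosity excess is attributable to
spatial clustering of identical genotypes plus short-range mating — the
Wahlund signal.

## Multilocus genotypes and outcrossing footprints

**MLG identity.** Two plants share an MLG when they agree at every marker
where both are called, each has ≥95% call rate, and membership is closed
transitively. The threshold prevents sparsely genotyped plants from
bridging distinct genotypes; wildcard matching prevents a single missing
call from splitting a clone. Monotypy is judged on this partition.

**Mosaic blocks.** A pairwise profile labels each marker identical (equal
homozygous calls), divergent (opposite homozygotes), het-involved, or
missing; the latter two are neutral everywhere. Blocks are maximal runs of
informative state per chromosome; runs shorter than `min_run` (default 5)
are absorbed into the longer flank, shortest-first, which makes the
segmentation deterministic and, at `min_run=1`, lossless. Block
coordinates are marker indices (0-based, inclusive) with bp spans from the
map; a crossover is localized only to the interval between informative
markers.

**Heterozygous stretches.** Maximal runs of dosage-1 calls per chromosome
with at least `min_run=3` heterozygous markers, tolerating
`max_interrupt=1` called homozygous marker inside a run. The defaults are
conservative at ~1 marker/250 kb: a genuine outcross one-or-few
generations back leaves tens of contiguous heterozygous markers, while an
isolated heterozygous call is more likely a genotyping artifact. How long
a run must be to count as outcrossing rather than artifact is a judgment
call; both knobs are exposed.

**F1 assignment.** Among homozygous candidate MLGs of a stand, the parent
pair maximizing the fraction of differentiating markers at which the
child is heterozygous (ties: more differentiating markers, then
lexicographic ids). A `first_generation` verdict requires heterozygosity
at *all* differentiating markers (threshold 1.0) and agreement with the
parents' shared state elsewhere; partial heterozygosity (~½ after one
selfed generation) yields `later_generation_or_recombinant`; zero yields
`none`. With a few hundred differentiating markers the probability that a
later-generation descendant passes the 100% threshold is ~2^(−k), so the
default threshold produces no false F1 calls in practice — the validation
suite checks for exactly zero on pedigree-logged pure-selfed plants.

**RIL reconstruction.** For a stand suspected to descend from a single
ancient cross, every pair of distinct homozygous MLGs is tried as the
founder pair; every genotype is painted by founder origin where the
founders differ; breakpoints are label switches along each chromosome; a
marker matching neither founder (counted over all markers, not only
differentiating ones — otherwise a recombinant line could itself pose as
a founder at zero cost) is unexplained. The best pair minimizes total
unexplained, then total breakpoints. Because a homozygous genotype
matches exactly one founder wherever the founders differ, the painting is
forced and the scan's breakpoint count equals the exhaustive minimum; the
suite verifies this by enumeration on ≤12-differentiating-marker
instances.

## Clustering

The individual-level distance is the allele-sharing distance
d = 1 − (shared alleles/2) averaged over jointly called markers, the
natural metric for dosage data and the basis of nonparametric clustering
when model-based ancestry assumptions (free outcrossing, Hardy–Weinberg)
are violated. Published survey analyses of this kind sometimes use
likelihood distances from sequence-evolution software whose exact model
settings are not reproducible from their text; the allele-sharing distance
is substituted deliberately, so absolute within/between distance means are
not comparable to such reports — only their contrasts are. Trees are
scipy agglomerative linkages (Ward by default) with deterministic
tie-breaking; Newick export uses half-height branch lengths so tip-to-tip
path lengths equal cophenetic distances. The gap statistic compares
log within-cluster dispersion against B = 100 reference datasets that
redraw each marker's dosages from its observed frequencies (preserving
allele frequencies, destroying linkage and structure), and selects the
smallest K with gap(K) ≥ gap(K+1) − se(K+1). Clustering input is one
representative per MLG per (stand, year).

## The simulator

Discrete non-overlapping generations; per-stand fixed carrying capacity
(an annual plant with a saturating seed rain); no seed bank; no mutation
(at tens of generations the per-base mutation rate is orders of magnitude
below any outcrossing rate of interest); no selection. Founders are fully
inbred lines: independent draws per marker with allele-b frequency uniform
in `maf_range` (default 0.2–0.5, intermediate-frequency markers as in
genotyping panels designed for informativeness). Markers are placed
uniformly over the five A. thaliana chromosome lengths (30.4, 19.7, 23.5,
18.6, 27.0 Mb); any five lengths are accepted.

Each offspring picks a uniform ovule parent; with probability `t` a pollen
parent is drawn from the other plants of the stand (uniformly if
`mating_kernel_sigma` is infinite, else Gaussian-weighted by distance),
otherwise the ovule self-fertilizes. Meiosis draws Poisson(`recomb_rate`,
default 1 per chromosome) crossovers at uniform bp positions. Offspring
are placed at the mother's position plus Gaussian seed-dispersal noise, so
selfing lineages form spatial patches — the substrate for the Wahlund and
transect analyses. Migration moves one selfed seed between stands with a
small per-stand probability. Every birth is logged (mother, father, selfed
flag, crossover positions), so F1 status, parentage, migration origin and
RIL paintings all have exact truth.

What the simulator does *not* emulate: seed banks and overlapping
generations, pollinator behavior beyond an isotropic kernel, selection
(including heterozygote advantage), genotyping error, and de novo
mutation. Passing tests therefore establish that the estimators recover
the truth of this model at field-like parameter values; they do not rule
out biases that these omitted processes could introduce in real data.

## Validation design choices and numerical notes

* **Equilibrium recovery runs** use 30 stands × 20 plants × 436 markers
  with fully homozygous founders and 10 generations: the heterozygosity
  recursion F' = (1−t)(1+F)/2 converges geometrically at rate ≈ ½, so 10
  generations reaches equilibrium to <1e−3, while drift in 20-plant
  stands (Ne ≈ N/(1+F) ≈ 10) has had as little time as possible to erode
  polymorphism and make "random partner" mean "related partner". Longer
  horizons measurably depress the pooled F_IS below (1−t)/(1+t) (by
  ~0.01–0.02 at 15–20 generations); a single 1000-plant stand reproduces
  the law to four decimals, confirming the deviation is a finite-stand
  property, not an estimator error. Confidence intervals for the pooled
  estimate resample stands, the independent units.
* **Per-stand OC at very low t** is granular: at t = 0.02 a 20-plant
  stand contains no heterozygous plant about half the time (and field
  surveys of this system indeed find most stands without a single
  heterozygote), so the median per-stand OC sits at or near zero and is
  not a consistent estimator of t at this sample size; the pooled
  multilocus F_IS is the reliable recovery route there.
* Reported percentages are rounded to one decimal, statistics to three.
* Degenerate inputs are flagged rather than silently dropped: monomorphic
  panels give NaN F-statistics with a zero informative-locus count;
  all-coincident points give R = 0; identical constant matrices raise on
  Mantel input; empty distance classes yield NaN with a flag.
* All stochastic procedures take explicit seeds; the pipeline derives one
  stream per stage from a master seed (CRC-tagged SeedSequence), so stages
  rerun independently reproduce byte-identical outputs.

## Known limitations

* GENEPOP I/O covers the package's own biallelic 2-digit convention, not
  the full format zoo (3-digit codes, haploid blocks).
* The gap statistic inherits the known flatness of its selection rule for
  weakly separated groups; K̂ should be read alongside the gap curve.
* Locus-bootstrap CIs understate uncertainty for small inbred stands (see
  above); they are reported because they are the field's convention.
* The aggregation index uses a square study area; for strongly elongated
  regions the CSR expectation is approximate.
* VCF ingestion and >2 alleles per marker are out of scope; the genotype
  table TSV is the interchange format.
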