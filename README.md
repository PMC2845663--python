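# standscape

Local-scale population genetics of predominantly selfing plant stands.

Highly selfing annual plants — *Arabidopsis thaliana* is the canonical
case — grow in small, patchy stands that are strongly differentiated from
one another even over tens of meters. Dense genome-wide SNP genotyping of
such stands reveals a distinctive local anatomy: most plants are fully
homozygous, many stands carry a single multilocus genotype (MLG), and yet
occasional outcrossing leaves unmistakable marks — heterozygous stretches
of linked markers, first-generation hybrids between resident genotypes,
and stands whose whole genotype inventory is a set of *natural recombinant
inbred lines* descended from one ancient cross.

`standscape` is a library for analysing exactly this kind of data, plus a
forward-time simulator of selfing metapopulations with complete pedigree
truth for validating every estimator against a known answer.

## What it computes

* **Genotype handling** (`standscape.core`) — TSV genotype tables and
  marker maps, MLG identification with a missing-data-tolerant identity
  rule, per-stand censuses (monotypy, heterozygote counts), MLGs shared
  between stands with geographic distances, GENEPOP export/import.
* **Diversity and inbreeding** (`standscape.popgen`) — gene diversity
  He (Nei–Chesser unbiased estimator), the inter-individual identity
  diversity 1−Q, observed heterozygosity, Weir–Cockerham variance-component
  F-statistics (F_IS, F_ST, F_IT), size-corrected estimates by repeated
  10-plant subsampling with locus-bootstrap CIs, matched-subsample
  year-to-year F_ST, and the effective-outcrossing transform

      OC = 1 − 2·F_IS / (1 + F_IS) = (1 − F_IS) / (1 + F_IS),

  the outcrossing rate that would produce the observed heterozygote
  deficit at inbreeding equilibrium (F_IS = (1−t)/(1+t) under mixed
  mating with outcrossing rate t).
* **Spatial structure** (`standscape.spatial`) — Mantel tests, Moran's I
  correlograms and Gregorius-D_G distograms over geographic distance
  classes with permutation envelopes, Clark–Evans aggregation index, and
  the within-stand transect statistics C2/C3 (proportions of plants with
  one / two flanking identical neighbors) with their regression on F_IS.
* **Outcrossing footprints** (`standscape.mosaic`) — pairwise
  identity/divergence mosaic blocks along chromosomes, heterozygous-stretch
  detection, F1 parent-pair assignment, and minimal-breakpoint
  reconstruction of natural recombinant-inbred stands.
* **Clustering** (`standscape.clustering`) — allele-sharing distances,
  within- vs between-stand distance distributions, agglomerative
  dendrograms with Newick export, gap-statistic choice of cluster number,
  rural-vs-urban rank-sum comparisons.
* **Simulation** (`standscape.simulate`) — discrete-generation selfing
  metapopulations: per-ovule outcrossing probability, Gaussian pollen and
  seed dispersal kernels, Poisson recombination on the five
  *A. thaliana*-length chromosomes, rare between-stand migration, and a
  full pedigree/event log (parents, selfing flags, crossover positions).
* **Pipeline** (`standscape.pipeline`) — `run_all` executes the whole
  analysis on simulated or ingested data and writes census, MLG-frequency,
  diversity/outcrossing and shared-MLG tables with a reproducibility
  manifest.

## A worked example

```bash
python examples/stand_diversity.py
```

simulates twelve stands — six "urban" with essentially no outcrossing and
six "rural" with t up to 10% — surveys them, and prints size-corrected
per-stand statistics:

```
 stand   site     He   F_IS    OC%
  S001  urban  0.147  1.000    0.0
  S002  urban  0.205  1.000    0.0
  S003  urban  0.000    nan    nan
  ...
  S010  rural  0.181  0.655   20.8
  S011  rural  0.253  0.796   11.4
  S012  rural  0.307  0.742   14.8

rural mean F_IS 0.862 vs urban 1.000 (Mann-Whitney p = 0.045)
```

Monotypic stands have He = 0 and an undefined F_IS; fully homozygous
polymorphic stands have F_IS = 1 (OC = 0%); stands where outcrossing is
ongoing show depressed F_IS, and the transform reads that as an effective
outcrossing rate — e.g. F_IS = 0.742 implies OC ≈ 14.8%. An overall
multilocus F_IS of 0.969 corresponds to OC = 1.6%, the regime typical of
wild *A. thaliana*.

The other scripts in `examples/` each demonstrate one capability:
`simulate_survey.py` (census of a simulated survey),
`spatial_autocorrelation.py` (correlograms, Mantel, aggregation),
`outcrossing_footprints.py` (het stretches, F1 calls, mosaic blocks, RIL
reconstruction), `cluster_genotypes.py` (distances, dendrogram, gap
statistic) and `full_study.py` (the end-to-end pipeline).

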