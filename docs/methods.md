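# Methods

`prebreedsim` simulates a genomic-selection pre-breeding program that mines
polygenic variation from maize landrace accessions: a discovery phase that
trains a prediction equation on a landrace × elite testcross population and
selects founder seeds, and an improvement phase that recurrently selects a
synthetic population formed from those seeds. This note records the models,
the parameters that matter, and the numerical choices, in the order the
pipeline runs them.

## Founder genomes

Founder haplotypes are sampled from a neutral coalescent with recombination
(msprime), one independent simulation per chromosome. The genome is maize-like
by default: 10 chromosomes of 2 Morgans (desk-scale runs shorten them; see
below). Coordinates are genetic throughout; an internal 10⁶ bp scaffold per
chromosome exists only to give msprime a sequence axis, with the per-bp
recombination rate set so the chromosome's total map length is exact.

`Ne` counts haploid founder lineages (msprime `ploidy=1`, pairwise coalescence
rate 1/Ne, θ = 2·Ne·μ per bp). The mutation rate is chosen adaptively so the
expected number of sites surviving the minor-allele-frequency filter
(MAF ≥ 0.05 by default) is about twice the locus budget; the frequency-spectrum
tail sum θ·ln((1−maf)/maf) gives that expectation. Surviving sites are thinned
evenly (by site rank) to the budget; a shortfall is a hard error naming the
deficit, never a silent smaller map. Allele 0 is ancestral. Loci are then
partitioned at random into QTL-eligible loci and candidate markers (disjoint
sets, so a marker is never a QTL).

## Landrace accessions

Each accession is founded from 4 founder haplotypes drawn from the panel
(shared across accessions, which produces the small background kinship between
landraces and the elite hybrid). A pool of `pool_size` plants (50 at full
scale; large enough to supply training and tested seeds disjointly) is then
bred under mixed selfing/outcrossing: the per-generation selfing probability
s = 2F/(1+F) has equilibrium inbreeding F, and the recursion
F_{t+1} = s/2·(1+F_t), started at the distinct-pair founding value
F₀ = −1/(k−1), gives analytically the number of generations needed to come
within 0.01 of the target (capped at 20; the cap is an error, not a clamp).
Realized inbreeding is estimated per accession as F̂ = 1 − ΣH_obs/ΣH_exp over
polymorphic loci, with the small-sample 2n/(2n−1) correction on expected
heterozygosity; the mean |F̂ − F| over accessions stays within 0.05 of target.
F is thus an excess-homozygosity coefficient (F_IS) relative to the
accession's *own* allele frequencies - pedigree autozygosity from the four
founders is necessarily higher in a small closed accession, and very small
seed pools (below ~15 plants) read a few points low on F̂ because drift
absorbs homozygosity into shifted frequencies.

## The elite hybrid

Two closed sub-populations are drawn from the founder panel and undergo
truncation selection on true breeding value; each is fixed through the best of
several doubled haploids of its best plant, and the elite hybrid is the F1 of
the two inbreds. Selection runs at least 5 generations and continues until the
prospective hybrid (mid-parent of the two sub-population leaders) is 16.8
landrace genetic standard deviations above the landrace mean, the superiority
that a landrace-normalized merit of 1 corresponds to in this design: on this
scale one merit unit equals about 16.8 GSD, so placing the elite at merit 1
and the landrace mean at 0 fixes the gap. Desk-scale worlds (100 QTL) hit
their Robertson selection limit near 11 SD and stop at the generation cap;
their merit values are therefore modestly inflated relative to a full-scale
world, a known and accepted distortion.

Because the inbreds fix favorable QTL alleles inside two small closed gene
pools, the elite genome carries those alleles in marker phases of its own -
the property that later breaks landrace-trained predictions in elite ×
landrace material.

## Meiosis and identity by descent

Gametes follow the Haldane model: per chromosome, crossover count ~
Poisson(genetic length in Morgans), positions uniform, no interference, no
obligate chiasma, fair-coin starting strand. Every haplotype carries an origin
track - a piecewise-constant map from genetic position to founder haplotype id
- spliced through each meiosis, so identity by descent is exact bookkeeping,
not an estimate. Reconstructing alleles from origin tracks plus the founder
panel must reproduce stored alleles bit-for-bit; the suite asserts this
invariant after founding, crossing, and doubling. Random mating excludes
selfing (each seed's father is drawn uniformly from the other plants).

## GBS genotyping

Read depth per locus per individual is Poisson at the platform coverage (10×
for the 10K panel, 1× for the 100K panel); each read reports the wrong allele
with probability 0.005. Dosages are posterior means of the genotype given the
reads under a Hardy–Weinberg prior at the current population's allele
frequency - continuous, never hard-called, which is what makes the 1× platform
usable. Zero-read entries are flagged missing and imputed to twice the allele
frequency, keeping the ridge design matrix complete. Marker panels are sampled
from the candidate set approximately uniformly on the genetic map
(per-chromosome counts proportional to map length).

## Trait and phenotypes

The trait is strictly additive: QTL effects are iid standard normal, TBV is
the dosage-weighted effect sum. Heritability is defined on the testcross
phenotype in the initial training population: σ²ₑ is calibrated there once per
replicate so Var(TBV)/(Var(TBV)+σ²ₑ) equals the scenario h², then held fixed
for all later phenotyping, including improvement-phase retraining. One
phenotype per testcross; h² = 0 is rejected (no training signal).

## Genomic prediction

Marker effects minimize ‖y − 1μ − Xβ‖² + λ‖β‖² with the RR-BLUP rule
λ = m(1−h²)/h² (m = markers, h² the scenario's true value; the equation is
never re-estimated by REML). Columns are centered by training means; the
system is solved in the n×n dual when n < m and in the primal otherwise, and
the two agree to 10⁻⁸. λ = 0 is an explicit OLS mode used only by tests.
Retraining in the improvement phase uses a cycle's synthetic-seed data alone
(discovery data excluded) and the updated equation becomes usable only in the
next cycle, because testcross phenotypes take two seasons to collect.

## Program stages and metrics

* **T** - grow 1/3/5 seeds per accession, testcross each to the elite hybrid,
  phenotype, regress testcross phenotypes on the *landrace seed* genotypes.
* **A** - rank accessions by mean EBV of their training seeds; keep 40 or 80.
* **S** - genotype 10/20/40 fresh seeds per selected accession (disjoint from
  training seeds) and select the best 10 with at most one per accession;
  units are those seeds (Landrace), their best doubled haploids by EBV
  (LandraceDH), or the selected landrace × elite testcross seeds
  (LandraceElite).
* **C1–C4** - random-mate the 10 plants, genotype 10 seeds per plant (100),
  select the top 10 by EBV with the equation available that cycle, phenotype
  0/20/40/60 of the remaining seeds as testcrosses, retrain.

Metrics per stage: normalized merit (mean TBV mapped so landraces are 0 and
the elite hybrid 1), prediction accuracy (Pearson EBV–TBV), kinship with the
elite hybrid, and heterozygosity over the sites segregating in the initial
landrace population (frozen at simulation start). Merit, kinship and
heterozygosity are computed on the stage's germplasm (training seeds; all
seeds of selected accessions; the 10 selected units; the 10 selected seeds per
cycle). Accuracy is computed on the genotyped *candidate pool* of the stage
(training seeds at T; all accessions at A, as the correlation between
accession-mean EBV and accession-mean TBV; the 400–3,200 stage-3 seeds at S;
the 100 candidates per cycle), because a correlation over 10
strongly-selected individuals measures nothing.

Kinship is the proportion of 1 cM genome bins whose founder-origin labels are
identical across the whole bin, averaged over the four (germplasm haplotype ×
elite haplotype) pairs, all bins, and all individuals - computed exactly from
the origin tracks by interval arithmetic, no grid sampling. An IBS mode
(allele identity per bin) exists for comparison and can only score higher,
markedly so in low-diversity founder worlds where unrelated copies of a
haplotype look identical. Expected anchors: elite hybrid against itself 0.5;
an elite inbred against itself 1; landrace × elite F1 seeds against the elite
hybrid 0.25 (the F1's elite-derived gamete matches one of the two elite
haplotypes wherever the bin is unbroken).

A reporting helper expresses response in landrace genetic standard deviations,
total and per season, with a configurable seasons map (6 seasons for the
Landrace and LandraceElite routes, 9 for LandraceDH, which spends two extra
seasons making doubled haploids; one phenotyping season each, as the program
scheme implies but does not itemize).

## Decision analysis

Marginal factor effects come from one-way linear models per design factor:
level means, 2.5/97.5% quantiles over scenarios × replicates, pairwise t
comparisons on the pooled residual variance, and a compact letter display
(maximal runs of mutually non-significant levels in mean order). The decision
tree recursively partitions records: at each node every factor with ≥ 2
observed levels is tested with a permutation F-test (1,000 permutations,
seeded per node path), p-values are Bonferroni-adjusted across the factors
tested at that node, and the winning factor splits into the two level groups
maximizing the between-group sum of squares - ordinal factors split only at
order-respecting cutpoints, categorical factors over all 2-partitions (≤ 12
levels enforced). Without the Bonferroni step an α = 0.01 gate over six
factors would fire on pure noise ~6% of the time; with it the false-split rate
stays under the 5% the suite asserts. Splitting stops when no adjusted p-value
clears α or the node is smaller than `min_leaf`.

## Desk-scale study conditions

The full design (3,000 accessions, 100,000 markers, founder Ne up to 100,000,
3,456 scenarios × 10 replicates) is a cluster-scale computation; the
coalescent alone is intractable at Ne = 100,000 (ρ = 4·Ne·L ≈ 8·10⁵ per
chromosome). The desk conditions in `prebreedsim.desk` shrink the world about
tenfold - 300 accessions, 200/2,000-marker panels, 100 QTL, 400 founder
haplotypes, 10 chromosomes of 0.25 Morgan - and use Ne = 1,000 and 10,000 as
the low/high founder-diversity levels. Coalescent cost grows with Ne × map
length, and of the two the prediction-breakdown phenomenon needs high Ne far
more than map length: it exists because at high founder diversity selection
fixes favorable QTL alleles in the elite *without* dragging the coupled
marker alleles along (marker-QTL LD is weak), so the elite's marker profile
scores near the training mean while the selected landrace gametes score high
- which is what makes elite genome fraction anticorrelate with EBV in the
synthetic population. The desk genome therefore keeps Ne at 10,000 and
shortens the chromosomes. The design-comparison bundle fixes the genetic
parameters where the phenomenon is most pronounced (high diversity, F = 0.9,
h² = 0.25) and uses five seeds per landrace (a 1,500-testcross training
population).

What desk-scale runs do show: the ordering and signs of the design
comparison - LandraceElite starts near merit 0.5 and stays most kin to the
elite; Landrace/LandraceDH stay distinct (kinship ≈ 0) and gain merit when
retraining is on; the first synthetic generation of LandraceElite is predicted
with negative accuracy by the landrace-trained equation; omitting retraining
depresses final merit. What they do not show: full-scale magnitudes. With a
~10× smaller training population accuracies sit below the full-scale values,
selection intensities per accession differ (40 of 300 versus 40 of 3,000), and
the elite gap caps near 11 SD, inflating landrace-side merit values. The
simulated landraces also carry none of the demographic structure of real
Mexican material - no admixture gradients, sweeps, or genotype × environment -
so passing tests validate the method's internal logic, not its field
performance.

## Determinism and seeds

Every run derives child seeds from a master seed through `SeedSequence` keyed
by *values* (replicate, Ne, F, h², platform size, …), never by position in a
scenario list: a scenario's records are identical whether it runs alone or
inside a grid, and rerunning any grid with the same master seed reproduces the
table exactly. Worlds are shared across scenarios that differ only in
logistics; discovery stages are shared across scenarios that differ only in
approach or retraining level, which is also how the factorial is affordable.

## Known limitations

Biallelic loci only; no dominance, epistasis, genotype × environment, or
selection during accession maintenance; no restriction-site dropout or batch
effects in GBS; random mating of synthetics assumes no selfing (the program
text leaves this open); the season bookkeeping is a configurable reporting
convention, not a schedule simulator.
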