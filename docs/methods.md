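# Methods

`invclines` analyses phased single-chromosome haplotypes of a species with
polymorphic chromosomal inversions, sampled along a geographic transect.
Each haplotype carries an arrangement label (its karyotypic class, e.g.
`J_ST` standard vs `J_1` inverted) and a multiallelic genotype (fragment
size in bp) at every microsatellite mapped on that chromosome.  The core
idea throughout is to treat each (population, chromosome, arrangement)
combination as an analysis unit, because suppressed recombination in
inversion heterokaryotypes lets different arrangements maintain distinct
gene pools even inside one panmictic population.

## Analysis units and missing data

Haplotypes are grouped by (population, arrangement); groups smaller than
`min_group_size` (default 7, the smallest unit a study of this design
retains) are dropped with a warning.  Missing alleles are removed
locus-wise (pairwise deletion), so per-locus sample sizes within a group
may differ; no haplotype is discarded for a single failed locus.  Allele
identity is the fragment size in base pairs, with no repeat-unit binning.

## Gene diversity

Nei's unbiased gene diversity for haploid samples,
He = n/(n−1) · (1 − Σ p̂ᵢ²), is the default; a biased mode (no n/(n−1))
exists because published arrangement-frequency tables sometimes omit n.
Where a variance-stabilised response is needed (ANOVA-style contrasts,
latitude regressions) the arcsine-square-root transform asin(√x), in
radians, is applied.

## Haploid F_ST (θ)

Differentiation is estimated by a one-way ANOVA on allele indicator
variables — the haploid analogue of the Weir–Cockerham estimator.  Per
locus and allele u: SSA = Σₖ nₖ(p_ku − p̄_u)² with r−1 df, SSW =
Σₖ nₖ p_ku(1−p_ku) with n−r df, n_c = (n − Σnₖ²/n)/(r−1), σ²ₐ =
(MSA−MSW)/n_c, σ²_w = MSW; θ is the ratio of summed components, over
alleles within a locus and over loci for the multi-locus value
(ratio-of-sums, not mean-of-ratios).  This is mathematically the
haplotypic AMOVA F_ST with allele-identity distance, so we implement θ
directly rather than AMOVA's SSD bookkeeping.  Significance comes from
permuting whole haplotypes among the compared groups (sizes preserved),
p = (1 + #{θ* ≥ θ})/(B+1) with B = 10 000 by default.

The between/within partition computes one "between" θ over all
population×arrangement units of a chromosome and one "within" θ per
arrangement across populations; their per-locus vectors are compared by
an exact one-sided paired Wilcoxon signed-rank, pairing each locus's
between value with its mean within value.  Pairing by locus is a design
choice: the locus is the natural exchangeable unit when the same markers
are scored in every partition.  Negative pairwise θ estimates are
retained in matrices (they are information for the signed-rank test) and
clamped to zero only inside PCoA, where θ is treated as a squared
dissimilarity: classical scaling (Gower double-centering of −F/2,
eigendecomposition, coordinates scaled by √λ) with percent variation
reported over positive eigenvalues.

## Linkage disequilibrium

Marker–inversion association treats the inversion as a pseudo-locus whose
alleles are the frequent arrangements.  We use Hedrick's multiallelic
normalization of Lewontin's D′: D′m = Σᵢⱼ pᵢ qⱼ |D′ᵢⱼ| with D′ᵢⱼ =
(xᵢⱼ − pᵢqⱼ)/Dmax and the usual sign-dependent Dmax.  (Some sources print
the weight as pᵢqᵢ; that repeated subscript does not define a valid
bivariate weighting and we read it as a typographical slip for pᵢqⱼ, the
PowerMarker definition.)  Significance uses a Monte-Carlo Fisher exact
test: category labels are permuted against allele labels and the
statistic is the table's conditional hypergeometric probability, so the
p-value converges to Fisher's two-sided probability-based p.  Per-allele
associations collapse each (allele, arrangement) cell to a 2×2 table,
report D′ and a Yates-corrected χ²₁, and are flagged unreliable below 3
joint observations regardless of p.

Multiple testing uses the Benjamini–Yekutieli step-up by default (valid
under arbitrary dependence, the usual recommendation for genetic scans);
Benjamini–Hochberg is available.

Ohta's variance decomposition for a locus pair across subpopulations is
computed from observed gametic frequencies with unweighted subpopulation
averages (a weighted mode exists):

    D²_IS  = Σᵢⱼ E_k(xᵢⱼₖ − pᵢₖqⱼₖ)²      within-population LD variance
    D²_ST  = Σᵢⱼ E_k(pᵢₖqⱼₖ − p̄ᵢq̄ⱼ)²
    D′²_IS = Σᵢⱼ E_k(xᵢⱼₖ − x̄ᵢⱼ)²         among-population variance of LD
    D′²_ST = Σᵢⱼ (x̄ᵢⱼ − p̄ᵢq̄ⱼ)²            LD of the pooled population
    D²_IT  = Σᵢⱼ E_k(xᵢⱼₖ − p̄ᵢq̄ⱼ)²

with the exact identity D²_IT = D′²_IS + D′²_ST.  D′²_IS ≫ D′²_ST is the
drift signature (each population couples different alleles); D′²_ST > 0
with small D′²_IS indicates the same coupling everywhere, the pattern
expected under systematic (epistatic) selection.

## Geography and clines

Distances are haversine great circles on a 6371-km sphere; coordinates
are decimal degrees (printed DMS converted as deg + min/60; longitudes of
the nine default towns are gazetteer values, so distances are
approximate).  Isolation by distance regresses pairwise θ (optionally
Slatkin-linearised θ/(1−θ); raw θ is the default) on log₁₀ distance, with
one-sided Mantel significance from permuting population identities (rows
and columns together).  R² and p are invariant to the log base.

Allele clines take, per locus×arrangement, the most common and second
most common allele ranked by unweighted mean frequency across populations
(ties broken toward the smaller fragment), regress asin(√freq) on
latitude, and FDR-adjust the batch.  Arrangement frequencies use a
degree-1 fit on the arcsin-sqrt scale; heterozygosity against latitude
uses a degree-2 fit, also on the arcsin-sqrt scale (the transformed scale
is what the ANOVA-style analyses use; the raw-scale fit is available via
`transform="none"`).

## The F_ST-outlier scan

The neutral null is a symmetric n-island model (default: 100 demes, 9
sampled, 30 haplotypes each) under the structured coalescent with
infinite-alleles mutation.  The simulator is an event-driven exact
algorithm written in-package (numba): lineages coalesce pairwise within
demes at rate 1 per pair (deme size 1 in coalescent units), migrate at
total rate M per lineage to a uniformly chosen other deme, and a branch's
allele changes with probability 1 − exp(−μ·len); only the most recent
mutation above a leaf matters.  Per-locus mutation rates are drawn
log-uniformly from a θ range (default 0.05–19, spanning He ≈ 0.05–0.95).
M is calibrated by log-scale bisection from the moment start
M₀ = (1−t)/(2t) until the median simulated multi-locus θ is within 5% of
the observed target, using pilot batches of ≥2000 loci.  The envelope
bins He into 50 equal bins (thin bins borrow neighbours), takes α/2 and
1−α/2 F_ST quantiles per bin, and classifies observed loci as positive /
balancing / neutral with empirical bin-tail p-values; an optional
LOSITAN-style refinement removes flagged loci, recalibrates and
reclassifies once.  Simple binning rather than LOESS smoothing is a
deliberate simplification.  msprime's structured coalescent is used as an
independent oracle in the test suite (distribution agreement at small
problem sizes), not in the scan itself.

## The synthetic-data generator

The generator reproduces the statistical structure the analyses assume,
not the biology that produced it — frequency structure rather than
forward simulation:

- Arrangement frequencies follow multinomial-logit clines,
  softmax(aₖ + bₖ·lat); defaults give standard arrangements rising and
  inverted ones falling with latitude at ~1–2% per degree, the magnitude
  of the European arrangement clines.
- At loci inside an inversion, every karyotypic class (each arrangement
  named as carrying the locus inside, plus one shared standard class)
  draws its own allele pool from the base by a Dirichlet divergence with
  concentration p·(1−F_arr)/F_arr, so Var(pᵢ) = F_arr·pᵢ(1−pᵢ) and
  pairwise between-class θ ≈ F_arr.  Outside loci share the base pool.
- Each population re-draws every pool with divergence F_pop
  (Balding–Nichols-style drift).  Defaults F_arr = 0.1, F_pop = 0.007
  match the contrast a study of this design reports (within-arrangement
  θ ≈ 0.007).
- Group sizes default to 30 haplotypes per arrangement×population
  ("quota" mode); "cline" mode draws karyotype counts from the cline
  frequencies instead.
- Optional injections: a clinal allele whose frequency is
  sin²(c0 + c1·lat) clipped to [0.01, 0.99] with the other alleles
  rescaled proportionally (exactly invertible by the arcsin-sqrt
  regression when unclipped), and a target D′ between one locus pair
  within one arrangement, realised by a 2×2 coupling on the two modal
  alleles spread proportionally over the remaining alleles.
- Within-chromosome LD between loci is otherwise zero, matching the
  mostly null inter-locus findings such data show.

What the generator does not emulate: stepwise microsatellite mutation
(allele sizes are labels drawn from fixed pools), inversion breakpoints
and gene flux gradients along the chromosome, temporal change, selection
dynamics, and non-equilibrium demography (the Scandinavian
differentiation seen in real data appears only through whatever F_pop
imposes).  Passing recovery tests therefore shows the estimators are
correct and calibrated under the assumed frequency model, not that real
data meet that model.

## Numerical choices and problem sizes

Permutation defaults are B = 10 000 (matching the study design);
p-values use the (1 + count)/(B + 1) convention and a 1e-12/1e-9 slack on
statistic ties.  Monte-Carlo tables and permuted θ are computed by
vectorised bincounts in blocks, so B = 10⁴ on study-sized data costs
seconds.  The test suite and acceptance script use scaled-down sizes
chosen as this package's own defaults — B = 199–2000 per permutation
test, 200 replicates in calibration checks, envelopes of 10⁴ neutral loci
(with a `--full` option of 10⁵) — which keep every Monte-Carlo check
well-resolved at its asserted tolerance.  Degenerate inputs are defined:
all-monomorphic θ is NaN with a warning, D′m requires two categories per
axis with nonzero margins, constant responses give R² = 0 with p = 1,
and θ = 1 cannot be Slatkin-linearised.

## Known limitations

- The He-conditioned envelope uses equal-width bins; very low-He bins
  borrow neighbours and are wider, so power is lowest exactly where
  microsatellite outliers are hardest to call.
- `theta_from_frequency_tables` reconstructs counts as round(freq·n) and
  inherits the rounding error of published precision.
- Individual-level Mantel permutation (as opposed to population-level) is
  not implemented; the population-level test is the one reported.
- The three-level hierarchical AMOVA and R_ST-style stepwise-mutation
  statistics are out of scope.
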