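# invclines

Population genetics of chromosomal inversions along geographic clines,
for phased multiallelic haplotype data.

Chromosomal inversions suppress recombination in heterokaryotypes, so a
marker locus lying *inside* an inverted segment can maintain a distinct
allele pool in each gene arrangement — even among flies caught in the
same orchard — while loci *outside* recombine freely.  Surveys of this
kind genotype microsatellites on phased wild chromosomes (one arrangement
call plus one allele per locus per chromosome), group haplotypes by
(population, chromosome, arrangement), and ask: how much differentiation
is there *between* arrangements versus *within* an arrangement across
populations?  Which alleles are locked to which inversion?  Do allele
frequencies inside inversions follow latitude, suggesting clinal
selection?  `invclines` implements that entire analysis as a tested
Python library, together with a synthetic-data generator that reproduces
the sampling design so every stage can be validated without any data
download.

## What it computes

| stage | statistic |
|---|---|
| diversity | Nei's unbiased gene diversity He = n/(n−1)(1 − Σp̂ᵢ²), per locus×group and for arrangement frequencies |
| structure | haploid Weir–Cockerham-style θ from ANOVA variance components σ²ₐ, σ²_w on allele indicators; permutation p; between/within-arrangement partition with exact paired Wilcoxon; pairwise θ matrices; PCoA |
| linkage | Hedrick's multiallelic D′m = Σᵢⱼ pᵢqⱼ\|D′ᵢⱼ\| between markers and the inversion pseudo-locus; Monte-Carlo Fisher exact tests; per-allele D′ with Yates χ²; Benjamini–Yekutieli FDR; Ohta's D²/D′² variance decomposition of two-locus LD |
| clines | haversine distances; Mantel-permuted regression of pairwise θ on log₁₀ km (IBD); MCA/SMCA allele-frequency clines on the arcsin-√ scale; polynomial He–latitude fits |
| outliers | fdist-style scan: island-model structured coalescent with infinite-alleles mutation, migration calibrated to the observed θ, He-conditioned F_ST quantile envelopes |
| simdata | nine-population latitudinal design: logit arrangement clines, arrangement-specific pools at inside loci (Dirichlet divergence F_arr), per-population drift (F_pop), injectable clinal alleles and locus-pair D′, truth file for recovery tests |

## Worked example

```python
import numpy as np
import invclines as ic
from invclines.structure import PartitionScheme, partition_fst

records, truth = ic.simulate_dataset(ic.study_config(seed=7))
groups = ic.group_counts(records)
part = partition_fst(groups, scheme=PartitionScheme(chromosome="J"))
print(f"between-arrangement theta = {part.between.multi_locus:.4f}")
for arr, res in part.within.items():
    print(f"within {arr}: theta = {res.multi_locus:.4f}")
print(f"paired Wilcoxon (per-locus, one-sided) p = {part.wilcoxon_p:.4f}")
```

prints

```
between-arrangement theta = 0.0126
within J_1: theta = 0.0052
within J_ST: theta = 0.0020
paired Wilcoxon (per-locus, one-sided) p = 0.0781
```

The between-arrangement θ (all population×arrangement units of the J
chromosome in one analysis) is several times the within-arrangement
values (one arrangement compared across the nine populations): the two
inversions hold partially distinct gene pools, driven by the loci inside
the inverted segment, while gene flow keeps each arrangement nearly
homogeneous across ~3700 km.  That contrast — here ~0.013 vs ~0.004
under the generator's defaults (between-class divergence 0.1 at inside
loci, within-arrangement drift 0.007) — is the quantity this kind of
survey is designed to measure.

The `examples/` directory has one short script per capability
(simulation & diversity, the θ partition, D′m linkage, clines & IBD, the
outlier scan), each printing its numbers with a line on how to read
them.  A thin CLI wraps the same calls
(`invclines simulate|diversity|fst|pcoa|ld|ohta|clines|ibd|outliers|report`).

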