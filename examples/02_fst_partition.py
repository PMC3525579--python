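"""Between- vs within-arrangement differentiation on one chromosome.

Loci inside an inversion cannot recombine freely in heterokaryotypes, so
the between-arrangement theta should exceed the within-arrangement theta
across populations - the contrast this partition quantifies.
"""
import numpy as np
import invclines as ic
from invclines.structure import PartitionScheme, partition_fst

records, _ = ic.simulate_dataset(ic.study_config(seed=7))
groups = ic.group_counts(records)
part = partition_fst(groups, scheme=PartitionScheme(chromosome="J"))
within = np.nanmean([r.multi_locus for r in part.within.values()])
print(f"between-arrangement theta = {part.between.multi_locus:.4f}")
for arr, res in part.within.items():
    print(f"within {arr}: theta = {res.multi_locus:.4f}")
print(f"paired Wilcoxon (per-locus, one-sided) p = {part.wilcoxon_p:.4f}")
print("\nA between value several times the within value, driven by the loci "
      "inside the inversion, is the signature of arrangement-partitioned gene pools.")
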