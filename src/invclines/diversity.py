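"""Gene diversity (expected heterozygosity) per locus, group and arrangement."""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GroupCounts, ValidationError

__all__ = [
    "gene_diversity",
    "diversity_table",
    "group_mean_diversity",
    "arrangement_diversity",
    "arcsin_sqrt",
]


def arcsin_sqrt(x):
    """Variance-stabilising transform asin(sqrt(x)), in radians."""
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def gene_diversity(counts: Mapping[int, int] | Sequence[int], unbiased: bool = True) -> float:
    """Nei's gene diversity from haploid allele counts.

    He = 1 - sum(p_i^2), scaled by n/(n-1) in the unbiased (default) mode.
    """
    values = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float)
    n = values.sum()
    if n < 2:
        raise ValidationError(f"gene diversity undefined for n={int(n)} < 2")
    p = values / n
    he = 1.0 - float(np.sum(p * p))
    if unbiased:
        he *= n / (n - 1.0)
    return he


def arrangement_diversity(freqs: Mapping[str, float] | Sequence[float], n: int | None = None,
                          unbiased: bool = True) -> float:
    """Gene diversity of arrangement frequencies (arrangements as alleles).

    When ``n`` is omitted the plain (biased) 1 - sum(p^2) is returned, since
    the unbiased correction needs the number of scored chromosomes.
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValidationError("arrangement frequencies must sum to 1")
    he = 1.0 - float(np.sum(p * p))
    if unbiased and n is not None:
        if n < 2:
            raise ValidationError("unbiased correction needs n >= 2")
        he *= n / (n - 1.0)
    return he


def diversity_table(groups: Sequence[GroupCounts], loci: Iterable[str] | None = None,
                    unbiased: bool = True) -> pd.DataFrame:
    """Per-locus gene diversity for every group, tidy layout.

    Columns: population, chromosome, arrangement, locus, n, he,
    asin_sqrt_he.  Loci scored in fewer than two haplotypes of a group are
    reported as NA.
    """
    if not groups:
        raise ValidationError("no groups supplied")
    rows = []
    for g in groups:
        locus_list = list(loci) if loci is not None else g.loci
        for locus in locus_list:
            n = g.n_locus.get(locus, 0)
            he = gene_diversity(g.counts[locus], unbiased=unbiased) if n >= 2 else np.nan
            rows.append(
                {
                    "population": g.key.population_id,
                    "chromosome": g.key.chromosome,
                    "arrangement": g.key.arrangement,
                    "locus": locus,
                    "n": n,
                    "he": he,
                }
            )
    df = pd.DataFrame(rows)
    df["asin_sqrt_he"] = arcsin_sqrt(df["he"])
    return df


def group_mean_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Average He over loci per group (the per-cell summary of the He table)."""
    out = (
        table.groupby(["population", "chromosome", "arrangement"], as_index=False)
        .agg(n=("n", "max"), he=("he", "mean"))
    )
    out["asin_sqrt_he"] = arcsin_sqrt(out["he"])
    return out
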