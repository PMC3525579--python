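"""Reproduction of headline quantities from published frequency tables.

The study deposited no raw genotypes; its arrangement-frequency and
per-arrangement allele-frequency supplements are the only route to its
numeric results.  This module consumes those tables in a simple TSV form
and recomputes the derived statistics: quadratic heterozygosity-latitude
fits, arrangement-frequency clines, MCA/SMCA allele clines, and
between/within-arrangement theta from counts reconstructed as
round(frequency x n).

Expected files under one directory:

  arrangement_frequencies.tsv : population, chromosome, arrangement, n, frequency
  allele_frequencies_<ARR>.tsv : locus, allele_bp, population, n, frequency
                                 (one file per arrangement, e.g. A_2 -> A_2)
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clines import latitude_polynomial_fit, _ols_poly, _ranked_common_alleles
from .core import PopulationMeta, ValidationError
from .diversity import arcsin_sqrt, arrangement_diversity
from .structure import theta_from_counts

__all__ = [
    "load_arrangement_frequencies",
    "load_allele_frequencies",
    "he_latitude_quadratic",
    "frequency_quadratic",
    "allele_cline_r2",
    "theta_from_frequency_tables",
]


def load_arrangement_frequencies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"population", "chromosome", "arrangement", "n", "frequency"}
    if not need.issubset(df.columns):
        raise ValidationError(f"arrangement frequency table lacks columns {need - set(df.columns)}")
    return df


def load_allele_frequencies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"locus", "allele_bp", "population", "n", "frequency"}
    if not need.issubset(df.columns):
        raise ValidationError(f"allele frequency table lacks columns {need - set(df.columns)}")
    return df


def he_latitude_quadratic(arr_freqs: pd.DataFrame, meta: Mapping[str, PopulationMeta],
                          chromosome: str):
    """Quadratic fit of arrangement-frequency He (arcsin-sqrt) on latitude."""
    sub = arr_freqs[arr_freqs["chromosome"] == chromosome]
    vals = {}
    for pop, rows in sub.groupby("population"):
        p = rows["frequency"].to_numpy(dtype=float)
        if p.sum() <= 0:
            continue
        n = int(rows["n"].iloc[0]) if rows["n"].notna().all() else None
        vals[pop] = arrangement_diversity(p / p.sum(), n=n)
    return latitude_polynomial_fit(vals, meta, degree=2, transform="arcsin-sqrt",
                                   response=f"He(arrangements:{chromosome})")


def frequency_quadratic(arr_freqs: pd.DataFrame, meta: Mapping[str, PopulationMeta],
                        arrangement: str):
    """Quadratic fit of one arrangement's frequency (arcsin-sqrt) on latitude."""
    sub = arr_freqs[arr_freqs["arrangement"] == arrangement]
    vals = dict(zip(sub["population"], sub["frequency"].astype(float)))
    return latitude_polynomial_fit(vals, meta, degree=2, transform="arcsin-sqrt",
                                   response=f"freq({arrangement})")


def allele_cline_r2(allele_freqs: pd.DataFrame, meta: Mapping[str, PopulationMeta],
                    locus: str, rank: int) -> tuple[int, float]:
    """(allele bp, R2) of the rank-th most common allele's latitude cline."""
    sub = allele_freqs[allele_freqs["locus"] == locus]
    if sub.empty:
        raise ValidationError(f"locus {locus} absent from allele frequency table")
    freqs_by_pop: dict[str, dict[int, float]] = {}
    for pop, rows in sub.groupby("population"):
        freqs_by_pop[pop] = dict(zip(rows["allele_bp"].astype(int), rows["frequency"].astype(float)))
    ranked = _ranked_common_alleles(freqs_by_pop)
    target = ranked[rank - 1]
    pops = sorted(freqs_by_pop)
    lat = np.array([meta[p].latitude for p in pops])
    y = arcsin_sqrt(np.array([freqs_by_pop[p].get(target, 0.0) for p in pops]))
    _, r2, _ = _ols_poly(lat, y, 1)
    return int(target), float(r2)


def _counts_from_freqs(allele_freqs: pd.DataFrame, locus: str) -> dict[str, np.ndarray]:
    """Integer count vectors per population, reconstructed as round(freq*n)."""
    sub = allele_freqs[allele_freqs["locus"] == locus]
    out = {}
    for pop, rows in sub.groupby("population"):
        n = float(rows["n"].iloc[0])
        out[pop] = np.round(rows["frequency"].to_numpy(dtype=float) * n)
    return out


def theta_from_frequency_tables(tables_by_arrangement: Mapping[str, pd.DataFrame],
                                loci: list[str]) -> dict[str, float]:
    """Between- and within-arrangement theta from published frequency tables.

    Alleles are aligned across arrangements per locus; counts are the
    rounded frequency x n products, so the result carries the rounding
    error of the published precision.
    """
    between_tabs = []
    within: dict[str, float] = {}
    for locus in loci:
        rows = []
        alleles = sorted({
            int(a) for df in tables_by_arrangement.values()
            for a in df[df["locus"] == locus]["allele_bp"]
        })
        for arr, df in tables_by_arrangement.items():
            sub = df[df["locus"] == locus]
            for pop, r in sub.groupby("population"):
                n = float(r["n"].iloc[0])
                vec = np.zeros(len(alleles))
                for a, f in zip(r["allele_bp"].astype(int), r["frequency"].astype(float)):
                    vec[alleles.index(a)] = np.round(f * n)
                rows.append(vec)
        if rows:
            between_tabs.append(np.vstack(rows))
    out = {"between": theta_from_counts(between_tabs)}
    for arr, df in tables_by_arrangement.items():
        tabs = []
        for locus in loci:
            sub = df[df["locus"] == locus]
            alleles = sorted(sub["allele_bp"].astype(int).unique())
            rows = []
            for pop, r in sub.groupby("population"):
                n = float(r["n"].iloc[0])
                vec = np.zeros(len(alleles))
                for a, f in zip(r["allele_bp"].astype(int), r["frequency"].astype(float)):
                    vec[alleles.index(a)] = np.round(f * n)
                rows.append(vec)
            if len(rows) >= 2:
                tabs.append(np.vstack(rows))
        if tabs:
            within[f"within:{arr}"] = theta_from_counts(tabs)
    out.update(within)
    return out
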