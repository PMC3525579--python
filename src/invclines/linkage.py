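"""Marker–inversion and inter-locus linkage disequilibrium.

Haplotypes are phased by construction, so two-way gametic tables (allele of
a marker x chromosomal arrangement, or allele x allele for a locus pair
within one arrangement) are directly observed.  Association is quantified
with Hedrick's multiallelic normalization of Lewontin's D':

    D'm = sum_ij p_i q_j |D'_ij|,  D_ij = x_ij - p_i q_j,
    D'_ij = D_ij / Dmax_ij

and tested with a Monte-Carlo Fisher exact test (the statistic is the
table's conditional hypergeometric probability under fixed margins).
Ohta's variance decomposition of two-locus LD across subpopulations
separates within-population from among-population disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import GroupCounts, HaplotypeRecord, ValidationError

__all__ = [
    "GameticTable",
    "DmResult",
    "AlleleInversionD",
    "OhtaComponents",
    "dm_statistic",
    "mc_exact_test",
    "allele_inversion_dprime",
    "fdr_adjust",
    "ohta_components",
    "pairwise_locus_ld",
    "marker_inversion_table",
    "locus_pair_table",
]


@dataclass
class GameticTable:
    """Joint counts over (allele i of locus A) x (category j)."""

    counts: np.ndarray            # (n_i, n_j) integer counts
    row_labels: list              # alleles of locus A
    col_labels: list              # arrangements, or alleles of locus B
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("gametic table must be two-dimensional")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        return self.counts.sum(axis=1) / self.n

    @property
    def q(self) -> np.ndarray:
        return self.counts.sum(axis=0) / self.n

    @property
    def x(self) -> np.ndarray:
        return self.counts / self.n


@dataclass
class DmResult:
    locus: str
    population: str
    dm: float
    p_value: float | None = None
    significant_fdr: bool | None = None


@dataclass
class AlleleInversionD:
    allele: int
    arrangement: str
    d: float
    dprime: float
    chi2_yates: float
    p_value: float
    joint_count: float
    passes_min_obs: bool


@dataclass
class OhtaComponents:
    d2_is: float
    d2_st: float
    dp2_is: float
    dp2_st: float
    d2_it: float


# ---------------------------------------------------------------------------
# table construction


def marker_inversion_table(records: Sequence[HaplotypeRecord], locus: str,
                           populations: Iterable[str] | None = None,
                           arrangements: Iterable[str] | None = None) -> GameticTable:
    """Joint counts of marker allele x arrangement within population(s)."""
    pops = set(populations) if populations is not None else None
    arrs = set(arrangements) if arrangements is not None else None
    pairs = [
        (rec.alleles.get(locus), rec.arrangement)
        for rec in records
        if (pops is None or rec.population_id in pops)
        and (arrs is None or rec.arrangement in arrs)
        and rec.alleles.get(locus) is not None
    ]
    if not pairs:
        raise ValidationError(f"no scored haplotypes for locus {locus}")
    alleles = sorted({a for a, _ in pairs})
    cats = sorted({c for _, c in pairs})
    counts = np.zeros((len(alleles), len(cats)))
    ai = {a: i for i, a in enumerate(alleles)}
    ci = {c: j for j, c in enumerate(cats)}
    for a, c in pairs:
        counts[ai[a], ci[c]] += 1
    return GameticTable(counts, alleles, cats, label=locus)


def locus_pair_table(records: Sequence[HaplotypeRecord], locus_a: str, locus_b: str,
                     arrangement: str | None = None,
                     populations: Iterable[str] | None = None) -> GameticTable:
    """Joint counts of allele(locus_a) x allele(locus_b) among phased haplotypes."""
    pops = set(populations) if populations is not None else None
    pairs = [
        (rec.alleles.get(locus_a), rec.alleles.get(locus_b))
        for rec in records
        if (arrangement is None or rec.arrangement == arrangement)
        and (pops is None or rec.population_id in pops)
        and rec.alleles.get(locus_a) is not None
        and rec.alleles.get(locus_b) is not None
    ]
    if not pairs:
        raise ValidationError(f"no jointly scored haplotypes for {locus_a}/{locus_b}")
    rows = sorted({a for a, _ in pairs})
    cols = sorted({b for _, b in pairs})
    counts = np.zeros((len(rows), len(cols)))
    ri = {a: i for i, a in enumerate(rows)}
    cj = {b: j for j, b in enumerate(cols)}
    for a, b in pairs:
        counts[ri[a], cj[b]] += 1
    return GameticTable(counts, rows, cols, label=f"{locus_a}x{locus_b}")


# ---------------------------------------------------------------------------
# D'm and per-cell D'


def _dprime_cells(p: np.ndarray, q: np.ndarray, x: np.ndarray):
    """Per-cell D_ij and D'_ij for marginals p, q and joint frequencies x."""
    d = x - np.outer(p, q)
    pq = np.outer(p, q)
    p1q = np.outer(p, 1.0 - q)
    pq1 = np.outer(1.0 - p, q)
    p1q1 = np.outer(1.0 - p, 1.0 - q)
    dmax = np.where(d < 0, np.minimum(pq, p1q1), np.minimum(p1q, pq1))
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(dmax > 0, d / dmax, 0.0)
    return d, dprime


def dm_statistic(table: GameticTable) -> float:
    """Hedrick's multiallelic D'm = sum_ij p_i q_j |D'_ij|, in [0, 1]."""
    keep_r = table.counts.sum(axis=1) > 0
    keep_c = table.counts.sum(axis=0) > 0
    counts = table.counts[np.ix_(keep_r, keep_c)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("D'm undefined: need >=2 categories with nonzero margins on each axis")
    n = counts.sum()
    p = counts.sum(axis=1) / n
    q = counts.sum(axis=0) / n
    _, dprime = _dprime_cells(p, q, counts / n)
    return float(np.sum(np.outer(p, q) * np.abs(dprime)))


def allele_inversion_dprime(table: GameticTable, min_obs: int = 3) -> list[AlleleInversionD]:
    """Per-(allele, arrangement) D' with Yates-corrected chi-square.

    Each cell is collapsed to a 2x2 table (allele i vs rest) x (category j
    vs rest).  Associations observed fewer than ``min_obs`` times are
    flagged as failing the minimum-observation rule regardless of p.
    """
    from scipy.stats import chi2 as chi2_dist

    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need >=2 categories on each axis")
    n = counts.sum()
    p = counts.sum(axis=1) / n
    q = counts.sum(axis=0) / n
    d, dprime = _dprime_cells(p, q, counts / n)
    out: list[AlleleInversionD] = []
    for i, allele in enumerate(table.row_labels):
        for j, cat in enumerate(table.col_labels):
            a = counts[i, j]
            b = counts[i].sum() - a
            c = counts[:, j].sum() - a
            dd = n - a - b - c
            denom = (a + b) * (c + dd) * (a + c) * (b + dd)
            if denom == 0:
                chi2 = 0.0
            else:
                adj = max(abs(a * dd - b * c) - n / 2.0, 0.0)
                chi2 = n * adj**2 / denom
            pval = float(chi2_dist.sf(chi2, df=1))
            out.append(
                AlleleInversionD(
                    allele=allele, arrangement=str(cat), d=float(d[i, j]),
                    dprime=float(dprime[i, j]), chi2_yates=float(chi2), p_value=pval,
                    joint_count=float(a), passes_min_obs=bool(a >= min_obs),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo Fisher exact test


def _log_table_prob(counts: np.ndarray) -> float:
    """Log conditional (hypergeometric) probability of a table given margins."""
    n = counts.sum()
    return float(
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(counts.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def mc_exact_test(table: GameticTable, B: int = 10000,
                  rng: np.random.Generator | int | None = None) -> float:
    """Monte-Carlo Fisher exact test for independence of the two axes.

    Category labels are permuted against allele labels B times; the test
    statistic is the conditional probability of the table, small values
    being extreme.  p = (1 + #{logP_perm <= logP_obs}) / (B + 1).
    """
    if table.n < 2:
        raise ValidationError("exact test needs n >= 2")
    counts = table.counts.astype(int)
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    if (row_m > 0).sum() < 2 or (col_m > 0).sum() < 2:
        return 1.0
    rng = np.random.default_rng(rng)
    log_obs = _log_table_prob(counts)

    n = int(counts.sum())
    n_i, n_j = counts.shape
    row_lab = np.repeat(np.arange(n_i), row_m)
    col_lab = np.repeat(np.arange(n_j), col_m)
    perms = np.tile(col_lab, (B, 1))
    perms = rng.permuted(perms, axis=1)
    flat = (np.arange(B)[:, None] * (n_i * n_j) + row_lab[None, :] * n_j + perms).ravel()
    tables = np.bincount(flat, minlength=B * n_i * n_j).reshape(B, n_i, n_j)
    log_perm = (
        gammaln(row_m + 1).sum()
        + gammaln(col_m + 1).sum()
        - gammaln(n + 1)
        - gammaln(tables + 1).sum(axis=(1, 2))
    )
    p = (1.0 + np.sum(log_perm <= log_obs + 1e-9)) / (B + 1.0)
    return float(p)


# ---------------------------------------------------------------------------
# multiple testing


def fdr_adjust(p_values: Sequence[float], method: str = "by", alpha: float = 0.05):
    """False-discovery-rate decisions (Benjamini–Yekutieli default).

    Returns (reject boolean array, adjusted p-values).  'bh' selects plain
    Benjamini–Hochberg.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    sm_method = {"by": "fdr_by", "bh": "fdr_bh"}[method]
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return reject, p_adj


# ---------------------------------------------------------------------------
# Ohta's variance decomposition


def ohta_components(tables_by_population: Mapping[str, GameticTable] | Sequence[GameticTable],
                    weighted: bool = False) -> OhtaComponents:
    """Ohta's D-statistics for one locus pair across subpopulations.

    With x_ijk the joint gametic frequency of (i, j) in subpopulation k,
    p_ik/q_jk its marginals, and unweighted subpopulation averages
    (pbar_i, qbar_j, xbar_ij):

        D2_IS  = sum_ij E_k (x_ijk - p_ik q_jk)^2
        D2_ST  = sum_ij E_k (p_ik q_jk - pbar_i qbar_j)^2
        D'2_IS = sum_ij E_k (x_ijk - xbar_ij)^2
        D'2_ST = sum_ij (xbar_ij - pbar_i qbar_j)^2
        D2_IT  = sum_ij E_k (x_ijk - pbar_i qbar_j)^2

    which satisfy D2_IT = D'2_IS + D'2_ST exactly.  A sample-size-weighted
    averaging mode is available but non-default.
    """
    tables = list(tables_by_population.values()) if isinstance(tables_by_population, Mapping) \
        else list(tables_by_population)
    if len(tables) < 2:
        raise ValidationError("Ohta decomposition needs >=2 subpopulations")

    rows = sorted({r for t in tables for r in t.row_labels})
    cols = sorted({c for t in tables for c in t.col_labels})
    k = len(tables)
    x = np.zeros((k, len(rows), len(cols)))
    ns = np.zeros(k)
    for ti, t in enumerate(tables):
        ri = [rows.index(r) for r in t.row_labels]
        cj = [cols.index(c) for c in t.col_labels]
        x[np.ix_([ti], ri, cj)] = (t.counts / t.n)[None]
        ns[ti] = t.n
    w = ns / ns.sum() if weighted else np.full(k, 1.0 / k)

    p = x.sum(axis=2)                      # (k, n_i)
    q = x.sum(axis=1)                      # (k, n_j)
    pq = p[:, :, None] * q[:, None, :]
    pbar = (w[:, None] * p).sum(axis=0)
    qbar = (w[:, None] * q).sum(axis=0)
    xbar = (w[:, None, None] * x).sum(axis=0)
    pbar_qbar = np.outer(pbar, qbar)

    def avg(sq):  # E_k over subpopulations, then sum over cells
        return float((w[:, None, None] * sq).sum())

    d2_is = avg((x - pq) ** 2)
    d2_st = avg((pq - pbar_qbar) ** 2)
    dp2_is = avg((x - xbar) ** 2)
    dp2_st = float(((xbar - pbar_qbar) ** 2).sum())
    d2_it = avg((x - pbar_qbar) ** 2)
    return OhtaComponents(d2_is=d2_is, d2_st=d2_st, dp2_is=dp2_is, dp2_st=dp2_st, d2_it=d2_it)


# ---------------------------------------------------------------------------
# inter-locus LD screens


def pairwise_locus_ld(records: Sequence[HaplotypeRecord], chromosome: str, arrangement: str,
                      pooled: bool = False,
                      populations: Iterable[str] | None = None,
                      exclude_populations: Iterable[str] = (),
                      loci: Sequence[str] | None = None,
                      B: int = 10000, fdr_method: str = "by", alpha: float = 0.05,
                      rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Exact-test screen of every locus pair within one arrangement.

    ``pooled`` merges haplotypes across populations (minus
    ``exclude_populations``); otherwise each population is tested
    separately.  Monomorphic loci are skipped.  Returns a tidy frame with
    FDR decisions across all tests performed.
    """
    rng = np.random.default_rng(rng)
    recs = [r for r in records if r.chromosome == chromosome and r.arrangement == arrangement]
    if populations is not None:
        pops_keep = set(populations)
        recs = [r for r in recs if r.population_id in pops_keep]
    recs = [r for r in recs if r.population_id not in set(exclude_populations)]
    if loci is None:
        loci = sorted({l for r in recs for l in r.alleles})
    pop_sets = [None] if pooled else sorted({r.population_id for r in recs})

    rows = []
    for pop in pop_sets:
        sub = recs if pop is None else [r for r in recs if r.population_id == pop]
        for i, la in enumerate(loci):
            for lb in loci[i + 1:]:
                try:
                    tab = locus_pair_table(sub, la, lb)
                except ValidationError:
                    continue
                if len(tab.row_labels) < 2 or len(tab.col_labels) < 2:
                    rows.append({"population": pop or "pooled", "locus_a": la, "locus_b": lb,
                                 "n": tab.n, "p_value": np.nan, "note": "monomorphic"})
                    continue
                p = mc_exact_test(tab, B=B, rng=rng)
                rows.append({"population": pop or "pooled", "locus_a": la, "locus_b": lb,
                             "n": tab.n, "p_value": p, "note": ""})
    df = pd.DataFrame(rows)
    if len(df):
        tested = df["p_value"].notna()
        reject = np.zeros(len(df), dtype=bool)
        p_adj = np.full(len(df), np.nan)
        if tested.any():
            rej, adj = fdr_adjust(df.loc[tested, "p_value"], method=fdr_method, alpha=alpha)
            reject[np.where(tested)[0]] = rej
            p_adj[np.where(tested)[0]] = adj
        df["significant_fdr"] = reject
        df["p_adjusted"] = p_adj
    return df


def dm_scan(records: Sequence[HaplotypeRecord], loci: Sequence[str], chromosome: str,
            arrangements: Sequence[str], populations: Sequence[str],
            B: int = 10000, fdr_method: str = "by", alpha: float = 0.05,
            rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """D'm between each locus and the arrangements, per population.

    The inversion is treated as a pseudo-locus whose alleles are the
    frequent arrangements.  Returns one row per (locus, population) with
    the exact-test p and an FDR decision over the whole scan.
    """
    rng = np.random.default_rng(rng)
    chrom_recs = [r for r in records if r.chromosome == chromosome
                  and r.arrangement in set(arrangements)]
    rows = []
    for pop in populations:
        for locus in loci:
            try:
                tab = marker_inversion_table(chrom_recs, locus, populations=[pop])
            except ValidationError:
                continue
            if len(tab.row_labels) < 2 or len(tab.col_labels) < 2:
                rows.append({"population": pop, "locus": locus, "n": tab.n,
                             "dm": np.nan, "p_value": np.nan})
                continue
            rows.append({"population": pop, "locus": locus, "n": tab.n,
                         "dm": dm_statistic(tab),
                         "p_value": mc_exact_test(tab, B=B, rng=rng)})
    df = pd.DataFrame(rows)
    if len(df):
        tested = df["p_value"].notna()
        reject = np.zeros(len(df), dtype=bool)
        if tested.any():
            rej, _ = fdr_adjust(df.loc[tested, "p_value"], method=fdr_method, alpha=alpha)
            reject[np.where(tested)[0]] = rej
        df["significant_fdr"] = reject
    return df
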