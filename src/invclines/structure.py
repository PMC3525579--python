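"""Haploid F_ST (variance-component theta), permutation tests and PCoA.

Theta is estimated from a one-way ANOVA on allele indicator variables, the
haploid analogue of the Weir–Cockerham estimator: for every locus and every
allele u, with r groups of sizes n_k (haplotypes scored at the locus),

    SSA = sum_k n_k (p_ku - pbar_u)^2            df = r - 1
    SSW = sum_k n_k p_ku (1 - p_ku)              df = n - r
    n_c = (n - sum_k n_k^2 / n) / (r - 1)
    sigma2_a,u = (MSA - MSW) / n_c,   sigma2_w,u = MSW

and theta is the ratio of summed components, over alleles within a locus
and over loci for the multi-locus value.  This is mathematically the
haplotypic AMOVA F_ST with allele-identity distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupCounts, GroupKey, ValidationError

__all__ = [
    "FstResult",
    "PairwiseFstMatrix",
    "PcoaResult",
    "PartitionScheme",
    "PartitionResult",
    "fst_theta",
    "fst_permutation_test",
    "pairwise_fst",
    "partition_fst",
    "pcoa",
    "theta_from_counts",
]


@dataclass
class FstResult:
    scope: str
    per_locus: dict[str, float]
    sigma_a: dict[str, float]
    sigma_w: dict[str, float]
    multi_locus: float
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class PairwiseFstMatrix:
    labels: list[GroupKey]
    values: np.ndarray  # symmetric, zero diagonal; may hold small negatives

    def to_frame(self) -> pd.DataFrame:
        names = [str(k) for k in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)

    def linearized(self) -> "PairwiseFstMatrix":
        """Slatkin's theta/(1-theta) transform for distance-based analyses."""
        if np.any(self.values >= 1.0 - 1e-12):
            raise ValidationError("theta = 1 cannot be linearized (infinite distance)")
        return PairwiseFstMatrix(self.labels, self.values / (1.0 - self.values))


@dataclass
class PcoaResult:
    labels: list
    coordinates: np.ndarray        # (n, n_positive_axes)
    eigenvalues: np.ndarray        # all eigenvalues, descending
    percent_variation: np.ndarray  # over positive eigenvalues, sums to 100


@dataclass
class PartitionScheme:
    chromosome: str
    populations: Sequence[str] | None = None   # None = all observed
    arrangements: Sequence[str] | None = None
    min_within_pops: int = 2


@dataclass
class PartitionResult:
    between: FstResult
    within: dict[str, FstResult]
    wilcoxon_p: float
    mean_within_per_locus: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coding helpers


def _code_groups(groups: Sequence[GroupCounts], loci: Sequence[str]):
    """Flatten groups into integer allele codes per haplotype (-1 = missing)."""
    allele_codes: dict[str, dict[int, int]] = {}
    for locus in loci:
        alleles = sorted({a for g in groups for a in g.counts.get(locus, {})})
        allele_codes[locus] = {a: i for i, a in enumerate(alleles)}
    n_total = sum(g.size for g in groups)
    codes = np.full((n_total, len(loci)), -1, dtype=np.int64)
    gidx = np.empty(n_total, dtype=np.int64)
    row = 0
    for gi, g in enumerate(groups):
        for hap in g.haplotypes:
            for li, locus in enumerate(loci):
                allele = hap.get(locus)
                if allele is not None:
                    codes[row, li] = allele_codes[locus][allele]
            gidx[row] = gi
            row += 1
    n_alleles = np.array([max(len(allele_codes[l]), 1) for l in loci], dtype=np.int64)
    return codes, gidx, n_alleles


def _components_from_counts(counts: np.ndarray) -> tuple[float, float]:
    """(sum sigma2_a, sum sigma2_w) over alleles from an (r, A) count table."""
    counts = np.asarray(counts, dtype=float)
    n_k = counts.sum(axis=1)
    keep = n_k > 0
    counts, n_k = counts[keep], n_k[keep]
    r = len(n_k)
    n = n_k.sum()
    if r < 2 or n - r <= 0:
        return np.nan, np.nan
    p = counts / n_k[:, None]
    pbar = counts.sum(axis=0) / n
    msa = (n_k[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msw_num = (n_k[:, None] * p * (1.0 - p)).sum(axis=0)
    msw = msw_num / (n - r)
    n_c = (n - (n_k**2).sum() / n) / (r - 1)
    sa = (msa - msw) / n_c
    sw = msw
    return float(sa.sum()), float(sw.sum())


def theta_from_counts(count_tables: Iterable[np.ndarray]) -> float:
    """Multi-locus theta from per-locus (groups x alleles) count tables."""
    tot_a = tot_w = 0.0
    any_defined = False
    for tab in count_tables:
        sa, sw = _components_from_counts(tab)
        if np.isnan(sa):
            continue
        any_defined = True
        tot_a += sa
        tot_w += sw
    if not any_defined or tot_a + tot_w == 0.0:
        return np.nan
    return tot_a / (tot_a + tot_w)


# ---------------------------------------------------------------------------
# public estimators


def _counts_for_locus(groups: Sequence[GroupCounts], locus: str) -> np.ndarray:
    alleles = sorted({a for g in groups for a in g.counts.get(locus, {})})
    idx = {a: i for i, a in enumerate(alleles)}
    out = np.zeros((len(groups), max(len(alleles), 1)))
    for gi, g in enumerate(groups):
        for a, c in g.counts.get(locus, {}).items():
            out[gi, idx[a]] = c
    return out


def fst_theta(groups: Sequence[GroupCounts], loci: Sequence[str] | None = None,
              scope: str = "between-arrangements") -> FstResult:
    """Haploid theta per locus and multi-locus (ratio of summed components)."""
    if len(groups) < 2:
        raise ValidationError("fst_theta needs at least two groups")
    if loci is None:
        loci = sorted({l for g in groups for l in g.counts})
    per_locus: dict[str, float] = {}
    sig_a: dict[str, float] = {}
    sig_w: dict[str, float] = {}
    for locus in loci:
        sa, sw = _components_from_counts(_counts_for_locus(groups, locus))
        if np.isnan(sa) or sa + sw == 0.0:
            per_locus[locus] = np.nan
            sig_a[locus] = np.nan
            sig_w[locus] = np.nan
        else:
            per_locus[locus] = sa / (sa + sw)
            sig_a[locus] = sa
            sig_w[locus] = sw
    tot_a = np.nansum([v for v in sig_a.values()])
    tot_w = np.nansum([v for v in sig_w.values()])
    if not np.any(~np.isnan(list(per_locus.values()))) or tot_a + tot_w == 0.0:
        warnings.warn("theta undefined: all groups monomorphic at all loci", stacklevel=2)
        multi = np.nan
    else:
        multi = tot_a / (tot_a + tot_w)
    return FstResult(scope=scope, per_locus=per_locus, sigma_a=sig_a, sigma_w=sig_w,
                     multi_locus=multi)


def _perm_theta(codes: np.ndarray, glab_perm: np.ndarray, r: int, n_alleles: np.ndarray,
                block: int = 2000) -> np.ndarray:
    """Multi-locus theta for each row of permuted group labels."""
    n_perm = glab_perm.shape[0]
    out = np.empty(n_perm)
    for start in range(0, n_perm, block):
        gl = glab_perm[start:start + block]
        b = gl.shape[0]
        tot_a = np.zeros(b)
        tot_w = np.zeros(b)
        for li in range(codes.shape[1]):
            code = codes[:, li]
            mask = code >= 0
            if mask.sum() < 2:
                continue
            a_count = int(n_alleles[li])
            labels = gl[:, mask]
            c = code[mask]
            flat = (np.arange(b)[:, None] * (r * a_count) + labels * a_count + c).ravel()
            counts = np.bincount(flat, minlength=b * r * a_count).reshape(b, r, a_count).astype(float)
            n_k = counts.sum(axis=2)                      # (b, r)
            n = n_k.sum(axis=1)                           # (b,)
            r_l = (n_k > 0).sum(axis=1)                   # (b,)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n_k[:, :, None] > 0, counts / np.maximum(n_k, 1)[:, :, None], 0.0)
                pbar = counts.sum(axis=1) / n[:, None]    # (b, A)
                ssa = (n_k[:, :, None] * (p - pbar[:, None, :]) ** 2).sum(axis=1)
                ssw = (n_k[:, :, None] * p * (1.0 - p)).sum(axis=1)
                msa = ssa / (r_l - 1)[:, None]
                msw = ssw / (n - r_l)[:, None]
                n_c = (n - (n_k**2).sum(axis=1) / n) / (r_l - 1)
                sa = (msa - msw) / n_c[:, None]
            valid = (r_l >= 2) & (n - r_l > 0)
            tot_a += np.where(valid, np.nansum(sa, axis=1), 0.0)
            tot_w += np.where(valid, np.nansum(msw, axis=1), 0.0)
        with np.errstate(invalid="ignore"):
            out[start:start + b] = tot_a / (tot_a + tot_w)
    return out


def fst_permutation_test(groups: Sequence[GroupCounts], loci: Sequence[str] | None = None,
                         B: int = 10000, rng: np.random.Generator | int | None = None) -> tuple[float, FstResult]:
    """Permute haplotypes among groups (sizes preserved) to test theta > 0.

    Returns (p_value, observed FstResult).  p = (1 + #{theta_perm >=
    theta_obs}) / (B + 1).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(rng)
    if loci is None:
        loci = sorted({l for g in groups for l in g.counts})
    observed = fst_theta(groups, loci)
    codes, gidx, n_alleles = _code_groups(groups, list(loci))
    glab_perm = np.tile(gidx, (B, 1))
    glab_perm = rng.permuted(glab_perm, axis=1)
    theta_perm = _perm_theta(codes, glab_perm, len(groups), n_alleles)
    theta_perm = theta_perm[~np.isnan(theta_perm)]
    p = (1.0 + np.sum(theta_perm >= observed.multi_locus - 1e-12)) / (B + 1.0)
    observed.p_value = float(p)
    observed.n_permutations = B
    return float(p), observed


def pairwise_fst(groups: Sequence[GroupCounts], loci: Sequence[str] | None = None) -> PairwiseFstMatrix:
    """Theta for every pair of groups (negatives retained)."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    k = len(groups)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = fst_theta([groups[i], groups[j]], loci, scope="pairwise")
            mat[i, j] = mat[j, i] = res.multi_locus
    return PairwiseFstMatrix([g.key for g in groups], mat)


def partition_fst(groups: Sequence[GroupCounts], loci: Sequence[str] | None = None,
                  scheme: PartitionScheme | None = None) -> PartitionResult:
    """Between-arrangement vs within-arrangement differentiation.

    "Between" pools every (population x arrangement) unit of the chromosome
    into one analysis; "within:<arr>" compares one arrangement's units
    across populations.  Per-locus theta vectors are compared by an exact
    one-sided paired Wilcoxon signed-rank, pairing each locus's between
    value with its mean within value.
    """
    if scheme is None:
        raise ValidationError("a PartitionScheme is required")
    sel = [g for g in groups if g.key.chromosome == scheme.chromosome]
    if scheme.populations is not None:
        sel = [g for g in sel if g.key.population_id in set(scheme.populations)]
    if scheme.arrangements is not None:
        sel = [g for g in sel if g.key.arrangement in set(scheme.arrangements)]
    arrs = sorted({g.key.arrangement for g in sel})
    pops = {g.key.population_id for g in sel}
    if len(arrs) < 2 or len(pops) < 2:
        raise ValidationError("partition needs >=2 arrangements and >=2 populations")
    if loci is None:
        loci = sorted({l for g in sel for l in g.counts})

    between = fst_theta(sel, loci, scope="between-arrangements")
    within: dict[str, FstResult] = {}
    for arr in arrs:
        sub = [g for g in sel if g.key.arrangement == arr]
        if len(sub) < scheme.min_within_pops:
            warnings.warn(f"arrangement {arr}: carried by <{scheme.min_within_pops} "
                          "populations, within-result omitted", stacklevel=2)
            continue
        within[arr] = fst_theta(sub, loci, scope=f"within:{arr}")

    mean_within: dict[str, float] = {}
    for locus in loci:
        vals = [w.per_locus.get(locus, np.nan) for w in within.values()]
        vals = [v for v in vals if not np.isnan(v)]
        mean_within[locus] = float(np.mean(vals)) if vals else np.nan

    diffs = np.array([
        between.per_locus[l] - mean_within[l]
        for l in loci
        if not (np.isnan(between.per_locus.get(l, np.nan)) or np.isnan(mean_within[l]))
    ])
    if len(diffs) == 0 or np.all(diffs == 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    return PartitionResult(between=between, within=within, wilcoxon_p=wilcoxon_p,
                           mean_within_per_locus=mean_within)


# ---------------------------------------------------------------------------
# principal coordinates


def pcoa(matrix: PairwiseFstMatrix | np.ndarray, labels: Sequence | None = None) -> PcoaResult:
    """Classical scaling of a pairwise theta matrix.

    Theta is treated as a squared dissimilarity: Gower double-centering of
    -F/2 followed by eigendecomposition.  Negative entries are clamped to
    zero first; percent variation is taken over positive eigenvalues.
    """
    if isinstance(matrix, PairwiseFstMatrix):
        labels = list(matrix.labels)
        f = np.array(matrix.values, dtype=float)
    else:
        f = np.array(matrix, dtype=float)
        labels = list(labels) if labels is not None else list(range(len(f)))
    if f.shape[0] != f.shape[1] or not np.allclose(f, f.T, atol=1e-10):
        raise ValidationError("pcoa requires a symmetric matrix")
    f = np.clip(f, 0.0, None)
    np.fill_diagonal(f, 0.0)
    n = f.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ f @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    percent = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return PcoaResult(labels=labels, coordinates=coords, eigenvalues=eigval,
                      percent_variation=percent)
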