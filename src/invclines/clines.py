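"""Geography and latitude: IBD Mantel regressions and clinal fits.

Latitudinal structure is tested three ways: isolation by distance (pairwise
theta against log10 great-circle distance, Mantel-permuted), linear or
quadratic regressions of transformed arrangement frequencies or
heterozygosity on latitude, and per-allele clines of the most common (MCA)
and second most common (SMCA) allele of each locus within one arrangement,
on the arcsin-square-root scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupCounts, PopulationMeta, ValidationError, allele_frequencies
from .diversity import arcsin_sqrt
from .linkage import fdr_adjust
from .structure import PairwiseFstMatrix

__all__ = [
    "ClineFit",
    "IbdResult",
    "geo_distance",
    "ibd_regression",
    "allele_cline_regression",
    "allele_cline_scan",
    "latitude_polynomial_fit",
    "he_inversion_correlation",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClineFit:
    response: str
    transform: str            # "arcsin-sqrt" | "none"
    degree: int
    coefficients: np.ndarray  # highest degree first (numpy polynomial order)
    r2: float
    p_value: float
    n: int


@dataclass
class IbdResult:
    arrangement: str
    locus: str                # or "all-loci"
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_pairs: int
    n_permutations: int


def geo_distance(meta_a: PopulationMeta, meta_b: PopulationMeta) -> float:
    """Haversine great-circle distance in kilometres (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(
        np.radians, (meta_a.latitude, meta_a.longitude, meta_b.latitude, meta_b.longitude)
    )
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int):
    """Polynomial OLS; returns (coefficients, R2, overall F-test p)."""
    n = len(x)
    if n < degree + 2:
        raise ValidationError(f"need >= {degree + 2} points for a degree-{degree} fit")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot <= 1e-14:  # constant response
        return coeffs, 0.0, 1.0
    r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    df_model, df_resid = degree, n - degree - 1
    if 1.0 - r2 <= 1e-12:
        return coeffs, r2, 0.0
    f = (r2 / df_model) / ((1.0 - r2) / df_resid)
    p = float(stats.f.sf(f, df_model, df_resid))
    return coeffs, r2, p


def ibd_regression(matrix: PairwiseFstMatrix, meta: Mapping[str, PopulationMeta],
                   B: int = 10000, rng: np.random.Generator | int | None = None,
                   linearized: bool = False, arrangement: str = "", locus: str = "all-loci",
                   log_base: float = 10.0) -> IbdResult:
    """OLS of pairwise theta on log distance, Mantel-permuted significance.

    Population identities are permuted (matrix rows and columns together);
    the one-sided p-value counts permuted slopes at least as positive as
    observed, p = (1 + #{slope_perm >= slope_obs}) / (B + 1).
    """
    if linearized:
        matrix = matrix.linearized()
    labels = matrix.labels
    if len(labels) < 4:
        raise ValidationError("IBD regression needs >= 4 populations")
    pops = [k.population_id if hasattr(k, "population_id") else str(k) for k in labels]
    k = len(labels)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dkm = geo_distance(meta[pops[i]], meta[pops[j]])
            dist[i, j] = dist[j, i] = dkm
    iu = np.triu_indices(k, 1)
    keep = dist[iu] > 0
    if not np.all(keep):
        warnings.warn("coincident populations: zero-distance pairs excluded", stacklevel=2)
    logd = np.log(dist[iu][keep]) / np.log(log_base)
    y = matrix.values[iu][keep]
    slope, intercept, r, _, _ = stats.linregress(logd, y)
    r2 = float(r**2)

    rng = np.random.default_rng(rng)
    count = 0
    fst = matrix.values
    for _ in range(B):
        perm = rng.permutation(k)
        yp = fst[np.ix_(perm, perm)][iu][keep]
        sxy = np.sum((logd - logd.mean()) * (yp - yp.mean()))
        slope_p = sxy / np.sum((logd - logd.mean()) ** 2)
        if slope_p >= slope - 1e-15:
            count += 1
    p = (1.0 + count) / (B + 1.0)
    return IbdResult(arrangement=arrangement, locus=locus, slope=float(slope),
                     intercept=float(intercept), r2=r2, p_value=float(p),
                     n_pairs=int(keep.sum()), n_permutations=B)


# ---------------------------------------------------------------------------
# allele clines (MCA / SMCA)


def _ranked_common_alleles(freqs_by_pop: Mapping[str, Mapping[int, float]]) -> list[int]:
    """Alleles ranked by unweighted mean frequency across populations.

    Ties break toward the smaller fragment size.
    """
    alleles = sorted({a for f in freqs_by_pop.values() for a in f})
    means = {a: float(np.mean([f.get(a, 0.0) for f in freqs_by_pop.values()])) for a in alleles}
    return sorted(alleles, key=lambda a: (-means[a], a))


def allele_cline_regression(groups: Sequence[GroupCounts], meta: Mapping[str, PopulationMeta],
                            arrangement: str, locus: str, rank: int = 1,
                            min_pops: int = 4) -> ClineFit:
    """Latitude regression of the rank-th most common allele's frequency.

    rank 1 = MCA, rank 2 = SMCA, defined by unweighted mean frequency
    across the populations carrying the arrangement; the response is
    asin(sqrt(frequency)).
    """
    sel = [g for g in groups if g.key.arrangement == arrangement and g.n_locus.get(locus, 0) >= 2]
    if len(sel) < min_pops:
        raise ValidationError(
            f"{locus}/{arrangement}: scored in only {len(sel)} populations (< {min_pops})"
        )
    freqs_by_pop = {g.key.population_id: allele_frequencies(g, locus) for g in sel}
    ranked = _ranked_common_alleles(freqs_by_pop)
    if len(ranked) < rank:
        raise ValidationError(f"{locus}/{arrangement}: fewer than {rank} alleles observed")
    target = ranked[rank - 1]
    pops = sorted(freqs_by_pop)
    lat = np.array([meta[p].latitude for p in pops])
    y = arcsin_sqrt(np.array([freqs_by_pop[p].get(target, 0.0) for p in pops]))
    coeffs, r2, p = _ols_poly(lat, y, 1)
    name = {1: "MCA", 2: "SMCA"}.get(rank, f"rank{rank}")
    return ClineFit(response=f"{locus}/{arrangement}/{name}({target}bp)",
                    transform="arcsin-sqrt", degree=1, coefficients=coeffs,
                    r2=r2, p_value=p, n=len(pops))


def allele_cline_scan(groups: Sequence[GroupCounts], meta: Mapping[str, PopulationMeta],
                      arrangements: Iterable[str] | None = None,
                      loci: Iterable[str] | None = None,
                      fdr_method: str = "by", alpha: float = 0.05,
                      min_pops: int = 4) -> pd.DataFrame:
    """MCA and SMCA cline regressions for all loci x arrangements, with FDR."""
    if arrangements is None:
        arrangements = sorted({g.key.arrangement for g in groups})
    rows = []
    for arr in arrangements:
        arr_groups = [g for g in groups if g.key.arrangement == arr]
        loci_here = sorted({l for g in arr_groups for l in g.counts}) if loci is None else list(loci)
        for locus in loci_here:
            for rank, name in ((1, "MCA"), (2, "SMCA")):
                try:
                    fit = allele_cline_regression(groups, meta, arr, locus, rank, min_pops=min_pops)
                except ValidationError:
                    continue
                rows.append({"arrangement": arr, "locus": locus, "rank": name,
                             "allele": fit.response.split("(")[-1].rstrip("bp)"),
                             "slope": fit.coefficients[0], "r2": fit.r2,
                             "p_value": fit.p_value, "n_pops": fit.n})
    df = pd.DataFrame(rows)
    if len(df):
        reject, p_adj = fdr_adjust(df["p_value"], method=fdr_method, alpha=alpha)
        df["significant_fdr"] = reject
        df["p_adjusted"] = p_adj
    return df


def latitude_polynomial_fit(values_by_population: Mapping[str, float],
                            meta: Mapping[str, PopulationMeta],
                            degree: int = 1, transform: str = "arcsin-sqrt",
                            response: str = "") -> ClineFit:
    """Polynomial OLS of a per-population quantity on latitude.

    Used degree-1 for arrangement-frequency clines and degree-2 for
    heterozygosity against latitude.  ``transform`` is "arcsin-sqrt" or
    "none".
    """
    pops = [p for p, v in values_by_population.items() if not np.isnan(v)]
    lat = np.array([meta[p].latitude for p in pops])
    y = np.array([values_by_population[p] for p in pops], dtype=float)
    if transform == "arcsin-sqrt":
        y = arcsin_sqrt(y)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    coeffs, r2, p = _ols_poly(lat, y, degree)
    return ClineFit(response=response, transform=transform, degree=degree,
                    coefficients=coeffs, r2=r2, p_value=p, n=len(pops))


def he_inversion_correlation(he_by_pop: Mapping[str, Mapping[str, float]],
                             arrangement_freqs: Mapping[str, Mapping[str, float]],
                             min_pops: int = 4) -> pd.DataFrame:
    """Pearson correlation of per-locus He with arrangement frequency.

    ``he_by_pop[locus][population]`` and
    ``arrangement_freqs[arrangement][population]``.  Returns one row per
    (locus, arrangement); constant series are reported with NA.
    """
    rows = []
    for locus, he in he_by_pop.items():
        for arr, freqs in arrangement_freqs.items():
            pops = sorted(set(he) & set(freqs))
            pops = [p for p in pops if not (np.isnan(he[p]) or np.isnan(freqs[p]))]
            if len(pops) < min_pops:
                continue
            x = np.array([freqs[p] for p in pops])
            y = np.array([he[p] for p in pops])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"locus": locus, "arrangement": arr, "r": np.nan,
                             "p_value": np.nan, "n": len(pops)})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"locus": locus, "arrangement": arr, "r": float(r),
                         "p_value": float(p), "n": len(pops)})
    df = pd.DataFrame(rows)
    if len(df):
        tested = df["p_value"].notna()
        df.attrs["fraction_nonsignificant"] = float(
            (df.loc[tested, "p_value"] >= 0.05).mean()) if tested.any() else np.nan
    return df
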