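"""fdist-style F_ST outlier detection under a neutral island-model null.

A symmetric n-island structured coalescent with infinite-alleles mutation
generates paired (He, F_ST) values for neutral loci; the migration
parameter M (migrants per deme per generation) is bisected until the
median simulated F_ST matches the observed multi-locus value; observed
loci falling outside He-conditioned quantile envelopes are flagged as
candidates for positive (high F_ST) or balancing (low F_ST) selection.

The coalescent is event-driven: lineages sampled from ``n_sampled_demes``
of ``n_demes`` exchangeable demes coalesce pairwise within demes and
migrate to uniformly chosen other demes; mutations are dropped on branches
at a per-generation rate, each mutation creating a brand-new allele (only
the most recent mutation above a leaf determines its allele).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .core import GroupCounts, ValidationError
from .diversity import gene_diversity
from .structure import fst_theta, _components_from_counts

__all__ = [
    "SampleConfig",
    "OutlierEnvelope",
    "calibrate_island_model",
    "simulate_neutral_fst_he",
    "build_envelope",
    "classify_outliers",
    "observed_locus_stats",
    "outlier_scan",
]


@dataclass(frozen=True)
class SampleConfig:
    """Sampling design of the neutral simulations (study defaults)."""

    n_demes: int = 100
    n_sampled_demes: int = 9
    haplotypes_per_deme: int = 30
    deme_size: float = 1.0


@dataclass
class OutlierEnvelope:
    he_bin_edges: np.ndarray
    lower: np.ndarray          # per-bin alpha/2 F_ST quantile
    upper: np.ndarray          # per-bin 1 - alpha/2 quantile
    median: np.ndarray
    n_loci: int
    M: float
    target_fst: float
    alpha: float
    sim_he: np.ndarray = field(repr=False, default=None)
    sim_fst: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items() if k not in ("sim_he", "sim_fst")}
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# event-driven island coalescent (numba)


@njit(cache=True)
def _island_coalescent_batch(n_demes, n_sampled, n_per_deme, m_total, mus, seed):
    """Allele codes (n_loci x n_samples) under the island model with IAM."""
    np.random.seed(seed)
    n = n_sampled * n_per_deme
    n_loci = mus.shape[0]
    out = np.zeros((n_loci, n), dtype=np.int32)
    max_nodes = 2 * n - 1
    for locus in range(n_loci):
        mu = mus[locus]
        deme = np.empty(n, dtype=np.int64)       # deme of each active lineage slot
        node = np.empty(n, dtype=np.int64)       # node id carried by the slot
        for i in range(n):
            deme[i] = i // n_per_deme
            node[i] = i
        parent = np.full(max_nodes, -1, dtype=np.int64)
        time = np.zeros(max_nodes)
        k_d = np.zeros(n_demes, dtype=np.int64)
        for i in range(n):
            k_d[i // n_per_deme] += 1
        n_active = n
        next_node = n
        t = 0.0
        pairs = 0.0
        for d in range(n_demes):
            pairs += k_d[d] * (k_d[d] - 1) / 2.0
        while n_active > 1:
            coal_rate = pairs  # deme size 1 in coalescent units
            mig_rate = n_active * m_total
            total = coal_rate + mig_rate
            t += np.random.exponential(1.0 / total)
            if np.random.random() < coal_rate / total:
                # choose deme proportional to k_d (k_d - 1)
                u = np.random.random() * 2.0 * pairs
                acc = 0.0
                dsel = 0
                for d in range(n_demes):
                    acc += k_d[d] * (k_d[d] - 1)
                    if acc > u:
                        dsel = d
                        break
                # pick two distinct slots in deme dsel
                i1 = np.random.randint(k_d[dsel])
                i2 = np.random.randint(k_d[dsel] - 1)
                if i2 >= i1:
                    i2 += 1
                s1 = -1
                s2 = -1
                seen = 0
                for s in range(n_active):
                    if deme[s] == dsel:
                        if seen == i1:
                            s1 = s
                        if seen == i2:
                            s2 = s
                        seen += 1
                anc = next_node
                next_node += 1
                time[anc] = t
                parent[node[s1]] = anc
                parent[node[s2]] = anc
                node[s1] = anc
                # remove slot s2
                deme[s2] = deme[n_active - 1]
                node[s2] = node[n_active - 1]
                n_active -= 1
                k_d[dsel] -= 1
                pairs -= k_d[dsel]  # k(k-1)/2 dropped by the new k
            else:
                s = np.random.randint(n_active)
                d_new = np.random.randint(n_demes - 1)
                if d_new >= deme[s]:
                    d_new += 1
                k_d[deme[s]] -= 1
                pairs -= k_d[deme[s]]
                k_d[d_new] += 1
                pairs += k_d[d_new] - 1
                deme[s] = d_new
        # mutations: allele changes on a branch with prob 1 - exp(-mu * len)
        allele = np.zeros(max_nodes, dtype=np.int32)
        next_allele = 1
        for v in range(max_nodes - 2, -1, -1):  # parents precede children in time
            pa = parent[v]
            if pa < 0:
                allele[v] = 0
                continue
            br = time[pa] - time[v]
            if np.random.random() < 1.0 - np.exp(-mu * br):
                allele[v] = next_allele
                next_allele += 1
            else:
                allele[v] = allele[pa]
        out[locus] = allele[:n]
    return out


def _locus_stats(alleles: np.ndarray, n_sampled: int, n_per_deme: int) -> tuple[float, float]:
    """(pooled unbiased He, haploid theta) for one simulated locus."""
    n = alleles.size
    codes, inv = np.unique(alleles, return_inverse=True)
    a = len(codes)
    if a < 2:
        return np.nan, np.nan
    deme_idx = np.arange(n) // n_per_deme
    counts = np.zeros((n_sampled, a))
    np.add.at(counts, (deme_idx, inv), 1.0)
    p = counts.sum(axis=0) / n
    he = (n / (n - 1.0)) * (1.0 - float(np.sum(p * p)))
    sa, sw = _components_from_counts(counts)
    theta = np.nan if (np.isnan(sa) or sa + sw == 0) else sa / (sa + sw)
    return he, theta


def simulate_neutral_fst_he(M: float, sample_config: SampleConfig = SampleConfig(),
                            n_loci: int = 10000,
                            theta_range: tuple[float, float] = (0.05, 19.0),
                            rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Neutral (He, F_ST) pairs; mutation theta log-uniform in theta_range.

    Monomorphic loci are excluded, so the returned frame may be shorter
    than ``n_loci``.
    """
    rng = np.random.default_rng(rng)
    sc = sample_config
    log_lo, log_hi = np.log(theta_range[0]), np.log(theta_range[1])
    thetas = np.exp(rng.uniform(log_lo, log_hi, size=n_loci))
    # theta is scaled to the metapopulation: per-generation rate on branches
    mus = thetas / (2.0 * sc.n_demes * sc.deme_size)
    seed = int(rng.integers(1, 2**31 - 1))
    batch = _island_coalescent_batch(sc.n_demes, sc.n_sampled_demes, sc.haplotypes_per_deme,
                                     float(M), mus, seed)
    rows = []
    for locus in range(n_loci):
        he, theta = _locus_stats(batch[locus], sc.n_sampled_demes, sc.haplotypes_per_deme)
        if not np.isnan(he) and not np.isnan(theta):
            rows.append((he, theta))
    return pd.DataFrame(rows, columns=["he", "fst"])


def calibrate_island_model(target_fst: float, sample_config: SampleConfig = SampleConfig(),
                           rng: np.random.Generator | int | None = None,
                           pilot_loci: int = 2000, rel_tol: float = 0.05,
                           max_iter: int = 40) -> float:
    """Bisect the migration parameter until median simulated F_ST hits target.

    Starts from the island-model moment approximation target = 1/(1 + 2M)
    and converges when the pilot median is within ``rel_tol`` relative.
    """
    if not 0.0 < target_fst < 1.0:
        raise ValidationError("target F_ST must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    m0 = (1.0 - target_fst) / (2.0 * target_fst)

    def median_fst(m: float) -> float:
        sim = simulate_neutral_fst_he(m, sample_config, n_loci=pilot_loci, rng=rng)
        return float(sim["fst"].median())

    # Lazy bracketing on the log scale starting from the moment
    # approximation; median F_ST is decreasing in M, so an evaluation
    # above target raises the lower bound and vice versa.  Evaluations
    # stay near m0 unless the approximation is genuinely off.
    lo = hi = np.nan
    m = m0
    med = np.nan
    for _ in range(max_iter):
        med = median_fst(m)
        if abs(med - target_fst) <= rel_tol * target_fst:
            return float(m)
        if med > target_fst:
            lo = m
            m = np.sqrt(lo * hi) if np.isfinite(hi) else m * 4.0
        else:
            hi = m
            m = np.sqrt(lo * hi) if np.isfinite(lo) else m / 4.0
    raise ValidationError(
        f"island-model calibration did not converge: target {target_fst}, "
        f"last median {med:.4f} at M={m:.3f} (bracket [{lo}, {hi}])"
    )


# ---------------------------------------------------------------------------
# envelopes and classification


def build_envelope(M: float, sample_config: SampleConfig = SampleConfig(),
                   n_loci: int = 10000, alpha: float = 0.01, n_bins: int = 50,
                   target_fst: float = np.nan,
                   theta_range: tuple[float, float] = (0.05, 19.0),
                   rng: np.random.Generator | int | None = None,
                   min_bin: int = 25) -> OutlierEnvelope:
    """He-binned F_ST quantile envelope from neutral simulations.

    He is cut into ``n_bins`` equal bins on (0, 1); thin bins borrow
    neighbouring loci until they hold at least ``min_bin`` values.
    """
    sim = simulate_neutral_fst_he(M, sample_config, n_loci=n_loci,
                                  theta_range=theta_range, rng=rng)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    he = sim["he"].to_numpy()
    fst = sim["fst"].to_numpy()
    idx = np.clip(np.digitize(he, edges) - 1, 0, n_bins - 1)
    lower = np.full(n_bins, np.nan)
    upper = np.full(n_bins, np.nan)
    median = np.full(n_bins, np.nan)
    for b in range(n_bins):
        width = 0
        sel = idx == b
        while sel.sum() < min_bin and width < n_bins:
            width += 1
            sel = (idx >= b - width) & (idx <= b + width)
        vals = fst[sel]
        if vals.size == 0:
            continue
        lower[b] = np.quantile(vals, alpha / 2.0)
        upper[b] = np.quantile(vals, 1.0 - alpha / 2.0)
        median[b] = np.median(vals)
    return OutlierEnvelope(he_bin_edges=edges, lower=lower, upper=upper, median=median,
                           n_loci=len(sim), M=float(M), target_fst=float(target_fst),
                           alpha=alpha, sim_he=he, sim_fst=fst)


def classify_outliers(observed: pd.DataFrame, envelope: OutlierEnvelope,
                      alpha: float | None = None) -> pd.DataFrame:
    """Assign {positive, balancing, neutral} per observed locus.

    ``observed`` needs columns locus, he, fst.  Empirical p-values are the
    He-bin tail fractions of simulated F_ST beyond the observed value.
    Observations outside the simulated He range use the nearest populated
    bin and are flagged.
    """
    if alpha is not None and abs(alpha - envelope.alpha) > 1e-12:
        raise ValidationError("envelope was built for a different alpha; rebuild it")
    edges = envelope.he_bin_edges
    n_bins = len(edges) - 1
    sim_idx = np.clip(np.digitize(envelope.sim_he, edges) - 1, 0, n_bins - 1)
    populated = np.where(~np.isnan(envelope.median))[0]
    rows = []
    for _, rec in observed.iterrows():
        he, fst = float(rec["he"]), float(rec["fst"])
        b = int(np.clip(np.digitize(he, edges) - 1, 0, n_bins - 1))
        out_of_range = np.isnan(envelope.median[b])
        if out_of_range:
            b = int(populated[np.argmin(np.abs(populated - b))])
        sel = sim_idx == b
        width = 0
        while sel.sum() < 25 and width < n_bins:
            width += 1
            sel = (sim_idx >= b - width) & (sim_idx <= b + width)
        vals = envelope.sim_fst[sel]
        p_high = (1.0 + np.sum(vals >= fst)) / (len(vals) + 1.0)
        p_low = (1.0 + np.sum(vals <= fst)) / (len(vals) + 1.0)
        if fst > envelope.upper[b]:
            cls = "positive"
        elif fst < envelope.lower[b]:
            cls = "balancing"
        else:
            cls = "neutral"
        rows.append({"locus": rec["locus"], "he": he, "fst": fst,
                     "classification": cls, "p_positive": p_high, "p_balancing": p_low,
                     "he_out_of_range": bool(out_of_range)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observed statistics and the full scan


def observed_locus_stats(groups: Sequence[GroupCounts],
                         loci: Sequence[str] | None = None) -> pd.DataFrame:
    """Pooled-sample He and across-group theta per locus (scan input)."""
    if loci is None:
        loci = sorted({l for g in groups for l in g.counts})
    res = fst_theta(groups, loci)
    rows = []
    for locus in loci:
        pooled: dict[int, int] = {}
        for g in groups:
            for a, c in g.counts.get(locus, {}).items():
                pooled[a] = pooled.get(a, 0) + c
        if sum(pooled.values()) < 2:
            continue
        he = gene_diversity(pooled)
        fst = res.per_locus.get(locus, np.nan)
        if not np.isnan(fst):
            rows.append({"locus": locus, "he": he, "fst": fst})
    return pd.DataFrame(rows)


def outlier_scan(groups: Sequence[GroupCounts], loci: Sequence[str] | None = None,
                 sample_config: SampleConfig = SampleConfig(), n_loci: int = 10000,
                 alpha: float = 0.01, refine: bool = False,
                 rng: np.random.Generator | int | None = None
                 ) -> tuple[pd.DataFrame, OutlierEnvelope]:
    """Calibrate, simulate and classify in one call (one arrangement's groups).

    ``refine`` performs one LOSITAN-style pass: flagged loci are removed,
    the migration parameter recalibrated on the remaining (putatively
    neutral) loci, and all loci reclassified against the new envelope.
    """
    rng = np.random.default_rng(rng)
    observed = observed_locus_stats(groups, loci)
    if observed.empty:
        raise ValidationError("no polymorphic loci to scan")
    target = float(np.average(observed["fst"]))
    target = min(max(target, 1e-3), 0.99)
    m = calibrate_island_model(target, sample_config, rng=rng)
    env = build_envelope(m, sample_config, n_loci=n_loci, alpha=alpha,
                         target_fst=target, rng=rng)
    result = classify_outliers(observed, env)
    if refine and (result["classification"] != "neutral").any():
        neutral = result[result["classification"] == "neutral"]
        if len(neutral) >= 2:
            target2 = min(max(float(neutral["fst"].mean()), 1e-3), 0.99)
            m = calibrate_island_model(target2, sample_config, rng=rng)
            env = build_envelope(m, sample_config, n_loci=n_loci, alpha=alpha,
                                 target_fst=target2, rng=rng)
            result = classify_outliers(observed, env)
    return result, env
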