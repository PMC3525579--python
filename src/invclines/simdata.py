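"""Synthetic haplotype datasets with the structure the analyses assume.

The generator emulates the sampling design of a nine-population latitudinal
survey: arrangement frequencies follow multinomial-logit clines in
latitude; loci inside an inversion draw from an arrangement-specific allele
pool (the footprint of suppressed recombination in heterokaryotypes);
every population re-draws its pool with a Dirichlet (Balding–Nichols-style)
divergence so that E[F_ST] of the draw against the base equals the chosen
F; optional features inject a clinal allele (arcsin-sqrt linear in
latitude) or a target D' between one locus pair.  A truth object records
every realized frequency for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import GroupKey, HaplotypeRecord, LocusInfo, PopulationMeta, ValidationError
from ._study import ARRANGEMENTS, LOCUS_MAP, POPULATIONS

__all__ = [
    "LocusSpec",
    "ClinalAlleleSpec",
    "LdPairSpec",
    "SimConfig",
    "SimTruth",
    "cline_arrangement_freqs",
    "draw_group_freqs",
    "inject_clinal_allele",
    "simulate_dataset",
    "study_config",
]


@dataclass(frozen=True)
class LocusSpec:
    name: str
    chromosome: str
    n_alleles: int = 8
    inside_of: frozenset[str] = frozenset()
    base_freqs: tuple[float, ...] | None = None   # None = symmetric Dirichlet(2) draw
    allele_start_bp: int = 100                    # allele sizes: start, start+2, ...

    def allele_sizes(self) -> np.ndarray:
        return self.allele_start_bp + 2 * np.arange(self.n_alleles)


@dataclass(frozen=True)
class ClinalAlleleSpec:
    locus: str
    arrangement: str
    allele_index: int
    c0: float     # arcsin-sqrt intercept (radians)
    c1: float     # arcsin-sqrt slope per degree latitude


@dataclass(frozen=True)
class LdPairSpec:
    locus_a: str
    locus_b: str
    arrangement: str
    dprime: float


@dataclass
class SimConfig:
    populations: dict[str, PopulationMeta]
    arrangements: dict[str, list[str]]
    cline_coeffs: dict[str, dict[str, tuple[float, float]]]  # chrom -> arr -> (a, b)
    loci: list[LocusSpec]
    f_arr: float = 0.1
    f_pop: float = 0.007
    group_size: int = 30           # quota mode: haplotypes per population x arrangement
    mode: str = "quota"            # "quota" | "cline" (karyotypes drawn from cline freqs)
    n_per_population: int = 90     # cline mode: chromosomes sampled per population
    min_group_size: int = 1
    clinal_allele: ClinalAlleleSpec | None = None
    ld_pair: LdPairSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f, name in ((self.f_arr, "f_arr"), (self.f_pop, "f_pop")):
            if not 0.0 <= f < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1), got {f}")
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate locus names in SimConfig")
        known_arrs = {a for arrs in self.arrangements.values() for a in arrs}
        for l in self.loci:
            if l.chromosome not in self.arrangements:
                raise ValidationError(f"locus {l.name}: unknown chromosome {l.chromosome}")
            bad = l.inside_of - known_arrs
            if bad:
                raise ValidationError(f"locus {l.name}: inside_of references unknown arrangements {bad}")
        if self.clinal_allele is not None and self.clinal_allele.locus not in names:
            raise ValidationError("clinal_allele references an unknown locus")
        if self.ld_pair is not None and (
            self.ld_pair.locus_a not in names or self.ld_pair.locus_b not in names
        ):
            raise ValidationError("ld_pair references unknown loci")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "populations": {p: {"latitude": m.latitude, "longitude": m.longitude,
                                "year": m.year} for p, m in self.populations.items()},
            "arrangements": self.arrangements,
            "cline_coeffs": {c: {a: list(ab) for a, ab in d.items()}
                             for c, d in self.cline_coeffs.items()},
            "loci": [{"name": l.name, "chromosome": l.chromosome,
                      "n_alleles": l.n_alleles, "inside_of": sorted(l.inside_of),
                      "base_freqs": list(l.base_freqs) if l.base_freqs else None,
                      "allele_start_bp": l.allele_start_bp} for l in self.loci],
            "f_arr": self.f_arr, "f_pop": self.f_pop, "group_size": self.group_size,
            "mode": self.mode, "n_per_population": self.n_per_population,
            "min_group_size": self.min_group_size, "seed": self.seed,
        }
        if self.clinal_allele:
            payload["clinal_allele"] = vars(self.clinal_allele).copy()
        if self.ld_pair:
            payload["ld_pair"] = vars(self.ld_pair).copy()
        import yaml
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text())
        pops = {p: PopulationMeta(p, v["latitude"], v["longitude"], v.get("year"))
                for p, v in d["populations"].items()}
        loci = [LocusSpec(name=l["name"], chromosome=l["chromosome"],
                          n_alleles=l.get("n_alleles", 8),
                          inside_of=frozenset(l.get("inside_of", [])),
                          base_freqs=tuple(l["base_freqs"]) if l.get("base_freqs") else None,
                          allele_start_bp=l.get("allele_start_bp", 100)) for l in d["loci"]]
        clinal = d.get("clinal_allele")
        ld = d.get("ld_pair")
        return cls(
            populations=pops,
            arrangements={c: list(a) for c, a in d["arrangements"].items()},
            cline_coeffs={c: {a: tuple(ab) for a, ab in m.items()}
                          for c, m in d["cline_coeffs"].items()},
            loci=loci, f_arr=d.get("f_arr", 0.1), f_pop=d.get("f_pop", 0.007),
            group_size=d.get("group_size", 30), mode=d.get("mode", "quota"),
            n_per_population=d.get("n_per_population", 90),
            min_group_size=d.get("min_group_size", 1),
            clinal_allele=ClinalAlleleSpec(**clinal) if clinal else None,
            ld_pair=LdPairSpec(**ld) if ld else None,
            seed=d.get("seed", 0),
        )

    def locus_map(self) -> dict[str, LocusInfo]:
        return {
            l.name: LocusInfo(name=l.name, chromosome=l.chromosome, cyto_order=i + 1,
                              inside_of=l.inside_of)
            for i, l in enumerate(self.loci)
        }


@dataclass
class SimTruth:
    """Realized generating frequencies, keyed by string tuples for JSON."""

    arrangement_freqs: dict[str, dict[str, dict[str, float]]]           # pop -> chrom -> arr
    allele_freqs: dict[str, dict[str, dict[str, list[float]]]]          # pop -> arr -> locus
    arrangement_pools: dict[str, dict[str, list[float]]]                # arr -> locus
    config_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# ---------------------------------------------------------------------------
# building blocks


def cline_arrangement_freqs(config: SimConfig, population_id: str,
                            chromosome: str) -> dict[str, float]:
    """Softmax of (a_k + b_k * latitude) over the chromosome's arrangements."""
    arrs = config.arrangements[chromosome]
    if not arrs:
        raise ValidationError(f"chromosome {chromosome} declares no arrangements")
    lat = config.populations[population_id].latitude
    scores = np.array([config.cline_coeffs[chromosome][a][0]
                       + config.cline_coeffs[chromosome][a][1] * lat for a in arrs])
    scores -= scores.max()
    w = np.exp(scores)
    w /= w.sum()
    return dict(zip(arrs, w))


def draw_group_freqs(base_freqs: Sequence[float], F: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dirichlet divergence draw with E[F_ST] = F against the base.

    Concentration base_i * (1 - F) / F, so Var(p_i) = F p_i (1 - p_i).
    F = 0 returns the base exactly; alleles absent from the base stay absent.
    """
    base = np.asarray(base_freqs, dtype=float)
    if not 0.0 <= F < 1.0:
        raise ValidationError(f"F must lie in [0, 1), got {F}")
    if F == 0.0:
        return base.copy()
    out = np.zeros_like(base)
    pos = base > 0
    alpha = base[pos] * (1.0 - F) / F
    out[pos] = rng.dirichlet(alpha)
    return out


def inject_clinal_allele(freqs_by_population: Mapping[str, Sequence[float]],
                         spec: ClinalAlleleSpec,
                         latitudes: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Force one allele's frequency to sin^2(c0 + c1 * lat), clipped to [0.01, 0.99].

    Remaining alleles are rescaled proportionally so each vector still sums
    to one.
    """
    out: dict[str, np.ndarray] = {}
    for pop, freqs in freqs_by_population.items():
        p = np.asarray(freqs, dtype=float).copy()
        if len(p) < 2:
            raise ValidationError("cannot inject a cline at a single-allele locus")
        target = float(np.clip(np.sin(spec.c0 + spec.c1 * latitudes[pop]) ** 2, 0.01, 0.99))
        rest = np.delete(p, spec.allele_index)
        if rest.sum() <= 0:
            rest = np.full(len(p) - 1, 1.0 / (len(p) - 1))
        else:
            rest = rest / rest.sum()
        p[spec.allele_index] = target
        rest_idx = [i for i in range(len(p)) if i != spec.allele_index]
        p[rest_idx] = (1.0 - target) * rest
        out[pop] = p
    return out


def _joint_ld_distribution(p: np.ndarray, q: np.ndarray, dprime: float) -> np.ndarray:
    """Two-locus joint distribution with target D' on the two modal alleles."""
    ia, ib = int(np.argmax(p)), int(np.argmax(q))
    pa, qb = p[ia], q[ib]
    dmax = min(pa * (1 - qb), (1 - pa) * qb) if dprime >= 0 else min(pa * qb, (1 - pa) * (1 - qb))
    d = dprime * dmax
    cell = np.array([[pa * qb + d, pa * (1 - qb) - d],
                     [(1 - pa) * qb - d, (1 - pa) * (1 - qb) + d]])
    cell = np.clip(cell, 0.0, None)
    cell /= cell.sum()
    wa = np.where(np.arange(len(p)) == ia, 1.0, 0.0)
    wa_rest = np.where(np.arange(len(p)) == ia, 0.0, p)
    wa_rest = wa_rest / wa_rest.sum() if wa_rest.sum() > 0 else wa_rest
    wb = np.where(np.arange(len(q)) == ib, 1.0, 0.0)
    wb_rest = np.where(np.arange(len(q)) == ib, 0.0, q)
    wb_rest = wb_rest / wb_rest.sum() if wb_rest.sum() > 0 else wb_rest
    joint = (cell[0, 0] * np.outer(wa, wb) + cell[0, 1] * np.outer(wa, wb_rest)
             + cell[1, 0] * np.outer(wa_rest, wb) + cell[1, 1] * np.outer(wa_rest, wb_rest))
    return joint / joint.sum()


# ---------------------------------------------------------------------------
# dataset generation


def simulate_dataset(config: SimConfig) -> tuple[list[HaplotypeRecord], SimTruth]:
    """Draw a full haplotype table plus its generating truth.

    Fully reproducible from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    loci_by_chrom: dict[str, list[LocusSpec]] = {}
    for l in config.loci:
        loci_by_chrom.setdefault(l.chromosome, []).append(l)

    # base allele pools per locus
    base_pools: dict[str, np.ndarray] = {}
    for l in config.loci:
        if l.base_freqs is not None:
            base = np.asarray(l.base_freqs, dtype=float)
            if len(base) != l.n_alleles or not np.isclose(base.sum(), 1.0):
                raise ValidationError(f"locus {l.name}: invalid base_freqs")
        else:
            base = rng.dirichlet(np.full(l.n_alleles, 2.0))
        base_pools[l.name] = base

    # Arrangement-specific pools at inside loci: each arrangement named in
    # inside_of keeps its own pool, and the remaining (standard-class)
    # arrangements share one further pool, every class drawn independently
    # at divergence f_arr so pairwise between-class F_ST is ~f_arr.
    # Loci inside nothing share the base pool across all arrangements.
    arr_pools: dict[tuple[str, str], np.ndarray] = {}
    for chrom, arrs in config.arrangements.items():
        for l in loci_by_chrom.get(chrom, []):
            if not l.inside_of:
                for arr in arrs:
                    arr_pools[(arr, l.name)] = base_pools[l.name].copy()
                continue
            class_pools: dict[str, np.ndarray] = {}
            for arr in arrs:
                cls = arr if arr in l.inside_of else "__standard__"
                if cls not in class_pools:
                    class_pools[cls] = draw_group_freqs(base_pools[l.name], config.f_arr, rng)
                arr_pools[(arr, l.name)] = class_pools[cls]

    # per-population pools re-drawn with f_pop
    pop_pools: dict[tuple[str, str, str], np.ndarray] = {}
    for pop in config.populations:
        for (arr, locus), pool in arr_pools.items():
            pop_pools[(pop, arr, locus)] = draw_group_freqs(pool, config.f_pop, rng)

    if config.clinal_allele is not None:
        spec = config.clinal_allele
        lats = {p: m.latitude for p, m in config.populations.items()}
        current = {p: pop_pools[(p, spec.arrangement, spec.locus)] for p in config.populations}
        adjusted = inject_clinal_allele(current, spec, lats)
        for p, v in adjusted.items():
            pop_pools[(p, spec.arrangement, spec.locus)] = v

    # group sizes
    sizes: dict[tuple[str, str, str], int] = {}
    arr_freq_truth: dict[str, dict[str, dict[str, float]]] = {}
    for pop in config.populations:
        arr_freq_truth[pop] = {}
        for chrom, arrs in config.arrangements.items():
            freqs = cline_arrangement_freqs(config, pop, chrom)
            arr_freq_truth[pop][chrom] = {a: float(f) for a, f in freqs.items()}
            if config.mode == "quota":
                for arr in arrs:
                    sizes[(pop, chrom, arr)] = config.group_size
            elif config.mode == "cline":
                draw = rng.multinomial(config.n_per_population, [freqs[a] for a in arrs])
                for arr, k in zip(arrs, draw):
                    if k >= config.min_group_size:
                        sizes[(pop, chrom, arr)] = int(k)
            else:
                raise ValidationError(f"unknown mode {config.mode!r}")

    ld = config.ld_pair
    records: list[HaplotypeRecord] = []
    allele_truth: dict[str, dict[str, dict[str, list[float]]]] = {}
    for (pop, chrom, arr), size in sorted(sizes.items()):
        loci = loci_by_chrom.get(chrom, [])
        drawn: dict[str, np.ndarray] = {}
        ld_here = ld is not None and ld.arrangement == arr and all(
            any(l.name == x and l.chromosome == chrom for l in loci) for x in (ld.locus_a, ld.locus_b)
        )
        if ld_here:
            p = pop_pools[(pop, arr, ld.locus_a)]
            q = pop_pools[(pop, arr, ld.locus_b)]
            joint = _joint_ld_distribution(p, q, ld.dprime)
            flat = rng.choice(joint.size, size=size, p=joint.ravel())
            ia, ib = np.unravel_index(flat, joint.shape)
            spec_a = next(l for l in loci if l.name == ld.locus_a)
            spec_b = next(l for l in loci if l.name == ld.locus_b)
            drawn[ld.locus_a] = spec_a.allele_sizes()[ia]
            drawn[ld.locus_b] = spec_b.allele_sizes()[ib]
        for l in loci:
            if l.name in drawn:
                continue
            pool = pop_pools[(pop, arr, l.name)]
            idx = rng.choice(l.n_alleles, size=size, p=pool)
            drawn[l.name] = l.allele_sizes()[idx]
        for i in range(size):
            records.append(
                HaplotypeRecord(
                    individual_id=f"{pop}_{chrom}_{arr}_{i:03d}",
                    population_id=pop,
                    chromosome=chrom,
                    arrangement=arr,
                    alleles={l.name: int(drawn[l.name][i]) for l in loci},
                )
            )
        allele_truth.setdefault(pop, {}).setdefault(arr, {})
        for l in loci:
            allele_truth[pop][arr][l.name] = [float(v) for v in pop_pools[(pop, arr, l.name)]]

    truth = SimTruth(
        arrangement_freqs=arr_freq_truth,
        allele_freqs=allele_truth,
        arrangement_pools={f"{arr}:{locus}": [float(v) for v in pool]
                           for (arr, locus), pool in arr_pools.items()},
        config_seed=config.seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# the default, study-shaped configuration


def study_config(seed: int = 0, f_arr: float = 0.1, f_pop: float = 0.007,
                 group_size: int = 30, mode: str = "quota",
                 clinal_allele: ClinalAlleleSpec | None = None,
                 ld_pair: LdPairSpec | None = None) -> SimConfig:
    """Nine populations spanning ~24 degrees of latitude, 3 chromosomes,
    19 loci with the study's inside/outside layout, ~30 haplotypes per
    arrangement x population.

    Cline coefficients give standard arrangements frequencies rising with
    latitude and inverted ones falling, with slopes of the magnitude seen
    in European arrangement clines (~1-2% frequency change per degree).
    """
    cline_coeffs = {
        "A": {"A_ST": (-3.2, 0.075), "A_1": (0.2, 0.0), "A_2": (3.0, -0.075)},
        "J": {"J_ST": (-4.0, 0.085), "J_1": (4.0, -0.085)},
        "U": {"U_ST": (-4.5, 0.095), "U_1+2": (2.4, -0.05), "U_1+2+8": (2.1, -0.055)},
    }
    loci = [
        LocusSpec(name=info.name, chromosome=info.chromosome, n_alleles=8,
                  inside_of=info.inside_of, allele_start_bp=100 + 30 * i)
        for i, info in enumerate(LOCUS_MAP.values())
    ]
    return SimConfig(
        populations=dict(POPULATIONS),
        arrangements={k: list(v) for k, v in ARRANGEMENTS.items()},
        cline_coeffs=cline_coeffs,
        loci=loci,
        f_arr=f_arr,
        f_pop=f_pop,
        group_size=group_size,
        mode=mode,
        clinal_allele=clinal_allele,
        ld_pair=ld_pair,
        seed=seed,
    )
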