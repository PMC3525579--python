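"""Orchestration: run every analysis stage on one dataset and render
study-shaped report tables.

The report mirrors the layouts population geneticists expect from this
kind of survey: an n/He table (arrangements x populations), a D'm table
with significance stars, and an R2 table of MCA/SMCA latitude clines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _study
from .core import (HaplotypeRecord, LocusInfo, PopulationMeta,
                   ValidationError, group_counts)
from .diversity import arrangement_diversity, diversity_table, group_mean_diversity
from .linkage import dm_scan, locus_pair_table, ohta_components
from .clines import (allele_cline_scan, ibd_regression, latitude_polynomial_fit)
from .structure import (PartitionScheme, pairwise_fst, partition_fst, pcoa)
from .outliers import SampleConfig, outlier_scan

log = logging.getLogger("invclines")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_report", "significance_stars"]


@dataclass
class PipelineConfig:
    locus_map: Mapping[str, LocusInfo]
    pop_meta: Mapping[str, PopulationMeta]
    arrangements: Mapping[str, Sequence[str]]
    exclude_populations: tuple[str, ...] = ()
    B: int = 10000
    fdr_method: str = "by"
    alpha: float = 0.05
    min_obs: int = 3
    min_group_size: int = 7
    seed: int = 0
    outlier_loci: int = 10000          # neutral loci per envelope
    outlier_alpha: float = 0.01
    run_outliers: bool = True

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValidationError("B must be >= 100")

    @classmethod
    def study_defaults(cls, **kw) -> "PipelineConfig":
        return cls(locus_map=dict(_study.LOCUS_MAP), pop_meta=dict(_study.POPULATIONS),
                   arrangements={k: list(v) for k, v in _study.ARRANGEMENTS.items()}, **kw)


@dataclass
class ReportBundle:
    stages: dict[str, object] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.errors)


def _arrangement_freqs(records: Sequence[HaplotypeRecord], chromosome: str,
                       arrangements: Sequence[str]) -> pd.DataFrame:
    """Observed arrangement frequencies per population for one chromosome."""
    rows = {}
    for rec in records:
        if rec.chromosome != chromosome:
            continue
        rows.setdefault(rec.population_id, {}).setdefault(rec.arrangement, 0)
        rows[rec.population_id][rec.arrangement] += 1
    out = []
    for pop, counts in sorted(rows.items()):
        n = sum(counts.values())
        row = {"population": pop, "n": n}
        for arr in arrangements:
            row[arr] = counts.get(arr, 0) / n
        out.append(row)
    return pd.DataFrame(out)


def run_pipeline(records: Sequence[HaplotypeRecord], config: PipelineConfig) -> ReportBundle:
    """diversity -> structure -> linkage -> clines -> outliers.

    A stage failure marks the bundle partial; completed stages are kept.
    Deterministic for a fixed config.seed.
    """
    bundle = ReportBundle()
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    keep = [r for r in records if r.population_id not in set(config.exclude_populations)]
    groups = group_counts(keep, min_group_size=config.min_group_size)
    chroms = sorted({g.key.chromosome for g in groups})
    pops_present = sorted({g.key.population_id for g in groups})

    def _stage(name, fn):
        log.info("stage %s starting (seed %s)", name, config.seed)
        try:
            bundle.stages[name] = fn()
        except Exception as exc:  # keep earlier stages on failure
            log.exception("stage %s failed", name)
            bundle.errors[name] = f"{type(exc).__name__}: {exc}"

    # -- diversity ---------------------------------------------------------
    def diversity_stage():
        per_locus = diversity_table(groups)
        per_group = group_mean_diversity(per_locus)
        arr_he = []
        for chrom in chroms:
            freqs = _arrangement_freqs(keep, chrom, config.arrangements[chrom])
            for _, row in freqs.iterrows():
                p = np.array([row[a] for a in config.arrangements[chrom]])
                if p.sum() > 0:
                    arr_he.append({"chromosome": chrom, "population": row["population"],
                                   "n": row["n"],
                                   "he": arrangement_diversity(p / p.sum(), n=int(row["n"]))})
        return {"per_locus": per_locus, "per_group": per_group,
                "arrangement_he": pd.DataFrame(arr_he)}

    _stage("diversity", diversity_stage)

    # -- structure ---------------------------------------------------------
    def structure_stage():
        rng = np.random.default_rng(seeds[1])
        out = {}
        for chrom in chroms:
            scheme = PartitionScheme(chromosome=chrom)
            part = partition_fst(groups, scheme=scheme)
            pw = pairwise_fst([g for g in groups if g.key.chromosome == chrom])
            out[chrom] = {"partition": part, "pairwise": pw, "pcoa": pcoa(pw)}
        return out

    _stage("structure", structure_stage)

    # -- linkage -----------------------------------------------------------
    def linkage_stage():
        rng = np.random.default_rng(seeds[2])
        out = {}
        for chrom in chroms:
            loci = sorted([l for l, info in config.locus_map.items() if info.chromosome == chrom],
                          key=lambda l: config.locus_map[l].cyto_order)
            dm = dm_scan(keep, loci, chrom, config.arrangements[chrom], pops_present,
                         B=config.B, fdr_method=config.fdr_method, alpha=config.alpha, rng=rng)
            ohta_rows = []
            for arr in config.arrangements[chrom]:
                for i, la in enumerate(loci):
                    for lb in loci[i + 1:]:
                        tabs = {}
                        for pop in pops_present:
                            try:
                                tabs[pop] = locus_pair_table(keep, la, lb, arrangement=arr,
                                                             populations=[pop])
                            except ValidationError:
                                continue
                        if len(tabs) < 2:
                            continue
                        comp = ohta_components(tabs)
                        ohta_rows.append({"arrangement": arr, "locus_a": la, "locus_b": lb,
                                          "n_pops": len(tabs), "d2_is": comp.d2_is,
                                          "d2_st": comp.d2_st, "dp2_is": comp.dp2_is,
                                          "dp2_st": comp.dp2_st, "d2_it": comp.d2_it})
            out[chrom] = {"dm": dm, "ohta": pd.DataFrame(ohta_rows)}
        return out

    _stage("linkage", linkage_stage)

    # -- clines ------------------------------------------------------------
    def clines_stage():
        rng = np.random.default_rng(seeds[3])
        meta = config.pop_meta
        arr_fits = []
        he_fits = []
        for chrom in chroms:
            freqs = _arrangement_freqs(keep, chrom, config.arrangements[chrom])
            for arr in config.arrangements[chrom]:
                vals = dict(zip(freqs["population"], freqs[arr]))
                try:
                    fit = latitude_polynomial_fit(vals, meta, degree=1, transform="arcsin-sqrt",
                                                  response=f"freq({arr})")
                except ValidationError:
                    continue
                arr_fits.append({"chromosome": chrom, "arrangement": arr,
                                 "slope": fit.coefficients[0], "r2": fit.r2,
                                 "p_value": fit.p_value})
            arr_cols = list(config.arrangements[chrom])
            he_vals = {}
            for _, row in freqs.iterrows():
                p = np.array([row[a] for a in arr_cols])
                if p.sum() > 0:
                    he_vals[row["population"]] = arrangement_diversity(p / p.sum(), n=int(row["n"]))
            try:
                fit = latitude_polynomial_fit(he_vals, meta, degree=2, transform="arcsin-sqrt",
                                              response=f"He(arrangements:{chrom})")
                he_fits.append({"chromosome": chrom, "quad_coeff": fit.coefficients[0],
                                "r2": fit.r2, "p_value": fit.p_value})
            except ValidationError:
                pass
        scan = allele_cline_scan(groups, meta, fdr_method=config.fdr_method, alpha=config.alpha)
        ibd_rows = []
        for chrom in chroms:
            for arr in config.arrangements[chrom]:
                sub = [g for g in groups if g.key.arrangement == arr]
                if len(sub) < 4:
                    continue
                pw = pairwise_fst(sub)
                res = ibd_regression(pw, meta, B=config.B, rng=rng, arrangement=arr)
                ibd_rows.append({"chromosome": chrom, "arrangement": arr, "slope": res.slope,
                                 "r2": res.r2, "p_value": res.p_value, "n_pairs": res.n_pairs})
        return {"arrangement_clines": pd.DataFrame(arr_fits),
                "he_latitude": pd.DataFrame(he_fits),
                "allele_clines": scan, "ibd": pd.DataFrame(ibd_rows)}

    _stage("clines", clines_stage)

    # -- outliers ----------------------------------------------------------
    if config.run_outliers:
        def outliers_stage():
            rng = np.random.default_rng(seeds[4])
            out = {}
            for chrom in chroms:
                for arr in config.arrangements[chrom]:
                    sub = [g for g in groups if g.key.arrangement == arr]
                    if len(sub) < 4:
                        continue
                    sc = SampleConfig(n_sampled_demes=len(sub),
                                      haplotypes_per_deme=int(np.mean([g.size for g in sub])))
                    try:
                        res, env = outlier_scan(sub, sample_config=sc,
                                                n_loci=config.outlier_loci,
                                                alpha=config.outlier_alpha, rng=rng)
                    except ValidationError as exc:
                        log.warning("outlier scan skipped for %s: %s", arr, exc)
                        continue
                    res.insert(0, "arrangement", arr)
                    out[arr] = {"classification": res, "M": env.M, "target_fst": env.target_fst}
            return out

        _stage("outliers", outliers_stage)

    return bundle


# ---------------------------------------------------------------------------
# rendering


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_report(bundle: ReportBundle, outdir: str | Path,
                  config: PipelineConfig | None = None) -> list[Path]:
    """Write study-shaped TSV tables and a text summary; returns the paths."""
    if not bundle.stages:
        raise ValidationError("empty bundle: nothing to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if "diversity" in bundle.stages:
        per_group = bundle.stages["diversity"]["per_group"]
        rows = []
        pops = sorted(per_group["population"].unique())
        for (chrom, arr), sub in per_group.groupby(["chromosome", "arrangement"]):
            by_pop = sub.set_index("population")
            n_row = {"arrangement": arr, "row": "n"}
            he_row = {"arrangement": arr, "row": "He"}
            for pop in pops:
                n_row[pop] = int(by_pop.loc[pop, "n"]) if pop in by_pop.index else "-"
                he_row[pop] = round(float(by_pop.loc[pop, "he"]), 3) if pop in by_pop.index else "-"
            rows.extend([n_row, he_row])
        _write(pd.DataFrame(rows), "table1_diversity.tsv")
        _write(bundle.stages["diversity"]["per_locus"], "diversity_per_locus.tsv")

    if "linkage" in bundle.stages:
        frames = []
        for chrom, data in bundle.stages["linkage"].items():
            dm = data["dm"]
            if dm.empty:
                continue
            wide = dm.pivot_table(index="locus", columns="population", values="dm", sort=False)
            stars = dm.assign(star=[significance_stars(p) if sig else ""
                                    for p, sig in zip(dm["p_value"].fillna(1.0),
                                                      dm.get("significant_fdr", [False] * len(dm)))])
            star_wide = stars.pivot_table(index="locus", columns="population", values="star",
                                          aggfunc="first", sort=False)
            merged = wide.round(3).astype(str) + star_wide.fillna("")
            merged.insert(0, "chromosome", chrom)
            frames.append(merged.reset_index())
            _write(dm, f"dm_long_{chrom}.tsv")
            _write(data["ohta"], f"ohta_{chrom}.tsv")
        if frames:
            _write(pd.concat(frames), "table2_dm.tsv")

    if "clines" in bundle.stages:
        scan = bundle.stages["clines"]["allele_clines"]
        if len(scan):
            wide = scan.pivot_table(index="locus", columns=["rank", "arrangement"], values="r2")
            _write(wide.round(3).reset_index(), "table3_clinal_r2.tsv")
            _write(scan, "allele_clines_long.tsv")
        for key in ("arrangement_clines", "he_latitude", "ibd"):
            df = bundle.stages["clines"][key]
            if len(df):
                _write(df, f"{key}.tsv")

    if "structure" in bundle.stages:
        rows = []
        for chrom, data in bundle.stages["structure"].items():
            part = data["partition"]
            rows.append({"chromosome": chrom, "scope": "between",
                         "theta": part.between.multi_locus, "wilcoxon_p": part.wilcoxon_p})
            for arr, res in part.within.items():
                rows.append({"chromosome": chrom, "scope": f"within:{arr}",
                             "theta": res.multi_locus, "wilcoxon_p": np.nan})
            _write(data["pairwise"].to_frame().reset_index(), f"pairwise_fst_{chrom}.tsv")
        _write(pd.DataFrame(rows), "fst_partition.tsv")

    if "outliers" in bundle.stages:
        frames = [d["classification"] for d in bundle.stages["outliers"].values()]
        if frames:
            _write(pd.concat(frames), "outlier_classification.tsv")

    summary = outdir / "summary.txt"
    with summary.open("w") as fh:
        fh.write("invclines report\n================\n")
        fh.write(f"stages completed: {sorted(bundle.stages)}\n")
        if bundle.partial:
            fh.write(f"MISSING stages (errors): {bundle.errors}\n")
        if "structure" in bundle.stages:
            for chrom, data in bundle.stages["structure"].items():
                part = data["partition"]
                within_mean = np.nanmean([r.multi_locus for r in part.within.values()])
                fh.write(
                    f"chromosome {chrom}: between-arrangement theta = "
                    f"{part.between.multi_locus:.4f}, mean within = {within_mean:.4f} "
                    f"(Wilcoxon one-sided p = {part.wilcoxon_p:.4g})\n"
                )
    written.append(summary)
    return written
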