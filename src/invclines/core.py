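"""Domain types, readers/writers and grouping for phased haplotype data.

The unit of observation is a single phased wild chromosome: one individual
contributes, per chromosome, one arrangement label (its karyotypic class,
e.g. ``J_1``) together with the microsatellite allele it carries at every
locus mapped on that chromosome.  Alleles are identified by their fragment
size in base pairs.  Analysis units are groups of haplotypes sharing a
(population, chromosome, arrangement) key.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "LocusInfo",
    "PopulationMeta",
    "HaplotypeRecord",
    "GroupKey",
    "GroupCounts",
    "ValidationError",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_locus_map",
    "read_population_meta",
    "group_counts",
    "allele_frequencies",
    "write_genepop",
    "read_genepop_codes",
]

#: Sentinel for an unscored locus in a haplotype record.
MISSING = None

_ID_COLUMNS = ("individual", "population", "chromosome", "arrangement")


class ValidationError(ValueError):
    """Raised when an input table violates the declared study design."""


@dataclass(frozen=True)
class LocusInfo:
    """A microsatellite locus and its cytological context.

    ``inside_of`` lists the arrangement labels for which the locus lies
    inside the inverted segment (or inside the region containing that
    inversion, for the sex chromosome's region scheme).  ``region`` is
    only meaningful on chromosome A.
    """

    name: str
    chromosome: str
    cyto_order: int
    inside_of: frozenset[str] = frozenset()
    region: str | None = None

    def __post_init__(self) -> None:
        if (self.region is not None) and self.chromosome != "A":
            raise ValidationError(
                f"locus {self.name}: region labels are defined only on chromosome A"
            )

    def is_inside(self, arrangement: str) -> bool:
        return arrangement in self.inside_of


@dataclass(frozen=True)
class PopulationMeta:
    population_id: str
    latitude: float
    longitude: float
    year: int | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.population_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.population_id}: longitude {self.longitude} out of range")


@dataclass
class HaplotypeRecord:
    """One phased wild chromosome."""

    individual_id: str
    population_id: str
    chromosome: str
    arrangement: str
    alleles: dict[str, int | None]

    def allele(self, locus: str) -> int | None:
        return self.alleles.get(locus, MISSING)


@dataclass(frozen=True, order=True)
class GroupKey:
    population_id: str
    chromosome: str
    arrangement: str

    def __str__(self) -> str:  # e.g. "BCN:J_1"
        return f"{self.population_id}:{self.arrangement}"


@dataclass
class GroupCounts:
    """Allele counts for one (population, chromosome, arrangement) unit.

    ``counts[locus]`` maps allele size -> count among the haplotypes scored
    at that locus; ``n_locus[locus]`` is that number of scored haplotypes
    (missing alleles are dropped locus-wise).  ``haplotypes`` retains the
    per-haplotype allele calls so permutation procedures can resample whole
    haplotypes rather than independent loci.
    """

    key: GroupKey
    size: int
    counts: dict[str, dict[int, int]] = field(default_factory=dict)
    n_locus: dict[str, int] = field(default_factory=dict)
    haplotypes: list[dict[str, int | None]] = field(default_factory=list)

    @classmethod
    def from_records(cls, key: GroupKey, records: Sequence[HaplotypeRecord]) -> "GroupCounts":
        counts: dict[str, dict[int, int]] = {}
        n_locus: dict[str, int] = {}
        haps = []
        for rec in records:
            haps.append(dict(rec.alleles))
            for locus, allele in rec.alleles.items():
                if allele is MISSING:
                    continue
                per = counts.setdefault(locus, {})
                per[allele] = per.get(allele, 0) + 1
                n_locus[locus] = n_locus.get(locus, 0) + 1
        return cls(key=key, size=len(records), counts=counts, n_locus=n_locus, haplotypes=haps)

    @property
    def loci(self) -> list[str]:
        return sorted(self.counts)


def allele_frequencies(group: GroupCounts, locus: str) -> dict[int, float]:
    """Relative allele frequencies of ``locus`` within one group."""
    if locus not in group.counts or group.n_locus.get(locus, 0) < 1:
        raise ValidationError(f"locus {locus} is unscored in group {group.key}")
    n = group.n_locus[locus]
    return {a: c / n for a, c in sorted(group.counts[locus].items())}


# ---------------------------------------------------------------------------
# readers / writers


def _parse_allele(value: object, row: int, locus: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return MISSING
    text = str(value).strip()
    if text in ("", "NA", "na", "NaN", "-"):
        return MISSING
    try:
        allele = int(float(text))
    except ValueError as exc:
        raise ValidationError(f"row {row}: allele {value!r} at locus {locus} is not an integer") from exc
    if allele <= 0:
        raise ValidationError(f"row {row}: allele {allele} at locus {locus} must be positive")
    return allele


def read_haplotype_table(
    path: str | Path,
    locus_map: Mapping[str, LocusInfo],
    pop_meta: Mapping[str, PopulationMeta],
    arrangements: Mapping[str, Iterable[str]],
) -> list[HaplotypeRecord]:
    """Read a delimited haplotype table and validate it against the design.

    The header must name ``individual``, ``population``, ``chromosome`` and
    ``arrangement``; every remaining column is taken to be a locus.  Missing
    alleles are encoded as empty cells or ``NA``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing_cols = [c for c in _ID_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"haplotype table lacks required columns: {missing_cols}")
    locus_cols = [c for c in df.columns if c not in _ID_COLUMNS]
    for locus in locus_cols:
        if locus not in locus_map:
            raise ValidationError(f"unknown locus column {locus!r}")

    declared = {chrom: set(arrs) for chrom, arrs in arrangements.items()}
    records: list[HaplotypeRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = dict(zip(df.columns, row))
        pop, chrom, arr = rec["population"], rec["chromosome"], rec["arrangement"]
        if pop not in pop_meta:
            raise ValidationError(f"row {i}: unknown population {pop!r}")
        if chrom not in declared:
            raise ValidationError(f"row {i}: unknown chromosome {chrom!r}")
        if arr not in declared[chrom]:
            raise ValidationError(f"row {i}: arrangement {arr!r} is not declared for chromosome {chrom!r}")
        key = (rec["individual"], chrom)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate (individual, chromosome) {key}")
        seen.add(key)
        alleles: dict[str, int | None] = {}
        for locus in locus_cols:
            if locus_map[locus].chromosome != chrom:
                continue  # columns of other chromosomes stay unscored for this record
            alleles[locus] = _parse_allele(rec[locus], i, locus)
        records.append(
            HaplotypeRecord(
                individual_id=rec["individual"],
                population_id=pop,
                chromosome=chrom,
                arrangement=arr,
                alleles=alleles,
            )
        )
    return records


def write_haplotype_table(records: Sequence[HaplotypeRecord], path: str | Path) -> None:
    loci = sorted({locus for rec in records for locus in rec.alleles})
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "individual": rec.individual_id,
            "population": rec.population_id,
            "chromosome": rec.chromosome,
            "arrangement": rec.arrangement,
        }
        for locus in loci:
            allele = rec.alleles.get(locus, MISSING)
            row[locus] = "" if allele is MISSING else allele
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locus_map(path: str | Path) -> dict[str, LocusInfo]:
    """Read a locus map TSV: name, chromosome, cyto_order, inside_of, region.

    ``inside_of`` is a comma-separated list of arrangement labels (may be
    empty); ``region`` may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, LocusInfo] = {}
    for _, row in df.iterrows():
        inside = frozenset(x for x in str(row.get("inside_of", "")).split(",") if x)
        region = str(row.get("region", "")) or None
        out[row["name"]] = LocusInfo(
            name=row["name"],
            chromosome=row["chromosome"],
            cyto_order=int(row["cyto_order"]),
            inside_of=inside,
            region=region,
        )
    return out


def read_population_meta(path: str | Path) -> dict[str, PopulationMeta]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        year = int(row["year"]) if "year" in df.columns and pd.notna(row.get("year")) else None
        out[str(row["population"])] = PopulationMeta(
            population_id=str(row["population"]),
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            year=year,
        )
    return out


def write_population_meta(meta: Mapping[str, PopulationMeta], path: str | Path) -> None:
    rows = [
        {"population": m.population_id, "latitude": m.latitude, "longitude": m.longitude, "year": m.year}
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# grouping


def group_counts(
    records: Sequence[HaplotypeRecord],
    min_group_size: int = 7,
) -> list[GroupCounts]:
    """Partition records into (population, chromosome, arrangement) units.

    Groups smaller than ``min_group_size`` (default 7, the smallest analysed
    unit in the study design) are dropped with a warning, mirroring the
    practice of excluding rare-arrangement samples.
    """
    by_key: dict[GroupKey, list[HaplotypeRecord]] = {}
    for rec in records:
        key = GroupKey(rec.population_id, rec.chromosome, rec.arrangement)
        by_key.setdefault(key, []).append(rec)
    groups = []
    for key in sorted(by_key):
        members = by_key[key]
        if len(members) < min_group_size:
            warnings.warn(
                f"group {key} dropped: size {len(members)} < min_group_size {min_group_size}",
                stacklevel=2,
            )
            continue
        groups.append(GroupCounts.from_records(key, members))
    return groups


def pool_groups(groups: Sequence[GroupCounts], by: str = "arrangement") -> list[GroupCounts]:
    """Merge groups sharing an arrangement (or population) into pooled units.

    Used when analyses need one unit per arrangement across populations
    (e.g. between-arrangement divergence at maximal sample size).
    """
    out: dict[GroupKey, GroupCounts] = {}
    for g in groups:
        if by == "arrangement":
            key = GroupKey("pooled", g.key.chromosome, g.key.arrangement)
        elif by == "population":
            key = GroupKey(g.key.population_id, g.key.chromosome, "pooled")
        else:
            raise ValidationError(f"unknown pooling axis {by!r}")
        tgt = out.setdefault(key, GroupCounts(key, 0))
        tgt.size += g.size
        tgt.haplotypes.extend(g.haplotypes)
        for locus, cnt in g.counts.items():
            per = tgt.counts.setdefault(locus, {})
            for a, c in cnt.items():
                per[a] = per.get(a, 0) + c
            tgt.n_locus[locus] = tgt.n_locus.get(locus, 0) + g.n_locus[locus]
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Genepop export (haploid written as homozygous diploid)


def write_genepop(groups: Sequence[GroupCounts], path: str | Path, title: str = "invclines export") -> dict[str, dict[int, int]]:
    """Write groups in the Genepop dialect, alleles rank-coded per locus.

    Haploid data are written as homozygous diploids so downstream tools that
    only accept diploid Genepop files can consume them.  Returns the
    allele-size -> 3-digit code map per locus, which is also written to a
    ``<path>.codes.tsv`` sidecar.
    """
    if not groups:
        raise ValidationError("no groups to export")
    loci = sorted({locus for g in groups for locus in g.counts})
    codes: dict[str, dict[int, int]] = {}
    for locus in loci:
        alleles = sorted({a for g in groups for a in g.counts.get(locus, {})})
        if len(alleles) > 999:
            raise ValidationError(f"locus {locus}: {len(alleles)} alleles exceed 3-digit Genepop coding")
        codes[locus] = {a: i + 1 for i, a in enumerate(alleles)}

    path = Path(path)
    with path.open("w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for g in groups:
            fh.write("POP\n")
            for hap in g.haplotypes:
                fields = []
                for locus in loci:
                    allele = hap.get(locus, MISSING)
                    code = 0 if allele is MISSING else codes[locus][allele]
                    fields.append(f"{code:03d}{code:03d}")
                fh.write(f"{g.key} , " + " ".join(fields) + "\n")

    side = [
        {"locus": locus, "allele_bp": a, "code": c}
        for locus in loci
        for a, c in codes[locus].items()
    ]
    pd.DataFrame(side).to_csv(path.with_suffix(path.suffix + ".codes.tsv"), sep="\t", index=False)
    return codes


def read_genepop_codes(path: str | Path) -> dict[str, dict[int, int]]:
    """Read a sidecar code map back (code -> allele size per locus)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["locus"], {})[int(row["code"])] = int(row["allele_bp"])
    return out
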