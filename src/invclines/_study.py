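"""Default study design: nine European populations, three chromosomes.

Latitudes follow the printed sampling-site coordinates (DMS converted to
decimal degrees).  Longitudes are not printed in the source study; the
values below are external gazetteer coordinates for the nine towns, so
geographic distances built from them are approximate.
"""

from __future__ import annotations

from .core import LocusInfo, PopulationMeta

# population_id -> (latitude, longitude, collection year)
POPULATIONS: dict[str, PopulationMeta] = {
    pid: PopulationMeta(pid, lat, lon, year)
    for pid, lat, lon, year in [
        ("MAL", 36.0 + 43.0 / 60, -4.421, 2008),   # Málaga, Spain
        ("VAL", 39.0 + 32.0 / 60, -0.375, 2008),   # València, Spain
        ("RAS", 40.0 + 57.0 / 60, 0.595, 2008),    # Rasquera, Spain
        ("BCN", 41.0 + 25.0 / 60, 2.168, 2007),    # Barcelona, Spain
        ("MON", 43.0 + 35.0 / 60, 3.877, 2009),    # Montpellier, France
        ("DIJ", 47.0 + 18.0 / 60, 5.041, 2009),    # Dijon, France
        ("GRO", 53.0 + 13.0 / 60, 6.566, 2009),    # Groningen, Netherlands
        ("DRO", 59.0 + 34.0 / 60, 10.630, 2005),   # Drøbak, Norway
        ("SUN", 60.0 + 8.0 / 60, 13.139, 2005),    # Sunne, Sweden
    ]
}

#: Frequent arrangements per chromosome (rarer classes are not analysed).
ARRANGEMENTS: dict[str, list[str]] = {
    "A": ["A_ST", "A_1", "A_2"],
    "J": ["J_ST", "J_1"],
    "U": ["U_ST", "U_1+2", "U_1+2+8"],
}

# 19 microsatellites in cytological order from the centromere.  On the sex
# chromosome three regions are compared instead of single inversions:
# region I contains inversion A_1, region II contains A_2, region III none.
_LOCI: list[tuple[str, str, frozenset[str], str | None]] = [
    ("dsub11", "A", frozenset({"A_1"}), "I"),
    ("dsub37", "A", frozenset({"A_1"}), "I"),
    ("dsub76", "A", frozenset({"A_2"}), "II"),
    ("dsub05", "A", frozenset({"A_2"}), "II"),
    ("dsub21", "A", frozenset({"A_2"}), "II"),
    ("dsub39", "A", frozenset({"A_2"}), "II"),
    ("dsub70", "A", frozenset(), "III"),
    ("dsub19", "A", frozenset(), "III"),
    ("dsub18", "J", frozenset(), None),
    ("dsub59", "J", frozenset({"J_1"}), None),
    ("dsub69", "J", frozenset({"J_1"}), None),
    ("dsub74", "J", frozenset(), None),
    ("dsub62", "J", frozenset(), None),
    ("dsub27", "J", frozenset(), None),
    ("dsub10", "U", frozenset(), None),
    ("dsub03", "U", frozenset(), None),
    ("dsub42", "U", frozenset({"U_1+2", "U_1+2+8"}), None),
    ("dsub64", "U", frozenset({"U_1+2", "U_1+2+8"}), None),
    ("dsub15", "U", frozenset(), None),
]


def study_locus_map() -> dict[str, LocusInfo]:
    out: dict[str, LocusInfo] = {}
    order: dict[str, int] = {}
    for name, chrom, inside, region in _LOCI:
        order[chrom] = order.get(chrom, 0) + 1
        out[name] = LocusInfo(name=name, chromosome=chrom, cyto_order=order[chrom],
                              inside_of=inside, region=region)
    return out


LOCUS_MAP = study_locus_map()

#: Scandinavian populations, excluded in the study's sensitivity reanalyses.
SCANDINAVIA = ("DRO", "SUN")
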