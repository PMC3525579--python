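import numpy as np
import pytest
from hypothesis import settings

import invclines as ic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_dataset():
    """One study-shaped synthetic dataset shared across tests."""
    cfg = ic.study_config(seed=11)
    records, truth = ic.simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def study_groups(study_dataset):
    _, records, _ = study_dataset
    return ic.group_counts(records)


def two_arrangement_config(seed, f_arr=0.1, f_pop=0.007, n_loci=8, n_inside=3,
                           group_size=30, **kw):
    """A single-chromosome design: 2 arrangements, 9 populations."""
    loci = [
        ic.LocusSpec(name=f"L{i:02d}", chromosome="J", n_alleles=8,
                     inside_of=frozenset({"J_1"}) if i < n_inside else frozenset(),
                     allele_start_bp=100 + 30 * i)
        for i in range(n_loci)
    ]
    from invclines._study import POPULATIONS
    return ic.SimConfig(
        populations=dict(POPULATIONS),
        arrangements={"J": ["J_ST", "J_1"]},
        cline_coeffs={"J": {"J_ST": (-4.0, 0.085), "J_1": (4.0, -0.085)}},
        loci=loci,
        f_arr=f_arr,
        f_pop=f_pop,
        group_size=group_size,
        seed=seed,
        **kw,
    )
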