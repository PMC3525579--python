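import numpy as np
import pytest

import invclines as ic
from invclines.simdata import (_joint_ld_distribution, cline_arrangement_freqs,
                               draw_group_freqs, inject_clinal_allele)
from invclines.structure import PartitionScheme, fst_theta, partition_fst
from conftest import two_arrangement_config


def test_cline_freqs_uniform_when_flat():
    cfg = ic.study_config(seed=0)
    cfg.cline_coeffs["J"] = {"J_ST": (0.0, 0.0), "J_1": (0.0, 0.0)}
    f = cline_arrangement_freqs(cfg, "BCN", "J")
    assert f["J_ST"] == pytest.approx(0.5)
    assert sum(f.values()) == pytest.approx(1.0)


def test_cline_freqs_monotone_in_latitude():
    cfg = ic.study_config(seed=0)
    pops = sorted(cfg.populations, key=lambda p: cfg.populations[p].latitude)
    freqs = [cline_arrangement_freqs(cfg, p, "J")["J_ST"] for p in pops]
    assert all(a < b for a, b in zip(freqs, freqs[1:]))


def test_cline_freqs_closed_form():
    cfg = ic.study_config(seed=0)
    cfg.populations["TEST"] = ic.PopulationMeta("TEST", 50.0, 0.0)
    cfg.cline_coeffs["J"] = {"J_ST": (0.0, 0.0), "J_1": (0.0, -0.2)}
    f = cline_arrangement_freqs(cfg, "TEST", "J")
    assert f["J_1"] == pytest.approx(1.0 / (1.0 + np.exp(10.0)), rel=1e-12)


def test_dirichlet_f_zero_identity():
    base = np.array([0.2, 0.3, 0.5])
    out = draw_group_freqs(base, 0.0, np.random.default_rng(0))
    assert np.array_equal(out, base)


def test_dirichlet_moments():
    rng = np.random.default_rng(1)
    draws = np.array([draw_group_freqs([0.5, 0.5], 0.5, rng) for _ in range(100000)])
    # Var(p1) = F p (1-p) = 0.125; mean unbiased
    assert draws[:, 0].var() == pytest.approx(0.125, rel=0.03)
    assert draws[:, 0].mean() == pytest.approx(0.5, abs=0.005)


def test_dirichlet_rejects_f_one():
    with pytest.raises(ic.ValidationError):
        draw_group_freqs([0.5, 0.5], 1.0, np.random.default_rng(0))


def test_inject_constant_when_flat_slope():
    spec = ic.ClinalAlleleSpec("L", "J_1", 0, c0=0.7, c1=0.0)
    freqs = {"a": [0.4, 0.6], "b": [0.1, 0.9]}
    out = inject_clinal_allele(freqs, spec, {"a": 40.0, "b": 60.0})
    assert out["a"][0] == pytest.approx(np.sin(0.7) ** 2)
    assert out["b"][0] == pytest.approx(np.sin(0.7) ** 2)


def test_inject_exact_inverse_regression():
    from invclines.diversity import arcsin_sqrt
    lats = {f"p{i}": 36.0 + 3.0 * i for i in range(9)}
    spec = ic.ClinalAlleleSpec("L", "J_1", 1, c0=1.5, c1=-0.015)  # no clipping in range
    freqs = {p: [0.3, 0.3, 0.4] for p in lats}
    out = inject_clinal_allele(freqs, spec, lats)
    x = np.array(list(lats.values()))
    y = arcsin_sqrt([out[p][1] for p in lats])
    slope, intercept = np.polyfit(x, y, 1)
    assert slope == pytest.approx(-0.015, rel=1e-9)
    assert intercept == pytest.approx(1.5, rel=1e-9)


def test_inject_preserves_other_allele_proportions():
    spec = ic.ClinalAlleleSpec("L", "J_1", 0, c0=0.9, c1=0.0)
    out = inject_clinal_allele({"a": [0.5, 0.3, 0.2]}, spec, {"a": 45.0})["a"]
    assert out.sum() == pytest.approx(1.0)
    assert out[1] / out[2] == pytest.approx(1.5)


def test_inject_single_allele_errors():
    spec = ic.ClinalAlleleSpec("L", "J_1", 0, 0.5, 0.0)
    with pytest.raises(ic.ValidationError):
        inject_clinal_allele({"a": [1.0]}, spec, {"a": 45.0})


# ---------------------------------------------------------------------------
# full dataset


def test_same_seed_byte_identical(tmp_path):
    cfg = ic.study_config(seed=5)
    r1, t1 = ic.simulate_dataset(cfg)
    r2, t2 = ic.simulate_dataset(ic.study_config(seed=5))
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    ic.write_haplotype_table(r1, p1)
    ic.write_haplotype_table(r2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_truth_roundtrip_json(tmp_path):
    cfg = two_arrangement_config(seed=2, n_loci=3)
    _, truth = ic.simulate_dataset(cfg)
    truth.to_json(tmp_path / "truth.json")
    import json
    loaded = json.loads((tmp_path / "truth.json").read_text())
    assert loaded["config_seed"] == 2
    assert "MAL" in loaded["arrangement_freqs"]


def test_no_structure_gives_zero_theta():
    cfg = two_arrangement_config(seed=3, f_arr=0.0, f_pop=0.0, group_size=500, n_loci=4)
    records, _ = ic.simulate_dataset(cfg)
    groups = ic.group_counts(records)
    theta = fst_theta(groups).multi_locus
    assert abs(theta) < 0.01


def test_f_arr_recovery_inside_vs_outside():
    from invclines.core import pool_groups
    thetas_in, thetas_out = [], []
    for seed in range(6):
        cfg = two_arrangement_config(seed=100 + seed, f_arr=0.25, f_pop=0.0,
                                     n_loci=8, n_inside=4, group_size=60)
        records, _ = ic.simulate_dataset(cfg)
        groups = pool_groups(ic.group_counts(records), by="arrangement")
        res = fst_theta(groups)
        inside = [f"L{i:02d}" for i in range(4)]
        thetas_in.append(np.nanmean([res.per_locus[l] for l in inside]))
        thetas_out.append(np.nanmean([res.per_locus[l] for l in res.per_locus
                                      if l not in inside]))
    assert np.mean(thetas_in) == pytest.approx(0.25, abs=0.05)
    assert abs(np.mean(thetas_out)) < 0.02


@pytest.mark.parametrize("f_pop", [0.005, 0.05, 0.2])
def test_f_pop_recovery_within_arrangement(f_pop):
    vals = []
    for seed in range(8):
        cfg = two_arrangement_config(seed=1000 + seed, f_arr=0.0, f_pop=f_pop,
                                     n_loci=6, n_inside=0, group_size=40)
        records, _ = ic.simulate_dataset(cfg)
        groups = [g for g in ic.group_counts(records) if g.key.arrangement == "J_ST"]
        vals.append(fst_theta(groups).multi_locus)
    assert np.mean(vals) == pytest.approx(f_pop, rel=0.20)


def test_ld_pair_injection_recovers_dprime():
    cfg = two_arrangement_config(
        seed=9, n_loci=4, n_inside=0, group_size=300, f_pop=0.0,
        ld_pair=ic.LdPairSpec("L00", "L01", "J_1", 0.8),
    )
    records, _ = ic.simulate_dataset(cfg)
    recs = [r for r in records if r.arrangement == "J_1" and r.population_id == "BCN"]
    from invclines.linkage import locus_pair_table, allele_inversion_dprime
    tab = locus_pair_table(recs, "L00", "L01")
    res = allele_inversion_dprime(tab, min_obs=1)
    best = max(res, key=lambda r: r.joint_count)
    assert 0.7 <= abs(best.dprime) <= 0.9


def test_joint_ld_distribution_margins():
    p = np.array([0.5, 0.3, 0.2])
    q = np.array([0.6, 0.4])
    joint = _joint_ld_distribution(p, q, 0.8)
    assert joint.sum() == pytest.approx(1.0)
    assert np.allclose(joint.sum(axis=1), p, atol=1e-12)
    assert np.allclose(joint.sum(axis=0), q, atol=1e-12)


def test_cline_mode_group_sizes_follow_frequencies():
    cfg = ic.study_config(seed=21, mode="cline")
    cfg.n_per_population = 200
    records, truth = ic.simulate_dataset(cfg)
    groups = ic.group_counts(records, min_group_size=1)
    # J_ST should dominate in the north, J_1 in the south
    north = {g.key.arrangement: g.size for g in groups
             if g.key.population_id == "SUN" and g.key.chromosome == "J"}
    south = {g.key.arrangement: g.size for g in groups
             if g.key.population_id == "MAL" and g.key.chromosome == "J"}
    assert north.get("J_ST", 0) > north.get("J_1", 0)
    assert south.get("J_1", 0) > south.get("J_ST", 0)


def test_config_yaml_roundtrip(tmp_path):
    cfg = two_arrangement_config(seed=8, ld_pair=ic.LdPairSpec("L00", "L01", "J_1", 0.5))
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = ic.SimConfig.from_yaml(path)
    r1, _ = ic.simulate_dataset(cfg)
    r2, _ = ic.simulate_dataset(back)
    assert [r.alleles for r in r1] == [r.alleles for r in r2]
    assert back.ld_pair == cfg.ld_pair


def test_invalid_config_rejected():
    with pytest.raises(ic.ValidationError):
        two_arrangement_config(seed=0, f_pop=1.0)
    cfg = two_arrangement_config(seed=0)
    with pytest.raises(ic.ValidationError):
        ic.SimConfig(populations=cfg.populations, arrangements=cfg.arrangements,
                     cline_coeffs=cfg.cline_coeffs, loci=cfg.loci,
                     ld_pair=ic.LdPairSpec("nope", "L01", "J_1", 0.5))
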