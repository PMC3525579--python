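import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import invclines as ic
from invclines.linkage import (GameticTable, allele_inversion_dprime, dm_statistic,
                               fdr_adjust, locus_pair_table, marker_inversion_table,
                               mc_exact_test, ohta_components, pairwise_locus_ld)


def dm_bruteforce(counts):
    """Cell-by-cell oracle for Hedrick's multiallelic D'."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    p = counts.sum(1) / n
    q = counts.sum(0) / n
    total = 0.0
    for i in range(len(p)):
        for j in range(len(q)):
            d = counts[i, j] / n - p[i] * q[j]
            if d < 0:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            else:
                dmax = min(p[i] * (1 - q[j]), (1 - p[i]) * q[j])
            dprime = d / dmax if dmax > 0 else 0.0
            total += p[i] * q[j] * abs(dprime)
    return total


def test_dm_endpoints():
    coupling = GameticTable(np.array([[10, 0], [0, 10]]), [1, 2], ["a", "b"])
    assert dm_statistic(coupling) == pytest.approx(1.0)
    indep = GameticTable(np.array([[9, 3], [6, 2]]), [1, 2], ["a", "b"])
    assert dm_statistic(indep) == pytest.approx(0.0, abs=1e-12)


def test_dm_spec_three_allele_table():
    counts = np.array([[20, 0], [5, 15], [0, 10]])
    tab = GameticTable(counts, [100, 102, 104], ["ST", "INV"])
    assert dm_statistic(tab) == pytest.approx(dm_bruteforce(counts), abs=1e-12)


@given(st.integers(0, 10**6))
def test_dm_matches_bruteforce_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 12, size=(5, 3))
    counts[0, 0] += 1
    counts[1, 1] += 1  # both axes have >= 2 nonzero margins
    tab = GameticTable(counts, list(range(5)), list(range(3)))
    dm = dm_statistic(tab)
    assert dm == pytest.approx(dm_bruteforce(counts), abs=1e-12)
    assert 0.0 <= dm <= 1.0 + 1e-12


def test_dm_allele_permutation_invariance():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 10, size=(4, 3))
    tab = GameticTable(counts, list(range(4)), list(range(3)))
    perm = rng.permutation(4)
    tab2 = GameticTable(counts[perm], list(range(4)), list(range(3)))
    assert dm_statistic(tab) == pytest.approx(dm_statistic(tab2), abs=1e-12)


def test_dm_reduces_to_abs_dprime_in_2x2():
    counts = np.array([[12, 4], [3, 9]], float)
    n = counts.sum()
    p, q = counts.sum(1)[0] / n, counts.sum(0)[0] / n
    d = counts[0, 0] / n - p * q
    dmax = min(p * (1 - q), (1 - p) * q) if d > 0 else min(p * q, (1 - p) * (1 - q))
    tab = GameticTable(counts, [1, 2], ["a", "b"])
    assert dm_statistic(tab) == pytest.approx(abs(d / dmax), abs=1e-12)


def test_dm_single_category_errors():
    with pytest.raises(ic.ValidationError):
        dm_statistic(GameticTable(np.array([[5], [3]]), [1, 2], ["only"]))


# ---------------------------------------------------------------------------
# Monte-Carlo exact test


def test_mc_exact_most_extreme_table():
    tab = GameticTable(np.array([[20, 0], [0, 20]]), [1, 2], ["a", "b"])
    assert mc_exact_test(tab, B=999, rng=0) == pytest.approx(1.0 / 1000.0)


def test_mc_exact_same_seed_identical():
    tab = GameticTable(np.array([[8, 3], [2, 7]]), [1, 2], ["a", "b"])
    assert mc_exact_test(tab, B=499, rng=7) == mc_exact_test(tab, B=499, rng=7)


@pytest.mark.parametrize("counts", [
    [[12, 3], [4, 11]],
    [[5, 5], [5, 5]],
    [[14, 2], [8, 9]],
])
def test_mc_exact_matches_fisher_two_sided(counts):
    counts = np.array(counts)
    tab = GameticTable(counts, [1, 2], ["a", "b"])
    p_mc = mc_exact_test(tab, B=100000, rng=5)
    _, p_fisher = stats.fisher_exact(counts)
    assert p_mc == pytest.approx(p_fisher, abs=0.01)


def test_mc_exact_degenerate_margin_is_one():
    tab = GameticTable(np.array([[10, 5], [0, 0]]), [1, 2], ["a", "b"])
    assert mc_exact_test(tab, B=99, rng=0) == 1.0


# ---------------------------------------------------------------------------
# per-allele D' with Yates chi-square


def test_allele_inversion_hand_computation():
    tab = GameticTable(np.array([[30, 0], [0, 30]]), [100, 102], ["ST", "INV"])
    res = allele_inversion_dprime(tab)
    first = res[0]
    assert first.dprime == pytest.approx(1.0)
    assert first.chi2_yates == pytest.approx(60 * (900 - 30) ** 2 / 30**4, abs=1e-9)
    assert first.passes_min_obs


def test_min_obs_rule():
    # significant-looking cell with only 2 joint observations fails the rule
    tab = GameticTable(np.array([[2, 0], [0, 40]]), [100, 102], ["ST", "INV"])
    res = {(r.allele, r.arrangement): r for r in allele_inversion_dprime(tab, min_obs=3)}
    assert not res[(100, "ST")].passes_min_obs
    assert res[(102, "INV")].passes_min_obs


def test_independence_cell_zero():
    tab = GameticTable(np.array([[9, 3], [6, 2]]), [1, 2], ["a", "b"])
    for r in allele_inversion_dprime(tab):
        assert r.dprime == pytest.approx(0.0, abs=1e-12)
        assert r.chi2_yates == pytest.approx(0.0, abs=0.5)  # Yates keeps it near 0


# ---------------------------------------------------------------------------
# FDR


def test_by_stepwise_oracle():
    # manual step-up: c(5) = 1 + 1/2 + ... + 1/5 = 2.2833;
    # thresholds k/5 * 0.05 / c(5) = 0.00438, 0.00876, ... so only
    # p = 0.001 clears its threshold (0.01 > 0.00876).
    p = [0.001, 0.01, 0.02, 0.4, 0.9]
    reject, _ = fdr_adjust(p, method="by", alpha=0.05)
    c5 = sum(1.0 / i for i in range(1, 6))
    thresh = [(k / 5) * 0.05 / c5 for k in range(1, 6)]
    passing = [k for k in range(5) if sorted(p)[k] <= thresh[k]]
    expected = max(passing) + 1 if passing else 0
    assert int(np.sum(reject)) == expected == 1
    assert list(reject) == [True, False, False, False, False]


def test_fdr_all_ones_no_rejections():
    reject, _ = fdr_adjust([1.0] * 6)
    assert not reject.any()


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_rejections_contain_by(p):
    by, _ = fdr_adjust(p, method="by")
    bh, _ = fdr_adjust(p, method="bh")
    assert np.all(bh | ~by)


def test_fdr_empty_and_invalid():
    r, a = fdr_adjust([])
    assert len(r) == 0
    with pytest.raises(ic.ValidationError):
        fdr_adjust([1.5])


# ---------------------------------------------------------------------------
# Ohta decomposition


def _table(counts):
    counts = np.asarray(counts)
    return GameticTable(counts, list(range(counts.shape[0])), list(range(counts.shape[1])))


def test_ohta_hand_example_opposite_coupling():
    # D = +0.25 and -0.25 at p = q = 0.5 in two subpopulations
    c = ohta_components([_table([[5, 0], [0, 5]]), _table([[0, 5], [5, 0]])])
    assert c.dp2_st == pytest.approx(0.0, abs=1e-12)
    assert c.dp2_is == pytest.approx(0.25, abs=1e-12)
    assert c.d2_is == pytest.approx(0.25, abs=1e-12)
    assert c.d2_st == pytest.approx(0.0, abs=1e-12)
    assert c.d2_it == pytest.approx(0.25, abs=1e-12)


def test_ohta_duplicated_subpopulation():
    t = _table([[6, 2], [1, 5]])
    c = ohta_components([t, t])
    assert c.dp2_is == pytest.approx(0.0, abs=1e-12)
    assert c.d2_it == pytest.approx(c.dp2_st, abs=1e-12)


@given(st.integers(0, 10**6))
def test_ohta_decomposition_identity(seed):
    rng = np.random.default_rng(seed)
    tabs = [_table(rng.integers(1, 10, size=(3, 4))) for _ in range(rng.integers(2, 6))]
    c = ohta_components(tabs)
    assert c.d2_it == pytest.approx(c.dp2_is + c.dp2_st, abs=1e-12)
    for v in (c.d2_is, c.d2_st, c.dp2_is, c.dp2_st, c.d2_it):
        assert v >= 0.0


def test_ohta_needs_two_subpopulations():
    with pytest.raises(ic.ValidationError):
        ohta_components([_table([[1, 2], [3, 4]])])


def test_ohta_drift_vs_systematic_signature():
    """Opposite per-population coupling looks like drift (IS >> ST);
    identical coupling across populations looks systematic (ST > 0)."""
    rng = np.random.default_rng(2)
    flip = [_table([[20, 2], [2, 20]]) if k % 2 == 0 else _table([[2, 20], [20, 2]])
            for k in range(6)]
    same = [_table([[20, 2], [2, 20]]) for _ in range(6)]
    c_flip = ohta_components(flip)
    c_same = ohta_components(same)
    assert c_flip.dp2_is > c_flip.dp2_st
    assert c_same.dp2_st > 0.01
    assert c_same.dp2_is < 0.01 * c_same.dp2_st + 1e-6


# ---------------------------------------------------------------------------
# table builders and the locus-pair screen


def test_marker_inversion_table_from_records(study_dataset):
    _, records, _ = study_dataset
    tab = marker_inversion_table(records, "dsub59", populations=["BCN"])
    assert tab.n == sum(1 for r in records
                        if r.population_id == "BCN" and r.chromosome == "J"
                        and r.alleles.get("dsub59") is not None)
    assert set(tab.col_labels) <= {"J_ST", "J_1"}


def test_pairwise_locus_ld_recovers_injected_pair():
    from conftest import two_arrangement_config
    cfg = two_arrangement_config(
        seed=17, n_loci=4, n_inside=0, group_size=40, f_pop=0.0,
        ld_pair=ic.LdPairSpec("L00", "L01", "J_1", 0.8),
    )
    records, _ = ic.simulate_dataset(cfg)
    df = pairwise_locus_ld(records, "J", "J_1", pooled=True, B=499, rng=3)
    df = df[df["p_value"].notna()].set_index(["locus_a", "locus_b"])
    target = df.loc[("L00", "L01")]
    assert target["p_value"] < 0.05
    assert target["p_value"] == df["p_value"].min()


def test_pairwise_locus_ld_skips_monomorphic(study_dataset):
    import copy
    _, records, _ = study_dataset
    recs = [copy.deepcopy(r) for r in records
            if r.chromosome == "J" and r.arrangement == "J_1"]
    # force one locus monomorphic
    for r in recs:
        r.alleles["dsub18"] = 100
    df = pairwise_locus_ld(recs, "J", "J_1", pooled=True, B=99, rng=0)
    mono = df[(df.locus_a == "dsub18") | (df.locus_b == "dsub18")]
    assert (mono["note"] == "monomorphic").all()
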