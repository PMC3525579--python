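import itertools

import numpy as np
import pytest

import invclines as ic
from invclines.core import GroupCounts, GroupKey
from invclines.structure import (PartitionScheme, fst_permutation_test, fst_theta,
                                 pairwise_fst, partition_fst, pcoa)


def _group(pop, counts, chrom="J", arr="J_ST", locus="L"):
    n = sum(counts.values())
    haps = [{locus: a} for a, c in counts.items() for _ in range(c)]
    return GroupCounts(GroupKey(pop, chrom, arr), n, {locus: dict(counts)}, {locus: n}, haps)


def theta_indicator_anova(count_tables):
    """Independent oracle: one-way ANOVA on raw allele-indicator vectors."""
    tot_a = tot_w = 0.0
    for tab in count_tables:
        tab = np.asarray(tab, float)
        n_k = tab.sum(1)
        keep = n_k > 0
        tab, n_k = tab[keep], n_k[keep]
        r, n = len(n_k), n_k.sum()
        if r < 2 or n - r <= 0:
            continue
        for u in range(tab.shape[1]):
            x = []  # raw 0/1 observations per group
            for k in range(r):
                x.append(np.array([1.0] * int(tab[k, u]) + [0.0] * int(n_k[k] - tab[k, u])))
            grand = np.concatenate(x).mean()
            ssa = sum(len(xk) * (xk.mean() - grand) ** 2 for xk in x)
            ssw = sum(((xk - xk.mean()) ** 2).sum() for xk in x)
            msa = ssa / (r - 1)
            msw = ssw / (n - r)
            n_c = (n - (n_k**2).sum() / n) / (r - 1)
            tot_a += (msa - msw) / n_c
            tot_w += msw
    if tot_a + tot_w == 0:
        return np.nan
    return tot_a / (tot_a + tot_w)


def test_theta_matches_indicator_anova_oracle_exhaustively():
    """All 2-group biallelic count tables with group sizes <= 6."""
    for n1, n2 in itertools.product(range(2, 7), repeat=2):
        for c1, c2 in itertools.product(range(n1 + 1), range(n2 + 1)):
            tab = np.array([[c1, n1 - c1], [c2, n2 - c2]], float)
            expected = theta_indicator_anova([tab])
            if np.isnan(expected):
                continue
            g1 = _group("p1", {100: c1, 102: n1 - c1})
            g2 = _group("p2", {100: c2, 102: n2 - c2})
            got = fst_theta([g1, g2]).multi_locus
            assert got == pytest.approx(expected, abs=1e-12), (n1, n2, c1, c2)


def test_theta_fixed_difference_is_one():
    res = fst_theta([_group("p1", {100: 5}), _group("p2", {102: 5})])
    assert res.multi_locus == pytest.approx(1.0)


def test_theta_identical_groups_nonpositive():
    res = fst_theta([_group("p1", {100: 3, 102: 3}), _group("p2", {100: 3, 102: 3})])
    assert res.multi_locus <= 0.0


def test_theta_spec_example_table():
    g1 = _group("p1", {100: 3, 102: 1})
    g2 = _group("p2", {100: 1, 102: 3})
    expected = theta_indicator_anova([np.array([[3, 1], [1, 3]], float)])
    assert fst_theta([g1, g2]).multi_locus == pytest.approx(expected, abs=1e-12)


def test_theta_allele_relabeling_invariance():
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 8, size=(3, 4))
    counts[:, 0] += 1
    groups = [_group(f"p{k}", {100 + 2 * i: int(c) for i, c in enumerate(row) if c})
              for k, row in enumerate(counts)]
    relab = [_group(f"p{k}", {500 - 2 * i: int(c) for i, c in enumerate(row) if c})
             for k, row in enumerate(counts)]
    assert fst_theta(groups).multi_locus == pytest.approx(fst_theta(relab).multi_locus, abs=1e-12)


def test_multilocus_theta_between_per_locus_extremes(study_groups):
    sel = [g for g in study_groups if g.key.chromosome == "U"]
    res = fst_theta(sel)
    per = [v for v in res.per_locus.values() if not np.isnan(v)]
    assert min(per) - 1e-12 <= res.multi_locus <= max(per) + 1e-12


def test_monomorphic_everywhere_warns_nan():
    g1 = _group("p1", {100: 5})
    g2 = _group("p2", {100: 5})
    with pytest.warns(UserWarning, match="monomorphic"):
        res = fst_theta([g1, g2])
    assert np.isnan(res.multi_locus)


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_fixed_difference_minimal_p():
    g1 = _group("p1", {100: 30})
    g2 = _group("p2", {102: 30})
    p, _ = fst_permutation_test([g1, g2], B=199, rng=0)
    assert p == pytest.approx(1.0 / 200.0)


def test_permutation_same_seed_identical(study_groups):
    sel = [g for g in study_groups if g.key.chromosome == "J"][:4]
    p1, _ = fst_permutation_test(sel, B=99, rng=42)
    p2, _ = fst_permutation_test(sel, B=99, rng=42)
    assert p1 == p2


def test_permutation_rejects_structured_data(study_groups):
    sel = [g for g in study_groups if g.key.chromosome == "J"]
    p, res = fst_permutation_test(sel, B=199, rng=1)
    assert res.multi_locus > 0
    assert p < 0.05


# ---------------------------------------------------------------------------
# pairwise and partition


def test_pairwise_symmetric_zero_diagonal_consistent(study_groups):
    sel = [g for g in study_groups if g.key.chromosome == "J"][:4]
    pw = pairwise_fst(sel)
    assert np.allclose(pw.values, pw.values.T)
    assert np.all(np.diag(pw.values) == 0)
    direct = fst_theta([sel[0], sel[2]]).multi_locus
    assert pw.values[0, 2] == pytest.approx(direct, abs=1e-12)


def test_pairwise_identical_groups_near_zero():
    base = {100: 10, 102: 10, 104: 10}
    groups = [_group(f"p{k}", base) for k in range(3)]
    pw = pairwise_fst(groups)
    off = pw.values[np.triu_indices(3, 1)]
    # identical counts give a slightly negative estimate of order -1/(n-1)
    assert np.all(off <= 0) and np.all(np.abs(off) < 0.05)


def test_linearized_matrix():
    m = ic.PairwiseFstMatrix([GroupKey("a", "J", "J_1"), GroupKey("b", "J", "J_1")],
                             np.array([[0.0, 0.2], [0.2, 0.0]]))
    assert m.linearized().values[0, 1] == pytest.approx(0.25)


def test_partition_between_exceeds_within_with_signed_rank(study_groups):
    part = partition_fst(study_groups, scheme=PartitionScheme(chromosome="J"))
    within_mean = np.nanmean([r.multi_locus for r in part.within.values()])
    assert part.between.multi_locus > within_mean
    # inside loci (dsub59, dsub69) carry the arrangement signal
    inside_diff = [part.between.per_locus[l] - part.mean_within_per_locus[l]
                   for l in ("dsub59", "dsub69")]
    assert all(d > 0 for d in inside_diff)
    assert 0 < part.wilcoxon_p <= 1


def test_partition_population_subset(study_groups):
    part = partition_fst(
        study_groups,
        scheme=PartitionScheme(chromosome="J", populations=[
            "MAL", "VAL", "RAS", "BCN", "MON", "DIJ", "GRO"]),
    )
    for res in part.within.values():
        assert res.scope.startswith("within:")


def test_exact_signed_rank_enumeration():
    # 8 loci, between > within at every locus: one-sided exact p = 1/2^8
    from scipy import stats
    diffs = np.array([0.02, 0.015, 0.01, 0.03, 0.025, 0.018, 0.022, 0.012])
    p = stats.wilcoxon(diffs, alternative="greater", method="exact").pvalue
    assert p == pytest.approx(1.0 / 256.0)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_two_groups_closed_form():
    m = np.array([[0.0, 0.1], [0.1, 0.0]])
    res = pcoa(m, labels=["a", "b"])
    assert len(res.percent_variation) == 1
    assert res.percent_variation[0] == pytest.approx(100.0)
    assert sorted(res.coordinates.ravel()) == pytest.approx(
        [-np.sqrt(0.1) / 2, np.sqrt(0.1) / 2])


def test_pcoa_three_equidistant_groups():
    f = 0.3
    m = np.full((3, 3), f)
    np.fill_diagonal(m, 0.0)
    res = pcoa(m)
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
    assert res.percent_variation[:2] == pytest.approx([50.0, 50.0])


def test_pcoa_reproduces_euclidean_distances():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(5, 3))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)  # squared distances
    res = pcoa(d2)
    coords = res.coordinates
    rec = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    assert np.allclose(rec, d2, atol=1e-9)


def test_pcoa_matches_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as skbio_pcoa
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(6, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ours = pcoa(d**2)  # theta treated as squared dissimilarity
    theirs = skbio_pcoa(skbio.DistanceMatrix(d))
    assert np.allclose(np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9]),
                       np.sort(theirs.eigvals[theirs.eigvals > 1e-9]), atol=1e-8)


def test_pcoa_rejects_asymmetric():
    with pytest.raises(ic.ValidationError):
        pcoa(np.array([[0.0, 0.1], [0.2, 0.0]]))
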