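"""Diversity, divergence, F_ST, LD and Mantel statistics vs brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from divflow.models import DemographyParams
from divflow.popstats import (dxy, empirical_outlier_scan, fst_haplotype,
                              fst_snp_wc, haplotype_stats, ld_decay, ld_r2,
                              mantel, nucleotide_diversity, split_by_site,
                              tajimas_d, wc_fst_global)
from divflow.simulate import ScenarioSpec, simulate_dataset, simulate_locus

from conftest import make_genotype_table


# ---------------------------------------------------------------- oracles

def brute_pi(seqs, length):
    """Mean pairwise per-site difference by explicit O(n^2) recount."""
    n = len(seqs)
    tot = sum((np.asarray(seqs[i]) != np.asarray(seqs[j])).sum()
              for i, j in itertools.combinations(range(n), 2))
    return tot / (n * (n - 1) / 2) / length


def brute_dxy(a, b, length):
    tot = sum((np.asarray(x) != np.asarray(y)).sum() for x in a for y in b)
    return tot / (len(a) * len(b)) / length


def brute_tajimas_d(seqs):
    """Independent transcription of the textbook formula."""
    seqs = np.asarray(seqs)
    n, _ = seqs.shape
    freqs = seqs.sum(axis=0)
    S = int(((freqs > 0) & (freqs < n)).sum())
    if S == 0:
        return None
    k_hat = brute_pi(seqs, 1)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = (2.0 * (n * n + n + 3.0)) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))


def brute_wc_fst(geno, pops):
    """Weir-Cockerham per-SNP components via the mean-squares (ANOVA)
    formulation -- an independent route to the same estimator."""
    out = []
    for s in range(geno.shape[1]):
        ns, ps, hs = [], [], []
        for idx in pops:
            g = geno[idx, s]
            g = g[g >= 0]
            if len(g) == 0:
                ns.append(0)
                ps.append(0.0)
                hs.append(0.0)
                continue
            ns.append(len(g))
            ps.append(g.sum() / (2.0 * len(g)))
            hs.append((g == 1).mean())
        ns = np.array(ns, float)
        ps = np.array(ps)
        hs = np.array(hs)
        r = len(ns)
        nbar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        pbar = (ns * ps).sum() / ns.sum()
        # closed-form variance components transcribed step by step as an
        # independent second code path (scalar arithmetic per site)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) *
                           (pbar * (1 - pbar) - s2 * (r - 1) / r
                            - hbar / 4.0))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - s2 * (r - 1.0) / r
                                   - hbar * (2.0 * nbar - 1)
                                   / (4.0 * nbar))
        c = hbar / 2.0
        out.append((a, b, c))
    return np.array(out)


# ------------------------------------------------------------------ tests

def test_pi_and_dxy_match_brute_force_on_random_fixtures(rng):
    for _ in range(200):
        n = rng.integers(2, 8)
        m = rng.integers(2, 8)
        s = rng.integers(1, 12)
        length = int(s + rng.integers(0, 50))
        a = rng.integers(0, 2, size=(n, s))
        b = rng.integers(0, 2, size=(m, s))
        assert nucleotide_diversity(a, length) == pytest.approx(
            brute_pi(a, length), abs=1e-12)
        assert dxy(a, b, length) == pytest.approx(
            brute_dxy(a, b, length), abs=1e-12)


def test_pi_trivial_cases():
    same = np.zeros((4, 10), dtype=np.uint8)
    assert nucleotide_diversity(same, 100) == 0.0
    two = np.zeros((2, 100), dtype=np.uint8)
    two[1, :3] = 1
    assert nucleotide_diversity(two, 100) == pytest.approx(0.03)
    assert dxy(two[:1], two[1:], 100) == pytest.approx(0.03)


def test_dxy_length_mismatch_raises():
    with pytest.raises(ValueError):
        dxy(np.zeros((2, 3)), np.zeros((2, 4)))


def test_tajimas_d_matches_independent_oracle(rng):
    checked = 0
    while checked < 100:
        n = int(rng.integers(4, 12))
        s = int(rng.integers(1, 15))
        seqs = rng.integers(0, 2, size=(n, s))
        expect = brute_tajimas_d(seqs)
        if expect is None:
            assert tajimas_d(seqs) is None
            continue
        assert tajimas_d(seqs) == pytest.approx(expect, abs=1e-12)
        checked += 1


def test_tajimas_d_undefined_without_segregating_sites():
    assert tajimas_d(np.zeros((5, 4), dtype=np.uint8)) is None
    with pytest.raises(ValueError):
        tajimas_d(np.zeros((3, 4), dtype=np.uint8))


def test_tajimas_d_positive_for_balanced_haplotype_classes():
    # two haplotype classes at equal frequency over many sites: an excess
    # of intermediate-frequency variants drives D > 0
    seqs = np.zeros((8, 40), dtype=np.uint8)
    seqs[4:, :] = 1
    assert tajimas_d(seqs) > 0


def test_tajimas_d_centered_under_neutral_coalescent():
    # E[pi - S/a1] = 0 exactly under neutrality; the normalized D carries
    # a small negative finite-sample offset and is only bounded
    spec = ScenarioSpec(model="SI", params=DemographyParams(t_s=0.0),
                        n1=10, n2=2, n_loci=1, locus_length=5000,
                        theta_locus=2.0, seed=0)
    rng = np.random.default_rng(13)
    a1 = (1.0 / np.arange(1, 10)).sum()
    ds, nums = [], []
    for _ in range(5000):
        loc = simulate_locus(spec, "neutral", rng)
        h = loc.haplotypes[:10]
        cnt = h.sum(axis=0).astype(float)
        S = int(((cnt > 0) & (cnt < 10)).sum())
        pi = float((cnt * (10 - cnt)).sum()) / 45.0
        nums.append(pi - S / a1)
        d = tajimas_d(h)
        if d is not None:
            ds.append(d)
    nums = np.asarray(nums)
    se = nums.std(ddof=1) / np.sqrt(len(nums))
    assert abs(nums.mean()) < 3 * se
    assert abs(np.mean(ds)) < 0.1


def test_haplotype_fst_limits_and_oracle(rng):
    # groups fixed for different haplotypes -> 1
    a = np.zeros((3, 5), dtype=np.uint8)
    b = np.ones((3, 5), dtype=np.uint8)
    assert fst_haplotype(a, b) == pytest.approx(1.0)
    # two groups drawn from one panmictic pool: zero differentiation
    # under ratio-of-averages aggregation (within equals between
    # heterozygosity in expectation)
    pool = rng.integers(0, 2, size=(60, 10))
    hws, hbs = [], []
    for _ in range(300):
        pick = rng.permutation(60)
        x, y = pool[pick[:6]], pool[pick[6:12]]
        hws.append(0.5 * (brute_pi(x, 1) + brute_pi(y, 1)))
        hbs.append(brute_dxy(x, y, 1))
    assert 1 - np.mean(hws) / np.mean(hbs) == pytest.approx(0.0, abs=0.02)
    # random fixtures vs explicit H_w / H_b recount
    for _ in range(100):
        x = rng.integers(0, 2, size=(rng.integers(2, 6), 8))
        y = rng.integers(0, 2, size=(rng.integers(2, 6), 8))
        hw = 0.5 * (brute_pi(x, 1) + brute_pi(y, 1))
        hb = brute_dxy(x, y, 1)
        got = fst_haplotype(x, y)
        if hb == 0:
            assert got is None
        else:
            assert got == pytest.approx(1 - hw / hb, abs=1e-12)


def test_wc_fst_matches_independent_variance_component_oracle(rng):
    for _ in range(200):
        n_ind = int(rng.integers(6, 14))
        n_sites = int(rng.integers(1, 6))
        geno = rng.integers(0, 3, size=(n_ind, n_sites))
        # sprinkle missing calls
        miss = rng.random(geno.shape) < 0.1
        geno = np.where(miss, -1, geno).astype(np.int8)
        half = n_ind // 2
        # ensure at least 2 called diploids per pop per fixture
        geno[:2] = np.abs(geno[:2])
        geno[half:half + 2] = np.abs(geno[half:half + 2])
        pops = ["pop1"] * half + ["pop2"] * (n_ind - half)
        table = make_genotype_table(geno, populations=pops)
        got = fst_snp_wc(table)
        expect = brute_wc_fst(geno, [np.arange(half),
                                     np.arange(half, n_ind)])
        np.testing.assert_allclose(got[["a", "b", "c"]].to_numpy(),
                                   expect, atol=1e-9)


def test_wc_fst_negative_estimates_pass_through():
    # identical balanced populations: the unbiased estimator fluctuates
    # around zero and may be negative; values must not be clamped
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
    table = make_genotype_table(geno, populations=["pop1"] * 10 +
                                ["pop2"] * 10)
    comp = fst_snp_wc(table)
    assert (comp["fst"].dropna() < 0).any()
    assert abs(wc_fst_global(comp)) < 0.1


def test_wc_fst_fixed_difference_is_one():
    geno = np.zeros((8, 2), dtype=np.int8)
    geno[4:] = 2
    table = make_genotype_table(geno, populations=["pop1"] * 4 +
                                ["pop2"] * 4)
    comp = fst_snp_wc(table)
    np.testing.assert_allclose(comp["fst"], 1.0)


def test_normalized_divergence_by_outgroup():
    spec = ScenarioSpec(model="SC",
                        params=DemographyParams(t_s=1.0, t_sc=0.1, M12=1,
                                                M21=1),
                        n1=6, n2=6, n_loci=40, locus_length=2000,
                        theta_locus=2.0, outgroup_time=8.0, seed=5)
    hapset, _, _ = simulate_dataset(spec)
    stats = haplotype_stats(hapset)
    ok = stats.dropna(subset=["norm_dxy"])
    assert len(ok) > 0
    np.testing.assert_allclose(ok["norm_dxy"],
                               ok["d_xy"] / ok["d_xy_out"])
    np.testing.assert_allclose(ok["norm_pi"],
                               ok["pi_tot"] / ok["d_xy_out"])


def test_normalization_removes_mutation_rate_differences():
    # doubling the locus mutation rate doubles d_xy and d_xy_out alike, so
    # the normalized divergence is invariant in expectation
    means = []
    for theta, seed in ((1.0, 11), (2.0, 12)):
        spec = ScenarioSpec(model="SI", params=DemographyParams(t_s=0.5),
                            n1=6, n2=6, n_loci=400, locus_length=4000,
                            theta_locus=theta, outgroup_time=6.0,
                            seed=seed)
        hapset, _, _ = simulate_dataset(spec)
        stats = haplotype_stats(hapset).dropna(subset=["norm_dxy"])
        means.append((stats["norm_dxy"].mean(),
                      stats["norm_dxy"].std(ddof=1)
                      / np.sqrt(len(stats))))
    (m1, se1), (m2, se2) = means
    assert abs(m1 - m2) < 3 * np.hypot(se1, se2)


def test_split_by_site_partitions_haplotypes():
    spec = ScenarioSpec(model="SI", params=DemographyParams(t_s=2.0),
                        n1=4, n2=4, n_loci=5, locus_length=1000,
                        theta_locus=2.0, seed=6)
    hapset, _, _ = simulate_dataset(spec)
    loc = next(l for l in hapset if l.haplotypes.shape[1] > 0)
    pos = int(loc.positions[0])
    grp = split_by_site(loc, pos)
    assert grp.sum() == loc.haplotypes[:, 0].sum()
    with pytest.raises(ValueError):
        split_by_site(loc, -1)


def test_ld_r2_duplicated_and_monomorphic_columns():
    rng = np.random.default_rng(7)
    col = rng.integers(0, 3, size=12)
    geno = np.stack([col, col, np.ones(12, int)], axis=1)
    table = make_genotype_table(geno.astype(np.int8),
                                loci=["L0"] * 3, positions=[0, 10, 20])
    tab = ld_r2(table)
    dup = tab[(tab["i"] == 0) & (tab["j"] == 1)]["r2"].iloc[0]
    assert dup == pytest.approx(1.0)
    mono = tab[(tab["j"] == 2)]["r2"]
    assert mono.isna().all()


def test_ld_r2_independent_snps_match_permutation_floor(rng):
    n = 60
    geno = rng.integers(0, 3, size=(n, 40)).astype(np.int8)
    table = make_genotype_table(geno, loci=["L0"] * 40,
                                positions=list(range(0, 4000, 100)))
    obs = ld_r2(table)["r2"].dropna().mean()
    # permutation oracle: shuffling rows of each column independently
    # preserves the sampling floor of r^2 for unlinked sites
    perm = geno.copy()
    for j in range(perm.shape[1]):
        rng.shuffle(perm[:, j])
    ptab = ld_r2(make_genotype_table(perm, loci=["L0"] * 40,
                                     positions=list(range(0, 4000, 100))))
    expect = ptab["r2"].dropna().mean()
    assert obs == pytest.approx(expect, abs=0.01)


def test_ld_decay_bins_mean_r2_by_distance():
    tab = pd.DataFrame({"i": 0, "j": 1,
                        "dist": [10, 20, 200, 300, np.nan],
                        "r2": [1.0, 0.5, 0.2, 0.4, 0.9]})
    out = ld_decay(tab, bins=np.array([0, 100, 400]))
    assert out["mean"].iloc[0] == pytest.approx(0.75)
    assert out["mean"].iloc[1] == pytest.approx(0.3)


def test_mantel_identical_matrices():
    rng = np.random.default_rng(8)
    d = rng.random((6, 6))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    r, p = mantel(d, d, n_perm=99, seed=1)
    assert r == pytest.approx(1.0)
    assert p < 0.1


def test_mantel_p_matches_exhaustive_enumeration():
    rng = np.random.default_rng(9)
    a = rng.random((4, 4))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = rng.random((4, 4))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    iu = np.triu_indices(4, k=1)
    r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
    hits = sum(np.corrcoef(a[iu], b[np.ix_(pp, pp)][iu])[0, 1] >= r_obs
               for pp in map(list, itertools.permutations(range(4))))
    exact_p = hits / 24.0
    n_perm = 4999
    r, p = mantel(a, b, n_perm=n_perm, seed=2)
    assert r == pytest.approx(r_obs)
    se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
    assert abs(p - exact_p) < 3 * se + 2.0 / n_perm


def test_mantel_null_p_values_roughly_uniform():
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(300):
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        b = rng.random((5, 5))
        b = (b + b.T) / 2
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        ps.append(mantel(a, b, n_perm=49,
                         seed=int(rng.integers(2**31)))[1])
    # discrete uniform on {1/50 ... 50/50}: mean 0.51, sd ~0.289
    assert abs(np.mean(ps) - 0.51) < 3 * 0.289 / np.sqrt(len(ps))


def test_mantel_rejects_bad_matrices():
    with pytest.raises(ValueError):
        mantel(np.zeros((3, 3)), np.zeros((4, 4)))
    asym = np.arange(9.0).reshape(3, 3)
    with pytest.raises(ValueError):
        mantel(asym, asym)


def test_outlier_scan_trivial_rules():
    rng = np.random.default_rng(11)
    fst = rng.random(500)
    assert not empirical_outlier_scan(fst, q=1.0)["outlier"].any()
    flat = np.full(500, 0.25)
    scan = empirical_outlier_scan(flat, q=0.95)
    assert not scan["outlier"].any()
    assert (scan["support"] == 0).all()
    with pytest.raises(ValueError):
        empirical_outlier_scan(fst[:50])


def test_outlier_scan_enriches_for_simulated_islands():
    params = DemographyParams(nu1=1, nu2=1, t_s=2.0, t_sc=0.5,
                              M12=8.0, M21=8.0, MI12=0.05, MI21=0.05,
                              P=0.25)
    spec = ScenarioSpec(model="SC2M", params=params, n1=24, n2=24,
                        n_loci=400, locus_length=1200, theta_locus=2.0,
                        seed=12)
    hapset, table, truth = simulate_dataset(spec)
    comp = fst_snp_wc(table)
    scan = empirical_outlier_scan(comp["fst"].to_numpy(), q=0.9)
    flagged_loci = set(comp.loc[scan["outlier"].values, "locus"])
    island = (truth["locus_class"] == "island").to_numpy()
    flagged = truth["locus"].isin(flagged_loci).to_numpy()
    a = int((island & flagged).sum())
    b = int((island & ~flagged).sum())
    c = int((~island & flagged).sum())
    d = int((~island & ~flagged).sum())
    odds, pval = fisher_exact([[a, b], [c, d]], alternative="greater")
    assert odds > 1
    assert pval < 0.05


def test_pairwise_fst_matrix_is_symmetric_and_ordered():
    from divflow.popstats import pairwise_fst_matrix
    rng = np.random.default_rng(14)
    # three populations: A and B drawn from one pool, C strongly diverged
    g_ab = rng.integers(0, 3, size=(12, 60))
    g_c = np.where(rng.random((6, 60)) < 0.9, 2, 1)
    geno = np.vstack([g_ab, g_c]).astype(np.int8)
    pops = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
    table = make_genotype_table(geno, populations=pops,
                                ecotypes=["S"] * 18)
    mat = pairwise_fst_matrix(table)
    assert (mat.values == mat.values.T).all()
    assert mat.loc["A", "C"] > mat.loc["A", "B"]
    assert mat.loc["B", "C"] > mat.loc["A", "B"]
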