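"""HWE exact test, genotypic disequilibrium, G differentiation, Fisher
combination, and Weir–Cockerham theta — each against an independent route."""

import itertools

import numpy as np
import pytest

from termipop.differentiation import (
    _g_stat,
    fisher_combine,
    g_differentiation_test,
    hwe_exact_test,
    ld_test,
    wc_fst,
)
from termipop.simulate import simulate_cluster_frequencies, simulate_simple_family

from conftest import make_table


# -- HWE -------------------------------------------------------------------


def test_hwe_monomorphic_is_one():
    t = make_table({"g": [[(1, 1)]] * 4})
    assert hwe_exact_test(t, "g", "L1") == 1.0


def test_hwe_all_heterozygotes_hand_enumeration():
    """2 alleles, n=5, all hets: three tables with these margins have
    Levene weights 32:160:60; only the observed one is <= its own weight,
    so p = 32/252."""
    t = make_table({"g": [[(1, 2)]] * 5})
    assert hwe_exact_test(t, "g", "L1") == pytest.approx(32 / 252)


def test_hwe_mc_matches_enumeration():
    rng = np.random.default_rng(11)
    gts = [tuple(sorted(rng.integers(1, 4, size=2).tolist())) for _ in range(12)]
    t = make_table({"g": [[g] for g in gts]})
    p_enum = hwe_exact_test(t, "g", "L1", method="enum")
    p_mc = hwe_exact_test(t, "g", "L1", method="mc", n_mc=40_000, seed=5)
    assert p_mc == pytest.approx(p_enum, abs=0.02)


def test_hwe_valid_level_under_random_mating():
    """Under simulated random mating the exact conditional test is valid
    (level <= alpha up to discreteness) and not wildly conservative."""
    rng = np.random.default_rng(99)
    rejections = 0
    pvals = []
    n_rep = 200
    for _ in range(n_rep):
        genes = rng.choice([1, 2, 3], size=40, p=[0.5, 0.3, 0.2])
        rng.shuffle(genes)
        gts = [tuple(sorted(genes[2 * i:2 * i + 2].tolist())) for i in range(20)]
        t = make_table({"g": [[g] for g in gts]})
        p = hwe_exact_test(t, "g", "L1")
        pvals.append(p)
        rejections += p <= 0.05
    assert rejections / n_rep <= 0.08
    assert np.mean(pvals) > 0.45


# -- LD --------------------------------------------------------------------


def test_ld_perfect_disequilibrium():
    rng = np.random.default_rng(1)
    gts = [tuple(sorted(rng.integers(1, 4, 2).tolist())) for _ in range(20)]
    t = make_table({"g": [[g, g] for g in gts]})  # locus B copies locus A
    assert ld_test(t, "g", "L1", "L2", n_perm=10_000, seed=2) <= 0.01


def test_ld_monomorphic_is_one():
    t = make_table({"g": [[(1, 1), (1, 2)], [(1, 1), (2, 2)]]})
    assert ld_test(t, "g", "L1", "L2", n_perm=99, seed=0) == 1.0


def test_ld_zero_permutations_rejected():
    t = make_table({"g": [[(1, 2), (1, 2)]] * 4})
    with pytest.raises(ValueError):
        ld_test(t, "g", "L1", "L2", n_perm=0)


# -- G differentiation -----------------------------------------------------


def test_g_test_identical_multisets():
    rows = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
    t = make_table({"A": rows, "B": list(reversed(rows))})
    res = g_differentiation_test(t, "A", "B", "L1", n_perm=500, seed=1)
    assert res.g == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_g_test_fixed_difference_extreme():
    t = make_table({"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10})
    res = g_differentiation_test(t, "A", "B", "L1", n_perm=10_000, seed=3)
    assert res.p <= 0.001


def test_g_test_symmetric_in_groups(two_group_table):
    r1 = g_differentiation_test(two_group_table, "A", "B", "L1", n_perm=2000, seed=7)
    r2 = g_differentiation_test(two_group_table, "B", "A", "L1", n_perm=2000, seed=7)
    assert r1.g == pytest.approx(r2.g)
    assert abs(r1.p - r2.p) < 0.03


def test_g_test_skips_empty_group():
    t = make_table({"A": [[None]] * 3, "B": [[(1, 2)]] * 3})
    res = g_differentiation_test(t, "A", "B", "L1", n_perm=99, seed=0)
    assert res.skipped


def test_g_test_permutation_matches_enumeration():
    """Permutation p equals complete enumeration over all C(n, nA) splits."""
    rng = np.random.default_rng(8)
    gts = [tuple(sorted(rng.integers(1, 3, 2).tolist())) for _ in range(12)]
    t = make_table({"A": [[g] for g in gts[:6]], "B": [[g] for g in gts[6:]]})
    res = g_differentiation_test(t, "A", "B", "L1", n_perm=100_000, seed=4)

    classes = sorted(set(gts))
    ids = np.array([classes.index(g) for g in gts])
    tot = np.bincount(ids, minlength=len(classes))
    hits = total = 0
    for subset in itertools.combinations(range(12), 6):
        ca = np.bincount(ids[list(subset)], minlength=len(classes))
        g = _g_stat(np.vstack([ca, tot - ca]))
        total += 1
        hits += g >= res.g - 1e-9
    assert res.p == pytest.approx(hits / total, abs=0.01)


def test_g_test_null_level():
    """Under panmixia the permutation test rejects at ~nominal rate."""
    freqs = simulate_cluster_frequencies(1, [4], divergence=0.0, seed=5)[0]
    rej = 0
    n_rep = 150
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        codes, p = freqs[0]
        def draw():
            a, b = rng.choice(codes, size=2, p=p)
            return (int(a), int(b)) if a <= b else (int(b), int(a))
        t = make_table({"A": [[draw()] for _ in range(15)],
                        "B": [[draw()] for _ in range(15)]})
        res = g_differentiation_test(t, "A", "B", "L1", n_perm=399, seed=rep)
        rej += res.p <= 0.05
    assert 0.01 <= rej / n_rep <= 0.10


# -- Fisher ----------------------------------------------------------------


def test_fisher_combine_identities():
    chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    _, _, p_single = fisher_combine([0.2])
    assert p_single == pytest.approx(0.2, rel=1e-9)


def test_fisher_combine_two_p05():
    chi2, df, p = fisher_combine([0.05, 0.05])
    assert chi2 == pytest.approx(11.98, abs=0.01)
    assert df == 4
    assert p == pytest.approx(0.0175, abs=0.0005)


def test_fisher_combine_errors_and_clamp():
    with pytest.raises(ValueError):
        fisher_combine([])
    with pytest.raises(ValueError):
        fisher_combine([0.0])
    chi2, df, p = fisher_combine([0.0, 0.5], n_perm=999)
    assert np.isfinite(chi2) and 0 < p < 1


# -- Weir & Cockerham ------------------------------------------------------


def _wc_theta_anova(table, groups):
    """Independent route: W&C theta via the mean-squares (ANOVA) arrangement."""
    num = den = 0.0
    for locus in table.loci:
        gts = {g: table.genotypes_at(locus, table.members(g)) for g in groups}
        sizes = np.array([len(gts[g]) for g in groups], dtype=float)
        if np.any(sizes == 0):
            continue
        alleles = sorted({a for g in groups for gt in gts[g] for a in gt})
        if len(alleles) < 2:
            continue
        r = len(groups)
        nsum = sizes.sum()
        nc = (nsum - np.sum(sizes**2) / nsum) / (r - 1)
        for al in alleles:
            p_i = np.array([
                np.mean([(x == al) + (y == al) for x, y in gts[g]]) / 2
                for g in groups
            ])
            h_i = np.array([
                np.mean([(x == al) != (y == al) for x, y in gts[g]])
                for g in groups
            ])
            pbar = np.sum(sizes * p_i) / nsum
            msg = np.sum(sizes * h_i) / (2.0 * nsum)
            msp = np.sum(2.0 * sizes * (p_i - pbar) ** 2) / (r - 1)
            # SSI = sum_ij 2 (ybar_ij - p_i)^2 = sum_i 2 n_i [p_i(1-p_i) - h_i/4]
            ssi = np.sum(2.0 * sizes * (p_i * (1 - p_i) - h_i / 4.0))
            msi = ssi / (nsum - r)
            a = (msp - msi) / (2 * nc)
            b = (msi - msg) / 2.0
            c = msg
            num += a
            den += a + b + c
    return num / den


def test_theta_maximal_differentiation():
    t = make_table({"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10})
    assert wc_fst(t).theta == pytest.approx(1.0)


def test_theta_near_zero_for_identical_populations():
    freqs = simulate_cluster_frequencies(1, [6, 6, 6, 6], divergence=0.0, seed=9)[0]
    rng = np.random.default_rng(10)
    codes_probs = freqs

    def draw_row():
        row = []
        for codes, p in codes_probs:
            a, b = rng.choice(codes, size=2, p=p)
            row.append((int(a), int(b)) if a <= b else (int(b), int(a)))
        return row

    t = make_table({"A": [draw_row() for _ in range(100)],
                    "B": [draw_row() for _ in range(100)]})
    assert abs(wc_fst(t).theta) < 0.02


def test_theta_matches_anova_route(rng):
    """Variance-component and mean-squares arrangements agree to 1e-10."""
    for rep in range(5):
        freqs = simulate_cluster_frequencies(
            2, [4, 5, 3], divergence=0.3, seed=rep
        )
        t = make_table({
            "A": [[_rand_gt(rng, loc) for loc in freqs[0]] for _ in range(12)],
            "B": [[_rand_gt(rng, loc) for loc in freqs[1]] for _ in range(9)],
        })
        res = wc_fst(t)
        if np.isnan(res.theta):
            continue
        assert res.theta == pytest.approx(_wc_theta_anova(t, ["A", "B"]), abs=1e-10)


def _rand_gt(rng, locus):
    codes, p = locus
    a, b = rng.choice(codes, size=2, p=p)
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def test_theta_undefined_when_monomorphic():
    t = make_table({"A": [[(1, 1)]] * 3, "B": [[(1, 1)]] * 3})
    assert np.isnan(wc_fst(t).theta)
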