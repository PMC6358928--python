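"""Colony simulator: frequency model, pedigrees, bottleneck test-bed,
haplotype trees, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from termipop.diversity import observed_heterozygosity
from termipop.differentiation import wc_fst
from termipop.network import pairwise_steps
from termipop.simulate import (
    ColonySpec,
    _offspring,
    simulate_bottleneck_population,
    simulate_cluster_frequencies,
    simulate_extended_family,
    simulate_haplotypes,
    simulate_mixed_family,
    simulate_simple_family,
    simulate_site,
    workers_to_table,
)

from conftest import make_table


def test_zero_divergence_gives_identical_clusters():
    f = simulate_cluster_frequencies(3, [5, 4], divergence=0.0, seed=1)
    for locus in range(2):
        assert np.allclose(f[0][locus][1], f[1][locus][1])
        assert np.allclose(f[0][locus][1], f[2][locus][1])


def test_large_alpha_near_uniform():
    f = simulate_cluster_frequencies(1, [10], divergence=0.0,
                                     dirichlet_alpha=1e6, seed=2)
    assert np.allclose(f[0][0][1], 0.1, atol=0.01)


def test_divergence_calibrates_realized_fst():
    """Requested divergence ~0.2 yields realized pairwise theta near 0.2."""
    rng = np.random.default_rng(3)
    thetas = []
    for rep in range(15):
        f = simulate_cluster_frequencies(2, [8] * 6, divergence=0.2, seed=rep)

        def draw_row(cluster):
            row = []
            for codes, p in cluster:
                a, b = rng.choice(codes, size=2, p=p)
                row.append((int(a), int(b)) if a <= b else (int(b), int(a)))
            return row

        t = make_table({
            "A": [draw_row(f[0]) for _ in range(40)],
            "B": [draw_row(f[1]) for _ in range(40)],
        })
        thetas.append(wc_fst(t).theta)
    assert np.mean(thetas) == pytest.approx(0.2, abs=0.05)


def test_simple_family_homozygous_parents():
    freqs = [(np.array([4]), np.array([1.0]))]
    w, truth = simulate_simple_family(freqs, 10, seed=4)
    assert all(row[0] == (4, 4) for row in w)
    assert truth.family_type == "simple"


def test_mendelian_quarter_ratios():
    rng = np.random.default_rng(5)
    mother, father = [(1, 2)], [(3, 4)]
    kids = [_offspring(rng, mother, father)[0] for _ in range(4000)]
    counts = {g: kids.count(g) for g in {(1, 3), (1, 4), (2, 3), (2, 4)}}
    assert set(kids) <= {(1, 3), (1, 4), (2, 3), (2, 4)}
    chi2 = sum((c - 1000) ** 2 / 1000 for c in counts.values())
    assert stats.chi2.sf(chi2, 3) > 0.001


def test_extended_zero_generations_reduces_to_simple():
    freqs = simulate_cluster_frequencies(1, [6] * 4, divergence=0.0, seed=6)[0]
    w, truth = simulate_extended_family(freqs, 0, 10, 15, seed=7)
    assert truth.family_type == "simple"
    assert truth.n_generations == 0
    # every worker is a Mendelian offspring of the founder pair
    mo, fa = truth.founders
    for row in w:
        for li, g in enumerate(row):
            kids = set()
            for x in mo[li]:
                for y in fa[li]:
                    kids.add((x, y) if x <= y else (y, x))
            assert g in kids


def test_inbreeding_raises_homozygosity():
    freqs = simulate_cluster_frequencies(1, [8] * 6, divergence=0.0,
                                         dirichlet_alpha=2.0, seed=8)[0]
    ho_out, ho_in = [], []
    for rep in range(60):
        w0, _ = simulate_extended_family(freqs, 0, 10, 20, seed=1000 + rep)
        w3, _ = simulate_extended_family(freqs, 3, 10, 20, seed=2000 + rep)
        ho_out.append(observed_heterozygosity(workers_to_table(w0)).mean().iloc[0])
        ho_in.append(observed_heterozygosity(workers_to_table(w3)).mean().iloc[0])
    assert np.mean(ho_in) < np.mean(ho_out) - 0.03


def test_extended_validation():
    freqs = simulate_cluster_frequencies(1, [4], divergence=0.0, seed=9)[0]
    with pytest.raises(ValueError):
        simulate_extended_family(freqs, 2, 1, 5, seed=0)


def test_mixed_zero_fraction_is_single_family():
    freqs = simulate_cluster_frequencies(1, [6] * 3, divergence=0.0, seed=10)[0]
    w, truth = simulate_mixed_family(freqs, 12, mixing_fraction=0.0, seed=11)
    assert truth.family_type == "simple"


def test_mixed_disjoint_parents_force_five_alleles():
    """Fusing families whose parents carry disjoint alleles at a 6-allele
    locus exposes > 4 alleles among workers."""
    from termipop.families import classify_family

    rng = np.random.default_rng(12)
    fam_a = [[(1, 2)], [(2, 3)]]
    fam_b = [[(4, 5)], [(5, 6)]]
    workers = [_offspring(rng, *fam_a) for _ in range(10)]
    workers += [_offspring(rng, *fam_b) for _ in range(10)]
    rep = classify_family(workers_to_table(workers))
    assert rep.call == "mixed"


def test_bottleneck_population_shapes_and_validation():
    tab = simulate_bottleneck_population(
        50, 50, 0, n_loci=4, mutation_rate=0.01, model="SMM",
        n_sample=10, seed=13,
    )
    assert tab.n_individuals == 10 and tab.n_loci == 4
    assert all(
        g is None or (g[0] > 0 and g[1] > 0)
        for row in tab.genotypes for g in row
    )
    with pytest.raises(ValueError):
        simulate_bottleneck_population(50, 60, 0, 2, 0.01, n_sample=5, seed=0)
    with pytest.raises(ValueError):
        simulate_bottleneck_population(50, 10, 0, 2, 0.01, n_sample=20, seed=0)


def test_haplotypes_zero_steps_identical():
    aln = simulate_haplotypes(50, [("r", "a", 0), ("r", "b", 0)], seed=14,
                              root_label="r")
    assert aln.sequences[0] == aln.sequences[1] == aln.sequences[2]


def test_haplotypes_star_distances():
    aln = simulate_haplotypes(
        100, [("r", "a", 1), ("r", "b", 2), ("r", "c", 7)], seed=15,
        root_label="r",
    )
    d = pairwise_steps(aln)
    ri = aln.labels.index("r")
    assert d[ri, aln.labels.index("a")] == 1
    assert d[ri, aln.labels.index("b")] == 2
    assert d[ri, aln.labels.index("c")] == 7
    # path additivity through the root
    assert d[aln.labels.index("a"), aln.labels.index("c")] == 8


def test_haplotypes_too_many_steps_rejected():
    with pytest.raises(ValueError):
        simulate_haplotypes(10, [("r", "a", 11)], seed=0)


def test_site_emission_reproducible():
    freqs = simulate_cluster_frequencies(1, [5] * 4, divergence=0.0, seed=16)[0]
    specs = [ColonySpec("simple", n_points=2, workers_per_point=5)]
    t1, s1, _ = simulate_site(freqs, specs, seed=17)
    t2, s2, _ = simulate_site(freqs, specs, seed=17)
    assert t1.genotypes == t2.genotypes
    assert np.array_equal(s1.x, s2.x)
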