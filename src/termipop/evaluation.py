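"""Parameter-recovery and calibration benchmarks.

Each function simulates data under known conditions with the package's own
generator, runs the corresponding analysis, and returns the measured
recovery rate / error rate.  They define the package's reference study
conditions in one place:

* worker sampling: 20 workers per sampling point;
* the allele-rich microsatellite regime (8 loci, 5-32 alleles per locus,
  moderately even frequencies) for family-type recovery;
* 6 polymorphic loci for colony delineation;
* extended families bred for 3 generations of 10 neotenics;
* mixed families as a 50:50 fusion of two unrelated pairs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from termipop.bottleneck import HeqLibrary, heterozygosity_excess_battery
from termipop.delineation import delineate_colonies
from termipop.differentiation import g_differentiation_test, ld_test
from termipop.datatypes import GenotypeTable
from termipop.families import classify_family
from termipop.simulate import (
    ALLELE_RICH_LOCUS_COUNTS,
    ColonySpec,
    simulate_bottleneck_population,
    simulate_cluster_frequencies,
    simulate_extended_family,
    simulate_mixed_family,
    simulate_simple_family,
    simulate_site,
    workers_to_table,
)


def _seeds(seed: Optional[int], n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def rand_index(a: Sequence, b: Sequence) -> float:
    """Plain Rand index between two partitions given as label sequences."""
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError("partitions must label the same items")
    agree = total = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            total += 1
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total if total else 1.0


def classifier_recovery(
    n_rep: int = 200,
    n_workers: int = 20,
    seed: Optional[int] = None,
) -> dict[str, float]:
    """Fraction of simulated colonies called with their true family type."""
    seeds = _seeds(seed, 2 * n_rep * 3)
    it = iter(seeds)
    out: dict[str, float] = {}
    for family in ("simple", "extended", "mixed"):
        hits = 0
        for _ in range(n_rep):
            freqs = simulate_cluster_frequencies(
                1, ALLELE_RICH_LOCUS_COUNTS, divergence=0.0,
                dirichlet_alpha=2.0, seed=next(it),
            )[0]
            rng = np.random.default_rng(next(it))
            if family == "simple":
                w, _ = simulate_simple_family(freqs, n_workers, rng=rng)
            elif family == "extended":
                w, _ = simulate_extended_family(freqs, 3, 10, n_workers, rng=rng)
            else:
                w, _ = simulate_mixed_family(freqs, n_workers, rng=rng)
            hits += classify_family(workers_to_table(w)).call == family
        out[family] = hits / n_rep
    return out


def mendelian_type1_error(
    n_rep: int = 200,
    n_workers: int = 20,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Rejection rate of the Mendelian G-test on true simple families."""
    seeds = _seeds(seed, 2 * n_rep)
    rej = used = 0
    for r in range(n_rep):
        freqs = simulate_cluster_frequencies(
            1, (10,) * 8, divergence=0.0, dirichlet_alpha=2.0, seed=seeds[2 * r]
        )[0]
        w, _ = simulate_simple_family(freqs, n_workers, seed=seeds[2 * r + 1])
        rep = classify_family(workers_to_table(w), alpha=alpha)
        if rep.mendelian_p is not None:
            used += 1
            rej += rep.mendelian_p < alpha
    return rej / used


def _panmictic_rows(rng, freqs, n):
    rows = []
    for _ in range(n):
        row = []
        for codes, p in freqs:
            a, b = rng.choice(codes, size=2, p=p)
            row.append((int(a), int(b)) if a <= b else (int(b), int(a)))
        rows.append(row)
    return rows


def _two_group_table(rows_a, rows_b, loci=None):
    n_loci = len(rows_a[0])
    loci = loci or [f"L{k + 1}" for k in range(n_loci)]
    inds = [f"a{i}" for i in range(len(rows_a))] + [f"b{i}" for i in range(len(rows_b))]
    return GenotypeTable(
        loci, inds, ["A", "B"], rows_a + rows_b,
        {i: ("A" if i.startswith("a") else "B") for i in inds},
    )


def differentiation_type1_error(
    n_rep: int = 200,
    n_per_group: int = 15,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Rejection rate of the genotypic G test for two panmictic samples."""
    seeds = _seeds(seed, 2 * n_rep)
    freqs = simulate_cluster_frequencies(1, [6], divergence=0.0,
                                         dirichlet_alpha=2.0, seed=seed)[0]
    rej = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seeds[2 * r])
        t = _two_group_table(
            _panmictic_rows(rng, freqs, n_per_group),
            _panmictic_rows(rng, freqs, n_per_group),
        )
        res = g_differentiation_test(t, "A", "B", "L1", n_perm=n_perm,
                                     seed=seeds[2 * r + 1])
        rej += res.p <= alpha
    return rej / n_rep


def ld_type1_error(
    n_rep: int = 200,
    n_ind: int = 30,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Rejection rate of the disequilibrium test for independent loci."""
    seeds = _seeds(seed, 2 * n_rep)
    freqs = simulate_cluster_frequencies(1, [5, 5], divergence=0.0,
                                         dirichlet_alpha=2.0, seed=seed)[0]
    rej = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seeds[2 * r])
        rows = _panmictic_rows(rng, freqs, n_ind)
        inds = [f"i{k}" for k in range(n_ind)]
        t = GenotypeTable(["L1", "L2"], inds, ["g"], rows,
                          {i: "g" for i in inds})
        p = ld_test(t, "g", "L1", "L2", n_perm=n_perm, seed=seeds[2 * r + 1])
        rej += p <= alpha
    return rej / n_rep


def wilcoxon_excess_type1_error(
    n_rep: int = 200,
    n_sample: int = 25,
    n_loci: int = 8,
    n_iter: int = 2000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Two-tailed Wilcoxon rejection rate on constant-size SMM populations."""
    seeds = _seeds(seed, n_rep + 1)
    lib = HeqLibrary(n_iter=n_iter, seed=seeds[-1])
    rej = 0
    for r in range(n_rep):
        tab = simulate_bottleneck_population(
            100, 100, 0, n_loci=n_loci, mutation_rate=0.005, model="SMM",
            n_sample=n_sample, seed=seeds[r],
        )
        rep = heterozygosity_excess_battery(
            tab, "pop", models=["SMM"], seed=seeds[r], heq_library=lib
        )
        rej += rep.batteries["SMM"].wilcoxon_two_tailed_p < alpha
    return rej / n_rep


def delineation_recovery(
    n_sites: int = 100,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Mean Rand index between inferred and true colony partitions over
    simulated three-colony sites (3 points per colony, 20 workers each,
    6 polymorphic loci)."""
    seeds = _seeds(seed, 3 * n_sites)
    rands = []
    for r in range(n_sites):
        freqs = simulate_cluster_frequencies(
            1, (6,) * 6, divergence=0.0, dirichlet_alpha=2.0, seed=seeds[3 * r]
        )[0]
        specs = [ColonySpec("simple", n_points=3) for _ in range(3)]
        table, _, truth = simulate_site(freqs, specs, seed=seeds[3 * r + 1])
        part = delineate_colonies(table, n_perm=n_perm, seed=seeds[3 * r + 2])
        true = [truth.colony_of_point[g] for g in table.groups]
        rands.append(rand_index(true, part.labels(table.groups)))
    return float(np.mean(rands))


def single_colony_merge_rate(
    n_rep: int = 40,
    n_points: int = 15,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Fraction of single extended-family colonies sampled at many points
    that the delineation merges back into one colony."""
    seeds = _seeds(seed, 3 * n_rep)
    merged = 0
    for r in range(n_rep):
        freqs = simulate_cluster_frequencies(
            1, (6,) * 6, divergence=0.0, dirichlet_alpha=2.0, seed=seeds[3 * r]
        )[0]
        table, _, _ = simulate_site(
            freqs, [ColonySpec("extended", n_points=n_points)],
            seed=seeds[3 * r + 1],
        )
        part = delineate_colonies(table, n_perm=n_perm, seed=seeds[3 * r + 2])
        merged += len(part.colonies) == 1
    return merged / n_rep


def bottleneck_power(
    n_rep: int = 100,
    n_iter: int = 2000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Detection rate (one-tailed IAM Wilcoxon excess) after a 99% crash
    10 generations before sampling (8 loci, 30 diploids sampled)."""
    seeds = _seeds(seed, n_rep + 1)
    lib = HeqLibrary(n_iter=n_iter, seed=seeds[-1])
    hits = 0
    for r in range(n_rep):
        tab = simulate_bottleneck_population(
            3000, 30, 10, n_loci=8, mutation_rate=0.0005, model="IAM",
            n_sample=30, seed=seeds[r],
        )
        rep = heterozygosity_excess_battery(
            tab, "pop", models=["IAM"], seed=seeds[r], heq_library=lib
        )
        hits += rep.batteries["IAM"].wilcoxon_one_tailed_p < alpha
    return hits / n_rep
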