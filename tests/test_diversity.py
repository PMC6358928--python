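"""Diversity statistics: closed-form values, printed-table aggregates,
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from termipop.datatypes import HaplotypeAlignment
from termipop.diversity import (
    allele_counts,
    allelic_richness,
    gene_diversity,
    haplotype_diversity,
    nucleotide_diversity,
    summarize_diversity,
)
from termipop.simulate import ColonySpec, simulate_cluster_frequencies, simulate_site

from conftest import make_table


# published per-locus columns of the regional 8-locus panel (five genetic
# clusters + pooled), used as input data for the summary machinery
NA_COLUMNS = {
    "S1": [4, 8, 5, 7, 3, 3, 3, 6],
    "S2": [6, 7, 5, 6, 2, 3, 4, 2],
    "S3": [4, 4, 2, 2, 1, 1, 3, 1],
    "S4": [6, 11, 15, 24, 4, 4, 19, 10],
    "S5": [7, 11, 10, 18, 4, 5, 7, 4],
    "All": [10, 20, 19, 32, 5, 5, 21, 10],
}
HS_COLUMNS = {
    "S1": [0.727, 0.867, 0.564, 0.782, 0.331, 0.612, 0.423, 0.669],
    "S2": [0.587, 0.711, 0.767, 0.648, 0.506, 0.542, 0.654, 0.307],
    "S3": [0.612, 0.671, 0.028, 0.44, 0.0, 0.0, 0.307, 0.0],
    "S4": [0.591, 0.852, 0.884, 0.944, 0.115, 0.525, 0.914, 0.835],
    "S5": [0.837, 0.895, 0.828, 0.951, 0.413, 0.716, 0.704, 0.503],
}


def test_allele_count_monomorphic():
    t = make_table({"g": [[(1, 1)], [(1, 1)]]})
    assert allele_counts(t).loc["L1", "g"] == 1


def test_allele_count_all_missing_is_absent():
    t = make_table({"g": [[None, (1, 2)], [None, (1, 1)]]})
    na = allele_counts(t)
    assert np.isnan(na.loc["L1", "g"])
    assert na.loc["L2", "g"] == 2


def test_allele_counts_match_enumeration(rng):
    freqs = simulate_cluster_frequencies(1, [5, 9, 3], divergence=0.0, seed=3)[0]
    table, _, _ = simulate_site(freqs, [ColonySpec("simple", n_points=2)], seed=4)
    na = allele_counts(table)
    for g in table.groups:
        for locus in table.loci:
            seen = set()
            for i in table.members(g):
                gt = table.genotypes[i][table.locus_index(locus)]
                if gt:
                    seen.update(gt)
            assert na.loc[locus, g] == len(seen)


def test_low_diversity_cluster_summary_row():
    """The depauperate cluster's printed allele counts average 2.25 +- 1.28."""
    frame = pd.DataFrame({"S3": NA_COLUMNS["S3"]}, dtype=float)
    summ = summarize_diversity(frame)
    assert summ.mean["S3"] == pytest.approx(2.25, abs=0.005)
    assert summ.sd["S3"] == pytest.approx(1.28, abs=0.005)


def test_richness_equals_na_at_full_size():
    t = make_table({"g": [[(1, 2)], [(1, 3)], [(2, 3)]]})
    rs = allelic_richness(t, g=6)
    assert rs.loc["L1", "g"] == pytest.approx(3.0)


def test_richness_fixed_locus_is_one():
    t = make_table({"g": [[(2, 2)], [(2, 2)], [(2, 2)]]})
    assert allelic_richness(t, g=2).loc["L1", "g"] == pytest.approx(1.0)


def test_richness_hand_expanded_hypergeometric():
    """N=10 genes, counts {6,4}, g=2: Rs = 2 - [C(4,2)+C(6,2)]/C(10,2)."""
    rows = [[(1, 1)]] * 3 + [[(2, 2)]] * 2  # 6 copies of 1, 4 of 2
    t = make_table({"g": rows})
    rs = allelic_richness(t, g=2)
    assert rs.loc["L1", "g"] == pytest.approx(2 - 21 / 45)


def test_richness_monotone_in_g():
    rows = [[(1, 2)], [(1, 3)], [(2, 4)], [(1, 1)], [(3, 4)]]
    t = make_table({"g": rows})
    values = [allelic_richness(t, g=g).loc["L1", "g"] for g in range(2, 11)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(4.0)


def test_richness_g_below_two_rejected():
    t = make_table({"g": [[(1, 2)]]})
    with pytest.raises(ValueError):
        allelic_richness(t, g=1)


def test_gene_diversity_closed_form():
    # p = (0.5, 0.5), n = 10 genes -> (10/9) * 0.5
    rows = [[(1, 2)]] * 5
    t = make_table({"g": rows})
    assert gene_diversity(t).loc["L1", "g"] == pytest.approx((10 / 9) * 0.5)


def test_gene_diversity_fixed_and_relabeled():
    t = make_table({"g": [[(3, 3)], [(3, 3)]]})
    assert gene_diversity(t).loc["L1", "g"] == 0.0
    a = make_table({"g": [[(1, 2)], [(2, 2)], [(1, 1)]]})
    b = make_table({"g": [[(7, 9)], [(9, 9)], [(7, 7)]]})
    assert gene_diversity(a).loc["L1", "g"] == pytest.approx(
        gene_diversity(b).loc["L1", "g"]
    )


def test_summary_reproduces_printed_means_and_kruskal():
    frame = pd.DataFrame(NA_COLUMNS, dtype=float)
    summ = summarize_diversity(frame[["S1", "S2", "S3", "S4", "S5"]])
    printed = {"S1": 4.88, "S2": 4.38, "S3": 2.25, "S4": 11.63, "S5": 8.25}
    for g, v in printed.items():
        assert summ.mean[g] == pytest.approx(v, abs=0.006)
    assert summ.kruskal_df == 4
    assert summ.kruskal_h == pytest.approx(19.5, abs=0.05)
    assert summarize_diversity(frame[["All"]]).mean["All"] == pytest.approx(15.25)
    hs = summarize_diversity(pd.DataFrame(HS_COLUMNS))
    assert hs.kruskal_h == pytest.approx(12.9, abs=0.05)
    assert hs.mean["S3"] == pytest.approx(0.257, abs=0.0006)


def test_summary_single_locus_sd_zero():
    summ = summarize_diversity(pd.DataFrame({"g": [3.0]}))
    assert summ.sd["g"] == 0.0


def test_haplotype_diversity():
    aln = HaplotypeAlignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"],
                             {"a": 5, "b": 3, "c": 2})
    assert haplotype_diversity(aln) == pytest.approx((10 / 9) * (1 - 0.38))
    mono = HaplotypeAlignment(["a"], ["AAAA"], {"a": 7})
    assert haplotype_diversity(mono) == 0.0
    uniq = HaplotypeAlignment(["a", "b"], ["AAAA", "AATT"], {"a": 1, "b": 1})
    assert haplotype_diversity(uniq) == pytest.approx(1.0)


def test_nucleotide_diversity_limit():
    # two equifrequent haplotypes differing at 1 site of 100, large n -> 0.005
    seq1 = "A" * 100
    seq2 = "T" + "A" * 99
    aln = HaplotypeAlignment(["a", "b"], [seq1, seq2], {"a": 5000, "b": 5000})
    assert nucleotide_diversity(aln) == pytest.approx(0.005, rel=1e-3)
    same = HaplotypeAlignment(["a", "b"], [seq1, seq1], {"a": 3, "b": 2})
    assert nucleotide_diversity(same) == 0.0


def test_nucleotide_diversity_matches_all_pairs_average(rng):
    """Frequency-weighted formula equals the O(n^2) per-individual average."""
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=40)
    seqs, counts = [], {}
    for i in range(5):
        s = root.copy()
        nmut = int(rng.integers(0, 6))
        sites = rng.choice(40, size=nmut, replace=False)
        for pos in sites:
            s[pos] = rng.choice(bases[bases != s[pos]])
        seqs.append("".join(s))
        counts[f"h{i}"] = int(rng.integers(1, 5))
    aln = HaplotypeAlignment([f"h{i}" for i in range(5)], seqs, counts)
    # brute force over expanded individuals
    pool = [s for lab, s in zip(aln.labels, aln.sequences)
            for _ in range(counts[lab])]
    n = len(pool)
    acc = sum(
        sum(c1 != c2 for c1, c2 in zip(pool[i], pool[j]))
        for i in range(n) for j in range(i + 1, n)
    )
    oracle = (2.0 * acc / (n * n)) * (n / (n - 1)) / 40
    assert nucleotide_diversity(aln) == pytest.approx(oracle, rel=1e-12)
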