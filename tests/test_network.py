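"""Mutational-step distances, parsimony connection limit, and the
minimum-spanning network."""

import networkx as nx
import numpy as np
import pytest

from termipop.datatypes import HaplotypeAlignment
from termipop.network import (
    build_msn,
    build_network,
    pairwise_steps,
    parsimony_limit,
    parsimony_probability,
)
from termipop.simulate import simulate_haplotypes


def test_pairwise_steps_basics():
    aln = HaplotypeAlignment(["a", "b", "c"],
                             ["ACGTACG", "ACGTACG", "TCGTACA"])
    d = pairwise_steps(aln)
    assert d[0, 1] == 0
    assert d[0, 2] == 2
    assert np.array_equal(d, d.T)


def test_pairwise_steps_excludes_gaps_and_n():
    aln = HaplotypeAlignment(["a", "b"], ["ACG-AN", "TCGTAC"])
    # compared columns: 0,1,2,4 -> one difference at column 0
    assert pairwise_steps(aln)[0, 1] == 1


def test_pairwise_steps_matches_brute_force(rng):
    aln = simulate_haplotypes(
        120, [("r", "a", 3), ("r", "b", 7), ("b", "c", 2)], seed=5, root_label="r"
    )
    d = pairwise_steps(aln)
    for i in range(len(aln.labels)):
        for j in range(len(aln.labels)):
            brute = sum(
                1
                for x, y in zip(aln.sequences[i], aln.sequences[j])
                if x != y and x in "ACGT" and y in "ACGT"
            )
            assert d[i, j] == brute


def test_parsimony_probability_monotone_decreasing():
    probs = [parsimony_probability(j, 658) for j in range(0, 30)]
    assert probs[0] == 1.0
    assert all(b <= a + 1e-12 for a, b in zip(probs, probs[1:]))


def test_parsimony_limit_nested_confidence():
    limits = [parsimony_limit(658, c) for c in (1e-12, 0.5, 0.90, 0.95, 0.999)]
    assert all(a >= b for a, b in zip(limits, limits[1:]))
    assert limits[0] > limits[2] > 0


def test_parsimony_limit_independent_evaluation():
    """Second-route evaluation of the same model: direct scan with scipy's
    Poisson pmf instead of the packaged log-space expression."""
    from scipy.stats import poisson

    for conf in (0.90, 0.95):
        limit = 0
        for j in range(1, 658):
            d = j / 658
            if d >= 0.75:
                break
            lam = -0.75 * np.log1p(-4 * d / 3)
            prob = (poisson.pmf(1, lam) / d) ** j * (
                poisson.pmf(0, lam) / (1 - d)
            ) ** (658 - j)
            if prob > conf:
                limit = j
            else:
                break
        assert parsimony_limit(658, conf) == limit


def test_parsimony_limit_validation():
    with pytest.raises(ValueError):
        parsimony_limit(0, 0.9)
    with pytest.raises(ValueError):
        parsimony_limit(100, 1.5)


def test_msn_two_haplotypes():
    d = np.array([[0, 1], [1, 0]])
    net = build_msn(d, ["a", "b"])
    assert net.edges() == [("a", "b", 1)]


def test_msn_star_topology():
    k = 4
    labels = ["center"] + [f"leaf{i}" for i in range(k)]
    d = np.full((k + 1, k + 1), 2)
    d[0, :] = d[:, 0] = 1
    np.fill_diagonal(d, 0)
    net = build_msn(d, labels)
    assert net.graph.degree("center") == k
    assert net.graph.number_of_edges() == k


def test_msn_tie_retention():
    """Two equal-weight alternatives joining the same components are both
    kept."""
    # square: a-b=1, c-d=1, a-c=2, b-d=2 (tie), a-d=b-c=3
    labels = list("abcd")
    d = np.array([[0, 1, 2, 3], [1, 0, 3, 2], [2, 3, 0, 1], [3, 2, 1, 0]])
    net = build_msn(d, labels)
    assert ("a", "c", 2) in net.edges() and ("b", "d", 2) in net.edges()


def test_msn_weight_bounded_by_spanning_tree():
    rng = np.random.default_rng(17)
    pts = rng.random((7, 2))
    d = np.rint(10 * np.hypot(*(pts[:, None, :] - pts[None, :, :]).T)).astype(int).T
    d = np.triu(d, 1)
    d = d + d.T
    labels = [f"h{i}" for i in range(7)]
    net = build_msn(d, labels)
    g = nx.Graph()
    for i in range(7):
        for j in range(i + 1, 7):
            g.add_edge(labels[i], labels[j], weight=max(int(d[i, j]), 1))
    mst = nx.minimum_spanning_tree(g)
    mst_w = sum(w for _, _, w in mst.edges.data("weight"))
    # the MSN is the MST plus tied alternatives; its tree skeleton weight
    # cannot exceed the MST weight, and every retained edge is <= max tie
    skel = nx.minimum_spanning_tree(net.graph, weight="steps")
    skel_w = sum(w for _, _, w in skel.edges.data("steps"))
    assert skel_w <= mst_w


def test_outlier_attaches_only_within_limit():
    aln = simulate_haplotypes(
        658,
        [("A", "B", 1), ("A", "C", 7), ("C", "E", 3), ("A", "CE", 19)],
        seed=23,
        root_label="A",
    )
    d = pairwise_steps(aln)
    lim90 = parsimony_limit(658, 0.90)
    net = build_msn(d, aln.labels, aln.counts, lim90)
    if lim90 >= 19:
        assert not net.unconnected
    else:
        assert net.unconnected == ["CE"]
    full = build_msn(d, aln.labels, aln.counts, 19)
    assert not full.unconnected


def test_network_invariant_under_relabeling():
    aln = simulate_haplotypes(
        100, [("r", "x", 2), ("r", "y", 4)], seed=3, root_label="r"
    )
    net1 = build_network(aln, confidence=0.95)
    perm = [2, 0, 1]
    aln2 = HaplotypeAlignment(
        [aln.labels[i] for i in perm],
        [aln.sequences[i] for i in perm],
        {aln.labels[i]: aln.counts[aln.labels[i]] for i in perm},
    )
    net2 = build_network(aln2, confidence=0.95)
    assert net1.edges() == net2.edges()
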