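"""Haplotype networks: mutational-step distances, the statistical-parsimony
connection limit, and a minimum-spanning network with tie retention.

The connection limit bounds how many observed differences between two
haplotypes can still be interpreted as that many single mutations: beyond
it, superimposed or parallel changes (homoplasy) become too likely.  We
evaluate the probability of a strictly parsimonious history under a
Jukes–Cantor finite-sites Poisson model: with L sites and j observed
differences, the per-site mutation intensity lambda is solved from the
JC-corrected divergence, and

    P(parsimony | j of L differ)
        = [lambda e^-lambda / d]^j  *  [e^-lambda / (1 - d)]^(L - j),

the probability that every differing site mutated exactly once and every
matching site not at all, given the observed pattern (d = j/L).  The limit
at a given confidence is the largest j whose parsimony probability still
exceeds it, in the spirit of the classic statistical-parsimony criterion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from termipop.datatypes import HaplotypeAlignment
from termipop.diversity import pairwise_site_differences

logger = logging.getLogger(__name__)


def pairwise_steps(aln: HaplotypeAlignment) -> np.ndarray:
    """Mutational-step (Hamming) distances; gap/N columns excluded pairwise."""
    return pairwise_site_differences(aln)


def parsimony_probability(j: int, length: int) -> float:
    """P(no homoplasy | j observed differences over ``length`` sites)."""
    if j == 0:
        return 1.0
    if j >= length:
        return 0.0
    d = j / length
    if d >= 0.75:  # beyond JC saturation
        return 0.0
    lam = -0.75 * np.log1p(-4.0 * d / 3.0)
    log_p = j * (np.log(lam) - lam - np.log(d)) + (length - j) * (
        -lam - np.log1p(-d)
    )
    return float(np.exp(min(log_p, 0.0)))


def parsimony_limit(length: int, confidence: float = 0.95) -> int:
    """Largest step count still connectable at the given confidence."""
    if length <= 0:
        raise ValueError("alignment length must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, length + 1):
        if parsimony_probability(j, length) > confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class HaploNetwork:
    """Minimum-spanning haplotype network."""

    graph: nx.Graph
    counts: dict[str, int]
    limit: int
    #: labels that could not be attached within the connection limit
    unconnected: list[str] = field(default_factory=list)

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), d["steps"]) for u, v, d in self.graph.edges(data=True)
        )

    def write_edge_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["haplotype_a", "haplotype_b", "steps", "intermediate_nodes"])
            for u, v, s in self.edges():
                w.writerow([u, v, s, max(s - 1, 0)])

    def write_gml(self, path: Union[str, Path]) -> None:
        g = self.graph.copy()
        for lab in g.nodes:
            g.nodes[lab]["count"] = self.counts.get(lab, 0)
        nx.write_gml(g, str(path))


def build_msn(
    dist: np.ndarray,
    labels: Sequence[str],
    counts: Optional[dict[str, int]] = None,
    limit: Optional[int] = None,
) -> HaploNetwork:
    """Minimum-spanning network by Kruskal with tie retention.

    Edges are added in ascending step order; *all* equal-weight edges that
    join components that were distinct before the weight class began are
    kept (so alternative equally short connections survive).  Edges above
    ``limit`` steps are discarded; components that remain separate are
    reported as unconnected.  Edges with more than one step stand for
    ``steps - 1`` unsampled intermediate haplotypes.
    """
    dist = np.asarray(dist)
    k = len(labels)
    if dist.shape != (k, k) or not np.array_equal(dist, dist.T):
        raise ValueError("distance matrix must be symmetric with matching labels")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    counts = counts or {lab: 1 for lab in labels}
    limit = int(limit) if limit is not None else int(dist.max())
    graph = nx.Graph()
    for lab in labels:
        graph.add_node(lab)
    edges = [
        (int(dist[i, j]), i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if 0 < dist[i, j] <= limit
    ]
    edges.sort()
    comp = list(range(k))  # union-find by full relabel (k is small)

    def find(x: int) -> int:
        return comp[x]

    def union(x: int, y: int) -> None:
        cx, cy = comp[x], comp[y]
        for z in range(k):
            if comp[z] == cy:
                comp[z] = cx

    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        batch = []
        snapshot = comp.copy()
        while pos < len(edges) and edges[pos][0] == w:
            _, i, j = edges[pos]
            if snapshot[i] != snapshot[j]:
                batch.append((i, j))
            pos += 1
        for i, j in batch:
            graph.add_edge(labels[i], labels[j], steps=w)
            if find(i) != find(j):
                union(i, j)
    main = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)[0]))
    unconnected = sorted(set(labels) - main) if len(main) < k else []
    if unconnected:
        logger.warning(
            "%d haplotype(s) beyond the %d-step connection limit: %s",
            len(unconnected), limit, ", ".join(unconnected),
        )
    return HaploNetwork(graph, dict(counts), limit, unconnected)


def build_network(
    aln: HaplotypeAlignment, confidence: float = 0.95
) -> HaploNetwork:
    """Distance matrix + parsimony limit + MSN in one call."""
    d = pairwise_steps(aln)
    lim = parsimony_limit(aln.length, confidence)
    return build_msn(d, aln.labels, aln.counts, lim)
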