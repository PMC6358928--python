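"""Colony delineation from pairwise genotypic differentiation.

Sampling locations are merged into colonies when their worker genotype
frequencies are statistically indistinguishable: every pair of locations
gets a per-locus G-based differentiation test whose p-values are combined
with Fisher's method, and locations joined by a chain of non-significant
pairs (at a Bonferroni-adjusted alpha) form one colony.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from termipop.datatypes import GenotypeTable
from termipop.differentiation import fisher_combine, g_differentiation_test

logger = logging.getLogger(__name__)


def pairwise_colony_matrix(
    table: GenotypeTable,
    groups: Optional[Sequence[str]] = None,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Symmetric matrix of Fisher-combined differentiation p-values.

    For each pair of groups, each informative locus contributes a
    permutation G test; the per-locus p-values are Fisher-combined.  A pair
    with no informative locus gets p = 1 (no evidence of differentiation).
    """
    groups = list(groups) if groups is not None else list(table.groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gb = groups[j]
            pvals = []
            for locus in table.loci:
                res = g_differentiation_test(
                    table, ga, gb, locus, n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                if not res.skipped:
                    pvals.append(res.p)
            if pvals:
                _, _, p = fisher_combine(pvals, n_perm=n_perm)
            else:
                p = 1.0
            m.iloc[i, j] = m.iloc[j, i] = p
    return m


@dataclass
class ColonyPartition:
    """Partition of sampling locations into colonies, with the evidence."""

    colonies: dict[str, list[str]]
    p_matrix: pd.DataFrame
    alpha: float
    adjusted_alpha: float
    #: pairs inside one colony that were themselves significant (chains that
    #: merged despite a significant direct comparison)
    triangle_inconsistencies: list[tuple[str, str]] = field(default_factory=list)

    def colony_of(self) -> dict[str, str]:
        return {g: cid for cid, members in self.colonies.items() for g in members}

    def labels(self, order: Sequence[str]) -> list[int]:
        """Integer colony labels in the given group order (for Rand index)."""
        of = self.colony_of()
        ids = {cid: k for k, cid in enumerate(self.colonies)}
        return [ids[of[g]] for g in order]


def merge_colonies(
    p_matrix: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ColonyPartition:
    """Merge locations into colonies by single-linkage over non-significance.

    An edge joins two locations iff their combined p >= the adjusted alpha
    (Bonferroni: alpha / number of pairs; Holm is applied stepwise on the
    sorted p-values).  Colonies are the connected components.  Pairs within
    one colony whose direct comparison was significant are reported as
    triangle inconsistencies of the single-linkage closure.
    """
    vals = p_matrix.to_numpy()
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T, equal_nan=True):
        raise ValueError("p matrix must be square and symmetric")
    groups = list(p_matrix.index)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    if correction == "bonferroni":
        adj = alpha / max(n_pairs, 1)
        significant = {
            (groups[i], groups[j]): p_matrix.iloc[i, j] < adj
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
    elif correction == "holm":
        pairs = [
            (p_matrix.iloc[i, j], groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
        pairs.sort()
        significant = {}
        still = True
        for rank, (p, a, b) in enumerate(pairs):
            thresh = alpha / (n_pairs - rank)
            if still and p < thresh:
                significant[(a, b)] = True
            else:
                still = False
                significant[(a, b)] = False
        adj = alpha / max(n_pairs, 1)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    graph = nx.Graph()
    graph.add_nodes_from(groups)
    for (a, b), sig in significant.items():
        if not sig:
            graph.add_edge(a, b)
    comps = sorted(nx.connected_components(graph), key=lambda c: min(groups.index(g) for g in c))
    colonies = {
        f"colony_{k + 1}": sorted(c, key=groups.index) for k, c in enumerate(comps)
    }
    inconsistencies = []
    for members in colonies.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                key = (a, b) if (a, b) in significant else (b, a)
                if significant[key]:
                    inconsistencies.append((a, b))
    if inconsistencies:
        logger.warning(
            "%d significant pair(s) were merged by single-linkage chains",
            len(inconsistencies),
        )
    return ColonyPartition(colonies, p_matrix, alpha, adj, inconsistencies)


def delineate_colonies(
    table: GenotypeTable,
    groups: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> ColonyPartition:
    """Pairwise tests + merging in one call."""
    m = pairwise_colony_matrix(table, groups, n_perm=n_perm, seed=seed)
    return merge_colonies(m, alpha=alpha, correction=correction)
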