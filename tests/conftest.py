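import numpy as np
import pytest

from termipop.datatypes import GenotypeTable


def make_table(groups: dict, loci=None) -> GenotypeTable:
    """Build a GenotypeTable from {group: [row, row, ...]} where each row is
    a list of (a, b) tuples or None."""
    first = next(iter(groups.values()))
    n_loci = len(first[0])
    loci = loci or [f"L{k + 1}" for k in range(n_loci)]
    individuals, genotypes, group_of = [], [], {}
    for g, rows in groups.items():
        for i, row in enumerate(rows):
            uid = f"{g}_{i + 1}"
            individuals.append(uid)
            genotypes.append(list(row))
            group_of[uid] = g
    return GenotypeTable(loci, individuals, list(groups), genotypes, group_of)


@pytest.fixture
def two_group_table():
    """Two groups of 6 diploids at 2 loci with moderate differentiation."""
    rng = np.random.default_rng(42)

    def draw(p1):
        a = rng.choice([1, 2], size=2, p=[p1, 1 - p1])
        return tuple(sorted(int(x) for x in a))

    return make_table(
        {
            "A": [[draw(0.8), draw(0.5)] for _ in range(6)],
            "B": [[draw(0.2), draw(0.5)] for _ in range(6)],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
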