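"""Core in-memory containers for genotype, haplotype and site data.

Conventions
-----------
* Allele codes are positive integers; a missing genotype is stored as
  ``None`` (never the allele code 0, which Genepop reserves as the missing
  sentinel on disk).
* Genotypes are unordered pairs; they are normalised to ``(min, max)``.
* Group labels (sampling locations) are unique and every individual belongs
  to exactly one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

Genotype = Optional[tuple[int, int]]


def _norm_genotype(g: Genotype) -> Genotype:
    if g is None:
        return None
    a, b = int(g[0]), int(g[1])
    if a <= 0 or b <= 0:
        raise ValueError(f"allele codes must be positive integers, got {g!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes grouped by sampling location.

    Parameters
    ----------
    loci
        Ordered locus names.
    individuals
        Ordered individual identifiers (unique).
    groups
        Ordered group (sampling-location) labels, unique.
    genotypes
        ``genotypes[i][l]`` is the unordered allele pair of individual ``i``
        at locus ``l`` or ``None`` when missing.
    group_of
        Individual id -> group label.
    """

    loci: list[str]
    individuals: list[str]
    groups: list[str]
    genotypes: list[list[Genotype]]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        if len(self.genotypes) != len(self.individuals):
            raise ValueError("one genotype row per individual required")
        nl = len(self.loci)
        for ind, row in zip(self.individuals, self.genotypes):
            if len(row) != nl:
                raise ValueError(
                    f"individual {ind!r} has {len(row)} genotype entries, "
                    f"expected {nl}"
                )
        gset = set(self.groups)
        for ind in self.individuals:
            g = self.group_of.get(ind)
            if g not in gset:
                raise ValueError(f"individual {ind!r} has unknown group {g!r}")
        self.genotypes = [[_norm_genotype(g) for g in row] for row in self.genotypes]

    # -- accessors ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def members(self, group: str) -> list[int]:
        """Row indices of the individuals in ``group`` (file order)."""
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [
            i
            for i, ind in enumerate(self.individuals)
            if self.group_of[ind] == group
        ]

    def genotypes_at(
        self, locus: str, rows: Optional[Sequence[int]] = None, drop_missing: bool = True
    ) -> list[tuple[int, int]]:
        """Genotypes at one locus for the given rows (default: everyone)."""
        li = self.locus_index(locus)
        rows = range(self.n_individuals) if rows is None else rows
        out = []
        for i in rows:
            g = self.genotypes[i][li]
            if g is None:
                if not drop_missing:
                    out.append(None)
            else:
                out.append(g)
        return out

    def alleles_at(self, locus: str, rows: Optional[Sequence[int]] = None) -> np.ndarray:
        """Flat array of non-missing allele copies (genes) at one locus."""
        gts = self.genotypes_at(locus, rows)
        if not gts:
            return np.empty(0, dtype=int)
        return np.asarray([a for g in gts for a in g], dtype=int)

    def subset(self, rows: Sequence[int], label: Optional[str] = None) -> "GenotypeTable":
        """New single-group table containing only the given rows."""
        label = label or "subset"
        inds = [self.individuals[i] for i in rows]
        return GenotypeTable(
            loci=list(self.loci),
            individuals=inds,
            groups=[label],
            genotypes=[list(self.genotypes[i]) for i in rows],
            group_of={ind: label for ind in inds},
        )

    def regroup(self, mapping: Mapping[str, str]) -> "GenotypeTable":
        """Re-assign groups: ``mapping`` sends old group labels to new ones.

        Useful to pool sampling locations into colonies or clusters.
        """
        new_of = {
            ind: mapping[self.group_of[ind]] for ind in self.individuals
        }
        seen: list[str] = []
        for g in self.groups:
            m = mapping[g]
            if m not in seen:
                seen.append(m)
        return GenotypeTable(
            loci=list(self.loci),
            individuals=list(self.individuals),
            groups=seen,
            genotypes=[list(r) for r in self.genotypes],
            group_of=new_of,
        )


@dataclass
class HaplotypeAlignment:
    """Aligned haplotype sequences with per-haplotype sample counts."""

    labels: list[str]
    sequences: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("haplotype labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - set("ACGT-N")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
        if not self.counts:
            self.counts = {lab: 1 for lab in self.labels}
        for lab in self.labels:
            if self.counts.get(lab, 0) < 1:
                raise ValueError(f"count for haplotype {lab!r} must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_samples(self) -> int:
        return sum(self.counts[lab] for lab in self.labels)

    def frequencies(self) -> np.ndarray:
        n = self.n_samples
        return np.asarray([self.counts[lab] / n for lab in self.labels])


@dataclass
class SiteTable:
    """Sampling-site metadata: one row per group label, planar or lon/lat."""

    site_ids: list[str]
    labels: list[str]
    x: np.ndarray
    y: np.ndarray
    lonlat: bool = False

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("site group labels must be unique")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if not (len(self.site_ids) == len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("site table columns differ in length")

    def pairwise_distances(self, order: Optional[Iterable[str]] = None) -> np.ndarray:
        """Pairwise distances in meters, in the given label order.

        Planar coordinates use Euclidean distance; lon/lat pairs use the
        haversine great-circle distance on a 6 371 km sphere.
        """
        labels = list(order) if order is not None else list(self.labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        try:
            rows = [idx[lab] for lab in labels]
        except KeyError as e:
            raise KeyError(f"site table has no coordinates for group {e}") from None
        x = self.x[rows]
        y = self.y[rows]
        if not self.lonlat:
            dx = x[:, None] - x[None, :]
            dy = y[:, None] - y[None, :]
            return np.hypot(dx, dy)
        lon = np.radians(x)
        lat = np.radians(y)
        dlon = lon[:, None] - lon[None, :]
        dlat = lat[:, None] - lat[None, :]
        h = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        )
        return 2.0 * 6_371_000.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
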