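"""Per-locus and aggregated diversity statistics.

Microsatellite side: number of alleles per locus (Na), rarefied allelic
richness (Rs, El Mousadik & Petit hypergeometric estimator), and Nei's
unbiased gene diversity (Hs), summarised per group with mean ± SD rows and
a Kruskal–Wallis test of group differences.  mtDNA side: haplotype
diversity (Hd) and nucleotide diversity per site (Nd).

All statistics exclude missing genotypes locus-wise; sample sizes are in
genes (2 × non-missing diploid individuals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from termipop.datatypes import GenotypeTable, HaplotypeAlignment


def _groups_rows(table: GenotypeTable, grouping: Optional[Mapping[str, Sequence[int]]]):
    if grouping is None:
        return {g: table.members(g) for g in table.groups}
    out = {}
    for g, rows in grouping.items():
        rows = list(rows)
        if not rows:
            raise ValueError(f"group {g!r} is empty")
        out[g] = rows
    return out


def allele_counts(
    table: GenotypeTable, grouping: Optional[Mapping[str, Sequence[int]]] = None
) -> pd.DataFrame:
    """Number of distinct non-missing alleles per locus (rows) per group.

    A locus with no data in a group is NaN (absent), never 0.
    """
    groups = _groups_rows(table, grouping)
    out = pd.DataFrame(index=table.loci, columns=list(groups), dtype=float)
    for g, rows in groups.items():
        for locus in table.loci:
            genes = table.alleles_at(locus, rows)
            out.loc[locus, g] = float(len(np.unique(genes))) if genes.size else np.nan
    return out


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """El Mousadik & Petit estimator: E[# alleles in a subsample of g genes].

    Rs = sum_a [1 - C(N - N_a, g) / C(N, g)] with N = sum(counts).
    Evaluated in log space so large N poses no overflow problem.
    """
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample size N={N}")

    def logC(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for Na in counts:
        total += 1.0 - np.exp(logC(N - int(Na), g) - logC(N, g))
    return float(total)


def allelic_richness(
    table: GenotypeTable,
    grouping: Optional[Mapping[str, Sequence[int]]] = None,
    g: Optional[int] = None,
) -> pd.DataFrame:
    """Rarefied allelic richness Rs per locus per group.

    ``g`` is the rarefaction size in genes; by default the per-locus minimum
    non-missing gene count across the compared groups (Fstat behaviour).
    """
    if g is not None and g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    groups = _groups_rows(table, grouping)
    out = pd.DataFrame(index=table.loci, columns=list(groups), dtype=float)
    for locus in table.loci:
        genes_per_group = {gr: table.alleles_at(locus, rows) for gr, rows in groups.items()}
        sizes = [arr.size for arr in genes_per_group.values() if arr.size > 0]
        if not sizes:
            continue
        g_loc = g if g is not None else min(sizes)
        if g_loc < 2:
            continue
        for gr, arr in genes_per_group.items():
            if arr.size < g_loc:
                out.loc[locus, gr] = np.nan
                continue
            _, counts = np.unique(arr, return_counts=True)
            out.loc[locus, gr] = _rarefied_richness(counts, g_loc)
    return out


def gene_diversity(
    table: GenotypeTable, grouping: Optional[Mapping[str, Sequence[int]]] = None
) -> pd.DataFrame:
    """Nei's unbiased gene diversity Hs = n/(n-1) (1 - sum p_a^2), n in genes."""
    groups = _groups_rows(table, grouping)
    out = pd.DataFrame(index=table.loci, columns=list(groups), dtype=float)
    for g, rows in groups.items():
        for locus in table.loci:
            genes = table.alleles_at(locus, rows)
            n = genes.size
            if n < 2:
                out.loc[locus, g] = np.nan
                continue
            _, counts = np.unique(genes, return_counts=True)
            p = counts / n
            out.loc[locus, g] = (n / (n - 1)) * (1.0 - float(np.sum(p * p)))
    return out


def observed_heterozygosity(
    table: GenotypeTable, grouping: Optional[Mapping[str, Sequence[int]]] = None
) -> pd.DataFrame:
    groups = _groups_rows(table, grouping)
    out = pd.DataFrame(index=table.loci, columns=list(groups), dtype=float)
    for g, rows in groups.items():
        for locus in table.loci:
            gts = table.genotypes_at(locus, rows)
            if not gts:
                out.loc[locus, g] = np.nan
            else:
                out.loc[locus, g] = float(np.mean([a != b for a, b in gts]))
    return out


@dataclass
class DiversitySummary:
    """Per-locus table of one statistic with mean ± SD rows and a KW test."""

    per_locus: pd.DataFrame  # loci x groups
    mean: pd.Series
    sd: pd.Series
    kruskal_h: float
    kruskal_df: int
    kruskal_p: float

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_locus.copy()
        frame.loc["Mean"] = self.mean
        frame.loc["SD"] = self.sd
        return frame


def summarize_diversity(per_locus: pd.DataFrame) -> DiversitySummary:
    """Mean ± sample SD across loci per group plus a Kruskal–Wallis test.

    The Kruskal–Wallis test compares the per-locus values across groups
    (midranks, tie-corrected); it is skipped (NaN) with < 2 groups.
    """
    if per_locus.shape[0] < 1:
        raise ValueError("need at least one locus")
    mean = per_locus.mean(axis=0, skipna=True)
    sd = per_locus.std(axis=0, ddof=1, skipna=True).fillna(0.0)
    cols = [per_locus[c].dropna().to_numpy() for c in per_locus.columns]
    cols = [c for c in cols if c.size > 0]
    if len(cols) >= 2:
        try:
            h, p = stats.kruskal(*cols)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        df = len(cols) - 1
    else:
        h, p, df = np.nan, np.nan, 0
    return DiversitySummary(per_locus, mean, sd, float(h), int(df), float(p))


# -- mtDNA ---------------------------------------------------------------


def haplotype_diversity(aln: HaplotypeAlignment) -> float:
    """Hd = n/(n-1) (1 - sum f_i^2) over haplotype frequencies."""
    n = aln.n_samples
    if n < 2:
        raise ValueError("haplotype diversity needs >= 2 sampled individuals")
    f = aln.frequencies()
    return float((n / (n - 1)) * (1.0 - np.sum(f * f)))


def pairwise_site_differences(aln: HaplotypeAlignment) -> np.ndarray:
    """Matrix of nucleotide differences; gap/N columns excluded pairwise."""
    seqs = np.array([list(s) for s in aln.sequences])
    valid = np.isin(seqs, list("ACGT"))
    k = len(aln.sequences)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            d[i, j] = d[j, i] = int(np.sum(seqs[i][both] != seqs[j][both]))
    return d


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Nd per site: 2 n/(n-1) sum_{i<j} f_i f_j d_ij / L."""
    if aln.length == 0:
        raise ValueError("alignment length must be positive")
    n = aln.n_samples
    if n < 2:
        return 0.0
    f = aln.frequencies()
    d = pairwise_site_differences(aln)
    acc = 0.0
    for i in range(len(f)):
        for j in range(i + 1, len(f)):
            acc += f[i] * f[j] * d[i, j]
    return float(2.0 * acc * (n / (n - 1)) / aln.length)
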