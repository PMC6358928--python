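"""Colony breeding-structure (family-type) classification.

A colony of termite workers is classified from its multilocus genotype
counts as

* **simple family** — direct offspring of one monogamous reproductive pair:
  every locus is compatible with some single parental pair and the observed
  genotype counts fit Mendelian segregation (G-test across loci, p >= alpha);
* **extended family** — descendants of inbreeding neotenic reproductives
  derived from one founding pair: four or fewer alleles at every locus but
  genotype patterns a single pair cannot produce (more than four genotype
  classes, three or more homozygote classes, or a significant Mendelian
  G-test);
* **mixed family** — unrelated reproductives present (e.g. after colony
  fusion): more than four alleles at one or more loci.

When every locus carries few alleles an extended-family call cannot be
distinguished from a mixed family; the report flags this explicitly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from termipop.datatypes import GenotypeTable

logger = logging.getLogger(__name__)

ParentPair = tuple[tuple[int, int], tuple[int, int]]


def mendelian_offspring(pair: ParentPair) -> dict[tuple[int, int], float]:
    """Offspring genotype distribution of one parental pair (unordered)."""
    (a1, a2), (b1, b2) = pair
    out: dict[tuple[int, int], float] = {}
    for x in (a1, a2):
        for y in (b1, b2):
            g = (x, y) if x <= y else (y, x)
            out[g] = out.get(g, 0.0) + 0.25
    return out


@dataclass
class LocusEvidence:
    locus: str
    n_workers: int
    n_alleles: int
    n_genotype_classes: int
    n_homozygote_classes: int
    single_pair_compatible: bool
    best_pair: Optional[ParentPair] = None
    compatible_pairs: list[ParentPair] = field(default_factory=list)
    used_in_gtest: bool = True


def enumerate_parent_pairs(
    genotypes: Sequence[tuple[int, int]]
) -> list[ParentPair]:
    """All unordered parental pairs whose Mendelian offspring cover the data.

    Parents range over diploid genotypes on the observed alleles.  The
    quick incompatibility certificates (> 4 alleles, > 4 genotype classes,
    >= 3 homozygote classes) shortcut to an empty set.
    """
    gts = [g for g in genotypes if g is not None]
    if not gts:
        raise ValueError("need at least one non-missing genotype")
    observed = set(gts)
    alleles = sorted({a for g in observed for a in g})
    homs = {g for g in observed if g[0] == g[1]}
    if len(alleles) > 4 or len(observed) > 4 or len(homs) >= 3:
        return []
    parents = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    out: list[ParentPair] = []
    for pa, pb in itertools.combinations_with_replacement(parents, 2):
        if observed <= set(mendelian_offspring((pa, pb))):
            out.append((pa, pb))
    return out


def _best_pair(
    gts: Sequence[tuple[int, int]], pairs: Sequence[ParentPair]
) -> ParentPair:
    """Multinomial-likelihood maximiser; ties broken by fewer distinct
    parental alleles, then lexicographically."""
    counts: dict[tuple[int, int], int] = {}
    for g in gts:
        counts[g] = counts.get(g, 0) + 1

    def loglik(pair: ParentPair) -> float:
        probs = mendelian_offspring(pair)
        return sum(c * np.log(probs[g]) for g, c in counts.items())

    def key(pair: ParentPair):
        distinct = len({a for p in pair for a in p})
        return (-loglik(pair), distinct, pair)

    return min(pairs, key=key)


def mendelian_g_test(
    evidence: Sequence[LocusEvidence],
    genotypes_by_locus: dict[str, list[tuple[int, int]]],
    pool_threshold: float = 1.0,
    williams: bool = True,
) -> tuple[float, int, float]:
    """Across-loci G-test of Mendelian segregation for chosen parental pairs.

    Per locus the expected class probabilities are the Mendelian ratios of
    the chosen pair restricted to its producible classes; classes with
    expected count < ``pool_threshold`` are pooled with the smallest-E
    remaining class before computing G, and Williams' small-sample
    correction (G / [1 + (a^2-1)/(6 n (a-1))], a = classes) is applied per
    locus, which keeps the test near nominal level at colony-sized samples.
    Loci whose best pair produces a single class contribute 0 to G and 0 to
    df.  Returns (G, df, p).
    """
    g_total = 0.0
    df_total = 0
    any_locus = False
    for ev in evidence:
        if not ev.used_in_gtest or ev.best_pair is None:
            continue
        gts = genotypes_by_locus[ev.locus]
        if not gts:
            continue
        any_locus = True
        probs = mendelian_offspring(ev.best_pair)
        classes = sorted(probs)
        n = len(gts)
        obs = np.array([sum(1 for g in gts if g == c) for c in classes], dtype=float)
        exp = np.array([probs[c] * n for c in classes])
        # pool small-expectation classes with the smallest-E neighbour
        while len(exp) > 1 and exp.min() < pool_threshold:
            i = int(np.argmin(exp))
            rest = [j for j in range(len(exp)) if j != i]
            j = rest[int(np.argmin(exp[rest]))]
            exp[j] += exp[i]
            obs[j] += obs[i]
            exp = np.delete(exp, i)
            obs = np.delete(obs, i)
        if len(exp) < 2:
            continue
        mask = obs > 0
        g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
        if williams:
            a = len(exp)
            g /= 1.0 + (a * a - 1.0) / (6.0 * n * (a - 1.0))
        g_total += g
        df_total += len(exp) - 1
    if not any_locus:
        raise ValueError("no locus with a compatible parental pair")
    if df_total == 0:
        return 0.0, 0, 1.0
    return g_total, df_total, float(stats.chi2.sf(g_total, df_total))


@dataclass
class FamilyCallReport:
    colony_id: str
    call: str  # simple | extended | mixed | ambiguous
    evidence: list[LocusEvidence]
    mendelian_g: Optional[float] = None
    mendelian_df: Optional[int] = None
    mendelian_p: Optional[float] = None
    #: extended call with low allele counts: a mixed family cannot be excluded
    mixed_not_excluded: bool = False
    flags: list[str] = field(default_factory=list)


def classify_family(
    table: GenotypeTable,
    rows: Optional[Sequence[int]] = None,
    colony_id: str = "colony",
    alpha: float = 0.05,
    min_workers_gtest: int = 10,
) -> FamilyCallReport:
    """Classify one colony's workers as simple / extended / mixed.

    Decision order: (1) any locus with more than four alleles -> mixed;
    (2) otherwise any single-pair-incompatible locus, or a significant
    across-loci Mendelian G-test -> extended; (3) otherwise simple.  All
    loci monomorphic -> ambiguous.  Loci with fewer than
    ``min_workers_gtest`` scored workers contribute evidence flags but are
    left out of the G-test.
    """
    rows = list(rows) if rows is not None else list(range(table.n_individuals))
    flags: list[str] = []
    if len(rows) < 5:
        flags.append("fewer than 5 workers: calls are unreliable")
    evidence: list[LocusEvidence] = []
    genotypes_by_locus: dict[str, list[tuple[int, int]]] = {}
    any_polymorphic = False
    for locus in table.loci:
        gts = table.genotypes_at(locus, rows)
        genotypes_by_locus[locus] = gts
        if not gts:
            evidence.append(
                LocusEvidence(locus, 0, 0, 0, 0, True, used_in_gtest=False)
            )
            continue
        observed = set(gts)
        alleles = {a for g in observed for a in g}
        homs = {g for g in observed if g[0] == g[1]}
        if len(alleles) > 1:
            any_polymorphic = True
        pairs = enumerate_parent_pairs(gts)
        ev = LocusEvidence(
            locus=locus,
            n_workers=len(gts),
            n_alleles=len(alleles),
            n_genotype_classes=len(observed),
            n_homozygote_classes=len(homs),
            single_pair_compatible=bool(pairs),
            compatible_pairs=pairs,
            best_pair=_best_pair(gts, pairs) if pairs else None,
            used_in_gtest=len(gts) >= min_workers_gtest,
        )
        evidence.append(ev)

    report = FamilyCallReport(colony_id, "ambiguous", evidence, flags=flags)
    if not any_polymorphic:
        flags.append("all loci monomorphic: family type undecidable")
        return report

    max_alleles = max(ev.n_alleles for ev in evidence)
    if max_alleles > 4:
        report.call = "mixed"
        return report

    incompatible = any(
        not ev.single_pair_compatible for ev in evidence if ev.n_workers > 0
    )
    usable = [ev for ev in evidence if ev.used_in_gtest and ev.best_pair is not None]
    if usable and not incompatible:
        g, df, p = mendelian_g_test(usable, genotypes_by_locus)
        report.mendelian_g, report.mendelian_df, report.mendelian_p = g, df, p
        report.call = "simple" if p >= alpha else "extended"
    elif incompatible:
        report.call = "extended"
    else:
        report.call = "ambiguous"
        flags.append("no locus eligible for the Mendelian G-test")

    if report.call == "extended" and max_alleles <= 3:
        report.mixed_not_excluded = True
        flags.append(
            "low allele counts: cannot exclude a mixed family "
            "(extended vs mixed indistinguishable)"
        )
    return report
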