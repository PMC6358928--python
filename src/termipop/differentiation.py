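"""Locus-level statistical machinery for genotypic data.

Contents: exact Hardy–Weinberg tests (full enumeration or Monte-Carlo under
Levene's conditional distribution), genotypic-disequilibrium permutation
tests, the log-likelihood (G) genotypic differentiation test between pairs
of groups with a permutation null, Fisher's combined probability test, and
the Weir & Cockerham (1984) theta estimator of FST.

Permutation p-values use the add-one estimator (b+1)/(n_perm+1), so a
reported p is never 0 and the test is exact-level at conventional alphas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from termipop.datatypes import GenotypeTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Hardy–Weinberg exact test
# --------------------------------------------------------------------------


def _log_levene(table: np.ndarray, n: int) -> float:
    """Log conditional probability of a genotype-count table given allele counts.

    P = n! prod_a(m_a!) 2^H / ((2n)! prod_{a<=b} t_ab!), H = # heterozygotes.
    ``table`` is upper-triangular genotype counts (k x k), n = individuals.
    """
    k = table.shape[0]
    m = np.zeros(k)
    H = 0
    logprod = 0.0
    for a in range(k):
        for b in range(a, k):
            t = table[a, b]
            m[a] += t
            m[b] += t
            if a != b:
                H += t
            logprod += gammaln(t + 1)
    return float(
        gammaln(n + 1)
        + np.sum(gammaln(m + 1))
        + H * np.log(2.0)
        - gammaln(2 * n + 1)
        - logprod
    )


def _obs_genotype_table(gts: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    alleles = np.unique([a for g in gts for a in g])
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    tab = np.zeros((k, k), dtype=int)
    for a, b in gts:
        tab[idx[a], idx[b]] += 1  # a <= b after normalisation
    return tab, alleles


def _enumerate_tables(margins: np.ndarray, cap: int):
    """Yield all genotype-count tables with the given allele-count margins.

    Stops (raises StopIteration internally) by returning None if more than
    ``cap`` tables would be generated.
    """
    k = len(margins)
    cells = [(a, b) for a in range(k) for b in range(a, k)]
    # alleles still placeable in cells[ci:]
    future: list[set[int]] = [set() for _ in range(len(cells) + 1)]
    for ci in range(len(cells) - 1, -1, -1):
        future[ci] = future[ci + 1] | set(cells[ci])
    out: list[np.ndarray] = []

    def rec(ci: int, rem: np.ndarray, tab: np.ndarray) -> bool:
        if ci == len(cells):
            out.append(tab.copy())
            return len(out) <= cap
        a, b = cells[ci]
        tmax = rem[a] // 2 if a == b else min(rem[a], rem[b])
        nxt = future[ci + 1]
        for t in range(int(tmax), -1, -1):
            rem2 = rem.copy()
            if a == b:
                rem2[a] -= 2 * t
            else:
                rem2[a] -= t
                rem2[b] -= t
            if any(rem2[x] > 0 and x not in nxt for x in range(k)):
                continue
            tab[a, b] = t
            if not rec(ci + 1, rem2, tab):
                return False
            tab[a, b] = 0
        return True

    complete = rec(0, margins.astype(int).copy(), np.zeros((k, k), dtype=int))
    return out if complete else None


def hwe_exact_test(
    table: GenotypeTable,
    group: str,
    locus: str,
    n_mc: int = 100_000,
    seed: Optional[int] = None,
    enum_cap: int = 200_000,
    method: str = "auto",
) -> float:
    """Exact probability test for Hardy–Weinberg proportions.

    Full enumeration of genotype tables with the observed allele counts when
    feasible (``method='auto'`` enumerates for <= 4 alleles), otherwise
    Monte-Carlo sampling of ``n_mc`` random pairings of the gene pool.
    p = probability mass of tables no more probable than the observed one
    under Levene's conditional distribution.  Monomorphic locus returns
    p = 1.  ``method`` may force ``'enum'`` or ``'mc'``.
    """
    gts = table.genotypes_at(locus, table.members(group))
    if len(gts) < 2:
        raise ValueError("need >= 2 individuals with data for the HWE test")
    obs_tab, alleles = _obs_genotype_table(gts)
    k = len(alleles)
    if k < 2:
        return 1.0
    n = len(gts)
    margins = obs_tab.sum(axis=0) + obs_tab.sum(axis=1)  # gene counts per allele
    logp_obs = _log_levene(obs_tab, n)
    if method not in ("auto", "enum", "mc"):
        raise ValueError(f"unknown method {method!r}")
    tables = None
    if method == "enum" or (method == "auto" and k <= 4):
        tables = _enumerate_tables(margins, enum_cap)
        if tables is None and method == "enum":
            raise ValueError("enumeration exceeds the table cap; use mc")
    tol = 1e-9
    if tables is not None:
        logps = np.array([_log_levene(t, n) for t in tables])
        total = np.exp(logps - logps.max())
        mass = total[logps <= logp_obs + tol].sum() / total.sum()
        return float(mass)
    # Monte-Carlo: shuffle the gene pool into random pairs
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), margins)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        pairs = pool.reshape(n, 2)
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        tab = np.zeros((k, k), dtype=int)
        np.add.at(tab, (lo, hi), 1)
        if _log_levene(tab, n) <= logp_obs + tol:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


# --------------------------------------------------------------------------
# G statistics on contingency tables
# --------------------------------------------------------------------------


def _g_stat(obs: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) for a contingency table; zero cells contribute 0."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    if n == 0:
        return 0.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def _genotype_class_ids(gts: Sequence[tuple[int, int]]) -> np.ndarray:
    classes = sorted(set(gts))
    idx = {c: i for i, c in enumerate(classes)}
    return np.asarray([idx[g] for g in gts], dtype=int), len(classes)


def ld_test(
    table: GenotypeTable,
    group: str,
    locus_a: str,
    locus_b: str,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Genotypic-disequilibrium permutation test between two loci.

    G on the two-locus genotype contingency table; the null is built by
    permuting locus-B genotypes among the individuals that have data at
    both loci.  Either locus monomorphic in the group -> p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rows = table.members(group)
    ia, ib = table.locus_index(locus_a), table.locus_index(locus_b)
    pairs = [
        (table.genotypes[i][ia], table.genotypes[i][ib])
        for i in rows
        if table.genotypes[i][ia] is not None and table.genotypes[i][ib] is not None
    ]
    if len(pairs) < 2:
        return 1.0
    ga, ca = _genotype_class_ids([p[0] for p in pairs])
    gb, cb = _genotype_class_ids([p[1] for p in pairs])
    if ca < 2 or cb < 2:
        return 1.0
    joint = ga * cb + gb
    obs_tab = np.bincount(joint, minlength=ca * cb).reshape(ca, cb)
    g_obs = _g_stat(obs_tab)
    rng = np.random.default_rng(seed)
    hits = 0
    gb_work = gb.copy()
    for _ in range(n_perm):
        rng.shuffle(gb_work)
        tab = np.bincount(ga * cb + gb_work, minlength=ca * cb).reshape(ca, cb)
        if _g_stat(tab) >= g_obs - 1e-12:
            hits += 1
    return float((hits + 1) / (n_perm + 1))


@dataclass
class GTestResult:
    g: float
    p: float
    n_a: int
    n_b: int
    skipped: bool = False


def g_differentiation_test(
    table: GenotypeTable,
    group_a: str,
    group_b: str,
    locus: str,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> GTestResult:
    """Log-likelihood (G) genotypic differentiation test for one locus.

    The contingency table crosses unordered genotype classes with the two
    groups; the null reallocates individuals between the groups keeping the
    group sizes, which fixes both margins, so G is computed against constant
    expectations and the whole permutation null is vectorised.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ga = table.genotypes_at(locus, table.members(group_a))
    gb = table.genotypes_at(locus, table.members(group_b))
    if not ga or not gb:
        logger.warning(
            "locus %s skipped for pair (%s, %s): a group has no data",
            locus, group_a, group_b,
        )
        return GTestResult(np.nan, np.nan, len(ga), len(gb), skipped=True)
    ids, k = _genotype_class_ids(ga + gb)
    na, nb = len(ga), len(gb)
    n = na + nb
    onehot = np.zeros((n, k))
    onehot[np.arange(n), ids] = 1.0
    col_tot = onehot.sum(axis=0)
    ea = na * col_tot / n
    eb = nb * col_tot / n

    def g_of(counts_a: np.ndarray) -> np.ndarray:
        counts_b = col_tot - counts_a
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = np.where(counts_a > 0, counts_a * np.log(counts_a / ea), 0.0)
            tb = np.where(counts_b > 0, counts_b * np.log(counts_b / eb), 0.0)
        return 2.0 * (ta.sum(axis=-1) + tb.sum(axis=-1))

    obs_a = onehot[:na].sum(axis=0)
    g_obs = float(g_of(obs_a))
    rng = np.random.default_rng(seed)
    # vectorised permutations: random subsets of size na via argsort of uniforms
    batch = 2000
    hits = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)[:, :na]
        counts = onehot[order].sum(axis=1)  # b x k
        hits += int(np.sum(g_of(counts) >= g_obs - 1e-12))
        done += b
    p = (hits + 1) / (n_perm + 1)
    return GTestResult(g_obs, float(p), na, nb)


def fisher_combine(pvals: Sequence[float], n_perm: Optional[int] = None):
    """Fisher's combined probability test: chi2 = -2 sum ln p, df = 2L.

    p = 0 entries are clamped to 1/(n_perm+1) (requires ``n_perm``).
    Returns (chi2, df, combined p).
    """
    pvals = list(pvals)
    if not pvals:
        raise ValueError("cannot combine an empty list of p-values")
    clamped = []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            if n_perm is None:
                raise ValueError("p = 0 requires n_perm to clamp against")
            logger.warning("p = 0 clamped to 1/(n_perm+1)")
            p = 1.0 / (n_perm + 1)
        clamped.append(p)
    chi2 = -2.0 * float(np.sum(np.log(clamped)))
    df = 2 * len(clamped)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# --------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# --------------------------------------------------------------------------


@dataclass
class FstResult:
    theta: float
    per_locus: dict[str, float] = field(default_factory=dict)
    components: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def wc_fst(
    table: GenotypeTable,
    groups: Optional[Sequence[str]] = None,
) -> FstResult:
    """Multilocus Weir & Cockerham theta over the given groups (default: all).

    Ratio-of-sums estimator: theta = sum_l,a a / sum_l,a (a + b + c), with
    the variance components of Weir & Cockerham (1984); missing genotypes
    excluded locus-wise; loci monomorphic across the groups contribute
    nothing.  Returns NaN theta (flagged by empty components) if every locus
    is monomorphic.
    """
    groups = list(groups) if groups is not None else list(table.groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for theta")
    rows = {g: table.members(g) for g in groups}
    num = 0.0
    den = 0.0
    per_locus: dict[str, float] = {}
    components: dict[str, tuple[float, float, float]] = {}
    for locus in table.loci:
        gts = {g: table.genotypes_at(locus, r) for g, r in rows.items()}
        sizes = np.array([len(gts[g]) for g in groups], dtype=float)
        if np.any(sizes == 0):
            continue
        alleles = sorted({a for g in groups for gt in gts[g] for a in gt})
        if len(alleles) < 2:
            continue
        r = len(groups)
        nbar = sizes.mean()
        nc = (r * nbar - np.sum(sizes**2) / (r * nbar)) / (r - 1)
        la = lb = lc = 0.0
        for al in alleles:
            p_i = np.array(
                [np.mean([(g1 == al) + (g2 == al) for g1, g2 in gts[g]]) / 2.0 for g in groups]
            )
            h_i = np.array(
                [np.mean([(g1 == al) != (g2 == al) for g1, g2 in gts[g]]) for g in groups]
            )
            pbar = np.sum(sizes * p_i) / (r * nbar)
            s2 = np.sum(sizes * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(sizes * h_i) / (r * nbar)
            if nbar <= 1:
                continue
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            la += a
            lb += b
            lc += c
        tot = la + lb + lc
        if tot != 0:
            per_locus[locus] = la / tot
        components[locus] = (la, lb, lc)
        num += la
        den += tot
    if den == 0 or not components:
        logger.warning("theta undefined: all loci monomorphic across groups")
        return FstResult(float("nan"), per_locus, components)
    return FstResult(num / den, per_locus, components)
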