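"""Heterozygosity-excess bottleneck detection (IAM / TPM / SMM battery).

A recent reduction in effective population size erodes allele number faster
than gene diversity, so for a short window the observed gene diversity He
exceeds the equilibrium diversity Heq expected for the observed number of
alleles.  For each locus we simulate coalescent genealogies of the sampled
genes, place mutations under the chosen model with the scaled mutation rate
calibrated so replicates yield exactly the observed allele count, and
standardise the deviation DH = (He - mean Heq) / SD(Heq).  Across loci the
excess is tested with a sign test (Poisson-binomial on the expected number
of excess loci) and Wilcoxon signed-rank tests, and the allele-frequency
spectrum is checked for a mode shift away from the L-shape expected at
mutation-drift equilibrium.

Mutation models
---------------
IAM   every mutation creates a novel allele.
SMM   every mutation steps the repeat score by +-1 (allele integer codes
      are interpreted as repeat scores for this state space only).
TPM   with probability ``p_smm`` a single step, otherwise a multi-step jump
      of geometric size tuned to the configured variance (defaults 0.70 and
      30, the classic BOTTLENECK v1.2 settings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from termipop.datatypes import GenotypeTable

logger = logging.getLogger(__name__)

MODELS = ("IAM", "TPM", "SMM")


@dataclass(frozen=True)
class TpmParams:
    p_smm: float = 0.70
    variance: float = 30.0

    def geometric_p(self) -> float:
        """Success probability of the multi-step geometric (support 1,2,...)
        chosen so the jump-size variance matches ``variance``."""
        # var = (1 - p) / p^2  ->  p = (-1 + sqrt(1 + 4 var)) / (2 var)
        v = self.variance
        return (-1.0 + np.sqrt(1.0 + 4.0 * v)) / (2.0 * v)


# --------------------------------------------------------------------------
# coalescent simulation of equilibrium samples
# --------------------------------------------------------------------------


def sample_coalescent_states(
    rng: np.random.Generator,
    n: int,
    theta: float,
    model: str,
    tpm: TpmParams = TpmParams(),
) -> np.ndarray:
    """Allelic states of ``n`` genes from one equilibrium coalescent genealogy.

    Time is in units of 2N generations; mutations are Poisson with rate
    ``theta/2`` per lineage per unit time.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    for m in range(n, 1, -1):
        t += rng.exponential(2.0 / (m * (m - 1)))
        i = active.pop(int(rng.integers(m)))
        j = active.pop(int(rng.integers(m - 1)))
        parent[i] = parent[j] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    root = n_nodes - 1
    blen = node_time[parent[:root]] - node_time[:root]
    muts = rng.poisson(theta / 2.0 * blen)
    state = np.zeros(n_nodes, dtype=np.int64)
    hit = np.nonzero(muts)[0]
    if model == "IAM":
        # the most recent mutation above a node defines its allele; a fresh
        # unique label per mutated branch realises the infinite-allele rule
        labels = np.zeros(root, dtype=np.int64)
        labels[hit] = hit + n_nodes  # unique, never clashes with root label 0
        for v in range(root - 1, -1, -1):
            state[v] = labels[v] if muts[v] > 0 else state[parent[v]]
    else:
        delta = np.zeros(root, dtype=np.int64)
        if hit.size:
            if model == "SMM":
                delta[hit] = 2 * rng.binomial(muts[hit], 0.5) - muts[hit]
            elif model == "TPM":
                for v in hit:
                    m_v = int(muts[v])
                    n_single = rng.binomial(m_v, tpm.p_smm)
                    d = 2 * rng.binomial(n_single, 0.5) - n_single
                    n_multi = m_v - n_single
                    if n_multi:
                        sizes = rng.geometric(tpm.geometric_p(), size=n_multi)
                        signs = rng.integers(0, 2, size=n_multi) * 2 - 1
                        d += int(np.sum(sizes * signs))
                    delta[v] = d
            else:
                raise ValueError(f"unknown mutation model {model!r}")
        for v in range(root - 1, -1, -1):
            state[v] = state[parent[v]] + delta[v]
    return state[:n]


def unbiased_gene_diversity(states: np.ndarray) -> float:
    """He = n/(n-1) (1 - sum p_a^2) over gene states."""
    n = states.size
    _, counts = np.unique(states, return_counts=True)
    p = counts / n
    return float((n / (n - 1)) * (1.0 - np.sum(p * p)))


def _mean_k(rng, n, theta, model, tpm, n_sims=80) -> float:
    ks = [
        len(np.unique(sample_coalescent_states(rng, n, theta, model, tpm)))
        for _ in range(n_sims)
    ]
    return float(np.mean(ks))


def calibrate_theta(
    n: int,
    k: int,
    model: str,
    tpm: TpmParams = TpmParams(),
    seed: Optional[int] = None,
) -> float:
    """Scaled mutation rate whose expected allele count is ~k for n genes.

    IAM starts from the exact E[K] = sum_i theta/(theta+i); the stepwise
    models inflate theta by stochastic bisection on simulated mean allele
    counts (back-mutation makes them less allele-rich at equal theta).
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k_alleles <= n_genes")

    def iam_ek(th: float) -> float:
        i = np.arange(n)
        return float(np.sum(th / (th + i)))

    lo, hi = 1e-4, 1e5
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if iam_ek(mid) < k:
            lo = mid
        else:
            hi = mid
    theta = np.sqrt(lo * hi)
    if model == "IAM":
        return theta
    rng = np.random.default_rng(seed)
    lo, hi = theta * 0.3, theta * 300.0
    for _ in range(14):
        mid = np.sqrt(lo * hi)
        if _mean_k(rng, n, mid, model, tpm) < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_heq(
    n_genes: int,
    k_alleles: int,
    model: str,
    n_iter: int = 10_000,
    seed: Optional[int] = None,
    tpm: TpmParams = TpmParams(),
    min_acceptance: float = 1e-4,
) -> np.ndarray:
    """Equilibrium gene-diversity sample conditioned on the allele count.

    Coalescent replicates are accepted only when they carry exactly
    ``k_alleles`` distinct alleles; ``n_iter`` accepted Heq values are
    returned.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not 2 <= k_alleles <= n_genes:
        raise ValueError("need 2 <= k_alleles <= n_genes")
    rng = np.random.default_rng(seed)
    theta = calibrate_theta(n_genes, k_alleles, model, tpm, seed=int(rng.integers(2**31)))
    out = np.empty(n_iter)
    accepted = 0
    attempts = 0
    check_at = max(5_000, 20 * n_iter // 10)
    while accepted < n_iter:
        states = sample_coalescent_states(rng, n_genes, theta, model, tpm)
        attempts += 1
        if len(np.unique(states)) == k_alleles:
            out[accepted] = unbiased_gene_diversity(states)
            accepted += 1
        if attempts >= check_at and accepted / attempts < min_acceptance:
            raise RuntimeError(
                f"acceptance rate {accepted / attempts:.2e} too low for "
                f"n={n_genes}, k={k_alleles}, {model}; review parameters"
            )
    return out


class HeqLibrary:
    """Reusable cache of conditioned equilibrium Heq samples.

    The battery needs one Heq sample per (sample size, allele count,
    mutation model); those samples do not depend on the data beyond that
    key, so repeated batteries (e.g. across many groups of equal size) can
    share a library instead of re-simulating.  Entries are seeded
    deterministically from the library seed and the key.
    """

    def __init__(self, n_iter: int = 10_000, seed: Optional[int] = None,
                 tpm: TpmParams = TpmParams()):
        self.n_iter = n_iter
        self.seed = 0 if seed is None else int(seed)
        self.tpm = tpm
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, n_genes: int, k_alleles: int, model: str) -> np.ndarray:
        key = (n_genes, k_alleles, model)
        if key not in self._store:
            entropy = np.random.SeedSequence(
                [self.seed, n_genes, k_alleles, MODELS.index(model)]
            )
            self._store[key] = simulate_heq(
                n_genes, k_alleles, model, n_iter=self.n_iter,
                seed=int(entropy.generate_state(1)[0] % (2**31)), tpm=self.tpm,
            )
        return self._store[key]


# --------------------------------------------------------------------------
# the per-group battery
# --------------------------------------------------------------------------


def _poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_l) by dynamic programming."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def sign_test_excess(dh: np.ndarray, p_excess: np.ndarray) -> float:
    """Two-tailed Poisson-binomial sign test on the number of excess loci.

    ``p_excess[l]`` is the equilibrium probability that locus l shows
    He > mean(Heq), estimated from the simulations; the observed count is
    compared with its expectation under independence across loci.
    """
    obs = int(np.sum(dh > 0))
    pmf = _poisson_binomial_pmf(p_excess)
    expected = float(np.sum(p_excess))
    if obs >= expected:
        tail = float(pmf[obs:].sum())
    else:
        tail = float(pmf[: obs + 1].sum())
    return min(1.0, 2.0 * tail)


def _wilcoxon(dh: np.ndarray, alternative: str) -> float:
    nz = dh[dh != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 15 else "approx"
    try:
        return float(
            stats.wilcoxon(nz, alternative=alternative, method=method).pvalue
        )
    except ValueError:
        return float(stats.wilcoxon(nz, alternative=alternative, method="approx").pvalue)


@dataclass
class ModelBattery:
    model: str
    loci: list[str]
    he: np.ndarray
    heq_mean: np.ndarray
    heq_sd: np.ndarray
    dh: np.ndarray
    p_excess: np.ndarray
    sign_p: float
    wilcoxon_one_tailed_p: float
    wilcoxon_two_tailed_p: float


@dataclass
class BottleneckReport:
    group: str
    batteries: dict[str, ModelBattery]
    mode_shift: str
    n_loci_used: int
    flags: list[str] = field(default_factory=list)


def heterozygosity_excess_battery(
    table: GenotypeTable,
    group: str,
    models: Sequence[str] = MODELS,
    n_iter: int = 10_000,
    seed: Optional[int] = None,
    tpm: TpmParams = TpmParams(),
    heq_library: Optional[HeqLibrary] = None,
) -> BottleneckReport:
    """Full bottleneck battery for one group (Table-2-shaped output).

    Passing a shared :class:`HeqLibrary` reuses equilibrium samples across
    calls (its ``n_iter``/seed then override the arguments here).
    """
    rows = table.members(group)
    flags: list[str] = []
    loci, he_obs, nk = [], [], []
    for locus in table.loci:
        genes = table.alleles_at(locus, rows)
        if genes.size < 2:
            continue
        k = len(np.unique(genes))
        if k < 2:
            logger.info("locus %s monomorphic in %s: skipped", locus, group)
            continue
        loci.append(locus)
        he_obs.append(unbiased_gene_diversity(genes))
        nk.append((genes.size, k))
    if len(loci) < 4:
        flags.append(
            f"only {len(loci)} polymorphic loci: Wilcoxon test has little power"
        )
    he_obs = np.asarray(he_obs)
    ss = np.random.SeedSequence(seed)
    batteries: dict[str, ModelBattery] = {}
    for model, child in zip(models, ss.spawn(len(list(models)))):
        locus_seeds = child.spawn(len(loci))
        mean = np.empty(len(loci))
        sd = np.empty(len(loci))
        p_exc = np.empty(len(loci))
        for li, ((n, k), ls) in enumerate(zip(nk, locus_seeds)):
            if heq_library is not None:
                heq = heq_library.get(n, k, model)
            else:
                heq = simulate_heq(
                    n, k, model, n_iter=n_iter,
                    seed=int(ls.generate_state(1)[0] % (2**31)), tpm=tpm,
                )
            mean[li] = heq.mean()
            sd[li] = heq.std(ddof=1)
            p_exc[li] = float(np.mean(heq > heq.mean()))
        with np.errstate(divide="ignore", invalid="ignore"):
            dh = np.where(sd > 0, (he_obs - mean) / sd, 0.0)
        batteries[model] = ModelBattery(
            model=model,
            loci=list(loci),
            he=he_obs.copy(),
            heq_mean=mean,
            heq_sd=sd,
            dh=dh,
            p_excess=p_exc,
            sign_p=sign_test_excess(dh, p_exc),
            wilcoxon_one_tailed_p=_wilcoxon(dh, "greater"),
            wilcoxon_two_tailed_p=_wilcoxon(dh, "two-sided"),
        )
    return BottleneckReport(
        group=group,
        batteries=batteries,
        mode_shift=mode_shift(table, group),
        n_loci_used=len(loci),
        flags=flags,
    )


def mode_shift(table: GenotypeTable, group: str) -> str:
    """Allele-frequency-class mode-shift indicator.

    Alleles from all loci are pooled into ten frequency classes
    ((0,0.1], ..., (0.9,1.0]); at mutation-drift equilibrium the rarest
    class holds the most alleles ("normal L-shaped"), otherwise "shifted".
    """
    rows = table.members(group)
    freqs = []
    for locus in table.loci:
        genes = table.alleles_at(locus, rows)
        if genes.size == 0:
            continue
        _, counts = np.unique(genes, return_counts=True)
        freqs.extend(counts / genes.size)
    if not freqs:
        raise ValueError(f"no allele data in group {group!r}")
    freqs = np.asarray(freqs)
    classes = np.clip(np.ceil(freqs * 10).astype(int) - 1, 0, 9)
    hist = np.bincount(classes, minlength=10)
    return "normal L-shaped" if np.all(hist[0] > hist[1:]) else "shifted"
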