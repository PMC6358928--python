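"""Synthetic colony / population generator.

Emulates the statistical structure of an urban invasive-termite dataset:
genetic clusters with Dirichlet-divergent microsatellite allele
frequencies, colonies of three breeding structures (simple pair, extended
neotenic-inbred, mixed fusion), 20 workers per sampling point, forward
Wright–Fisher populations for bottleneck test-beds, and mtDNA haplotype
alignments generated on an explicit mutation tree.  Every emission is
reproducible from a seed, and each generator returns the ground truth
needed for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from termipop.datatypes import GenotypeTable, HaplotypeAlignment, SiteTable
from termipop.bottleneck import TpmParams, sample_coalescent_states

#: one locus = (allele codes, frequencies)
LocusFreqs = tuple[np.ndarray, np.ndarray]

#: allele counts of a highly polymorphic urban microsatellite panel
#: (2-32 alleles per locus); the allele-rich regime where colony fusion
#: is detectable from worker genotypes
ALLELE_RICH_LOCUS_COUNTS = (10, 20, 19, 32, 5, 5, 21, 10)

#: allele counts at an invasion front with strongly reduced diversity
#: (2-3 alleles per locus); extended and mixed families are then
#: indistinguishable
LOW_DIVERSITY_LOCUS_COUNTS = (3, 2, 3, 2, 2, 2)


# --------------------------------------------------------------------------
# cluster allele frequencies
# --------------------------------------------------------------------------


def simulate_cluster_frequencies(
    n_clusters: int,
    alleles_per_locus: Sequence[int],
    divergence: float = 0.2,
    dirichlet_alpha: float = 1.0,
    seed: Optional[int] = None,
    allele_offset: int = 1,
) -> list[list[LocusFreqs]]:
    """Per-cluster, per-locus allele frequencies.

    A shared base frequency vector is drawn per locus from a symmetric
    Dirichlet(``dirichlet_alpha``); each cluster then draws its own vector
    from Dirichlet(tau * base) with tau = (1 - divergence)/divergence, so
    ``divergence`` approximates the expected FST between clusters
    (divergence -> 0 gives identical clusters).

    Allele codes are consecutive integers starting at ``allele_offset``
    (spaced per locus so codes are locus-unique and usable as repeat
    scores).
    """
    rng = np.random.default_rng(seed)
    out: list[list[LocusFreqs]] = [[] for _ in range(n_clusters)]
    code_start = allele_offset
    for n_all in alleles_per_locus:
        if n_all < 1:
            raise ValueError("each locus needs >= 1 allele")
        base = rng.dirichlet(np.full(n_all, dirichlet_alpha))
        base = np.clip(base, 1e-3, None)
        base /= base.sum()
        codes = np.arange(code_start, code_start + n_all)
        code_start += n_all + 2
        for c in range(n_clusters):
            if divergence <= 0:
                p = base.copy()
            else:
                tau = (1.0 - divergence) / divergence
                p = rng.dirichlet(np.maximum(tau * base, 1e-6))
            out[c].append((codes, p))
    return out


def _draw_genotype(rng: np.random.Generator, locus: LocusFreqs) -> tuple[int, int]:
    codes, p = locus
    a, b = rng.choice(codes, size=2, p=p)
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def _draw_parent(rng: np.random.Generator, freqs: Sequence[LocusFreqs]) -> list[tuple[int, int]]:
    return [_draw_genotype(rng, loc) for loc in freqs]


def _offspring(rng, mother, father) -> list[tuple[int, int]]:
    out = []
    for gm, gf in zip(mother, father):
        a = gm[int(rng.integers(2))]
        b = gf[int(rng.integers(2))]
        out.append((a, b) if a <= b else (b, a))
    return out


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated genotypes."""

    family_type: str
    founders: list
    n_generations: int = 0
    n_neotenics: int = 0
    colony_of_point: dict = field(default_factory=dict)
    cluster_of_colony: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, indent=2)


# --------------------------------------------------------------------------
# colony pedigrees
# --------------------------------------------------------------------------


def simulate_simple_family(
    freqs: Sequence[LocusFreqs],
    n_workers: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[list[tuple[int, int]]], SimTruth]:
    """Workers as independent Mendelian offspring of one random pair."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    mother = _draw_parent(rng, freqs)
    father = _draw_parent(rng, freqs)
    workers = [_offspring(rng, mother, father) for _ in range(n_workers)]
    return workers, SimTruth("simple", [mother, father])


def simulate_extended_family(
    freqs: Sequence[LocusFreqs],
    generations: int,
    n_neotenics: int,
    n_workers: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[list[tuple[int, int]]], SimTruth]:
    """Neotenic-inbred colony: the founder pair's line breeds within itself.

    Each generation, ``n_neotenics`` offspring of random matings within the
    current reproductive pool become the next pool (selfing excluded);
    workers are offspring of random matings in the final pool.
    ``generations = 0`` reduces exactly to a simple family.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if generations > 0 and n_neotenics < 2:
        raise ValueError("need >= 2 neotenics per generation")
    mother = _draw_parent(rng, freqs)
    father = _draw_parent(rng, freqs)
    pool = [mother, father]
    for _ in range(generations):
        nxt = []
        for _ in range(n_neotenics):
            i = int(rng.integers(len(pool)))
            j = int(rng.integers(len(pool) - 1))
            if j >= i:
                j += 1
            nxt.append(_offspring(rng, pool[i], pool[j]))
        pool = nxt
    workers = []
    for _ in range(n_workers):
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        workers.append(_offspring(rng, pool[i], pool[j]))
    truth = SimTruth("extended" if generations > 0 else "simple",
                     [mother, father], generations, n_neotenics)
    return workers, truth


def simulate_mixed_family(
    freqs: Sequence[LocusFreqs],
    n_workers: int,
    mixing_fraction: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[list[tuple[int, int]]], SimTruth]:
    """Fusion colony: workers from two unrelated founding pairs.

    ``mixing_fraction`` is the share of workers from the second family;
    0 reduces to a single simple family.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if not 0.0 <= mixing_fraction <= 1.0:
        raise ValueError("mixing_fraction must be in [0, 1]")
    pairs = [(_draw_parent(rng, freqs), _draw_parent(rng, freqs)) for _ in range(2)]
    n_b = int(round(n_workers * mixing_fraction))
    workers = [_offspring(rng, *pairs[0]) for _ in range(n_workers - n_b)]
    workers += [_offspring(rng, *pairs[1]) for _ in range(n_b)]
    truth = SimTruth("mixed" if n_b > 0 else "simple",
                     [g for pair in pairs for g in pair])
    return workers, truth


def workers_to_table(
    workers: Sequence[Sequence[tuple[int, int]]],
    n_loci: Optional[int] = None,
    group: str = "colony",
    prefix: str = "w",
) -> GenotypeTable:
    """Wrap a list of worker genotype rows into a one-group table."""
    n_loci = n_loci if n_loci is not None else len(workers[0])
    loci = [f"L{k + 1}" for k in range(n_loci)]
    inds = [f"{prefix}{i + 1}" for i in range(len(workers))]
    return GenotypeTable(
        loci=loci,
        individuals=inds,
        groups=[group],
        genotypes=[list(w) for w in workers],
        group_of={i: group for i in inds},
    )


# --------------------------------------------------------------------------
# multi-point sites
# --------------------------------------------------------------------------


@dataclass
class ColonySpec:
    family_type: str  # simple | extended | mixed
    n_points: int = 1
    workers_per_point: int = 20
    generations: int = 3
    n_neotenics: int = 10
    mixing_fraction: float = 0.5


def simulate_site(
    freqs: Sequence[LocusFreqs],
    colonies: Sequence[ColonySpec],
    seed: Optional[int] = None,
    area_m2: float = 3500.0,
) -> tuple[GenotypeTable, SiteTable, SimTruth]:
    """A sampled urban site: several colonies, each at >= 1 sampling points.

    Every sampling point of a colony draws its workers from that colony's
    pedigree (extended colonies share one final neotenic pool, so points
    are genetically exchangeable).  Points are placed uniformly in a square
    of ``area_m2``; coordinates are planar meters.
    """
    rng = np.random.default_rng(seed)
    loci = [f"L{k + 1}" for k in range(len(freqs))]
    individuals, genotypes, groups, group_of = [], [], [], {}
    colony_of_point: dict[str, str] = {}
    side = float(np.sqrt(area_m2))
    xs, ys, site_ids, labels = [], [], [], []
    pt = 0
    for ci, spec in enumerate(colonies):
        cid = f"colony_{ci + 1}"
        n_total = spec.n_points * spec.workers_per_point
        if spec.family_type == "simple":
            workers, _ = simulate_simple_family(freqs, n_total, rng=rng)
        elif spec.family_type == "extended":
            workers, _ = simulate_extended_family(
                freqs, spec.generations, spec.n_neotenics, n_total, rng=rng
            )
        elif spec.family_type == "mixed":
            workers, _ = simulate_mixed_family(
                freqs, n_total, spec.mixing_fraction, rng=rng
            )
        else:
            raise ValueError(f"unknown family type {spec.family_type!r}")
        for p in range(spec.n_points):
            pt += 1
            label = f"P{pt:02d}"
            groups.append(label)
            colony_of_point[label] = cid
            site_ids.append(label)
            labels.append(label)
            xs.append(float(rng.uniform(0, side)))
            ys.append(float(rng.uniform(0, side)))
            chunk = workers[p * spec.workers_per_point:(p + 1) * spec.workers_per_point]
            for w, row in enumerate(chunk):
                uid = f"{label}_w{w + 1}"
                individuals.append(uid)
                genotypes.append(list(row))
                group_of[uid] = label
    table = GenotypeTable(loci, individuals, groups, genotypes, group_of)
    sites = SiteTable(site_ids, labels, np.asarray(xs), np.asarray(ys))
    truth = SimTruth(
        family_type=";".join(c.family_type for c in colonies),
        founders=[],
        colony_of_point=colony_of_point,
    )
    return table, sites, truth


# --------------------------------------------------------------------------
# bottleneck test-bed populations
# --------------------------------------------------------------------------


def _equilibrium_pool(
    rng: np.random.Generator, n_genes: int, theta: float, model: str, tpm: TpmParams
) -> np.ndarray:
    """Gene pool at mutation-drift equilibrium (coalescent sample)."""
    if model == "IAM":
        # Chinese-restaurant / Ewens sampling: O(n) and exact
        states = np.empty(n_genes, dtype=np.int64)
        states[0] = 0
        nxt = 1
        for i in range(1, n_genes):
            if rng.random() < theta / (theta + i):
                states[i] = nxt
                nxt += 1
            else:
                states[i] = states[int(rng.integers(i))]
        return states
    return sample_coalescent_states(rng, n_genes, theta, model, tpm)


def simulate_bottleneck_population(
    n_anc: int,
    n_crash: int,
    t_gen: int,
    n_loci: int,
    mutation_rate: float,
    model: str = "IAM",
    n_sample: int = 30,
    seed: Optional[int] = None,
    tpm: TpmParams = TpmParams(),
    group: str = "pop",
) -> GenotypeTable:
    """Wright–Fisher population sampled ``t_gen`` generations after a crash.

    The ancestral population of ``n_anc`` diploids starts at mutation-drift
    equilibrium (its 2N genes drawn as one equilibrium coalescent sample
    with theta = 4 N u); the crash resizes it to ``n_crash`` diploids
    (``n_crash = n_anc`` gives a constant-size equilibrium population), and
    ``t_gen`` further generations of drift + mutation follow before
    ``n_sample`` diploids are sampled.
    """
    if n_crash > n_anc:
        raise ValueError("n_crash must be <= n_anc")
    if n_sample > n_crash:
        raise ValueError("cannot sample more diploids than the crashed size")
    rng = np.random.default_rng(seed)
    theta = 4.0 * n_anc * mutation_rate
    rows: list[list[tuple[int, int]]] = [[] for _ in range(n_sample)]
    fresh = 10**6  # IAM novel-allele counter, per locus
    for _ in range(n_loci):
        pool = _equilibrium_pool(rng, 2 * n_anc, theta, model, tpm)
        pool = pool - pool.min() + 1  # positive allele codes
        # crash + t_gen generations of WF at the crashed size
        size = 2 * n_crash
        pool = pool[rng.integers(0, pool.size, size)]
        nxt_label = fresh
        for _ in range(t_gen):
            pool = pool[rng.integers(0, size, size)]
            n_mut = rng.binomial(size, mutation_rate)
            if n_mut:
                where = rng.choice(size, size=n_mut, replace=False)
                if model == "IAM":
                    pool[where] = np.arange(nxt_label, nxt_label + n_mut)
                    nxt_label += n_mut
                elif model == "SMM":
                    pool[where] += rng.integers(0, 2, n_mut) * 2 - 1
                else:  # TPM
                    single = rng.random(n_mut) < tpm.p_smm
                    steps = np.where(
                        single, 1, rng.geometric(tpm.geometric_p(), n_mut)
                    )
                    signs = rng.integers(0, 2, n_mut) * 2 - 1
                    pool[where] += steps * signs
        if model != "IAM":
            pool = pool - pool.min() + 1
        picks = rng.choice(size, size=2 * n_sample, replace=False)
        genes = pool[picks]
        for i in range(n_sample):
            a, b = int(genes[2 * i]), int(genes[2 * i + 1])
            rows[i].append((a, b) if a <= b else (b, a))
    inds = [f"ind{i + 1}" for i in range(n_sample)]
    return GenotypeTable(
        loci=[f"L{k + 1}" for k in range(n_loci)],
        individuals=inds,
        groups=[group],
        genotypes=rows,
        group_of={i: group for i in inds},
    )


# --------------------------------------------------------------------------
# mtDNA haplotypes
# --------------------------------------------------------------------------


def simulate_haplotypes(
    length: int,
    tree: Sequence[tuple[str, str, int]],
    seed: Optional[int] = None,
    counts: Optional[dict[str, int]] = None,
    root_label: str = "root",
    include_root: bool = True,
) -> HaplotypeAlignment:
    """Haplotypes generated by placing substitutions along an explicit tree.

    ``tree`` lists edges (parent_label, child_label, steps).  Substituted
    sites are chosen without replacement globally (infinite-sites), so
    pairwise step distances equal path sums; requesting more total steps
    than free sites raises.
    """
    rng = np.random.default_rng(seed)
    total = sum(s for _, _, s in tree)
    if total > length:
        raise ValueError(f"{total} requested steps exceed the {length} free sites")
    bases = np.array(list("ACGT"))
    root_seq = rng.choice(bases, size=length)
    free = list(rng.permutation(length))
    seqs = {root_label: root_seq.copy()}
    for parent, child, steps in tree:
        if parent not in seqs:
            raise ValueError(f"edge parent {parent!r} not yet generated; order edges root-first")
        s = seqs[parent].copy()
        for _ in range(steps):
            site = free.pop()
            cur = s[site]
            s[site] = rng.choice(bases[bases != cur])
        seqs[child] = s
    labels = list(seqs)
    if not include_root:
        labels.remove(root_label)
    return HaplotypeAlignment(
        labels=labels,
        sequences=["".join(seqs[lab]) for lab in labels],
        counts={lab: (counts or {}).get(lab, 1) for lab in labels},
    )


def write_truth(truth: SimTruth, path: Union[str, Path]) -> None:
    Path(path).write_text(truth.to_json() + "\n")
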