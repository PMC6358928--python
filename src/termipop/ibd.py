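"""Isolation by distance: linearized FST against ln geographic distance.

Within a site, pairwise theta between sampling locations is linearized as
theta/(1-theta) and correlated with the natural log of the pairwise
distances in meters; significance comes from a Mantel permutation test
(simultaneous row/column permutation of one matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from termipop.datatypes import GenotypeTable, SiteTable
from termipop.differentiation import wc_fst

logger = logging.getLogger(__name__)


def linearize_fst(theta):
    """theta / (1 - theta), elementwise; negative estimates pass through."""
    arr = np.asarray(theta, dtype=float)
    if np.any(arr >= 1.0):
        raise ValueError("theta = 1 cannot be linearized")
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(theta) else out


@dataclass
class IbdResult:
    n_locations: int
    r: float
    r2: float
    p: float
    slope: float
    flags: list


def mantel_test(
    gen: np.ndarray,
    geo: np.ndarray,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> IbdResult:
    """Mantel permutation test between two symmetric distance matrices.

    r is the Pearson correlation over the strict lower triangles; the null
    permutes the location labels of the genetic matrix; the one-tailed p
    (positive association) uses the add-one estimator.  Also reports the
    least-squares slope of gen on geo (the IBD regression slope).
    """
    gen = np.asarray(gen, dtype=float)
    geo = np.asarray(geo, dtype=float)
    if gen.shape != geo.shape or gen.shape[0] != gen.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = gen.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 locations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    il = np.tril_indices(n, k=-1)
    x = geo[il]
    y = gen[il]
    flags = []
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance distance triangle: Mantel r undefined")
        return IbdResult(n, float("nan"), float("nan"), 1.0, float("nan"),
                         ["zero-variance matrix"])
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = gen[np.ix_(perm, perm)][il]
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return IbdResult(n, r_obs, r_obs**2, float(p), slope, flags)


def ibd_within_site(
    table: GenotypeTable,
    sites: SiteTable,
    groups: Optional[Sequence[str]] = None,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> IbdResult:
    """IBD analysis across the sampling locations of one site.

    Pairwise Weir–Cockerham theta between locations (computed even within a
    single colony), linearized, against ln distance in meters.  Distances of
    0 m between distinct locations are replaced by half the smallest nonzero
    distance before taking logs.
    """
    groups = list(groups) if groups is not None else list(table.groups)
    n = len(groups)
    theta = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = wc_fst(table, [groups[i], groups[j]])
            theta[i, j] = theta[j, i] = 0.0 if np.isnan(res.theta) else res.theta
    gen = linearize_fst(np.clip(theta, None, 0.999999))
    dist = sites.pairwise_distances(groups)
    off = ~np.eye(n, dtype=bool)
    nz = dist[off & (dist > 0)]
    if nz.size == 0:
        raise ValueError("all pairwise distances are zero")
    floor = nz.min() / 2.0
    dist = np.where(off & (dist <= 0), floor, dist)
    geo = np.zeros_like(dist)
    geo[off] = np.log(dist[off])
    return mantel_test(gen, geo, n_perm=n_perm, seed=seed)


def fst_matrix(
    table: GenotypeTable, groups: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus theta estimates."""
    groups = list(groups) if groups is not None else list(table.groups)
    m = pd.DataFrame(np.zeros((len(groups), len(groups))), index=groups, columns=groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            res = wc_fst(table, [groups[i], groups[j]])
            m.iloc[i, j] = m.iloc[j, i] = res.theta
    return m
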