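"""Demographic and spatial statistics of the burial community.

Exact binomial confidence intervals for sex ratios, occupation-duration
arithmetic from generation counts, permutation tests for within-category
grave distances (e.g. father vs subadult son), a Mantel test of spatial
against genetic distance, and uniparental-haplogroup diversity summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import beta

from .datatypes import IndividualRecord
from .pedigree import MOTHER, PedigreeGraph

GENERATION_YEARS = 28.0


@dataclass(frozen=True)
class ProportionCI:
    """Exact (Clopper-Pearson) binomial confidence interval."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def point(self) -> float:
        return self.successes / self.trials

    @property
    def ratio(self) -> str:
        """The x:1 ratio of successes to failures, as printed in reports."""
        failures = self.trials - self.successes
        if failures == 0:
            return f"{self.successes}:0"
        r = self.successes / failures
        return f"{r:.2g}:1"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError("CI does not bracket the point estimate")


def proportion_ci(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Clopper-Pearson interval from Beta quantiles.

    The boundary cases are exact: zero successes give a lower bound of 0,
    and all successes an upper bound of 1.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    alpha = 1.0 - level
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k, n, level, lower, upper)


def occupation_duration(
    n_generations: tuple[int, int], generation_years: float = GENERATION_YEARS
) -> tuple[float, float]:
    """Site-use duration implied by a range of reproductive generations."""
    lo, hi = n_generations
    if lo < 0 or hi < 0 or generation_years < 0:
        raise ValueError("negative input")
    return (lo * generation_years, hi * generation_years)


@dataclass(frozen=True)
class DistanceTestResult:
    category: str
    n_pairs: int
    mean_distance: float
    p_value: float
    n_permutations: int
    seed: int
    degenerate: bool = False


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.hypot(d[:, 0], d[:, 1])


def category_distance_test(
    coords: dict[str, tuple[float, float]],
    pairs: Sequence[tuple[str, str]],
    category: str = "",
    n_perm: int = 9_999,
    seed: int = 0,
) -> DistanceTestResult:
    """Are category pairs buried closer together than chance?

    The statistic is the mean Euclidean grave distance over the category's
    pairs; the null redraws it after permuting which individual lies in
    which grave (coordinates fixed, identities shuffled), keeping the pair
    structure. One-sided: small distances are extreme. ``p`` has resolution
    1/(n_perm+1) and is exact-valid under exchangeability.
    """
    if len(pairs) == 0:
        raise ValueError(f"category {category!r} has no pairs")
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    ids = sorted(coords)
    index = {ind: i for i, ind in enumerate(ids)}
    missing = [i for p in pairs for i in p if i not in index]
    if missing:
        raise ValueError(f"pair members without coordinates: {sorted(set(missing))}")
    xy = np.array([coords[i] for i in ids], dtype=float)
    pair_idx = np.array([(index[a], index[b]) for a, b in pairs], dtype=int)

    observed = float(_pair_distances(xy, pair_idx).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(len(ids))
        null[r] = _pair_distances(xy[perm], pair_idx).mean()
    p = (1.0 + np.sum(null <= observed)) / (1.0 + n_perm)
    degenerate = bool(np.allclose(null, observed))
    return DistanceTestResult(
        category=category,
        n_pairs=len(pairs),
        mean_distance=observed,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        degenerate=degenerate,
    )


def mantel_test(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 9_999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: correlation of two distance matrices by permutation.

    ``r`` is the Pearson correlation of the upper-triangle entries; the
    null distribution permutes rows and columns of the second matrix
    jointly. Returns ``(r, p)``.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    for name, m in (("first", a), ("second", b)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"{name} matrix is not square")
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError(f"{name} matrix has nonzero diagonal")
    if a.shape != b.shape:
        raise ValueError("matrix size mismatch")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    za = (va - va.mean()) / va.std()

    def corr(v: np.ndarray) -> float:
        return float(np.mean(za * (v - v.mean()) / v.std()))

    r_obs = corr(vb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = corr(b[np.ix_(perm, perm)][iu])
        if alternative == "greater":
            count += r >= r_obs
        elif alternative == "less":
            count += r <= r_obs
        else:
            count += abs(r) >= abs(r_obs)
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, float(p)


def haplogroup_summary(
    metadata: Sequence[IndividualRecord],
    pedigrees: Iterable[PedigreeGraph] = (),
) -> dict:
    """Uniparental-marker diversity and mitochondrial transmission depth.

    Transmission depth of an mt haplogroup is the longest mother-to-child
    chain carrying it inside the assembled pedigrees (0 = never observed
    transmitted; in an exogamous community most labels arrive with one
    mother and stop after her children, depth 1).
    """
    mt = [r.mt_hg for r in metadata if r.mt_hg]
    y = [r.y_hg for r in metadata if r.y_hg]
    rec = {r.id: r for r in metadata}

    depths: dict[str, int] = {label: 0 for label in set(mt)}
    for g in pedigrees:
        def mt_of(node):
            if node in rec:
                return rec[node].mt_hg
            return g.nodes[node].get("mt_hg")

        chain: dict[str, int] = {}
        for node in nx.topological_sort(g):
            label = mt_of(node)
            if not label:
                continue
            mother = g.parent_of(node, MOTHER)
            if mother is not None and mt_of(mother) == label:
                chain[node] = chain.get(mother, 0) + 1
            else:
                chain[node] = 0
            depths[label] = max(depths.get(label, 0), chain[node])

    depth_values = sorted(depths.values())
    positive = [d for d in depth_values if d > 0]
    modal = 0
    if positive:
        counts = Counter(positive)
        top = max(counts.values())
        modal = min(d for d, c in counts.items() if c == top)
    return {
        "n_individuals_mt": len(mt),
        "n_mt_haplogroups": len(set(mt)),
        "n_individuals_y": len(y),
        "n_y_haplogroups": len(set(y)),
        "mt_transmission_depth": depths,
        "max_mt_transmission_depth": max(depth_values) if depth_values else 0,
        "modal_mt_transmission_depth": modal,
    }


def pairwise_distance_matrix(
    coords: dict[str, tuple[float, float]], ids: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, list[str]]:
    """Euclidean grave-distance matrix over ``ids`` (sorted by default)."""
    ids = sorted(coords) if ids is None else list(ids)
    xy = np.array([coords[i] for i in ids], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1]), ids


def genetic_distance_matrix(table: pd.DataFrame, ids: Sequence[str]) -> np.ndarray:
    """Normalized-PMR distance matrix from a relatedness table."""
    index = {ind: i for i, ind in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for row in table.itertuples(index=False):
        if row.id1 in index and row.id2 in index:
            i, j = index[row.id1], index[row.id2]
            m[i, j] = m[j, i] = row.norm_pmr
    return m
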