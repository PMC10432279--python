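"""Pairwise-mismatch-rate kinship classification.

The pairwise mismatch rate (PMR) of two pseudo-haploid call vectors is the
fraction of jointly covered sites at which they disagree. Between unrelated
members of one population it fluctuates around a background rate ``p0``;
sharing genome IBD lowers it by a factor determined by the degree of
relatedness:

    expected PMR at degree d  =  p0 * (1 - 2^-(d+1))

so identical genomes (or two samplings of one individual) sit at p0/2,
first-degree pairs at 0.75*p0, second-degree at 0.875*p0, and so on toward
p0. Classification treats the mismatch count as binomial and assigns a
posterior over degree classes; parent-offspring and full siblings, both
first degree, are separated by the distribution of PMR along the genome in
fixed genetic-length windows: parent-offspring pairs are IBD1 everywhere
(flat profile) whereas sibling genomes mix IBD 0/1/2 in 1/4:1/2:1/4
proportions (heterogeneous profile).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .datatypes import MISSING, IndividualRecord, PseudoHaploidMatrix, SNPPanel

logger = logging.getLogger(__name__)

UNRELATED = "UNRELATED"
PARENT_OFFSPRING = "PARENT_OFFSPRING"
SIBLING = "SIBLING"
INDETERMINATE = "INDETERMINATE"

#: default degree classes, nearest first
DEFAULT_CLASSES: tuple = (0, 1, 2, UNRELATED)
#: extended classes for deeper (low-confidence) calls
EXTENDED_CLASSES: tuple = (0, 1, 2, 3, 4, 5, UNRELATED)

DEFAULT_MIN_OVERLAP = 5_000
DEFAULT_WINDOW_CM = 20.0
MIN_SITES_PER_WINDOW = 50

#: background-trim threshold: halfway (in normalized PMR) between third
#: degree (0.9375) and fourth degree (0.96875); pairs below it are treated
#: as provisional relatives when estimating the background rate. A looser
#: trim that keeps third-degree pairs biases the background several percent
#: low in pedigree-dense cohorts, which misclassifies first-degree pairs
#: as second degree.
BACKGROUND_TRIM = 0.953125

LOW_OVERLAP = "LOW_OVERLAP"


@dataclass(frozen=True)
class PairwiseStats:
    """Mismatch summary for one unordered pair."""

    id1: str
    id2: str
    n: int  # jointly covered sites
    k: int  # mismatching sites
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")

    @property
    def pmr(self) -> float:
        return self.k / self.n if self.n else math.nan

    @property
    def se(self) -> float:
        if self.n == 0:
            return math.nan
        p = self.pmr
        return math.sqrt(p * (1.0 - p) / self.n)

    def normalized(self, p0: float) -> float:
        return self.pmr / p0


@dataclass(frozen=True)
class BackgroundRate:
    """Unrelated-pair PMR baseline from the robust iterative median."""

    p0: float
    n_pairs_used: int
    iterations: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"background rate {self.p0} outside (0, 1)")


@dataclass(frozen=True)
class DegreePosterior:
    """Posterior over degree classes for one pair."""

    probabilities: dict  # class -> posterior probability
    chosen: object  # degree class with maximal posterior
    n: int
    k: int
    p0: float

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, not 1")
        best = max(self.probabilities.values())
        if self.probabilities[self.chosen] < best - 1e-12:
            raise ValueError("chosen class is not the posterior mode")


@dataclass
class WindowSeries:
    """Per-window mismatch counts along the genome for one pair."""

    id1: str
    id2: str
    table: pd.DataFrame  # chrom, g_start, g_end, n, k, pmr, usable

    def usable(self) -> pd.DataFrame:
        return self.table[self.table["usable"]]


def pairwise_mismatch(
    matrix: PseudoHaploidMatrix,
    i: str,
    j: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PairwiseStats:
    """Count overlapping and mismatching sites for one pair.

    Only sites non-missing in both individuals enter ``n``; the pair is
    flagged LOW_OVERLAP when fewer than ``min_overlap`` remain.
    """
    a = matrix.row(i)
    b = matrix.row(j)
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    k = int((a[both] != b[both]).sum())
    flags = (LOW_OVERLAP,) if n < min_overlap else ()
    first, second = sorted((i, j))
    return PairwiseStats(first, second, n, k, flags)


def estimate_background(
    stats: Iterable[PairwiseStats],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    trim: float = BACKGROUND_TRIM,
    max_iter: int = 10,
    init_quantile: float = 0.95,
) -> BackgroundRate:
    """Robust background PMR from the unrelated-pair cluster.

    Relatedness only lowers the PMR, so the top of the pairwise PMR
    distribution is formed by genuinely unrelated pairs. The estimate
    starts from a high quantile (robust even when most pairs in a
    pedigree-dense cohort are relatives), then iteratively excludes pairs
    whose PMR falls below ``trim`` times the current estimate (provisional
    relatives) and re-takes the median over the retained pairs, until the
    retained set is stable or ``max_iter`` rounds have run.
    """
    pmrs = np.array([s.pmr for s in stats if s.n >= min_overlap])
    if len(pmrs) < 3:
        raise ValueError(f"need >= 3 pairs with overlap >= {min_overlap}, got {len(pmrs)}")
    p0 = float(np.quantile(pmrs, init_quantile))
    kept = np.zeros(len(pmrs), dtype=bool)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_kept = pmrs >= trim * p0
        if not new_kept.any():
            break
        if np.array_equal(new_kept, kept):
            break
        kept = new_kept
        p0 = float(np.median(pmrs[kept]))
    return BackgroundRate(p0=p0, n_pairs_used=int(kept.sum()), iterations=iterations)


def expected_pmr(degree, p0: float) -> float:
    """Expected PMR at a relatedness degree: ``p0 * (1 - 2^-(d+1))``.

    Degree 0 (one individual sampled twice, identical twins) halves the
    background; each further degree halves the remaining deficit.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} outside (0, 1)")
    if degree == UNRELATED:
        return p0
    d = int(degree)
    if d < 0:
        raise ValueError("degree must be >= 0")
    return p0 * (1.0 - 2.0 ** -(d + 1))


def _class_order(cls) -> float:
    """Sort key placing closer relationships first, UNRELATED last."""
    return math.inf if cls == UNRELATED else float(cls)


def classify_degree(
    stats: PairwiseStats,
    p0: float,
    prior: Optional[dict] = None,
    classes: Sequence = DEFAULT_CLASSES,
) -> DegreePosterior:
    """Binomial posterior over degree classes for one pair.

    The mismatch count k is modelled Binomial(n, p_d) with p_d the expected
    PMR of each class; the posterior combines the binomial likelihoods with
    the prior (uniform by default) in log space. Exact posterior ties break
    toward the more distant class.
    """
    classes = list(classes)
    if prior is None:
        prior = {c: 1.0 / len(classes) for c in classes}
    n, k = stats.n, stats.k
    if n == 0:
        total = sum(prior[c] for c in classes)
        probs = {c: prior[c] / total for c in classes}
    else:
        logpost = np.array(
            [math.log(prior[c]) + binom.logpmf(k, n, expected_pmr(c, p0)) for c in classes]
        )
        logpost -= logsumexp(logpost)
        probs = {c: float(p) for c, p in zip(classes, np.exp(logpost))}
        total = sum(probs.values())
        probs = {c: p / total for c, p in probs.items()}
    best_p = max(probs.values())
    tied = [c for c, p in probs.items() if p >= best_p - 1e-12]
    chosen = max(tied, key=_class_order)
    if len(tied) > 1:
        logger.warning(
            "pair %s-%s: posterior tie among %s; choosing %s", stats.id1, stats.id2, tied, chosen
        )
    return DegreePosterior(probabilities=probs, chosen=chosen, n=n, k=k, p0=p0)


def windowed_pmr(
    matrix: PseudoHaploidMatrix,
    i: str,
    j: str,
    panel: SNPPanel,
    window_cm: float = DEFAULT_WINDOW_CM,
    min_sites: int = MIN_SITES_PER_WINDOW,
) -> WindowSeries:
    """Mismatch counts in fixed genetic-length windows along each chromosome.

    Windows with fewer than ``min_sites`` jointly covered sites are kept in
    the table but flagged unusable.
    """
    a = matrix.row(i)
    b = matrix.row(j)
    both = (a != MISSING) & (b != MISSING)
    mism = both & (a != b)
    win_m = window_cm / 100.0
    rows = []
    for c in panel.chromosomes():
        sel = panel.chrom == c
        gpos = panel.gpos[sel]
        if len(gpos) == 0:
            continue
        g0 = 0.0
        n_windows = max(1, math.ceil((gpos.max() - g0) / win_m + 1e-12))
        idx = np.minimum(((gpos - g0) / win_m).astype(int), n_windows - 1)
        n_w = np.bincount(idx, weights=both[sel].astype(float), minlength=n_windows)
        k_w = np.bincount(idx, weights=mism[sel].astype(float), minlength=n_windows)
        for w in range(n_windows):
            n_sites_w = int(n_w[w])
            rows.append(
                {
                    "chrom": c,
                    "g_start": g0 + w * win_m,
                    "g_end": g0 + (w + 1) * win_m,
                    "n": n_sites_w,
                    "k": int(k_w[w]),
                    "pmr": k_w[w] / n_sites_w if n_sites_w else math.nan,
                    "usable": n_sites_w >= min_sites,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty or not table["usable"].any():
        raise ValueError(f"pair {i}-{j}: no usable windows")
    return WindowSeries(*sorted((i, j)), table=table)


#: IBD-state weights for full siblings and their relative mismatch rates
_SIB_WEIGHTS = np.log(np.array([0.25, 0.5, 0.25]))
_SIB_RATE_FACTORS = np.array([1.0, 0.75, 0.5])  # IBD0, IBD1, IBD2


def classify_po_vs_sibling(
    series: WindowSeries, p0: float, min_windows: int = 10
) -> tuple[str, float]:
    """Separate parent-offspring from full siblings by windowed PMR.

    Parent-offspring model: every window Binomial(n_w, 0.75*p0).
    Sibling model: per-window mixture over IBD state s in {0,1,2} with
    weights (1/4, 1/2, 1/4) and rates (p0, 0.75*p0, 0.5*p0).
    Returns the winning model and the summed log-Bayes-factor
    (positive favours parent-offspring).
    """
    usable = series.usable()
    if len(usable) < min_windows:
        return INDETERMINATE, 0.0
    n_w = usable["n"].to_numpy()
    k_w = usable["k"].to_numpy()
    log_po = binom.logpmf(k_w, n_w, 0.75 * p0)
    rates = _SIB_RATE_FACTORS * p0
    comp = binom.logpmf(k_w[:, None], n_w[:, None], rates[None, :]) + _SIB_WEIGHTS[None, :]
    log_sib = logsumexp(comp, axis=1)
    log_bf = float(np.sum(log_po - log_sib))
    call = PARENT_OFFSPRING if log_bf > 0 else SIBLING
    return call, log_bf


def relatedness_table(
    matrix: PseudoHaploidMatrix,
    panel: Optional[SNPPanel] = None,
    metadata: Optional[Sequence[IndividualRecord]] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    window_cm: float = DEFAULT_WINDOW_CM,
    classes: Sequence = DEFAULT_CLASSES,
    background: Optional[BackgroundRate] = None,
) -> pd.DataFrame:
    """Classify every unordered pair of individuals.

    The background rate is estimated internally from the pair set unless
    given. Degree-1 pairs are sub-classified parent-offspring vs sibling
    from their windowed PMR profile when a panel with genetic positions is
    supplied.
    """
    ids = matrix.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    stats = [pairwise_mismatch(matrix, a, b, min_overlap) for a, b in combinations(ids, 2)]
    if background is None:
        background = estimate_background(stats, min_overlap=min_overlap)
    p0 = background.p0

    rows = []
    for s in stats:
        flags = list(s.flags)
        if LOW_OVERLAP in flags:
            row = {
                "id1": s.id1,
                "id2": s.id2,
                "n": s.n,
                "k": s.k,
                "pmr": s.pmr,
                "se": s.se,
                "norm_pmr": s.normalized(p0),
                "call": INDETERMINATE,
                "po_sib_call": "",
                "log_bf": math.nan,
            }
            for c in classes:
                row[f"P({c})"] = math.nan
        else:
            post = classify_degree(s, p0, classes=classes)
            row = {
                "id1": s.id1,
                "id2": s.id2,
                "n": s.n,
                "k": s.k,
                "pmr": s.pmr,
                "se": s.se,
                "norm_pmr": s.normalized(p0),
                "call": post.chosen,
                "po_sib_call": "",
                "log_bf": math.nan,
            }
            for c in classes:
                row[f"P({c})"] = post.probabilities[c]
            if post.chosen == 1 and panel is not None:
                try:
                    series = windowed_pmr(matrix, s.id1, s.id2, panel, window_cm)
                    call, log_bf = classify_po_vs_sibling(series, p0)
                    row["po_sib_call"] = call
                    row["log_bf"] = log_bf
                    if call == INDETERMINATE:
                        flags.append("PO_SIB_INDETERMINATE")
                except ValueError:
                    row["po_sib_call"] = INDETERMINATE
                    flags.append("PO_SIB_INDETERMINATE")
        row["flags"] = ";".join(flags)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["background"] = background
    return table
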