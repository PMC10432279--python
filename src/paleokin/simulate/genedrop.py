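"""Gene dropping through a pedigree with recombination, and the
pseudo-haploid single-read degradation applied afterwards.

Founders receive independent haplotypes drawn site-wise from a truncated
Beta allele-frequency law. Children inherit one recombined gamete from each
parent: the crossover count per chromosome is Poisson in its genetic length
(Haldane model, no interference) with breakpoints uniform on the genetic
map. Alongside each allele the engine carries the label of the founder
haplotype it descends from, which provides exact identity-by-descent truth
for any pair of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..datatypes import MISSING, PseudoHaploidMatrix, SNPPanel
from .config import SimulationConfig
from .pedigree import TruePedigree


def make_panel(config: SimulationConfig, rng: np.random.Generator) -> SNPPanel:
    """Draw a SNP panel: sites uniform in physical position, linear genetic map."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms, poss, gposs = [], [], []
    rate = config.morgans_per_chromosome / config.bp_per_chromosome
    for c in range(config.n_chromosomes):
        n = int(per_chrom[c])
        # rejection sampling of distinct positions; collisions are rare at
        # panel densities far below 1 site/bp
        pos = np.unique(rng.integers(1, config.bp_per_chromosome + 1, size=int(n * 1.05) + 8))
        while len(pos) < n:
            extra = rng.integers(1, config.bp_per_chromosome + 1, size=n)
            pos = np.unique(np.concatenate((pos, extra)))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        chroms.append(np.full(n, str(c + 1), dtype=object))
        poss.append(pos)
        gposs.append(pos * rate)
    alleles = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, size=config.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_snps)) % 4
    return SNPPanel(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        gpos=np.concatenate(gposs),
        ref=alleles[ref_idx],
        alt=alleles[alt_idx],
    )


@dataclass
class DiploidGenomes:
    """Diploid alleles and founder-haplotype ancestry labels per individual.

    ``alleles[i, h, s]`` is the REF/ALT allele on haplotype ``h`` of
    individual ``ids[i]`` at site ``s``; ``labels`` carries the founder
    haplotype id each position descends from (the IBD-truth sidecar).
    """

    ids: list[str]
    alleles: np.ndarray  # int8,  (n, 2, n_sites)
    labels: np.ndarray  # int32, (n, 2, n_sites)
    founder_freq: np.ndarray  # float, (n_sites,)

    def index_of(self, ind: str) -> int:
        try:
            return self.ids.index(ind)
        except ValueError:
            raise KeyError(f"unknown individual {ind!r}") from None

    def ibd_states(self, a: str, b: str) -> np.ndarray:
        """Per-site IBD state (0, 1 or 2) between two individuals."""
        la = self.labels[self.index_of(a)]
        lb = self.labels[self.index_of(b)]
        m11 = la[0] == lb[0]
        m12 = la[0] == lb[1]
        m21 = la[1] == lb[0]
        m22 = la[1] == lb[1]
        ibd2 = (m11 & m22) | (m12 & m21)
        ibd1 = (m11 | m12 | m21 | m22) & ~ibd2
        return ibd2.astype(np.int8) * 2 + ibd1.astype(np.int8)

    def subset(self, keep: list[str]) -> "DiploidGenomes":
        idx = [self.index_of(i) for i in keep]
        return DiploidGenomes(
            list(keep), self.alleles[idx], self.labels[idx], self.founder_freq
        )


def draw_founder_frequencies(
    config: SimulationConfig, rng: np.random.Generator, n_sites: Optional[int] = None
) -> np.ndarray:
    """ALT allele frequencies: Beta(a, b) truncated by rejection to the
    configured band."""
    n = config.n_snps if n_sites is None else n_sites
    f = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.beta(config.founder_freq_alpha, config.founder_freq_beta, size=int(need.sum()))
        f[need] = draw
        need = (f < config.founder_freq_min) | (f > config.founder_freq_max)
    return f


def _chrom_slices(panel: SNPPanel) -> list[tuple[slice, np.ndarray]]:
    """Contiguous (slice, gpos) per chromosome; panel sites are stored in
    chromosome blocks."""
    out = []
    start = 0
    for c in panel.chromosomes():
        n = int(np.sum(panel.chrom == c))
        sl = slice(start, start + n)
        out.append((sl, panel.gpos[sl]))
        start += n
    return out


def _meiosis_mask(
    slices: list[tuple[slice, np.ndarray]],
    n_sites: int,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete's per-site choice of parental haplotype (0/1)."""
    mask = np.empty(n_sites, dtype=np.intp)
    for sl, gpos in slices:
        n_x = rng.poisson(length)
        breaks = np.sort(rng.uniform(0.0, length, size=n_x))
        start = rng.integers(0, 2)
        mask[sl] = (start + np.searchsorted(breaks, gpos)) % 2
    return mask


def drop_genes(
    pedigree: TruePedigree,
    panel: SNPPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    founder_freq: Optional[np.ndarray] = None,
) -> DiploidGenomes:
    """Simulate diploid genomes for every pedigree node.

    Nodes are processed in generation order so both parental genomes exist
    when a child's gametes are formed; Mendelian consistency holds by
    construction.
    """
    if panel.gpos is None:
        raise ValueError("panel lacks genetic positions")
    ids = sorted(pedigree.nodes, key=lambda i: (pedigree.nodes[i].generation, i))
    index = {ind: k for k, ind in enumerate(ids)}
    n, S = len(ids), panel.n_sites
    alleles = np.empty((n, 2, S), dtype=np.int8)
    labels = np.empty((n, 2, S), dtype=np.int32)
    f = founder_freq if founder_freq is not None else draw_founder_frequencies(config, rng, S)
    if len(f) != S:
        raise ValueError("founder_freq length != panel size")

    slices = _chrom_slices(panel)
    site_idx = np.arange(S)
    next_label = 0
    for ind in ids:
        node = pedigree.nodes[ind]
        k = index[ind]
        for h, parent in enumerate((node.mother_id, node.father_id)):
            if parent is None:
                alleles[k, h] = (rng.random(S) < f).astype(np.int8)
                labels[k, h] = next_label
                next_label += 1
            else:
                p = index[parent]
                mask = _meiosis_mask(slices, S, config.morgans_per_chromosome, rng)
                alleles[k, h] = alleles[p, mask, site_idx]
                labels[k, h] = labels[p, mask, site_idx]
    return DiploidGenomes(ids, alleles, labels, f)


def sample_pseudohaploid(
    diploid: DiploidGenomes,
    config: SimulationConfig,
    rng: np.random.Generator,
    ids: Optional[list[str]] = None,
) -> PseudoHaploidMatrix:
    """Degrade diploid genomes to pseudo-haploid single-read calls.

    Per site: read depth ~ Poisson(coverage); zero depth is a missing call;
    otherwise one chromosome copy is sampled uniformly and its allele
    misread with probability ``error_rate``.
    """
    keep = ids if ids is not None else diploid.ids
    idx = [diploid.index_of(i) for i in keep]
    n, S = len(idx), diploid.alleles.shape[2]
    cov = rng.poisson(config.coverage, size=(n, S))
    hap = rng.integers(0, 2, size=(n, S))
    rows = np.asarray(idx)[:, None]
    calls = diploid.alleles[rows, hap, np.arange(S)[None, :]].astype(np.int8)
    if config.error_rate > 0:
        flip = rng.random((n, S)) < config.error_rate
        calls[flip] = 1 - calls[flip]
    calls[cov == 0] = MISSING
    return PseudoHaploidMatrix(list(keep), calls)


def segment_table(diploid: DiploidGenomes, panel: SNPPanel) -> "pd.DataFrame":
    """Ancestry segments as a BED-like table (chrom, start, end, individual,
    haplotype, founder label), one row per run of constant founder label."""
    import pandas as pd

    rows = []
    for k, ind in enumerate(diploid.ids):
        for h in range(2):
            lab = diploid.labels[k, h]
            for c in panel.chromosomes():
                sel = np.flatnonzero(panel.chrom == c)
                lc = lab[sel]
                pos = panel.pos[sel]
                change = np.flatnonzero(np.diff(lc) != 0)
                starts = np.concatenate(([0], change + 1))
                ends = np.concatenate((change, [len(lc) - 1]))
                for s, e in zip(starts, ends):
                    rows.append(
                        {
                            "chrom": c,
                            "start": int(pos[s]) - 1,
                            "end": int(pos[e]),
                            "individual": ind,
                            "haplotype": h,
                            "founder_label": int(lc[s]),
                        }
                    )
    return pd.DataFrame(rows)
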