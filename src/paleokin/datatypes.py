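"""Core containers shared across the pipeline.

Genotypes are stored pseudo-haploid: one sampled allele per individual per
site, encoded in a dense ``int8`` matrix with ``0`` = reference allele,
``1`` = alternate allele and ``-1`` = missing. This is the standard
representation for low-coverage ancient-DNA data where diploid calls are
unattainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

REF: int = 0
ALT: int = 1
MISSING: int = -1

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

#: genetic sex calls
XX = "XX"
XY = "XY"
INDETERMINATE = "INDETERMINATE"

#: age-at-death classes
SUBADULT = "SUBADULT"
ADULT = "ADULT"


@dataclass(frozen=True)
class SNPPanel:
    """SNP site coordinates: the panel every genotype column refers to.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per site (autosomes ``"1"``..``"22"``).
    pos : array of int
        Physical position, base pairs, 1-based.
    gpos : array of float
        Genetic position in Morgans, non-decreasing within a chromosome.
    ref, alt : arrays of single characters
        The two observed alleles at each site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    gpos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom)
        for name in ("pos", "gpos", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} length != {n}")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            p = self.pos[sel]
            g = self.gpos[sel]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(g) < 0):
                raise ValueError(f"genetic positions decreasing on chromosome {c}")
        if np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ at every site")

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c))
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "gpos": self.gpos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


@dataclass
class PseudoHaploidMatrix:
    """Individuals x sites matrix of pseudo-haploid calls.

    ``calls[i, s]`` is ``REF``/``ALT``/``MISSING`` for individual ``ids[i]``
    at panel site ``s``.
    """

    ids: list[str]
    calls: np.ndarray  # int8, shape (n_individuals, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x sites)")
        if self.calls.shape[0] != len(self.ids):
            raise ValueError("row count != number of individual ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError("calls must be REF/ALT/MISSING")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def index_of(self, individual: str) -> int:
        try:
            return self.ids.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual id {individual!r}") from None

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.index_of(individual)]

    def covered_counts(self) -> np.ndarray:
        """Number of non-missing calls per individual."""
        return (self.calls != MISSING).sum(axis=1)

    def subset(self, keep: list[str]) -> "PseudoHaploidMatrix":
        idx = [self.index_of(i) for i in keep]
        return PseudoHaploidMatrix(list(keep), self.calls[idx].copy())


@dataclass
class IndividualRecord:
    """Per-individual metadata used as pedigree constraints."""

    id: str
    sex: str  # XX / XY / INDETERMINATE
    age_class: Optional[str] = None  # SUBADULT / ADULT
    age_min: Optional[float] = None
    age_max: Optional[float] = None
    mt_hg: Optional[str] = None
    y_hg: Optional[str] = None
    grave_x: Optional[float] = None
    grave_y: Optional[float] = None
    generation: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in (XX, XY, INDETERMINATE):
            raise ValueError(f"{self.id}: invalid sex {self.sex!r}")
        if self.age_class is not None and self.age_class not in (SUBADULT, ADULT):
            raise ValueError(f"{self.id}: invalid age class {self.age_class!r}")
        if self.y_hg is not None and self.sex != XY:
            raise ValueError(f"{self.id}: Y haplogroup given for non-XY individual")
        if (
            self.age_min is not None
            and self.age_max is not None
            and self.age_min > self.age_max
        ):
            raise ValueError(f"{self.id}: age_min > age_max")

    @property
    def has_coords(self) -> bool:
        return self.grave_x is not None and self.grave_y is not None


@dataclass(frozen=True)
class ReadCountProfile:
    """Mapped-read counts per chromosome class, for genetic sexing."""

    autosomal_reads: int
    autosomal_target_bp: int
    x_reads: int
    x_target_bp: int
    y_reads: int
    y_target_bp: int

    def __post_init__(self) -> None:
        for f in ("autosomal_reads", "x_reads", "y_reads"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        for f in ("autosomal_target_bp", "x_target_bp", "y_target_bp"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
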