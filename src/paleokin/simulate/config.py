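"""Configuration for the synthetic burial-community generator."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class SimulationConfig:
    """Parameters of the synthetic patrilineal community.

    The generator emulates a multi-generation patrilocal, patrilineal group
    with female exogamy: sons stay and reproduce with in-migrating unrelated
    mothers, most adult daughters leave (and are therefore absent from the
    burial record). Genotypes are produced by gene dropping over a SNP panel
    with recombination, then degraded to pseudo-haploid single-read calls
    with Poisson per-site coverage and symmetric read error.

    Attributes
    ----------
    n_generations : int
        Number of generations spanned by the pedigree (founders = 1).
    mean_offspring : float
        Poisson mean number of children per union.
    daughter_outmigration_prob : float
        Probability that an adult daughter leaves the community (unsampled).
    subadult_death_prob : float
        Probability a child dies before adulthood (buried as SUBADULT,
        never reproduces).
    mother_sampled_prob : float
        Probability an in-migrating mother is buried at the site.
    endogamy_prob : float
        Probability a union partner is a stay-at-home lineage daughter
        instead of an unrelated immigrant (off by default).
    n_snps, n_chromosomes, morgans_per_chromosome, bp_per_chromosome :
        Panel structure; sites are uniform in physical position with a
        linear genetic map.
    founder_freq_alpha/beta, founder_freq_min/max :
        Truncated Beta law for founder ALT allele frequencies.
    coverage : float
        Poisson mean per-site read depth; depth 0 yields a missing call.
    error_rate : float
        Per-read probability that the sampled allele is misread.
    sigma_within, cluster_spacing, father_son_shrink :
        Grave layout: Gaussian scatter (m) of lineage members around their
        patriline cluster centre, spacing between cluster centres, and the
        multiplicative shrink applied to the scatter of subadult sons
        around their father.
    """

    seed: int = 0
    n_generations: int = 5
    mean_offspring: float = 3.0
    daughter_outmigration_prob: float = 0.8
    subadult_death_prob: float = 0.2
    mother_sampled_prob: float = 0.7
    endogamy_prob: float = 0.0
    n_founder_couples: int = 1

    n_snps: int = 50_000
    n_chromosomes: int = 22
    morgans_per_chromosome: float = 1.5
    bp_per_chromosome: int = 130_000_000

    founder_freq_alpha: float = 0.5
    founder_freq_beta: float = 0.5
    founder_freq_min: float = 0.05
    founder_freq_max: float = 0.95

    coverage: float = 1.0
    error_rate: float = 0.01

    sigma_within: float = 3.0
    cluster_spacing: float = 15.0
    father_son_shrink: float = 0.3

    max_extinction_retries: int = 20

    def __post_init__(self) -> None:
        probs = {
            "daughter_outmigration_prob": self.daughter_outmigration_prob,
            "subadult_death_prob": self.subadult_death_prob,
            "mother_sampled_prob": self.mother_sampled_prob,
            "endogamy_prob": self.endogamy_prob,
            "error_rate": self.error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mean_offspring <= 0:
            raise ValueError("mean_offspring must be > 0")
        if self.morgans_per_chromosome <= 0:
            raise ValueError("morgans_per_chromosome must be > 0")
        if not 0 <= self.founder_freq_min < self.founder_freq_max <= 1:
            raise ValueError("founder frequency bounds invalid")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
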