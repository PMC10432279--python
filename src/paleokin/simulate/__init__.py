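"""Synthetic low-coverage ancient-DNA data with pedigree ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ..datatypes import (
    ADULT,
    SUBADULT,
    XY,
    IndividualRecord,
    PseudoHaploidMatrix,
    SNPPanel,
)
from ..eigenstrat import write_eigenstrat, write_metadata
from .config import SimulationConfig
from .genedrop import (
    DiploidGenomes,
    draw_founder_frequencies,
    drop_genes,
    make_panel,
    sample_pseudohaploid,
    segment_table,
)
from .graves import place_graves
from .pedigree import (
    LINEAL,
    NON_LINEAL,
    UNRELATED,
    PedNode,
    TruePedigree,
    generate_pedigree,
    kinship_coefficient,
    true_degree,
)

__all__ = [
    "SimulationConfig",
    "TruePedigree",
    "PedNode",
    "DiploidGenomes",
    "SimulatedDataset",
    "generate_pedigree",
    "kinship_coefficient",
    "true_degree",
    "make_panel",
    "draw_founder_frequencies",
    "drop_genes",
    "sample_pseudohaploid",
    "segment_table",
    "place_graves",
    "simulate_dataset",
    "simulate_dataset_sized",
    "pedigree_records",
    "true_degree_table",
    "UNRELATED",
    "LINEAL",
    "NON_LINEAL",
]

#: nominal age-at-death ranges (years) attached to the two age classes
AGE_RANGES = {SUBADULT: (0.0, 15.0), ADULT: (20.0, 60.0)}


def pedigree_records(
    pedigree: TruePedigree,
    coords: Optional[dict[str, tuple[float, float]]] = None,
    sampled_only: bool = True,
) -> list[IndividualRecord]:
    """Metadata records for (sampled) pedigree members."""
    records = []
    for node in pedigree.nodes.values():
        if sampled_only and not node.sampled:
            continue
        lo, hi = AGE_RANGES[node.age_class]
        xy = (coords or {}).get(node.id)
        records.append(
            IndividualRecord(
                id=node.id,
                sex=node.sex,
                age_class=node.age_class,
                age_min=lo,
                age_max=hi,
                mt_hg=node.mt_hg,
                y_hg=node.y_hg if node.sex == XY else None,
                grave_x=None if xy is None else float(xy[0]),
                grave_y=None if xy is None else float(xy[1]),
                generation=node.generation,
            )
        )
    return records


def true_degree_table(pedigree: TruePedigree, ids: Optional[list[str]] = None) -> pd.DataFrame:
    """Ground-truth degree class for every unordered pair of ``ids``."""
    ids = ids if ids is not None else pedigree.sampled_ids()
    rows = []
    for a, b in combinations(sorted(ids), 2):
        degree, lineality = true_degree(pedigree, a, b)
        rows.append({"id1": a, "id2": b, "true_degree": degree, "lineality": lineality})
    return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """Everything one synthetic community provides, truth included."""

    config: SimulationConfig
    panel: SNPPanel
    pedigree: TruePedigree
    diploid: DiploidGenomes
    matrix: PseudoHaploidMatrix  # sampled individuals only
    records: list[IndividualRecord]
    coords: dict[str, tuple[float, float]]

    def write(self, outdir: str | Path, prefix: str = "sim", segments: bool = False) -> None:
        """Write EIGENSTRAT trio, metadata, truth tables and the config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_eigenstrat(
            self.panel,
            self.matrix,
            self.records,
            outdir / f"{prefix}.geno",
            outdir / f"{prefix}.snp",
            outdir / f"{prefix}.ind",
        )
        write_metadata(self.records, outdir / f"{prefix}_metadata.tsv")
        true_degree_table(self.pedigree).to_csv(
            outdir / f"{prefix}_true_degrees.tsv", sep="\t", index=False
        )
        edges = pd.DataFrame(self.pedigree.edges(), columns=["parent", "child"])
        edges.to_csv(outdir / f"{prefix}_true_edges.tsv", sep="\t", index=False)
        self.config.to_json(outdir / f"{prefix}_config.json")
        if segments:
            segment_table(self.diploid, self.panel).to_csv(
                outdir / f"{prefix}_segments.bed", sep="\t", index=False
            )


def simulate_dataset_sized(
    config: SimulationConfig,
    min_sampled: int,
    max_sampled: Optional[int] = None,
    max_tries: int = 100,
) -> SimulatedDataset:
    """Simulate a community whose sampled size falls in a target range.

    Offspring numbers are Poisson, so the sampled cohort size varies a lot
    between runs; analyses specified for a cohort of a given size redraw
    (advancing the seed deterministically) until the pedigree matches.
    """
    for attempt in range(max_tries):
        cfg = SimulationConfig(**{**vars(config), "seed": config.seed + attempt})
        ds = simulate_dataset(cfg)
        n = ds.matrix.n_individuals
        if n >= min_sampled and (max_sampled is None or n <= max_sampled):
            return ds
    raise RuntimeError(
        f"no cohort of {min_sampled}..{max_sampled} sampled individuals in {max_tries} tries"
    )


def simulate_dataset(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedDataset:
    """Run the full generator: pedigree, genomes, pseudo-haploid calls,
    graves, metadata."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pedigree = generate_pedigree(config, rng)
    panel = make_panel(config, rng)
    diploid = drop_genes(pedigree, panel, config, rng)
    sampled = pedigree.sampled_ids()
    matrix = sample_pseudohaploid(diploid, config, rng, ids=sorted(sampled))
    coords = place_graves(pedigree, config, rng)
    records = pedigree_records(pedigree, coords)
    return SimulatedDataset(config, panel, pedigree, diploid, matrix, records, coords)
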