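"""End-to-end pipeline: simulate -> kinship -> pedigree -> demography.

A single global seed fans out to independent per-stage streams via
``numpy.random.SeedSequence``, so any stage rerun alone reproduces its
output. Every run writes a manifest with the seed, parameters and sha256
hashes of inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import SUBADULT, XY
from .demography import (
    category_distance_test,
    genetic_distance_matrix,
    haplogroup_summary,
    mantel_test,
    occupation_duration,
    pairwise_distance_matrix,
    proportion_ci,
)
from .eigenstrat import read_eigenstrat, read_metadata
from .kinship import relatedness_table
from .pedigree import build_pedigrees, export_pedigree, validate_pedigree
from .qc import filter_low_coverage
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kinship", "pedigree", "demography")


@dataclass
class RunConfig:
    """Serializable pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "results/run"
    # either simulate, or read these inputs
    simulate: bool = True
    geno: Optional[str] = None
    snp: Optional[str] = None
    ind: Optional[str] = None
    metadata: Optional[str] = None
    # stage toggles
    run_kinship: bool = True
    run_pedigree: bool = True
    run_demography: bool = True
    # stage parameters
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_overlap: int = 5_000
    min_sites: int = 20_000
    window_cm: float = 20.0
    n_perm: int = 9_999
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible, stage-specific 31-bit seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns a result bundle and writes files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"version": __version__, "seed": config.seed, "inputs": {}, "outputs": {}}
    bundle: dict = {}

    try:
        if config.simulate:
            sim_cfg = SimulationConfig(seed=stage_seed(config.seed, "simulate"), **config.sim)
            dataset = simulate_dataset(sim_cfg)
            dataset.write(out / "sim")
            panel, matrix = dataset.panel, dataset.matrix
            records = dataset.records
            bundle["dataset"] = dataset
            truth_edges = dataset.pedigree.edges()
        else:
            for name in ("geno", "snp", "ind", "metadata"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input {name!r} missing: {p}")
                manifest["inputs"][name] = _sha256(Path(p))
            panel, matrix, _ = read_eigenstrat(config.geno, config.snp, config.ind)
            records = read_metadata(config.metadata)
            truth_edges = None
    except Exception as e:
        raise RuntimeError(f"[simulate] stage failed: {e}") from e

    retained, counts = filter_low_coverage(matrix, min_sites=min(config.min_sites, matrix.n_sites))
    matrix = matrix.subset(retained)
    records = [r for r in records if r.id in set(retained)]
    bundle["retained"] = retained
    bundle["covered_counts"] = counts

    if config.run_kinship:
        try:
            table = relatedness_table(
                matrix,
                panel,
                records,
                min_overlap=config.min_overlap,
                window_cm=config.window_cm,
            )
            table.to_csv(out / "relatedness.tsv", sep="\t", index=False)
            bundle["relatedness"] = table
        except Exception as e:
            raise RuntimeError(f"[kinship] stage failed: {e}") from e
    else:
        table = None

    if config.run_pedigree and table is not None:
        try:
            graphs = build_pedigrees(table, records)
            bundle["pedigrees"] = graphs
            bundle["violations"] = [validate_pedigree(g, records) for g in graphs]
            for i, g in enumerate(graphs):
                if g.number_of_nodes() < 2:
                    continue
                export_pedigree(
                    g,
                    out / f"pedigree_{i}.ped",
                    out / f"pedigree_{i}.dot",
                    out / f"pedigree_{i}.json",
                    family_id=f"FAM{i}",
                )
        except Exception as e:
            raise RuntimeError(f"[pedigree] stage failed: {e}") from e
    else:
        graphs = []

    if config.run_demography and table is not None:
        try:
            demo = demography_report(
                records,
                table,
                bundle.get("pedigrees", []),
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "demography"),
                truth_edges=truth_edges,
            )
            (out / "demography.json").write_text(json.dumps(demo, indent=2, default=str) + "\n")
            bundle["demography"] = demo
        except Exception as e:
            raise RuntimeError(f"[demography] stage failed: {e}") from e

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle


def demography_report(
    records,
    table: pd.DataFrame,
    pedigrees,
    n_perm: int = 9_999,
    seed: int = 0,
    truth_edges=None,
) -> dict:
    """Demographic statistics over one community."""
    rec = {r.id: r for r in records}
    report: dict = {}

    adults = [r for r in records if r.age_class == "ADULT"]
    subs = [r for r in records if r.age_class == SUBADULT]
    for label, group in (("adult", adults), ("subadult", subs)):
        males = sum(1 for r in group if r.sex == XY)
        n = sum(1 for r in group if r.sex in (XY, "XX"))
        if n:
            ci = proportion_ci(males, n)
            report[f"{label}_sex_ratio"] = {
                "males": males,
                "n": n,
                "ratio": ci.ratio,
                "ci_lower_pct": round(100 * ci.lower, 1),
                "ci_upper_pct": round(100 * ci.upper, 1),
            }

    coords = {r.id: (r.grave_x, r.grave_y) for r in records if r.has_coords}

    # father - subadult son grave distances
    fs_pairs = []
    for g in pedigrees:
        for p, c, role in g.parent_edges():
            if (
                role == "FATHER"
                and p in coords
                and c in coords
                and rec.get(c) is not None
                and rec[c].age_class == SUBADULT
                and rec[c].sex == XY
            ):
                fs_pairs.append((p, c))
    if fs_pairs:
        res = category_distance_test(
            coords, fs_pairs, category="father_subadult_son", n_perm=n_perm, seed=seed
        )
        report["father_subadult_son_distance"] = dataclasses.asdict(res)

    # Mantel: grave distance vs normalized-PMR genetic distance
    genotyped = {row.id1 for row in table.itertuples()} | {row.id2 for row in table.itertuples()}
    ids = sorted(set(coords) & genotyped)
    if len(ids) >= 4:
        spatial, _ = pairwise_distance_matrix(coords, ids)
        genetic = genetic_distance_matrix(table, ids)
        r, p = mantel_test(spatial, genetic, n_perm=n_perm, seed=seed + 1)
        report["mantel_spatial_vs_genetic"] = {"r": r, "p": p, "n": len(ids)}

    report["haplogroups"] = haplogroup_summary(records, pedigrees)

    n_gens = [
        max(g.generations().values()) for g in pedigrees if g.number_of_nodes() >= 2
    ]
    if n_gens:
        span = max(n_gens)
        # reproductive generations exclude the founding and final ones
        lo, hi = max(span - 4, 0), max(span - 3, 0)
        years = occupation_duration((lo, hi))
        report["occupation"] = {
            "max_generations": span,
            "reproductive_generations": [lo, hi],
            "duration_years": list(years),
        }
    return report
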