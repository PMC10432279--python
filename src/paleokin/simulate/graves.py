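"""Grave-coordinate generator: lineage-clustered burial layout.

Sampled individuals are grouped into patriline clusters (everyone attached
to the same top male ancestor, with mothers joining their partner's
lineage). Cluster centres sit on a ring; members scatter around the centre
with Gaussian noise, and subadult sons are drawn tighter around their
father to emulate the close father–subadult-son burials the spatial tests
look for. The layout is a test harness for spatial statistics, not a model
of any real necropolis plan.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from ..datatypes import SUBADULT, XY
from .config import SimulationConfig
from .pedigree import TruePedigree


def _patriline(ped: TruePedigree, node_id: str) -> str:
    """Top male ancestor through father links; mothers follow a child."""
    n = ped.nodes[node_id]
    while n.father_id is not None:
        n = ped.nodes[n.father_id]
    if n.sex == XY:
        return n.id
    # founder woman: attach to her partner's patriline via any child
    for child in ped.nodes.values():
        if child.mother_id == n.id and child.father_id is not None:
            return _patriline(ped, child.father_id)
    return n.id


def place_graves(
    pedigree: TruePedigree,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, tuple[float, float]]:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sampled = pedigree.sampled_ids()
    lineages = sorted({_patriline(pedigree, i) for i in sampled})
    n_lin = len(lineages)
    radius = 0.0 if n_lin == 1 else config.cluster_spacing / (2 * math.sin(math.pi / n_lin))
    centres = {
        lin: (
            radius * math.cos(2 * math.pi * k / n_lin),
            radius * math.sin(2 * math.pi * k / n_lin),
        )
        for k, lin in enumerate(lineages)
    }

    coords: dict[str, tuple[float, float]] = {}
    deferred: list[str] = []
    for ind in sampled:
        node = pedigree.nodes[ind]
        if (
            node.age_class == SUBADULT
            and node.sex == XY
            and node.father_id is not None
            and pedigree.nodes[node.father_id].sampled
        ):
            deferred.append(ind)
            continue
        cx, cy = centres[_patriline(pedigree, ind)]
        dx, dy = rng.normal(0.0, config.sigma_within, size=2)
        coords[ind] = (cx + dx, cy + dy)
    for ind in deferred:
        father = pedigree.nodes[ind].father_id
        fx, fy = coords[father]
        sigma = config.sigma_within * config.father_son_shrink
        dx, dy = rng.normal(0.0, sigma, size=2)
        coords[ind] = (fx + dx, fy + dy)
    return coords
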