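"""Ground-truth pedigree generation and pedigree-based relatedness.

The generated community is patrilineal and patrilocal: every union pairs a
lineage son with a newly created, unrelated immigrant mother carrying a
fresh mitochondrial haplogroup, so mt lineages die out after one
transmission while a single Y lineage runs through the whole patriline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from ..datatypes import ADULT, SUBADULT, XX, XY
from .config import SimulationConfig

UNRELATED = "UNRELATED"
LINEAL = "LINEAL"
NON_LINEAL = "NON_LINEAL"

#: degrees deeper than this are reported as UNRELATED by true_degree
MAX_DEGREE = 5


@dataclass
class PedNode:
    id: str
    sex: str
    generation: int
    sampled: bool
    age_class: str
    birth_order: int
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    mt_hg: Optional[str] = None
    y_hg: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None


@dataclass
class TruePedigree:
    """Ground-truth pedigree: nodes keyed by id, insertion-ordered."""

    nodes: dict[str, PedNode] = field(default_factory=dict)

    def add(self, node: PedNode) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node

    @property
    def ids(self) -> list[str]:
        return list(self.nodes)

    def sampled_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.sampled]

    def edges(self) -> list[tuple[str, str]]:
        """Parent -> child edges."""
        out = []
        for n in self.nodes.values():
            if n.mother_id is not None:
                out.append((n.mother_id, n.id))
            if n.father_id is not None:
                out.append((n.father_id, n.id))
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, **vars(n))
        g.add_edges_from(self.edges())
        return g

    def parents(self, node_id: str) -> list[str]:
        n = self.nodes[node_id]
        return [p for p in (n.mother_id, n.father_id) if p is not None]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a (strict) ancestor of ``b``."""
        stack = list(self.parents(b))
        seen = set()
        while stack:
            p = stack.pop()
            if p == a:
                return True
            if p not in seen:
                seen.add(p)
                stack.extend(self.parents(p))
        return False


def generate_pedigree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TruePedigree:
    """Grow a patrilineal pedigree forward in time.

    Founder couples start generation 1. Adult sons stay and form a union
    with an immigrant founder mother; adult daughters out-migrate with the
    configured probability (unsampled) and otherwise stay childless at the
    site. Children dying young are buried as subadults. Retries on
    extinction (no generation-G node) up to the configured limit.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    last_err: Optional[str] = None
    for _ in range(config.max_extinction_retries):
        ped = _grow(config, rng)
        if any(n.generation == config.n_generations for n in ped.nodes.values()):
            return ped
        last_err = "pedigree extinct before final generation"
    raise RuntimeError(
        f"{last_err} after {config.max_extinction_retries} retries; "
        "increase mean_offspring or retries"
    )


def _grow(config: SimulationConfig, rng: np.random.Generator) -> TruePedigree:
    ped = TruePedigree()
    counter = {"node": 0, "mt": 0, "y": 0}

    def new_id() -> str:
        counter["node"] += 1
        return f"I{counter['node']:04d}"

    def new_mt() -> str:
        counter["mt"] += 1
        return f"mt{counter['mt']:03d}"

    def new_y() -> str:
        counter["y"] += 1
        return f"Y{counter['y']:03d}"

    def make_immigrant_mother(generation: int) -> PedNode:
        node = PedNode(
            id=new_id(),
            sex=XX,
            generation=generation,
            sampled=bool(rng.random() < config.mother_sampled_prob),
            age_class=ADULT,
            birth_order=0,
            mt_hg=new_mt(),
        )
        ped.add(node)
        return node

    unions: list[tuple[PedNode, PedNode]] = []
    for _ in range(config.n_founder_couples):
        father = PedNode(
            id=new_id(),
            sex=XY,
            generation=1,
            sampled=True,
            age_class=ADULT,
            birth_order=0,
            mt_hg=new_mt(),
            y_hg=new_y(),
        )
        ped.add(father)
        mother = make_immigrant_mother(1)
        unions.append((father, mother))

    for gen in range(1, config.n_generations):
        next_unions: list[tuple[PedNode, PedNode]] = []
        # stay-at-home adult daughters available for endogamous unions
        local_daughters: list[PedNode] = []
        for father, mother in unions:
            n_children = int(rng.poisson(config.mean_offspring))
            for order in range(n_children):
                sex = XY if rng.random() < 0.5 else XX
                subadult = rng.random() < config.subadult_death_prob
                child = PedNode(
                    id=new_id(),
                    sex=sex,
                    generation=gen + 1,
                    sampled=True,
                    age_class=SUBADULT if subadult else ADULT,
                    birth_order=order,
                    mother_id=mother.id,
                    father_id=father.id,
                    mt_hg=mother.mt_hg,
                    y_hg=father.y_hg if sex == XY else None,
                )
                if subadult:
                    ped.add(child)
                    continue
                if sex == XX:
                    if rng.random() < config.daughter_outmigration_prob:
                        child.sampled = False
                    else:
                        local_daughters.append(child)
                    ped.add(child)
                else:
                    ped.add(child)
                    if gen + 1 < config.n_generations:
                        if local_daughters and rng.random() < config.endogamy_prob:
                            partner = local_daughters.pop(0)
                        else:
                            partner = make_immigrant_mother(gen + 1)
                        next_unions.append((child, partner))
        unions = next_unions
    return ped


def kinship_coefficient(ped: TruePedigree, a: str, b: str) -> float:
    """Kinship coefficient phi by the standard pedigree recursion."""
    if a not in ped.nodes or b not in ped.nodes:
        missing = a if a not in ped.nodes else b
        raise KeyError(f"unknown node id {missing!r}")
    cache: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        if x > y:
            x, y = y, x
        key = (x, y)
        if key in cache:
            return cache[key]
        nx_, ny_ = ped.nodes[x], ped.nodes[y]
        if x == y:
            f, m = nx_.father_id, nx_.mother_id
            val = 0.5 * (1.0 + (phi(f, m) if f and m else 0.0))
        else:
            # recurse on the node of the later generation; at equal
            # generations neither can descend from the other
            if ny_.generation >= nx_.generation:
                younger, other = ny_, nx_
            else:
                younger, other = nx_, ny_
            if younger.is_founder:
                val = 0.0
            else:
                val = 0.5 * (
                    phi(younger.father_id, other.id)
                    + phi(younger.mother_id, other.id)
                )
        cache[key] = val
        return val

    return phi(a, b)


def true_degree(ped: TruePedigree, a: str, b: str) -> tuple[int | str, str]:
    """Relatedness degree class and lineality between two pedigree members.

    Returns ``(degree, lineality)`` where degree is 0 (same individual /
    identical twin), 1..5, or ``UNRELATED``; lineality is ``LINEAL`` when
    one member is a direct ancestor of the other (or they coincide).
    """
    phi = kinship_coefficient(ped, a, b)
    lineal = a == b or ped.is_ancestor(a, b) or ped.is_ancestor(b, a)
    lin = LINEAL if lineal else NON_LINEAL
    if phi <= 0.0:
        return UNRELATED, NON_LINEAL
    degree = round(-math.log2(2.0 * phi))
    if degree > MAX_DEGREE:
        return UNRELATED, lin
    return max(degree, 0), lin
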