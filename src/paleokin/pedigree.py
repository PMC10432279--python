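"""Constraint-based pedigree assembly.

Degree calls alone do not orient a parent-offspring pair; orientation and
assembly lean on the classical transmission constraints: mitochondrial
haplogroups follow the mother, Y haplogroups follow the father, a child who
died as a subadult cannot be anyone's parent, and full siblings share both
parents. Second-degree calls never create edges directly - they act as
cross-checks (triangulation and merge vetoes) only.

The assembly is deliberately deterministic: pairs are processed in
lexicographic order and every rule is mechanical, trading the case-by-case
judgment of expert curation for reproducibility.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .datatypes import SUBADULT, XX, XY, IndividualRecord
from .kinship import PARENT_OFFSPRING, SIBLING, UNRELATED

logger = logging.getLogger(__name__)

MOTHER = "MOTHER"
FATHER = "FATHER"
PLACEHOLDER_PREFIX = "U_"

# violation kinds
MT_MISMATCH = "MT_MISMATCH"
Y_MISMATCH = "Y_MISMATCH"
SEX_ROLE = "SEX_ROLE"
AGE_ORDER = "AGE_ORDER"
CYCLE = "CYCLE"
DOUBLE_PARENT = "DOUBLE_PARENT"
DEGREE_CONFLICT = "DEGREE_CONFLICT"
CLOSURE_CONFLICT = "CLOSURE_CONFLICT"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ConstraintViolation:
    kind: str
    ids: tuple[str, ...]
    message: str


@dataclass
class FamilyUnit:
    """A seeded nuclear unit: an oriented parent-child duo or a sibling set."""

    kind: str  # "PO_DUO" or "SIBSHIP"
    members: tuple[str, ...]
    parent: Optional[str] = None  # PO_DUO only; None when unresolved
    child: Optional[str] = None
    role: Optional[str] = None  # MOTHER / FATHER
    flags: tuple[str, ...] = ()


class PedigreeGraph(nx.DiGraph):
    """Directed parent->child graph; nodes carry metadata, edges a role.

    Placeholder (inferred, unsampled) parents have ids prefixed ``U_`` and
    ``sampled=False``.
    """

    def add_individual(self, record: IndividualRecord, sampled: bool = True) -> None:
        self.add_node(
            record.id,
            sampled=sampled,
            sex=record.sex,
            age_class=record.age_class,
            mt_hg=record.mt_hg,
            y_hg=record.y_hg,
        )

    def add_placeholder(self, node_id: str, sex: str) -> None:
        self.add_node(
            node_id, sampled=False, sex=sex, age_class=None, mt_hg=None, y_hg=None
        )

    def parent_of(self, child: str, role: str) -> Optional[str]:
        for p in self.predecessors(child):
            if self.edges[p, child]["role"] == role:
                return p
        return None

    def add_parent(self, parent: str, child: str, role: str) -> None:
        existing = self.parent_of(child, role)
        if existing is not None and existing != parent:
            raise ValueError(f"{child} already has a {role}: {existing}")
        self.add_edge(parent, child, role=role)

    def parent_edges(self) -> list[tuple[str, str, str]]:
        return [(p, c, d["role"]) for p, c, d in self.edges(data=True)]

    def generations(self) -> dict[str, int]:
        """Longest root-to-node depth; used as generation index."""
        order = list(nx.topological_sort(self))
        depth = {n: 1 for n in order}
        for n in order:
            for c in self.successors(n):
                depth[c] = max(depth[c], depth[n] + 1)
        return depth


# ---------------------------------------------------------------------------
# call lookup helpers


class _Calls:
    """Indexed view over a relatedness table."""

    def __init__(self, table: pd.DataFrame):
        self.call: dict[frozenset, object] = {}
        self.po_sib: dict[frozenset, str] = {}
        for row in table.itertuples(index=False):
            key = frozenset((row.id1, row.id2))
            self.call[key] = row.call
            self.po_sib[key] = getattr(row, "po_sib_call", "") or ""

    def degree(self, a: str, b: str):
        return self.call.get(frozenset((a, b)))


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _feasible_parent(parent: IndividualRecord, child: IndividualRecord) -> bool:
    """Can ``parent`` be the biological parent of ``child``?"""
    if parent.age_class == SUBADULT:
        return False
    if parent.sex == XX:
        if parent.mt_hg and child.mt_hg and parent.mt_hg != child.mt_hg:
            return False
        return True
    if parent.sex == XY:
        if child.sex == XY and parent.y_hg and child.y_hg and parent.y_hg != child.y_hg:
            return False
        return True
    return False  # indeterminate sex cannot take a parental role


# ---------------------------------------------------------------------------
# seeding


def seed_nuclear_units(
    table: pd.DataFrame, metadata: Sequence[IndividualRecord]
) -> list[FamilyUnit]:
    """Seed sibling sets and oriented parent-child duos from degree-1 calls.

    Orientation uses, in order: haplogroup transmission (an XX member whose
    mt label differs from the other's cannot be the mother; Y labels must
    match down a father-son edge), then age class (a subadult cannot be a
    parent), then sibling-set lifting (one individual with parent-offspring
    calls to two members of a sibship is their shared parent; one with a
    single parent-offspring call plus second-degree calls into the sibship
    is that member's child). Unresolved duos are flagged AMBIGUOUS.
    """
    rec = {r.id: r for r in metadata}
    calls = _Calls(table)

    sib_pairs, po_pairs = [], []
    for key, deg in sorted(calls.call.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if deg != 1:
            continue
        a, b = sorted(key)
        sub = calls.po_sib[key]
        if sub == SIBLING:
            sib_pairs.append((a, b))
        elif sub == PARENT_OFFSPRING:
            po_pairs.append((a, b))
        else:
            po_pairs.append((a, b))  # unspecified degree-1: try to orient anyway

    uf = _UnionFind()
    for a, b in sib_pairs:
        uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for a, b in sib_pairs:
        groups.setdefault(uf.find(a), [])
    for x in {m for p in sib_pairs for m in p}:
        groups.setdefault(uf.find(x), []).append(x)

    units: list[FamilyUnit] = []
    sibship_of: dict[str, tuple[str, ...]] = {}
    for root in sorted(groups):
        members = tuple(sorted(groups[root]))
        flags = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                d = calls.degree(a, b)
                if d is not None and d not in (1,):
                    flags.append(CLOSURE_CONFLICT)
                    logger.warning("sibship %s: pair %s-%s called %s", members, a, b, d)
        units.append(FamilyUnit(kind="SIBSHIP", members=members, flags=tuple(sorted(set(flags)))))
        for m in members:
            sibship_of[m] = members

    def sibs(x: str) -> tuple[str, ...]:
        return sibship_of.get(x, (x,))

    def feasible(p: str, c: str) -> bool:
        if p not in rec or c not in rec:
            return False
        # a parent of c is a parent of c's whole sibship
        return all(_feasible_parent(rec[p], rec[m]) for m in sibs(c))

    for a, b in po_pairs:
        if sibship_of.get(a) is not None and sibship_of.get(a) == sibship_of.get(b):
            units.append(
                FamilyUnit(kind="PO_DUO", members=(a, b), flags=(CLOSURE_CONFLICT,))
            )
            logger.warning("pair %s-%s called both sibling and parent-offspring", a, b)
            continue
        parent = None
        # sibling-set lifting
        for p, c in ((a, b), (b, a)):
            s = sibs(c)
            if len(s) >= 2:
                n_po = sum(
                    1
                    for m in s
                    if calls.degree(p, m) == 1
                    and calls.po_sib.get(frozenset((p, m))) in (PARENT_OFFSPRING, "")
                )
                n_d2 = sum(1 for m in s if calls.degree(p, m) == 2)
                if n_po >= 2:
                    parent = p
                    break
                if n_po == 1 and n_d2 >= 1:
                    parent = c  # p is the child of its sole PO partner
                    break
        if parent is None:
            fa = feasible(a, b)  # a as parent of b
            fb = feasible(b, a)
            if fa and not fb:
                parent = a
            elif fb and not fa:
                parent = b
        if parent is None:
            units.append(FamilyUnit(kind="PO_DUO", members=(a, b), flags=(AMBIGUOUS,)))
            continue
        child = b if parent == a else a
        if not feasible(parent, child):
            units.append(FamilyUnit(kind="PO_DUO", members=(a, b), flags=(AMBIGUOUS,)))
            logger.warning("pair %s-%s: no transmission-consistent orientation", a, b)
            continue
        role = MOTHER if rec[parent].sex == XX else FATHER
        units.append(
            FamilyUnit(kind="PO_DUO", members=(a, b), parent=parent, child=child, role=role)
        )
    return units


# ---------------------------------------------------------------------------
# expansion


def _graph_degree(graph: nx.DiGraph, a: str, b: str):
    """Degree implied by the current graph (UNRELATED when no common ancestor)."""
    if a not in graph or b not in graph:
        return UNRELATED
    parents = {n: list(graph.predecessors(n)) for n in graph}
    order = {n: i for i, n in enumerate(nx.topological_sort(graph))}
    cache: dict[frozenset, float] = {}

    def phi(x: str, y: str) -> float:
        key = frozenset((x, y))
        if key in cache:
            return cache[key]
        if x == y:
            val = 0.5
        else:
            younger = x if order[x] >= order[y] else y
            other = y if younger == x else x
            ps = parents[younger]
            val = 0.0 if not ps else sum(phi(p, other) for p in ps) / 2.0
        cache[key] = val
        return val

    f = phi(a, b)
    if f <= 0.0:
        return UNRELATED
    return max(round(-math.log2(2.0 * f)), 0)


def expand_pedigrees(
    units: Sequence[FamilyUnit],
    table: pd.DataFrame,
    metadata: Sequence[IndividualRecord],
) -> list[PedigreeGraph]:
    """Merge seeded units into pedigrees, resolving what triangulation can.

    Remaining ambiguous parent-offspring duos are re-examined against
    already committed edges (a filled parent slot, or a second-degree /
    unrelated call to an established parent or child, fixes the direction).
    Sibling sets without a sampled parent receive placeholder parents, a
    single known parent receives a placeholder partner, and committing an
    edge that would make some called pair more than one degree closer than
    its call is rejected and logged.
    """
    rec = {r.id: r for r in metadata}
    calls = _Calls(table)

    sibships = [u for u in units if u.kind == "SIBSHIP"]
    duos = [u for u in units if u.kind == "PO_DUO"]
    sibship_of: dict[str, tuple[str, ...]] = {}
    for u in sibships:
        for m in u.members:
            sibship_of[m] = u.members

    def sibs(x: str) -> tuple[str, ...]:
        return sibship_of.get(x, (x,))

    def feasible(p: str, c: str) -> bool:
        if p not in rec or c not in rec:
            return False
        return all(_feasible_parent(rec[p], rec[m]) for m in sibs(c))

    # child -> {role: parent} from oriented duos (parent of one sibling is
    # parent of the whole sibship)
    assigned: dict[str, dict[str, str]] = {}
    conflicts: list[ConstraintViolation] = []

    def assign(parent: str, child: str, role: str) -> None:
        for m in sibs(child):
            slot = assigned.setdefault(m, {})
            if role in slot and slot[role] != parent:
                conflicts.append(
                    ConstraintViolation(
                        DOUBLE_PARENT,
                        (slot[role], parent, m),
                        f"{m} assigned two {role}s: {slot[role]}, {parent}",
                    )
                )
                logger.warning("double %s for %s: %s vs %s", role, m, slot[role], parent)
            else:
                slot[role] = parent

    for u in duos:
        if u.parent is not None:
            assign(u.parent, u.child, u.role)

    # iterative resolution of ambiguous duos against committed structure
    pending = [u for u in duos if u.parent is None and CLOSURE_CONFLICT not in u.flags]
    resolved: list[FamilyUnit] = []
    changed = True
    while changed and pending:
        changed = False
        still: list[FamilyUnit] = []
        for u in sorted(pending, key=lambda u: u.members):
            a, b = u.members
            parent = _triangulate(a, b, assigned, calls, sibs, feasible, rec)
            if parent is None:
                still.append(u)
                continue
            child = b if parent == a else a
            role = MOTHER if rec[parent].sex == XX else FATHER
            assign(parent, child, role)
            resolved.append(
                FamilyUnit(kind="PO_DUO", members=u.members, parent=parent, child=child, role=role)
            )
            changed = True
        pending = still
    for u in pending:
        conflicts.append(
            ConstraintViolation(
                AMBIGUOUS, u.members, f"parent-offspring pair {u.members} left unoriented"
            )
        )
        logger.info("unresolved parent-offspring orientation: %s", u.members)

    # ------------------------------------------------------------------
    # commit to a graph
    graph = PedigreeGraph()
    involved = sorted(
        {m for u in units for m in u.members} | {i for i in assigned}
    )
    for ind in involved:
        if ind in rec:
            graph.add_individual(rec[ind])

    def committable(parent: str, child: str, role: str) -> bool:
        """Cycle and degree-consistency veto: the new edge must keep the
        graph acyclic and must not make any called pair more than one
        degree closer than its call."""
        if parent in graph and child in graph and nx.has_path(graph, child, parent):
            conflicts.append(
                ConstraintViolation(
                    CYCLE, (parent, child), f"edge {parent}->{child} would create a cycle"
                )
            )
            return False
        graph.add_edge(parent, child, role=role)
        try:
            comp = nx.node_connected_component(graph.to_undirected(as_view=True), child)
            for x in comp:
                for y in comp:
                    if x >= y:
                        continue
                    called = calls.degree(x, y)
                    if called is None:
                        continue  # no call for this pair (e.g. a placeholder)
                    if called == UNRELATED:
                        called_num = 6
                    elif called in (0, 1, 2, 3, 4, 5):
                        called_num = int(called)
                    else:
                        continue
                    implied = _graph_degree(graph, x, y)
                    implied_num = 6 if implied == UNRELATED else int(implied)
                    # only implied degrees within the classifier's trusted
                    # range (<= 2) can contradict a call: an UNRELATED call
                    # is fully consistent with a true 3rd+ degree
                    if implied_num <= 2 and implied_num < called_num - 1:
                        conflicts.append(
                            ConstraintViolation(
                                DEGREE_CONFLICT,
                                (parent, child, x, y),
                                f"edge {parent}->{child} implies degree {implied} for "
                                f"{x}-{y} called {called}",
                            )
                        )
                        return False
            return True
        finally:
            graph.remove_edge(parent, child)

    placeholder_count = {"n": 0}

    def new_placeholder(role: str) -> str:
        placeholder_count["n"] += 1
        node_id = f"{PLACEHOLDER_PREFIX}{'M' if role == MOTHER else 'F'}{placeholder_count['n']:03d}"
        graph.add_placeholder(node_id, XX if role == MOTHER else XY)
        return node_id

    # family groups: sibships plus singleton children with assigned parents
    family_children: list[tuple[str, ...]] = [u.members for u in sibships]
    in_sibship = set(sibship_of)
    for child in sorted(assigned):
        if child not in in_sibship:
            family_children.append((child,))

    for members in sorted(family_children, key=lambda m: m[0]):
        slots = assigned.get(members[0], {})
        parents: dict[str, Optional[str]] = {
            MOTHER: slots.get(MOTHER),
            FATHER: slots.get(FATHER),
        }
        committed: dict[str, Optional[str]] = {MOTHER: None, FATHER: None}
        for role in (MOTHER, FATHER):
            p = parents[role]
            if p is None:
                continue
            added = []
            for m in members:
                if committable(p, m, role):
                    graph.add_parent(p, m, role)
                    added.append(m)
            if added:
                committed[role] = p
        n_sampled = sum(1 for r in (MOTHER, FATHER) if committed[r] is not None)
        need_placeholders = len(members) >= 2 or n_sampled >= 1
        if need_placeholders:
            for role in (MOTHER, FATHER):
                if committed[role] is None:
                    ph = new_placeholder(role)
                    for m in members:
                        graph.add_parent(ph, m, role)

    if not nx.is_directed_acyclic_graph(graph):
        # should not happen with generation-consistent rules; drop back edges
        conflicts.append(ConstraintViolation(CYCLE, (), "assembled graph contains a cycle"))
        logger.error("assembled pedigree contains a cycle")

    out: list[PedigreeGraph] = []
    for comp in sorted(nx.weakly_connected_components(graph), key=lambda c: sorted(c)[0]):
        sub = PedigreeGraph()
        sub.add_nodes_from((n, dict(graph.nodes[n])) for n in sorted(comp))
        sub.add_edges_from(
            (p, c, dict(d)) for p, c, d in graph.edges(data=True) if p in comp
        )
        sub.conflicts = [v for v in conflicts if not set(v.ids) or set(v.ids) & comp]
        out.append(sub)
    return out


def _triangulate(a, b, assigned, calls, sibs, feasible, rec):
    """Decide the parent of an ambiguous PO pair from committed structure."""
    for x, y in ((a, b), (b, a)):
        # y's candidate-parent slot already filled by someone else -> y is x's parent
        if y in rec and rec[y].sex in (XX, XY):
            role = MOTHER if rec[y].sex == XX else FATHER
            cur = assigned.get(x, {}).get(role)
            if cur is not None and cur != y and feasible(x, y):
                return x
        # second-degree / unrelated call between y and an established parent of x
        for role, p in sorted(assigned.get(x, {}).items()):
            if p == y:
                continue
            d = calls.degree(p, y)
            if d == 2 and feasible(x, y):
                return x  # y is x's child: grandparent pattern
            if d == UNRELATED and feasible(y, x):
                return y  # y is x's other parent: partners are unrelated
        # an established child of y: sibling call -> x..; degree-2 -> y is
        # the grandchild side's parent
        for child, slots in sorted(assigned.items()):
            if y in slots.values():
                d = calls.degree(child, x)
                if d == 2 and feasible(y, x):
                    return y  # x is grandparent-side: y's child is x's grandchild
                if d == 1 and calls.po_sib.get(frozenset((child, x))) == SIBLING:
                    if feasible(y, x):
                        return y  # x is a sibling of y's child
    return None


# ---------------------------------------------------------------------------
# validation & scoring


def validate_pedigree(
    graph: PedigreeGraph, metadata: Optional[Sequence[IndividualRecord]] = None
) -> list[ConstraintViolation]:
    """Check all structural and transmission invariants; empty list iff valid."""
    rec = {r.id: r for r in metadata} if metadata else {}

    def attr(node, name):
        if node in rec:
            return getattr(rec[node], name)
        return graph.nodes[node].get(name)

    violations: list[ConstraintViolation] = []
    if not nx.is_directed_acyclic_graph(graph):
        violations.append(ConstraintViolation(CYCLE, (), "graph contains a cycle"))

    for child in sorted(graph.nodes):
        seen_roles: dict[str, list[str]] = {}
        for p in graph.predecessors(child):
            seen_roles.setdefault(graph.edges[p, child]["role"], []).append(p)
        for role, ps in sorted(seen_roles.items()):
            if len(ps) > 1:
                violations.append(
                    ConstraintViolation(
                        DOUBLE_PARENT, (child, *sorted(ps)), f"{child} has {len(ps)} {role}s"
                    )
                )
        for role, want_sex in ((MOTHER, XX), (FATHER, XY)):
            for p in seen_roles.get(role, []):
                sex = attr(p, "sex")
                if sex is not None and sex != want_sex:
                    violations.append(
                        ConstraintViolation(
                            SEX_ROLE, (p, child), f"{role} {p} of {child} has sex {sex}"
                        )
                    )
                if attr(p, "age_class") == SUBADULT:
                    violations.append(
                        ConstraintViolation(
                            AGE_ORDER, (p, child), f"subadult {p} is a parent of {child}"
                        )
                    )
        for p in seen_roles.get(MOTHER, []):
            m_mt, c_mt = attr(p, "mt_hg"), attr(child, "mt_hg")
            if m_mt and c_mt and m_mt != c_mt:
                violations.append(
                    ConstraintViolation(
                        MT_MISMATCH, (p, child), f"{child} mt {c_mt} != mother {p} mt {m_mt}"
                    )
                )
        for p in seen_roles.get(FATHER, []):
            if attr(child, "sex") == XY:
                f_y, c_y = attr(p, "y_hg"), attr(child, "y_hg")
                if f_y and c_y and f_y != c_y:
                    violations.append(
                        ConstraintViolation(
                            Y_MISMATCH, (p, child), f"{child} Y {c_y} != father {p} Y {f_y}"
                        )
                    )
    return violations


def compare_to_truth(
    graphs: Iterable[PedigreeGraph], true_edges: Iterable[tuple[str, str]], sampled_ids: Iterable[str]
) -> dict:
    """Parent-edge precision/recall of inferred pedigrees against truth.

    ``true_edges`` are (parent, child) pairs of the generating pedigree;
    ``sampled_ids`` the individuals the inference saw. Placeholder parents
    are matched to latent (unseen) truth parents by best overlap of child
    sets; a matched placeholder edge counts as correct.
    """
    sampled = set(sampled_ids)
    truth = [(p, c) for p, c in true_edges if c in sampled]
    if not truth and not any(g.edges for g in graphs):
        return {"precision": 1.0, "recall": 1.0, "n_inferred": 0, "n_truth": 0, "zero_edges": True}

    inferred: list[tuple[str, str]] = []
    placeholder_children: dict[str, set[str]] = {}
    for g in graphs:
        for p, c, _role in g.parent_edges():
            inferred.append((p, c))
            if p.startswith(PLACEHOLDER_PREFIX):
                placeholder_children.setdefault(p, set()).add(c)

    latent_children: dict[str, set[str]] = {}
    for p, c in truth:
        if p not in sampled:
            latent_children.setdefault(p, set()).add(c)

    # greedy best-overlap matching, deterministic order (largest overlap,
    # then lexicographic); child sets are small so greedy == optimal in
    # practice
    candidates = []
    for ph, ch in placeholder_children.items():
        for lat, lch in latent_children.items():
            ov = len(ch & lch)
            if ov:
                candidates.append((-ov, ph, lat))
    mapping: dict[str, str] = {}
    used_lat: set[str] = set()
    for _, ph, lat in sorted(candidates):
        if ph not in mapping and lat not in used_lat:
            mapping[ph] = lat
            used_lat.add(lat)

    inferred_mapped = {(mapping.get(p, p), c) for p, c in inferred}
    truth_set = set(truth)
    tp = len(inferred_mapped & truth_set)
    n_inf = len(inferred_mapped)
    n_truth = len(truth_set)
    precision = tp / n_inf if n_inf else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_inferred": n_inf,
        "n_truth": n_truth,
        "true_positive": tp,
        "zero_edges": n_inf == 0,
        "placeholder_mapping": mapping,
    }


def degree_confusion(table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix of called vs true degree classes over shared pairs."""
    t = truth.set_index(
        truth.apply(lambda r: frozenset((r["id1"], r["id2"])), axis=1)
    )["true_degree"]
    rows = []
    for row in table.itertuples(index=False):
        key = frozenset((row.id1, row.id2))
        if key in t.index:
            rows.append({"true": t[key], "called": row.call})
    df = pd.DataFrame(rows)
    return pd.crosstab(df["true"], df["called"]) if len(df) else pd.DataFrame()


# ---------------------------------------------------------------------------
# export / import


def export_pedigree(
    graph: PedigreeGraph, ped_path: str | Path, dot_path: str | Path, json_path: str | Path,
    family_id: str = "FAM1",
) -> None:
    """Write PED/FAM-style table, DOT rendering and a lossless JSON dump."""
    gens = graph.generations()
    with open(ped_path, "w") as fh:
        fh.write("family\tid\tfather\tmother\tsex\tsampled\n")
        for n in sorted(graph.nodes):
            father = graph.parent_of(n, FATHER) or "0"
            mother = graph.parent_of(n, MOTHER) or "0"
            sex = {XY: "1", XX: "2"}.get(graph.nodes[n].get("sex"), "0")
            sampled = "1" if graph.nodes[n].get("sampled") else "0"
            fh.write(f"{family_id}\t{n}\t{father}\t{mother}\t{sex}\t{sampled}\n")

    with open(dot_path, "w") as fh:
        fh.write("digraph pedigree {\n  rankdir=TB;\n")
        by_gen: dict[int, list[str]] = {}
        for n, g in gens.items():
            by_gen.setdefault(g, []).append(n)
        for g in sorted(by_gen):
            ranked = " ".join(f'"{n}"' for n in sorted(by_gen[g]))
            fh.write(f"  {{ rank=same; {ranked} }}\n")
        for n in sorted(graph.nodes):
            shape = {XY: "box", XX: "ellipse"}.get(graph.nodes[n].get("sex"), "diamond")
            style = "solid" if graph.nodes[n].get("sampled") else "dashed"
            fh.write(f'  "{n}" [shape={shape}, style={style}];\n')
        for p, c, role in sorted(graph.parent_edges()):
            fh.write(f'  "{p}" -> "{c}" [label="{role[0]}"];\n')
        fh.write("}\n")

    data = {
        "nodes": {n: dict(graph.nodes[n]) for n in sorted(graph.nodes)},
        "edges": [[p, c, role] for p, c, role in sorted(graph.parent_edges())],
    }
    Path(json_path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def import_pedigree(json_path: str | Path) -> PedigreeGraph:
    data = json.loads(Path(json_path).read_text())
    graph = PedigreeGraph()
    for n, attrs in data["nodes"].items():
        graph.add_node(n, **attrs)
    for p, c, role in data["edges"]:
        graph.add_edge(p, c, role=role)
    return graph


def build_pedigrees(
    table: pd.DataFrame, metadata: Sequence[IndividualRecord]
) -> list[PedigreeGraph]:
    """Seed and expand in one call."""
    units = seed_nuclear_units(table, metadata)
    return expand_pedigrees(units, table, metadata)
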