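"""Enumeration of valid superassemblies under the four assembly rules.

A superassembly is a choice of engaged interface types; its assemblies are
the connected components of the engaged subgraph.  Validity requires:

1. full coverage — every chain belongs to exactly one assembly (automatic:
   components partition the nodes);
2. uniform composition — all instances of a type engaged together
   (by construction: engagement is per type);
3. isomorphism — assemblies with non-orthogonal stoichiometries must be
   isomorphic as entity/type-labeled graphs (no co-crystals of the same
   entities);
4. closed symmetry — no combination of engaged operators yields a non-zero
   pure lattice translation, i.e. every fundamental cycle of the engaged
   subgraph has zero net translation (no infinite fibers/sheets).

Enumeration traverses the power set of types depth-first, pruning every
superset of a rule-4 failure (a bad cycle persists when edges are added).
Rule-3 failures mark a set invalid but do not prune, since isomorphism is
not monotone in general.  Heteromers are handled by greedy entity
contraction: for the highest-probability inter-entity type c the traversal
branches into "engage c" (contract c's edges, merging entities into
meta-entities) and "disengage c" (delete them), recursing until graphs are
homomeric; entity-disconnected blocks are enumerated independently and
combined (their stoichiometries are orthogonal).  Every candidate engaged
set is finally re-validated on the uncontracted graph.
"""

from __future__ import annotations

import dataclasses
import itertools

import networkx as nx
import numpy as np

from .lattice import QuotientGraph, TypeInfo, component_offsets, cycle_basis
from .symmetry import detect_point_group, infer_point_group_topological
from .structure import apply_operator

__all__ = [
    "Assembly",
    "Superassembly",
    "ValidityResult",
    "check_closed_symmetry",
    "check_isomorphism",
    "extract_assemblies",
    "enumerate_superassemblies",
    "contract_entities",
    "validate_superassembly",
    "annotate_point_groups",
]

DEFAULT_MAX_TYPES = 32

ENTITY_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclasses.dataclass
class ValidityResult:
    valid: bool
    failed_rule: str | None = None  # closure | isomorphism | coverage | uniform
    witness: object = None


@dataclasses.dataclass
class Assembly:
    members: list  # [(node, cell offset)]
    stoichiometry: dict  # entity -> count
    engaged_types: frozenset
    point_group: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def formula(self, entity_order=None) -> str:
        """Stoichiometry string like 'A2B2' (letters follow entity order)."""
        ents = entity_order or sorted(self.stoichiometry)
        parts = []
        for i, e in enumerate(ents):
            c = self.stoichiometry.get(e, 0)
            if c:
                letter = ENTITY_LETTERS[i % 26]
                parts.append(f"{letter}{c if c > 1 else ''}")
        return "".join(parts) or "-"

    def stoich_key(self) -> tuple:
        return tuple(sorted(self.stoichiometry.items()))


@dataclasses.dataclass
class Superassembly:
    engaged: frozenset
    valid: bool
    assemblies: list = dataclasses.field(default_factory=list)
    failed_rule: str | None = None
    witness: object = None
    prob_raw: float | None = None
    prob_norm: float | None = None

    def stoich_multiset(self) -> tuple:
        return tuple(sorted(a.stoich_key() for a in self.assemblies))

    @property
    def total_chains(self) -> int:
        return sum(a.size for a in self.assemblies)


# ---------------------------------------------------------------------------
# Rule 4: closed symmetry


def check_closed_symmetry(qg: QuotientGraph, engaged) -> ValidityResult:
    """Valid iff every fundamental cycle of the engaged subgraph has zero
    net translation; a failing basis cycle is returned as witness."""
    sub = qg.engaged_subgraph(engaged)
    for comp in nx.connected_components(sub):
        _, bad = component_offsets(sub, comp)
        if bad:
            witness = _witness_cycle(sub, comp, bad[0])
            return ValidityResult(False, "closure", witness)
    return ValidityResult(True)


def _witness_cycle(sub, comp, bad_edge):
    for cyc in cycle_basis(sub.subgraph(comp).copy()):
        net = np.zeros(3, dtype=int)
        for _, _, _, tvec in cyc:
            net += np.array(tvec)
        if net.any():
            return cyc
    return bad_edge


# ---------------------------------------------------------------------------
# Assembly extraction (requires rule 4)


def extract_assemblies(qg: QuotientGraph, engaged) -> list:
    """Connected components lifted to concrete cell offsets.

    Offsets come from a BFS spanning tree (root at offset (0,0,0)); rule 4
    guarantees consistency, and a different tree only shifts every offset by
    a global constant.  Each quotient component is one representative of a
    lattice-translation orbit of assemblies.
    """
    sub = qg.engaged_subgraph(engaged)
    assemblies = []
    for comp in sorted(nx.connected_components(sub), key=min):
        off, bad = component_offsets(sub, comp)
        if bad:
            raise ValueError(
                "extract_assemblies called on a rule-4-violating engaged set; "
                "run check_closed_symmetry first"
            )
        stoich: dict = {}
        for n in comp:
            e = qg.entity_of(n)
            stoich[e] = stoich.get(e, 0) + 1
        comp_types = frozenset(
            d["type"] for _, _, d in sub.edges(comp, data=True)
        )
        assemblies.append(
            Assembly(
                members=sorted(off.items()),
                stoichiometry=stoich,
                engaged_types=comp_types,
            )
        )
    return assemblies


# ---------------------------------------------------------------------------
# Rule 3: isomorphism


def check_isomorphism(qg: QuotientGraph, engaged, assemblies=None) -> ValidityResult:
    """Assemblies with non-orthogonal stoichiometry must be isomorphic as
    labeled graphs (node label: entity; edge label: interface type)."""
    sub = qg.engaged_subgraph(engaged)
    comps = [set(c) for c in sorted(nx.connected_components(sub), key=min)]
    node_match = nx.algorithms.isomorphism.categorical_node_match("entity", None)
    edge_match = nx.algorithms.isomorphism.categorical_multiedge_match("type", None)

    classes: list = []  # (representative subgraph, stoich support, member idx)
    comp_class = []
    for ci, comp in enumerate(comps):
        g = sub.subgraph(comp)
        support = frozenset(qg.entity_of(n) for n in comp)
        assigned = None
        for ki, (rep, _, _) in enumerate(classes):
            if nx.is_isomorphic(g, rep, node_match=node_match, edge_match=edge_match):
                assigned = ki
                break
        if assigned is None:
            classes.append((g, support, ci))
            assigned = len(classes) - 1
        comp_class.append(assigned)

    for (ka, kb) in itertools.combinations(range(len(classes)), 2):
        if classes[ka][1] & classes[kb][1]:  # shared entity -> non-orthogonal
            return ValidityResult(
                False, "isomorphism", (classes[ka][2], classes[kb][2])
            )
    return ValidityResult(True)


# ---------------------------------------------------------------------------
# Full validation of one engaged set


def validate_superassembly(qg: QuotientGraph, engaged) -> Superassembly:
    engaged = frozenset(engaged)
    r4 = check_closed_symmetry(qg, engaged)
    if not r4.valid:
        return Superassembly(engaged, False, failed_rule="closure", witness=r4.witness)
    assemblies = extract_assemblies(qg, engaged)
    r3 = check_isomorphism(qg, engaged, assemblies)
    if not r3.valid:
        return Superassembly(
            engaged, False, assemblies=assemblies,
            failed_rule="isomorphism", witness=r3.witness,
        )
    return Superassembly(engaged, True, assemblies=assemblies)


# ---------------------------------------------------------------------------
# Entity contraction


def _type_edges(qg: QuotientGraph, type_id):
    return [
        (u, v, k)
        for u, v, k, d in qg.g.edges(keys=True, data=True)
        if d["type"] == type_id
    ]


def _inter_entity_types(qg: QuotientGraph) -> set:
    out = set()
    for u, v, d in qg.g.edges(data=True):
        if qg.entity_of(u) != qg.entity_of(v):
            out.add(d["type"])
    return out


def _entity_signature(sub, comp, qg) -> str:
    ents = sorted(qg.entity_of(n) for n in comp)
    g = nx.Graph()
    for n in comp:
        g.add_node(n, entity=qg.entity_of(n))
    for u, v, _ in sub.edges(comp, data=True):
        if u != v:
            g.add_edge(u, v)
    h = nx.weisfeiler_lehman_graph_hash(g, node_attr="entity")
    return "+".join(ents) + ":" + h[:8]


def contract_type(qg: QuotientGraph, type_id):
    """Contract every edge of one interface type, merging its connected
    node groups into meta-nodes with internal cell offsets.

    Returns (contracted graph, mapping meta-node -> {node: offset}), or
    None when the type's own subgraph violates rule 4 (engaging it can
    never be valid).  Remaining edge translations are re-anchored to the
    meta-nodes, preserving the cycle space net translations.
    """
    sub = qg.engaged_subgraph({type_id})
    out = QuotientGraph()
    node_map: dict = {}
    mapping: dict = {}
    for comp in sorted(nx.connected_components(sub), key=min):
        comp = set(comp)
        has_edge = any(True for _ in sub.edges(comp))
        if not has_edge:
            (n,) = comp
            out.g.add_node(n, **qg.g.nodes[n])
            node_map[n] = (n, (0, 0, 0))
            mapping[n] = {n: (0, 0, 0)}
            continue
        off, bad = component_offsets(sub, comp)
        if bad:
            return None
        name = "|".join(sorted(comp))
        sig = _entity_signature(sub, comp, qg)
        out.g.add_node(name, chain=name, op=0, entity=sig)
        for n in comp:
            node_map[n] = (name, off[n])
        mapping[name] = dict(off)

    for u, v, d in qg.g.edges(data=True):
        if d["type"] == type_id:
            continue
        tvec = QuotientGraph.tvec_from(d["src"], d)
        uu = d["src"]
        vv = v if uu == u else u
        mu, du = node_map[uu]
        mv, dv = node_map[vv]
        new_t = tuple(
            int(a + b - c) for a, b, c in zip(du, tvec, dv)
        )
        out.add_edge(mu, mv, new_t, type_id=d["type"], interface_id=d["interface"],
                     area=d.get("area", 0.0), isologous=d.get("isologous", False))
    out.types = {t: info for t, info in qg.types.items() if t != type_id}
    return out, mapping


def _greedy_inter_entity_type(qg: QuotientGraph):
    inter = _inter_entity_types(qg)
    if not inter:
        return None

    def key(t):
        info = qg.types.get(t, TypeInfo(type_id=t))
        p = info.probability if info.probability is not None else 0.0
        return (-p, -info.mean_area, t)

    return min(inter, key=key)


def contract_entities(qg: QuotientGraph):
    """Iteratively contract the greedy inter-entity type until no
    inter-entity types remain (one meta-entity per connected entity block).

    Returns (contracted graph, mapping meta-node -> {original node: offset}).
    """
    current = qg
    mapping = {n: {n: (0, 0, 0)} for n in qg.g.nodes}
    while True:
        c = _greedy_inter_entity_type(current)
        if c is None:
            return current, mapping
        res = contract_type(current, c)
        if res is None:
            raise ValueError(
                f"inter-entity type {c} violates closed symmetry on its own; "
                "contraction would never be engaged"
            )
        current, step = res
        new_mapping = {}
        for meta, members in step.items():
            flat: dict = {}
            for node, off in members.items():
                for orig, off0 in mapping[node].items():
                    flat[orig] = tuple(int(a + b) for a, b in zip(off, off0))
            new_mapping[meta] = flat
        mapping = new_mapping


# ---------------------------------------------------------------------------
# Enumeration


def enumerate_superassemblies(
    qg: QuotientGraph,
    max_types: int = DEFAULT_MAX_TYPES,
    use_contraction: bool | None = None,
) -> list:
    """All valid superassemblies of the lattice graph, largest types first.

    The empty set (all-monomer superassembly) is always present.  The
    result is a set of engaged type subsets independent of traversal order.
    """
    type_ids = qg.type_ids
    if len(type_ids) > max_types:
        raise ValueError(
            f"{len(type_ids)} interface types exceeds max_types={max_types}; "
            "raise the limit or rely on entity contraction"
        )
    if use_contraction is None:
        use_contraction = len(qg.entity_labels) > 1
    if use_contraction and len(qg.entity_labels) > 1:
        candidates = _enum_exact(qg)
        results = []
        for s in sorted(candidates, key=sorted):
            sa = validate_superassembly(qg, s)
            if sa.valid:
                results.append(sa)
        return results
    return [validate_superassembly(qg, s) for s in sorted(_enum_dfs(qg), key=sorted)]


def _enum_dfs(qg: QuotientGraph) -> set:
    """Pruned depth-first power-set traversal; returns valid engaged sets."""
    type_ids = qg.type_ids
    valid: set = set()

    def visit(prefix: tuple, start: int):
        engaged = frozenset(prefix)
        r4 = check_closed_symmetry(qg, engaged)
        if not r4.valid:
            return  # rule-4 failures poison every superset
        if check_isomorphism(qg, engaged).valid:
            valid.add(engaged)
        for i in range(start, len(type_ids)):
            visit(prefix + (type_ids[i],), i + 1)

    visit((), 0)
    return valid


def _entity_blocks(qg: QuotientGraph) -> list:
    """Groups of entities connected through inter-entity interface types."""
    eg = nx.Graph()
    eg.add_nodes_from(qg.entity_labels)
    for u, v, d in qg.g.edges(data=True):
        eu, ev = qg.entity_of(u), qg.entity_of(v)
        if eu != ev:
            eg.add_edge(eu, ev)
    return [set(c) for c in nx.connected_components(eg)]


def _induced_block(qg: QuotientGraph, entities: set) -> QuotientGraph:
    out = QuotientGraph()
    keep = [n for n in qg.g.nodes if qg.entity_of(n) in entities]
    for n in keep:
        d = qg.g.nodes[n]
        out.g.add_node(n, **d)
    block_types = set()
    for u, v, d in qg.g.edges(data=True):
        if u in out.g and v in out.g:
            src = d["src"]
            dst = v if src == u else u
            out.add_edge(src, dst, d["tvec"], d["type"], d["interface"],
                         d.get("area", 0.0), d.get("isologous", False))
            block_types.add(d["type"])
    out.types = {t: info for t, info in qg.types.items() if t in block_types}
    return out


def _enum_exact(qg: QuotientGraph) -> set:
    """Exact contraction-based enumeration for heteromeric graphs.

    Returns candidate engaged sets (validated again by the caller on the
    original graph).
    """
    if len(qg.entity_labels) <= 1:
        return _enum_dfs(qg)
    blocks = _entity_blocks(qg)
    if len(blocks) > 1:
        per_block = [_enum_exact(_induced_block(qg, b)) for b in blocks]
        combined = {frozenset()}
        for sets in per_block:
            combined = {a | b for a in combined for b in sets}
        return combined
    c = _greedy_inter_entity_type(qg)
    if c is None:  # single block but no inter-entity edges: treat as homomer mix
        return _enum_dfs(qg)
    results: set = set()
    contracted = contract_type(qg, c)
    if contracted is not None:
        sub_sets = _enum_exact(contracted[0])
        results |= {s | {c} for s in sub_sets}
    deleted = qg.copy()
    deleted.g.remove_edges_from(_type_edges(qg, c))
    deleted.types = {t: i for t, i in qg.types.items() if t != c}
    results |= _enum_exact(deleted)
    return results


# ---------------------------------------------------------------------------
# Point-group annotation


def annotate_point_groups(superassemblies, qg, structure=None, tol: float = 2.0):
    """Fill Assembly.point_group for every valid superassembly.

    With a structure, groups are detected geometrically from chain-set
    self-isometries; for abstract graphs a topological heuristic is used.
    """
    for sa in superassemblies:
        if not sa.valid:
            continue
        for asm in sa.assemblies:
            if structure is not None:
                asm.point_group = _geometric_point_group(asm, structure, tol)
            else:
                asm.point_group = _topological_point_group(asm, qg, sa.engaged)
    return superassemblies


def _geometric_point_group(asm: Assembly, structure, tol: float) -> str:
    coords, entities = [], []
    by_entity_len: dict = {}
    for node, offset in asm.members:
        chain_id, op_id = node.rsplit("_", 1)
        chain = structure.chain(chain_id)
        moved = apply_operator(chain, structure.op(int(op_id)), offset, structure.cell)
        ids, ca = moved.ca_coords()
        coords.append((chain.entity_id, dict(zip(ids, range(len(ids)))), ca))
        entities.append(chain.entity_id)
    # restrict each entity's chains to shared residue ids so arrays match
    matched = []
    for ent, idmap, ca in coords:
        common = None
        for e2, idmap2, _ in coords:
            if e2 == ent:
                s = set(idmap2)
                common = s if common is None else (common & s)
        ids = sorted(common)
        matched.append(ca[[idmap[i] for i in ids]])
    return detect_point_group(matched, entities, tol)


def _topological_point_group(asm: Assembly, qg: QuotientGraph, engaged) -> str:
    counts = set(asm.stoichiometry.values())
    u = max(counts) if counts else 1
    has_iso = False
    has_het = False
    sub = qg.engaged_subgraph(engaged)
    nodes = {n for n, _ in asm.members}
    comp = sub.subgraph(nodes)
    for a, b, d in comp.edges(data=True):
        if d.get("isologous", False):
            has_iso = True
        else:
            has_het = True
    single_cycle = comp.number_of_edges() == comp.number_of_nodes()
    return infer_point_group_topological(u, has_iso, has_het, single_cycle)
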