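"""The periodic lattice graph (crystal net) of a protein crystal.

Nodes are chain images in one unit cell, identified "A_1"-style by chain id
and 1-based space-group operator id.  Edges are interface instances labeled
with an integer lattice-translation vector (the Miller-index difference
between the two participating chains), an interface id and an interface
type id.  Although drawn in one cell, the graph represents every contact in
the infinite crystal; translations make cycles with non-zero net shift
detectable (infinite assemblies).

The graph also has an abstract entry point: a JSON dialect carrying nodes,
edges and per-type probabilities lets callers bypass geometry entirely.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "QuotientGraph",
    "TypeInfo",
    "build_lattice_graph",
    "cycle_basis",
    "graph_to_json",
    "graph_from_json",
    "export_graph",
    "import_graph",
]


@dataclasses.dataclass
class TypeInfo:
    type_id: int
    probability: float | None = None
    mean_area: float = 0.0
    isologous: bool = False
    entity_pair: tuple | None = None
    n_members: int = 0


class QuotientGraph:
    """Labeled multigraph of one unit cell with translation-tagged edges.

    Edge translation vectors are oriented: each edge stores its source node
    and the integer vector source -> target; traversing the edge backwards
    negates the vector (``tvec_from`` handles this).
    """

    def __init__(self):
        self.g = nx.MultiGraph()
        self.types: dict = {}  # type_id -> TypeInfo
        self._edge_keys = set()

    # -- construction ---------------------------------------------------

    def add_node(self, chain: str, op: int, entity: str):
        self.g.add_node(f"{chain}_{op}", chain=chain, op=op, entity=entity)

    def add_edge(self, src: str, dst: str, tvec, type_id: int,
                 interface_id: int = 0, area: float = 0.0, isologous: bool = False):
        """Add one edge in canonical orientation; duplicates are ignored.

        Canonical: the lexicographically lower endpoint is the source; for
        self-loops the first non-zero translation component is positive.
        """
        tvec = tuple(int(x) for x in tvec)
        if dst < src:
            src, dst, tvec = dst, src, tuple(-x for x in tvec)
        elif dst == src:
            for x in tvec:
                if x > 0:
                    break
                if x < 0:
                    tvec = tuple(-v for v in tvec)
                    break
        key = (src, dst, tvec, interface_id)
        if key in self._edge_keys:
            return False
        self._edge_keys.add(key)
        self.g.add_edge(src, dst, tvec=tvec, src=src, type=type_id,
                        interface=interface_id, area=area, isologous=isologous)
        return True

    # -- queries --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def entity_of(self, node: str) -> str:
        return self.g.nodes[node]["entity"]

    @property
    def entity_labels(self) -> list:
        seen = []
        for n in sorted(self.g.nodes):
            e = self.entity_of(n)
            if e not in seen:
                seen.append(e)
        return sorted(seen)

    @property
    def type_ids(self) -> list:
        return sorted(self.types)

    @staticmethod
    def tvec_from(node: str, data: dict) -> tuple:
        """Translation vector oriented away from ``node`` along this edge."""
        t = data["tvec"]
        return t if data["src"] == node else tuple(-x for x in t)

    def engaged_subgraph(self, engaged) -> nx.MultiGraph:
        engaged = set(engaged)
        sub = nx.MultiGraph()
        sub.add_nodes_from(self.g.nodes(data=True))
        for u, v, k, d in self.g.edges(keys=True, data=True):
            if d["type"] in engaged:
                sub.add_edge(u, v, key=k, **d)
        return sub

    def copy(self) -> "QuotientGraph":
        out = QuotientGraph()
        out.g = self.g.copy()
        out.types = dict(self.types)
        out._edge_keys = set(self._edge_keys)
        return out


# ---------------------------------------------------------------------------
# Geometry -> graph lift


def build_lattice_graph(structure, interfaces, types=None) -> QuotientGraph:
    """Lift detected interfaces to the full unit-cell quotient graph.

    Every AU interface (chain i, identity) -- (chain j, g, t) induces, for
    each group operator h, an edge between nodes (i, h) and (j, h∘g) with a
    translation adjusted by the composition's residual lattice vector.  The
    result is closed under the group action.
    """
    qg = QuotientGraph()
    chains = [ch for ch in structure.chains if ch.is_protein]
    for ch in chains:
        for op in structure.space_group:
            qg.add_node(ch.chain_id, op.op_id, ch.entity_id)

    for iface in interfaces:
        g_op = structure.op(iface.chain_b.op_id)
        t = iface.chain_b.cell_shift
        for h in structure.space_group:
            k_op, shift = structure.compose(h, g_op, t)
            # node a: (chain_a, h) at cell offset given by h's pure part (0)
            # node b: (chain_b, k) shifted by the composition residual
            na = f"{iface.chain_a.chain_id}_{h.op_id}"
            nb = f"{iface.chain_b.chain_id}_{k_op.op_id}"
            qg.add_edge(
                na, nb, tuple(int(x) for x in shift),
                type_id=iface.type_id or 0,
                interface_id=iface.interface_id,
                area=iface.area,
                isologous=iface.isologous,
            )
    if types is not None:
        for t_ in types:
            qg.types[t_.type_id] = TypeInfo(
                type_id=t_.type_id,
                probability=t_.probability,
                mean_area=t_.mean_area,
                isologous=t_.isologous,
                entity_pair=t_.entity_pair,
                n_members=len(t_.members),
            )
    else:
        _infer_types(qg)
    return qg


def _infer_types(qg: QuotientGraph):
    for u, v, d in qg.g.edges(data=True):
        tid = d["type"]
        info = qg.types.setdefault(tid, TypeInfo(type_id=tid))
        info.n_members += 1
        info.mean_area = d.get("area", 0.0)
        info.isologous = d.get("isologous", False)
        info.entity_pair = tuple(sorted((qg.entity_of(u), qg.entity_of(v))))


# ---------------------------------------------------------------------------
# Cycle machinery


def cycle_basis(sub: nx.MultiGraph, qg_cls=QuotientGraph) -> list:
    """Fundamental cycle basis of an engaged subgraph (Paton-style).

    Builds a BFS spanning forest; every non-tree edge (self-loops included)
    closes exactly one basis cycle.  Each cycle is returned as a list of
    (node, next_node, edge_data, oriented_tvec) steps; the basis size is
    |E| - |V| + #components.
    """
    cycles = []
    seen = set()
    for comp in nx.connected_components(sub):
        root = min(comp)
        parent = {root: None}  # node -> (pred, edge_data)
        order = [root]
        tree_edges = set()
        queue = [root]
        while queue:
            u = queue.pop(0)
            for _, v, k, d in sub.edges(u, keys=True, data=True):
                if v not in parent:
                    parent[v] = (u, d)
                    tree_edges.add((min(u, v), max(u, v), k))
                    order.append(v)
                    queue.append(v)
        seen |= comp
        for u, v, k, d in sub.edges(comp, keys=True, data=True):
            if (min(u, v), max(u, v), k) in tree_edges:
                continue
            if u > v:
                u, v = v, u  # deterministic orientation of the chord
            cycles.append(_close_cycle(u, v, d, parent, qg_cls))
    return cycles


def _close_cycle(u, v, chord, parent, qg_cls):
    """Cycle = tree path v -> root -> u plus the chord u -> v."""

    def path_to_root(x):
        steps = []
        while parent[x] is not None:
            pred, d = parent[x]
            steps.append((x, pred, d))
            x = pred
        return steps, x

    up_u, _ = path_to_root(u)
    up_v, _ = path_to_root(v)
    # strip the common tail above the lowest common ancestor
    while up_u and up_v and up_u[-1] == up_v[-1]:
        up_u.pop()
        up_v.pop()
    steps = []
    for x, pred, d in reversed(up_u):  # from LCA down... traverse pred -> x
        steps.append((pred, x, d, qg_cls.tvec_from(pred, d)))
    steps.append((u, v, chord, qg_cls.tvec_from(u, chord)))
    for x, pred, d in up_v:  # back from v up to the LCA
        steps.append((x, pred, d, qg_cls.tvec_from(x, d)))
    return steps


def cycle_net_translation(cycle) -> tuple:
    net = np.zeros(3, dtype=int)
    for _, _, _, tvec in cycle:
        net += np.array(tvec, dtype=int)
    return tuple(int(x) for x in net)


def component_offsets(sub: nx.MultiGraph, comp) -> tuple:
    """BFS cell offsets for one component plus the list of offending edges.

    Offsets place each node at root_offset + sum of translations along the
    tree path.  An edge whose endpoints' offsets are inconsistent with its
    translation vector witnesses a non-zero-net cycle (rule-4 violation).
    """
    root = min(comp)
    off = {root: np.zeros(3, dtype=int)}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for _, v, d in sub.edges(u, data=True):
            if v not in off:
                off[v] = off[u] + np.array(QuotientGraph.tvec_from(u, d), dtype=int)
                queue.append(v)
    bad = []
    for u, v, k, d in sub.edges(comp, keys=True, data=True):
        residual = off[u] + np.array(QuotientGraph.tvec_from(u, d)) - off[v]
        if residual.any():
            bad.append((u, v, k, tuple(int(x) for x in residual)))
    return {n: tuple(int(x) for x in o) for n, o in off.items()}, bad


# ---------------------------------------------------------------------------
# Serialization ("lattice-graph JSON" and GraphML)


def graph_to_json(qg: QuotientGraph) -> dict:
    nodes = [
        {"id": n, "chain": d["chain"], "op": d["op"], "entity": d["entity"]}
        for n, d in sorted(qg.g.nodes(data=True))
    ]
    edges = []
    for u, v, d in qg.g.edges(data=True):
        src = d["src"]
        dst = v if src == u else u
        edges.append(
            {
                "src": src,
                "dst": dst,
                "type": d["type"],
                "interface": d["interface"],
                "xtal": list(d["tvec"]),
                "area": d.get("area", 0.0),
                "isologous": bool(d.get("isologous", False)),
            }
        )
    edges.sort(key=lambda e: (e["src"], e["dst"], e["interface"], e["xtal"]))
    types = [
        {
            "id": t.type_id,
            "p": t.probability,
            "area": t.mean_area,
            "isologous": t.isologous,
        }
        for t in (qg.types[k] for k in sorted(qg.types))
    ]
    return {"nodes": nodes, "edges": edges, "types": types}


def graph_from_json(doc: dict) -> QuotientGraph:
    qg = QuotientGraph()
    for n in doc.get("nodes", []):
        qg.add_node(n["chain"], int(n["op"]), str(n["entity"]))
    for e in doc.get("edges", []):
        qg.add_edge(
            e["src"], e["dst"], tuple(e.get("xtal", (0, 0, 0))),
            type_id=int(e["type"]), interface_id=int(e.get("interface", 0)),
            area=float(e.get("area", 0.0)), isologous=bool(e.get("isologous", False)),
        )
    if doc.get("types"):
        for t in doc["types"]:
            qg.types[int(t["id"])] = TypeInfo(
                type_id=int(t["id"]),
                probability=t.get("p"),
                mean_area=float(t.get("area", 0.0)),
                isologous=bool(t.get("isologous", False)),
            )
    else:
        _infer_types(qg)
    return qg


def export_graph(qg: QuotientGraph, path, fmt: str = "json"):
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(graph_to_json(qg), indent=1))
    elif fmt == "graphml":
        g = nx.MultiGraph()
        g.add_nodes_from(qg.g.nodes(data=True))
        for u, v, d in qg.g.edges(data=True):
            g.add_edge(u, v, tvec=",".join(map(str, d["tvec"])), src=d["src"],
                       type=d["type"], interface=d["interface"],
                       area=float(d.get("area", 0.0)),
                       isologous=bool(d.get("isologous", False)))
        # type table rides along as graph attributes
        for tid, t in qg.types.items():
            g.graph[f"type_{tid}"] = json.dumps(
                {"p": t.probability, "area": t.mean_area, "isologous": t.isologous}
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def import_graph(path, fmt: str = "auto") -> QuotientGraph:
    path = Path(path)
    if fmt == "auto":
        fmt = "graphml" if path.suffix == ".graphml" else "json"
    if fmt == "json":
        return graph_from_json(json.loads(path.read_text()))
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        qg = QuotientGraph()
        for n, d in g.nodes(data=True):
            qg.add_node(d["chain"], int(d["op"]), str(d["entity"]))
        for u, v, d in g.edges(data=True):
            tvec = tuple(int(x) for x in d["tvec"].split(","))
            src = d["src"]
            dst = v if src == u else u
            qg.add_edge(src, dst, tvec, type_id=int(d["type"]),
                        interface_id=int(d["interface"]), area=float(d.get("area", 0.0)),
                        isologous=bool(d.get("isologous", False)))
        for key, val in g.graph.items():
            if str(key).startswith("type_"):
                info = json.loads(val)
                tid = int(str(key)[5:])
                qg.types[tid] = TypeInfo(
                    type_id=tid, probability=info.get("p"),
                    mean_area=info.get("area", 0.0),
                    isologous=info.get("isologous", False),
                )
        if not qg.types:
            _infer_types(qg)
        return qg
    raise ValueError(f"unknown graph format {fmt!r}")
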