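"""Deterministic synthetic fixtures: abstract lattice graphs, miniature
crystals and painted-entropy alignments.

Every topological regime the assembly rules distinguish has a canned
template: an isologous C2 dimer, an infinite fiber (and its capped
contrast), a lattice whose dimer is not isomorphic throughout, a D3
hexamer with an induced interface, a two-entity heterodimer for
contraction, and seeded random graphs for oracle testing.  Geometric
templates write minimal mmCIF crystals of rigid pseudo-atom clouds whose
end-to-end pipeline output matches the corresponding abstract graph.
Same template + seed always yields byte-identical output.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import gemmi
import numpy as np

from .lattice import QuotientGraph, graph_from_json

__all__ = [
    "GRAPH_TEMPLATES",
    "CRYSTAL_TEMPLATES",
    "make_graph_fixture",
    "make_crystal_fixture",
    "make_entity_alignment",
    "FixtureError",
]


class FixtureError(ValueError):
    pass


AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_LETTERS = "".join(AA1TO3)


# ---------------------------------------------------------------------------
# Abstract lattice-graph templates


def _node(chain, op=1, entity="1"):
    return {"id": f"{chain}_{op}", "chain": chain, "op": op, "entity": entity}


def _edge(src, dst, type_id, xtal=(0, 0, 0), interface=0, area=0.0, isologous=False):
    return {
        "src": src, "dst": dst, "type": type_id, "interface": interface,
        "xtal": list(xtal), "area": area, "isologous": isologous,
    }


def _c2_dimer(seed=0):
    """One entity, one isologous type; {} and {1} valid, dimer is C2."""
    return {
        "nodes": [_node("A", 1), _node("A", 2)],
        "edges": [_edge("A_1", "A_2", 1, interface=1, area=820.0, isologous=True)],
        "types": [{"id": 1, "p": 0.9, "area": 820.0, "isologous": True}],
    }


def _fiber(seed=0):
    """Uncapped fiber: a chain contacting its own +a translate.

    Engaging the type closes a length-1 cycle with net translation
    (1,0,0) — an infinite filament; only the monomer is valid.
    """
    return {
        "nodes": [_node("A", 1)],
        "edges": [_edge("A_1", "A_1", 1, xtal=(1, 0, 0), interface=1, area=640.0)],
        "types": [{"id": 1, "p": 0.8, "area": 640.0, "isologous": False}],
    }


def _fiber_capped(seed=0):
    """Capped contrast case: the same face-to-back contact interrupted.

    Two NCS copies meet through one heterologous contact whose would-be
    continuation is blocked, so no cycle forms: the asymmetric dimer
    passes all four rules (point group C1).
    """
    return {
        "nodes": [_node("A", 1), _node("B", 1)],
        "edges": [_edge("A_1", "B_1", 1, interface=1, area=640.0)],
        "types": [{"id": 1, "p": 0.8, "area": 640.0, "isologous": False}],
    }


def _non_isomorphic(seed=0):
    """A valid-looking C2 dimer that is not isomorphic throughout.

    Four chains of one entity; each isologous type pairs only two of them,
    leaving the others as monomers — rule 3 rejects every dimer subset and
    the engaged pair of types gives two non-isomorphic dimers (different
    edge labels).  Only the monomer survives.
    """
    return {
        "nodes": [_node(c, 1) for c in "ABCD"],
        "edges": [
            _edge("A_1", "B_1", 1, interface=1, area=900.0, isologous=True),
            _edge("C_1", "D_1", 2, interface=2, area=850.0, isologous=True),
        ],
        "types": [
            {"id": 1, "p": 0.6, "area": 900.0, "isologous": True},
            {"id": 2, "p": 0.55, "area": 850.0, "isologous": True},
        ],
    }


def _d3_hexamer(seed=0):
    """D3 hexamer: two 3-member isologous types plus the 6-member
    heterologous ring, one of the three induced."""
    top = ["A", "B", "C"]
    bot = ["D", "E", "F"]
    edges = []
    iid = itertools.count(1)
    for k in range(3):  # type 1: stacked 2-fold contacts
        edges.append(_edge(f"{top[k]}_1", f"{bot[k]}_1", 1,
                           interface=next(iid), area=1000.0, isologous=True))
    for k in range(3):  # type 2: diagonal 2-fold contacts
        edges.append(_edge(f"{top[k]}_1", f"{bot[(k + 1) % 3]}_1", 2,
                           interface=next(iid), area=800.0, isologous=True))
    for ring in (top, bot):  # type 3: the C3 rings
        for k in range(3):
            edges.append(_edge(f"{ring[k]}_1", f"{ring[(k + 1) % 3]}_1", 3,
                               interface=next(iid), area=300.0))
    return {
        "nodes": [_node(c, 1) for c in top + bot],
        "edges": edges,
        "types": [
            {"id": 1, "p": 0.95, "area": 1000.0, "isologous": True},
            {"id": 2, "p": 0.4, "area": 800.0, "isologous": True},
            {"id": 3, "p": 0.9, "area": 300.0, "isologous": False},
        ],
    }


def _heterodimer_ab(seed=0):
    """Two entities joined by one heterologous type (contraction tests)."""
    return {
        "nodes": [_node("A", 1, "1"), _node("B", 1, "2")],
        "edges": [_edge("A_1", "B_1", 1, interface=1, area=600.0)],
        "types": [{"id": 1, "p": 0.8, "area": 600.0, "isologous": False}],
    }


def _random_graph(n=6, seed=0, n_chains=None, n_entities=1, zero_translation=False):
    """Seeded random abstract lattice graph with n interface types.

    ``zero_translation`` yields rule-4-clean graphs (all edge vectors 0,
    no self-loops); otherwise translations are drawn from {-1,0,1}^3 and
    self-loops are allowed (never with a zero vector).
    """
    rng = np.random.default_rng(seed)
    if n_chains is None:
        n_chains = int(rng.integers(2, 6))
    n_chains = max(n_chains, n_entities)
    chains = [chr(ord("A") + i) for i in range(n_chains)]
    entities = [str(i % n_entities + 1) for i in range(n_chains)]
    order = rng.permutation(n_chains)
    nodes = [_node(chains[i], 1, entities[order[i]]) for i in range(n_chains)]
    entity_of = {nd["id"]: nd["entity"] for nd in nodes}

    n_edges = int(rng.integers(n, 2 * n + 3))
    type_of_edge = list(range(1, n + 1)) + [
        int(rng.integers(1, n + 1)) for _ in range(n_edges - n)
    ]
    edges = []
    seen = set()
    for ei, tid in enumerate(type_of_edge, start=1):
        for _ in range(40):
            a = int(rng.integers(n_chains))
            b = int(rng.integers(n_chains))
            if zero_translation:
                if a == b:
                    continue
                xtal = (0, 0, 0)
            else:
                xtal = tuple(int(x) for x in rng.integers(-1, 2, size=3))
                if a == b and xtal == (0, 0, 0):
                    xtal = (1, 0, 0)
            src, dst = f"{chains[a]}_1", f"{chains[b]}_1"
            if dst < src:
                src, dst = dst, src
                xtal = tuple(-x for x in xtal)
            key = (src, dst, xtal)
            if key in seen:
                continue
            seen.add(key)
            same = entity_of[src] == entity_of[dst]
            edges.append(
                _edge(src, dst, tid, xtal=xtal, interface=ei,
                      area=1000.0 - 40.0 * (tid - 1),
                      isologous=bool(same and rng.random() < 0.5))
            )
            break
    present = sorted({e["type"] for e in edges})
    types = [
        {
            "id": t,
            "p": float(np.round(rng.uniform(0.05, 0.95), 3)),
            "area": 1000.0 - 40.0 * (t - 1),
            "isologous": all(e["isologous"] for e in edges if e["type"] == t),
        }
        for t in present
    ]
    return {"nodes": nodes, "edges": edges, "types": types}


GRAPH_TEMPLATES = {
    "c2_dimer": _c2_dimer,
    "fiber": _fiber,
    "fiber_capped": _fiber_capped,
    "non_isomorphic": _non_isomorphic,
    "d3_hexamer": _d3_hexamer,
    "heterodimer_ab": _heterodimer_ab,
    "random": _random_graph,
}


def make_graph_fixture(name: str, seed: int = 0, as_graph: bool = False, **params):
    """Lattice-graph JSON for a canned template (or a QuotientGraph)."""
    if name not in GRAPH_TEMPLATES:
        raise FixtureError(
            f"unknown graph template {name!r}; available: "
            + ", ".join(sorted(GRAPH_TEMPLATES))
        )
    doc = GRAPH_TEMPLATES[name](seed=seed, **params)
    return graph_from_json(doc) if as_graph else doc


# ---------------------------------------------------------------------------
# Geometric (mmCIF) templates


def _cloud(rng, n_atoms=12, radius=2.6) -> np.ndarray:
    """Rigid asymmetric pseudo-atom cloud centred at the origin."""
    pts = rng.normal(size=(n_atoms, 3))
    pts *= radius * rng.uniform(0.35, 1.0, size=(n_atoms, 1)) / np.linalg.norm(
        pts, axis=1, keepdims=True
    )
    return pts - pts.mean(axis=0)


def _sequence(rng, n) -> str:
    return "".join(AA_LETTERS[i] for i in rng.integers(0, 20, size=n))


def _rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


_C2X = np.diag([1.0, -1.0, -1.0])


def _geo_c2_dimer(seed):
    rng = np.random.default_rng(seed)
    cloud = _cloud(rng)
    seq = _sequence(rng, len(cloud))
    # the 2-fold of P 1 2 1 runs along b at x=z=0; straddle it
    chains = {"A": cloud + np.array([3.4, 15.0, 0.6])}
    return ("P 1 2 1", (50.0, 30.0, 50.0, 90.0, 90.0, 90.0), chains, {"A": seq})


def _geo_fiber(seed):
    rng = np.random.default_rng(seed)
    cloud = _cloud(rng)
    seq = _sequence(rng, len(cloud))
    chains = {"A": cloud + np.array([0.0, 20.0, 20.0])}
    return ("P 1", (8.2, 40.0, 40.0, 90.0, 90.0, 90.0), chains, {"A": seq})


def _geo_heterodimer_ab(seed):
    rng = np.random.default_rng(seed)
    ca, cb = _cloud(rng), _cloud(rng)
    sa, sb = _sequence(rng, len(ca)), _sequence(rng, len(cb))
    chains = {
        "A": ca + np.array([12.0, 12.0, 12.0]),
        "B": cb + np.array([18.3, 12.0, 12.0]),
    }
    return ("P 1", (50.0, 50.0, 50.0, 90.0, 90.0, 90.0), chains, {"A": sa, "B": sb})


def _geo_d3_hexamer(seed):
    """Six copies of one protomer in exact D3 arrangement (NCS, P1 cell).

    Ring radius, stacking height and an azimuthal offset are chosen so
    each protomer touches its ring neighbours (heterologous), its straight
    2-fold partner (largest contact) and one diagonal 2-fold partner
    (intermediate contact) — three interface types, one induced.
    """
    rng = np.random.default_rng(seed)
    cloud = _cloud(rng, n_atoms=16, radius=2.2)
    seq = _sequence(rng, len(cloud))
    r, h2, phi0 = 4.6, 2.3, 24.0
    base = cloud + np.array([r, 0.0, h2])
    base = base @ _rot_z(phi0).T
    centre = np.array([40.0, 40.0, 40.0])
    chains = {}
    seqs = {}
    for k, name in enumerate("ABC"):
        chains[name] = base @ _rot_z(120 * k).T + centre
        seqs[name] = seq
    for k, name in enumerate("DEF"):
        chains[name] = (base @ _C2X.T) @ _rot_z(120 * k).T + centre
        seqs[name] = seq
    return ("P 1", (80.0, 80.0, 80.0, 90.0, 90.0, 90.0), chains, seqs)


CRYSTAL_TEMPLATES = {
    "c2_dimer": _geo_c2_dimer,
    "fiber": _geo_fiber,
    "heterodimer_ab": _geo_heterodimer_ab,
    "d3_hexamer": _geo_d3_hexamer,
}

CLASH_DISTANCE = 1.5  # Å


def make_crystal_fixture(name: str, path=None, seed: int = 0) -> str:
    """Write a minimal mmCIF crystal for a canned geometric template.

    Returns the mmCIF text (and writes it to ``path`` if given).  Raises
    FixtureError for unknown templates or clashing chain placements.
    """
    if name not in CRYSTAL_TEMPLATES:
        raise FixtureError(
            f"unknown crystal template {name!r}; available: "
            + ", ".join(sorted(CRYSTAL_TEMPLATES))
        )
    sg_symbol, cell, chains, seqs = CRYSTAL_TEMPLATES[name](seed)
    _check_clashes(sg_symbol, cell, chains)

    st = gemmi.Structure()
    st.name = name
    st.cell = gemmi.UnitCell(*cell)
    st.spacegroup_hm = sg_symbol
    model = gemmi.Model("1")
    for cname in sorted(chains):
        chain = gemmi.Chain(cname)
        seq = seqs[cname]
        for i, pos in enumerate(chains[cname]):
            res = gemmi.Residue()
            res.name = AA1TO3[seq[i]]
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("X")  # pseudo-atom, vdW radius 1.9 Å
            atom.pos = gemmi.Position(*(float(x) for x in pos))
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    _merge_entities_by_sequence(st)
    text = st.make_mmcif_document().as_string()
    if path is not None:
        Path(path).write_text(text)
    return text


def _merge_entities_by_sequence(st: gemmi.Structure):
    """Rebuild the entity table so identical-sequence chains share one
    entity (gemmi's setup_entities gives every subchain its own)."""
    groups: dict = {}
    for chain in st[0]:
        poly = chain.get_polymer()
        key = tuple(r.name for r in poly)
        groups.setdefault(key, []).append(poly.subchain_id())
    st.entities.clear()
    for i, (key, subchains) in enumerate(groups.items(), start=1):
        ent = gemmi.Entity(str(i))
        ent.entity_type = gemmi.EntityType.Polymer
        ent.polymer_type = gemmi.PolymerType.PeptideL
        ent.subchains = subchains
        ent.full_sequence = list(key)
        st.entities.append(ent)


def _check_clashes(sg_symbol, cell, chains):
    from .structure import CrystalCell, space_group_ops

    ccell = CrystalCell(*cell)
    ops = space_group_ops(sg_symbol)
    coords = {n: np.asarray(c) for n, c in chains.items()}
    names = sorted(coords)
    images = []
    for n in names:
        frac = ccell.fractionalize(coords[n])
        for op in ops:
            for t in itertools.product((-1, 0, 1), repeat=3):
                images.append((n, op.op_id, t, ccell.orthogonalize(op.apply_frac(frac) + np.array(t))))
    for i, (na, oa, ta, ca) in enumerate(images):
        for nb, ob, tb, cb in images[i + 1 :]:
            if (na, oa, ta) == (nb, ob, tb):
                continue
            d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
            if d2.min() < CLASH_DISTANCE**2:
                raise FixtureError(
                    f"chains {na}({oa},{ta}) and {nb}({ob},{tb}) clash: "
                    f"min distance {np.sqrt(d2.min()):.2f} Å"
                )


# ---------------------------------------------------------------------------
# Synthetic alignments


def make_entity_alignment(
    sequence: str,
    conserved: set,
    seed: int = 0,
    n_rows: int = 30,
    fasta_path=None,
):
    """Alignment with entropy painted low on ``conserved`` positions.

    Conserved columns sample letters only from the query residue's reduced
    class (zero reduced-alphabet entropy); other columns sample uniformly
    over all twenty letters (high entropy).  Row 0 is the query.
    """
    from .evo import ALPHABET_CLASSES, EntityAlignment

    class_of = {}
    for cls in ALPHABET_CLASSES:
        for ch in cls:
            class_of[ch] = cls
    rng = np.random.default_rng(seed)
    rows = [sequence]
    for _ in range(n_rows - 1):
        row = []
        for i, ch in enumerate(sequence):
            if i in conserved:
                cls = class_of.get(ch, ch)
                row.append(cls[rng.integers(len(cls))])
            else:
                row.append(AA_LETTERS[rng.integers(20)])
        rows.append("".join(row))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">seq{i}\n{row}\n")
    return EntityAlignment(entity_id="?", rows=rows, query_index=0)
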