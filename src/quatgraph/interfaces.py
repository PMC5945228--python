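"""Pairwise crystal contacts: detection, buried surface area, core/rim
residues, clustering into interface types and isologous/heterologous calls.

An interface is a contact between an asymmetric-unit chain (identity
operator) and any chain image (space-group operator + lattice translation
within a 3x3x3 cell neighborhood).  Interface *types* are equivalence
classes of contacts with similar residue-residue contact sets between the
same entity pair — the unit the assembly rules operate on.
"""

from __future__ import annotations

import dataclasses
import itertools
import json

import numpy as np
from scipy.spatial import cKDTree

from . import sasa
from .structure import ChainRecord, Structure, apply_operator

__all__ = [
    "NodeRef",
    "Interface",
    "InterfaceType",
    "find_interfaces",
    "buried_surface_area",
    "classify_core_rim",
    "cluster_interface_types",
    "detect_isologous",
    "interfaces_to_records",
]

DEFAULT_CUTOFF = 5.5  # Å, atom-atom candidate detection
DEFAULT_MIN_AREA = 35.0  # Å², micro-contact floor
DEFAULT_CORE_CUTOFF = 0.95  # burial fraction bsa/asa for core residues
DEFAULT_SURFACE_CUTOFF = 0.05  # relative ASA for surface residues
DEFAULT_SIM_CUTOFF = 0.3  # Jaccard threshold for type clustering
ISOLOGOUS_TOL = 0.8  # transpose-Jaccard threshold


@dataclasses.dataclass(frozen=True, order=True)
class NodeRef:
    """Reference to a chain image: (chain id, operator id, cell shift)."""

    chain_id: str
    op_id: int
    cell_shift: tuple

    def __str__(self):
        s = "" if self.cell_shift == (0, 0, 0) else str(tuple(self.cell_shift))
        return f"{self.chain_id}_{self.op_id}{s}"


@dataclasses.dataclass
class Interface:
    """One pairwise contact in the crystal, with per-residue burial data."""

    interface_id: int
    chain_a: NodeRef
    chain_b: NodeRef
    entity_a: str
    entity_b: str
    area: float
    contacts: frozenset  # residue-index pairs (a-side, b-side)
    core_a: list
    core_b: list
    rim_a: list
    rim_b: list
    isologous: bool
    type_id: int | None = None
    probability: float | None = None  # filled by the scoring stage
    # per-residue arrays used by the evolutionary scoring
    bsa_a: np.ndarray | None = dataclasses.field(default=None, repr=False)
    bsa_b: np.ndarray | None = dataclasses.field(default=None, repr=False)
    asa_a: np.ndarray | None = dataclasses.field(default=None, repr=False)
    asa_b: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def entity_pair(self) -> tuple:
        return tuple(sorted((self.entity_a, self.entity_b)))

    def canonical_contacts(self) -> frozenset:
        """Contact set with the lower entity on the first side."""
        if self.entity_a <= self.entity_b:
            return self.contacts
        return frozenset((b, a) for a, b in self.contacts)


@dataclasses.dataclass
class InterfaceType:
    type_id: int
    members: list  # list[Interface]
    mean_area: float
    entity_pair: tuple
    isologous: bool
    probability: float | None = None

    @property
    def member_ids(self) -> list:
        return [i.interface_id for i in self.members]


# ---------------------------------------------------------------------------


def buried_surface_area(
    chain_a: ChainRecord,
    chain_b: ChainRecord,
    probe: float = sasa.DEFAULT_PROBE,
    n_points: int = sasa.DEFAULT_N_POINTS,
) -> float:
    """BSA = ASA(A) + ASA(B) - ASA(AB), Shrake-Rupley, probe 1.4 Å."""
    asa_a = sasa.atom_asa(chain_a.coords, chain_a.radii, probe, n_points).sum()
    asa_b = sasa.atom_asa(chain_b.coords, chain_b.radii, probe, n_points).sum()
    coords = np.vstack([chain_a.coords, chain_b.coords])
    radii = np.concatenate([chain_a.radii, chain_b.radii])
    asa_ab = sasa.atom_asa(coords, radii, probe, n_points).sum()
    return float(asa_a + asa_b - asa_ab)


def classify_core_rim(
    bsa_res: np.ndarray,
    asa_res: np.ndarray,
    res_names,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    surface_cutoff: float = DEFAULT_SURFACE_CUTOFF,
    bsa_tol: float = 0.1,
) -> list:
    """Label each residue core / rim / surface / buried.

    Core: interface residue with burial fraction bsa/asa >= core_cutoff.
    Rim: any other interface residue (bsa > 0).  Surface: non-interface
    residue whose relative ASA exceeds surface_cutoff.  A residue with
    zero isolated ASA can never be core.
    """
    labels = []
    for bsa, asa, name in zip(bsa_res, asa_res, res_names):
        if bsa > bsa_tol and asa > 0:
            labels.append("core" if bsa / asa >= core_cutoff else "rim")
        elif asa / sasa.max_asa(name) >= surface_cutoff:
            labels.append("surface")
        else:
            labels.append("buried")
    return labels


def detect_isologous(contacts: frozenset, same_entity: bool, tol: float = ISOLOGOUS_TOL) -> bool:
    """True iff both partners engage the same face (2-fold-like contact).

    Measured as the Jaccard similarity between the residue-residue contact
    set and its transpose; only meaningful for same-entity contacts.
    """
    if not same_entity or not contacts:
        return False
    transpose = frozenset((b, a) for a, b in contacts)
    return _jaccard(contacts, transpose) >= tol


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------


def find_interfaces(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    min_area: float = DEFAULT_MIN_AREA,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    surface_cutoff: float = DEFAULT_SURFACE_CUTOFF,
    probe: float = sasa.DEFAULT_PROBE,
    n_points: int = sasa.DEFAULT_N_POINTS,
) -> list:
    """All unique pairwise interfaces in the crystal, largest area first.

    Each contact between chain i (identity) and an image of chain j within
    the 3x3x3 cell neighborhood is reported once in canonical orientation.
    Interface ids are 1-based by non-increasing area (ties broken
    lexicographically by chain/operator/shift).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chains = [ch for ch in structure.chains if ch.is_protein]
    if not chains:
        raise ValueError("structure has no protein chains")
    cell = structure.cell

    # caches keyed by (chain index, op id): rotated coords and isolated ASA
    op_coords: dict = {}
    asa_cache: dict = {}

    def image(ci: int, op_id: int) -> np.ndarray:
        if (ci, op_id) not in op_coords:
            op_coords[(ci, op_id)] = apply_operator(
                chains[ci], structure.op(op_id), (0, 0, 0), cell
            ).coords
        return op_coords[(ci, op_id)]

    def iso_asa(ci: int, op_id: int) -> np.ndarray:
        if (ci, op_id) not in asa_cache:
            ch = chains[ci]
            asa_cache[(ci, op_id)] = sasa.residue_asa(
                image(ci, op_id), ch.radii, ch.atom_res, ch.n_residues, probe, n_points
            )
        return asa_cache[(ci, op_id)]

    shifts = [np.array(s) for s in itertools.product((-1, 0, 1), repeat=3)]
    raw = []
    for i, j in itertools.combinations_with_replacement(range(len(chains)), 2):
        cha, chb = chains[i], chains[j]
        reach = cha.bounding_radius + chb.bounding_radius + cutoff
        for op in structure.space_group:
            base = image(j, op.op_id)
            base_centroid = base.mean(axis=0)
            for t in shifts:
                if i == j and op.op_id == 1 and not t.any():
                    continue  # self image
                if i == j and not _self_pair_canonical(structure, op, t):
                    continue
                delta = cell.orthogonalize(t.astype(float))
                if np.linalg.norm(cha.centroid - (base_centroid + delta)) > reach:
                    continue
                coords_b = base + delta
                iface = _build_interface(
                    structure, cha, chb, coords_b,
                    NodeRef(cha.chain_id, 1, (0, 0, 0)),
                    NodeRef(chb.chain_id, op.op_id, tuple(int(x) for x in t)),
                    iso_asa(i, 1), iso_asa(j, op.op_id),
                    cutoff, min_area, core_cutoff, probe, n_points,
                )
                if iface is not None:
                    raw.append(iface)

    raw.sort(key=lambda f: (-f.area, f.chain_a, f.chain_b))
    for n, iface in enumerate(raw, start=1):
        iface.interface_id = n
    return raw


def _self_pair_canonical(structure: Structure, op, t: np.ndarray) -> bool:
    """For same-chain pairs, keep one of {(g,t), inverse(g,t)}.

    Preference: smaller operator id; for ties, lexicographically larger
    shift (so a pure +a translation contact is reported as shift (1,0,0)).
    """
    inv_op, extra = structure.invert(op, tuple(int(x) for x in t))
    key = (op.op_id, tuple(-int(x) for x in t))
    inv_key = (inv_op.op_id, tuple(-int(x) for x in extra))
    return key <= inv_key


def _build_interface(
    structure, cha, chb, coords_b, ref_a, ref_b, asa_a, asa_b,
    cutoff, min_area, core_cutoff, probe, n_points,
):
    tree_a = cKDTree(cha.coords)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, cutoff)
    contacts = set()
    for ia, nbrs in enumerate(pairs):
        for ib in nbrs:
            contacts.add((int(cha.atom_res[ia]), int(chb.atom_res[ib])))
    if not contacts:
        return None

    combined = np.vstack([cha.coords, coords_b])
    radii = np.concatenate([cha.radii, chb.radii])
    atom_res = np.concatenate([cha.atom_res, chb.atom_res + cha.n_residues])
    asa_cplx = sasa.residue_asa(
        combined, radii, atom_res, cha.n_residues + chb.n_residues, probe, n_points
    )
    bsa_a = np.clip(asa_a - asa_cplx[: cha.n_residues], 0.0, None)
    bsa_b = np.clip(asa_b - asa_cplx[cha.n_residues :], 0.0, None)
    area = float(bsa_a.sum() + bsa_b.sum())
    if area < min_area:
        return None

    labels_a = classify_core_rim(bsa_a, asa_a, cha.res_names, core_cutoff)
    labels_b = classify_core_rim(bsa_b, asa_b, chb.res_names, core_cutoff)
    contacts = frozenset(contacts)
    same_entity = cha.entity_id == chb.entity_id
    return Interface(
        interface_id=0,
        chain_a=ref_a,
        chain_b=ref_b,
        entity_a=cha.entity_id,
        entity_b=chb.entity_id,
        area=area,
        contacts=contacts,
        core_a=[k for k, l in enumerate(labels_a) if l == "core"],
        core_b=[k for k, l in enumerate(labels_b) if l == "core"],
        rim_a=[k for k, l in enumerate(labels_a) if l == "rim"],
        rim_b=[k for k, l in enumerate(labels_b) if l == "rim"],
        isologous=detect_isologous(contacts, same_entity),
        bsa_a=bsa_a,
        bsa_b=bsa_b,
        asa_a=asa_a,
        asa_b=asa_b,
    )


# ---------------------------------------------------------------------------


def cluster_interface_types(
    interfaces: list,
    sim_cutoff: float = DEFAULT_SIM_CUTOFF,
) -> list:
    """Single-linkage clustering of contacts into interface types.

    Two interfaces join one type iff they connect the same unordered entity
    pair and their entity-level contact sets have Jaccard similarity >=
    sim_cutoff (for same-entity contacts, the transpose orientation is also
    tried).  Types are numbered 1..k by descending mean member area.
    """
    n = len(interfaces)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for x, y in itertools.combinations(range(n), 2):
        fa, fb = interfaces[x], interfaces[y]
        if fa.entity_pair != fb.entity_pair:
            continue
        ca, cb = fa.canonical_contacts(), fb.canonical_contacts()
        sim = _jaccard(ca, cb)
        if fa.entity_a == fa.entity_b:
            sim = max(sim, _jaccard(ca, frozenset((b, a) for a, b in cb)))
        if sim >= sim_cutoff:
            union(x, y)

    groups: dict = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(interfaces[k])
    clusters = sorted(
        groups.values(),
        key=lambda g: (-float(np.mean([f.area for f in g])), min(f.interface_id for f in g)),
    )
    types = []
    for tid, members in enumerate(clusters, start=1):
        for f in members:
            f.type_id = tid
        types.append(
            InterfaceType(
                type_id=tid,
                members=members,
                mean_area=float(np.mean([f.area for f in members])),
                entity_pair=members[0].entity_pair,
                isologous=all(f.isologous for f in members),
            )
        )
    return types


# ---------------------------------------------------------------------------


def interfaces_to_records(interfaces: list) -> list:
    """Plain-dict rows for TSV/JSON export."""
    rows = []
    for f in interfaces:
        rows.append(
            {
                "id": f.interface_id,
                "typeId": f.type_id,
                "chainA": str(f.chain_a),
                "chainB": str(f.chain_b),
                "operator": f.chain_b.op_id,
                "shift": list(f.chain_b.cell_shift),
                "area": round(f.area, 2),
                "isologous": f.isologous,
                "coreA": len(f.core_a),
                "coreB": len(f.core_b),
            }
        )
    return rows


def interfaces_to_json(interfaces: list) -> str:
    return json.dumps(interfaces_to_records(interfaces), indent=1)
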