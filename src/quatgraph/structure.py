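"""Crystal structures: unit cell, space-group operators, chains and entities.

Parsing of mmCIF/PDB files is delegated to gemmi; this module exposes the
minimal crystallographic model the rest of the package operates on.  All
symmetry algebra is done in fractional coordinates; atom coordinates are
stored in Cartesian angstroms.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "CrystalCell",
    "SymOp",
    "ChainRecord",
    "Structure",
    "read_structure",
    "apply_operator",
    "StructureError",
]

# Van der Waals radii (angstrom) for the elements common in protein models.
# 'X' is the pseudo-atom element used by the synthetic fixture generator.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "X": 1.90,
}
DEFAULT_RADIUS = 1.80


class StructureError(ValueError):
    """Raised when an input structure is unusable (missing cell, no polymers...)."""


@dataclasses.dataclass(frozen=True)
class CrystalCell:
    """Unit-cell geometry with orthogonalization/fractionalization transforms."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        object.__setattr__(self, "_orth", self._orth_matrix())
        object.__setattr__(self, "_frac", np.linalg.inv(self._orth))

    def _orth_matrix(self) -> np.ndarray:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def orth_matrix(self) -> np.ndarray:
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        return self._frac

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> Cartesian (works on (3,) vectors or (N, 3) arrays)."""
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        """Cartesian -> fractional."""
        return np.asarray(cart, dtype=float) @ self._frac.T

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self._orth)))


@dataclasses.dataclass(frozen=True)
class SymOp:
    """A space-group operator in the fractional basis.

    ``op_id`` is 1-based in the order of the space-group table; the identity
    is always op 1.  ``rot`` has integer entries in the fractional basis and
    ``tran`` is the fractional translation part.
    """

    op_id: int
    rot: tuple  # 3x3 nested tuple of ints/floats
    tran: tuple  # fractional 3-vector

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.tran, dtype=float)

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rot_array, np.eye(3))
            and np.allclose(self.tran_array, 0.0)
        )

    def apply_frac(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rot_array.T + self.tran_array

    def triplet(self) -> str:
        op = gemmi.Op()
        den = gemmi.Op.DEN
        op.rot = [[int(round(x * den)) for x in row] for row in self.rot]
        op.tran = [int(round(x * den)) for x in self.tran]
        return op.triplet()


@dataclasses.dataclass
class ChainRecord:
    """One polymer chain: residue bookkeeping plus a flat Cartesian atom table."""

    chain_id: str
    entity_id: str
    sequence: str
    res_names: list  # residue names, len = n residues
    res_ids: list  # author residue numbers (or sequential for fixtures)
    coords: np.ndarray  # (n_atoms, 3) Cartesian angstrom
    atom_res: np.ndarray  # (n_atoms,) residue index per atom
    atom_names: list
    elements: list
    is_protein: bool = True

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in self.elements])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.coords - self.centroid, axis=1).max())

    def ca_coords(self) -> tuple:
        """(residue ids, coords) of CA atoms; falls back to first atom per residue."""
        mask = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        if len(mask) == self.n_residues:
            return list(self.res_ids), self.coords[mask]
        # fall back: one representative atom per residue
        reps = []
        seen = set()
        for i, r in enumerate(self.atom_res):
            if r not in seen:
                seen.add(r)
                reps.append(i)
        return [self.res_ids[self.atom_res[i]] for i in reps], self.coords[reps]

    def transformed(self, coords: np.ndarray) -> "ChainRecord":
        return dataclasses.replace(self, coords=coords)


@dataclasses.dataclass
class Structure:
    cell: CrystalCell
    space_group: list  # list[SymOp]
    chains: list  # list[ChainRecord]
    pdb_id: str | None = None
    space_group_symbol: str | None = None

    def __post_init__(self):
        if not self.chains:
            raise StructureError("structure has no chains")
        if not self.space_group:
            raise StructureError("structure has no symmetry operators")
        self._op_lookup = None

    @property
    def n_ops(self) -> int:
        return len(self.space_group)

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    def op(self, op_id: int) -> SymOp:
        return self.space_group[op_id - 1]

    @property
    def entities(self) -> dict:
        """entity id -> list of chain ids, in chain order."""
        out: dict = {}
        for ch in self.chains:
            out.setdefault(ch.entity_id, []).append(ch.chain_id)
        return out

    # -- group algebra -------------------------------------------------

    def _lookup(self):
        if self._op_lookup is None:
            table = {}
            for op in self.space_group:
                key = _op_key(op.rot_array, op.tran_array)
                table[key] = op
            self._op_lookup = table
        return self._op_lookup

    def find_op(self, rot: np.ndarray, tran: np.ndarray):
        """Match (rot, tran) to a group operator modulo lattice translations.

        Returns (SymOp, integer shift) with tran = op.tran + shift, or raises
        if the element is not in the group (a bookkeeping error upstream).
        """
        key = _op_key(rot, tran)
        op = self._lookup().get(key)
        if op is None:
            raise StructureError("operator composition left the space group")
        shift = np.rint(np.asarray(tran) - op.tran_array).astype(int)
        if not np.allclose(tran - shift, op.tran_array, atol=1e-6):
            raise StructureError("non-integer residual lattice translation")
        return op, shift

    def compose(self, op_a: SymOp, op_b: SymOp, shift_b=(0, 0, 0)):
        """op_a ∘ (op_b + shift_b) as (SymOp, integer shift)."""
        rot = op_a.rot_array @ op_b.rot_array
        tran = op_a.rot_array @ (op_b.tran_array + np.asarray(shift_b, dtype=float)) + op_a.tran_array
        return self.find_op(rot, tran)

    def invert(self, op: SymOp, shift=(0, 0, 0)):
        """Inverse of (op + shift) as (SymOp, integer shift)."""
        rinv = np.linalg.inv(op.rot_array)
        tran = -rinv @ (op.tran_array + np.asarray(shift, dtype=float))
        return self.find_op(rinv, tran)


def _op_key(rot: np.ndarray, tran: np.ndarray) -> tuple:
    r = tuple(int(round(x * 24)) for x in np.asarray(rot).ravel())
    t = tuple(int(round(x * 24)) % 24 for x in np.asarray(tran).ravel())
    return r + t


def space_group_ops(symbol: str) -> list:
    """Resolve a Hermann–Mauguin symbol to the 1-based operator list."""
    sg = gemmi.SpaceGroup(symbol)
    den = float(gemmi.Op.DEN)
    ops = []
    raw = list(sg.operations())
    # put the identity first
    raw.sort(key=lambda op: 0 if op.triplet() == "x,y,z" else 1)
    for i, op in enumerate(raw, start=1):
        rot = tuple(tuple(x / den for x in row) for row in op.rot)
        tran = tuple((x / den) % 1.0 for x in op.tran)
        ops.append(SymOp(op_id=i, rot=rot, tran=tran))
    return ops


# ---------------------------------------------------------------------------
# Parsing


def read_structure(path, fmt: str = "auto") -> Structure:
    """Read a crystal structure from mmCIF or PDB.

    Non-polymer components (waters, ligands) are dropped.  Nucleic-acid
    chains are kept but flagged ``is_protein=False`` and excluded from
    interface scoring downstream.  Entities come from file metadata when
    present, else from exact sequence identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "auto":
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    if fmt == "mmcif":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    elif fmt == "pdb":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    st.setup_entities()
    st.remove_alternative_conformations()  # keeps the highest-occupancy conformer
    st.remove_hydrogens()
    st.remove_ligands_and_waters()

    cell = st.cell
    if not cell.is_crystal() or cell.a <= 0:
        raise StructureError(f"{path.name}: missing or invalid _cell record")
    sg = st.find_spacegroup()
    if sg is None:
        raise StructureError(f"{path.name}: missing or unresolvable space-group symbol")

    ops = space_group_ops(sg.xhm())
    ccell = CrystalCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    if len(st) == 0:
        raise StructureError(f"{path.name}: no polymer chains found")
    model = st[0]
    chains = []
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        ptype = polymer.check_polymer_type()
        is_protein = ptype in (
            gemmi.PolymerType.PeptideL,
            gemmi.PolymerType.PeptideD,
            gemmi.PolymerType.Unknown,
        )
        rec = _chain_record(chain, polymer, is_protein)
        if rec.n_atoms:
            chains.append(rec)
    if not chains:
        raise StructureError(f"{path.name}: no polymer chains found")

    _assign_entities(st, chains)
    pdb_id = st.name.lower() if st.name else None
    return Structure(
        cell=ccell,
        space_group=ops,
        chains=chains,
        pdb_id=pdb_id,
        space_group_symbol=sg.xhm(),
    )


def _chain_record(chain, polymer, is_protein: bool) -> ChainRecord:
    res_names, res_ids, atom_names, elements = [], [], [], []
    coords, atom_res = [], []
    for ridx, res in enumerate(polymer):
        res_names.append(res.name)
        res_ids.append(res.seqid.num)
        for atom in res:
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            atom_res.append(ridx)
            atom_names.append(atom.name)
            elements.append(atom.element.name)
    seq = gemmi.one_letter_code([r for r in res_names])
    return ChainRecord(
        chain_id=chain.name,
        entity_id="?",
        sequence=seq.upper(),
        res_names=res_names,
        res_ids=res_ids,
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        atom_res=np.array(atom_res, dtype=int),
        atom_names=atom_names,
        elements=elements,
        is_protein=is_protein,
    )


def _assign_entities(st: gemmi.Structure, chains: Sequence[ChainRecord]) -> None:
    """Entity labels from mmCIF metadata, or sequence-identity fallback."""
    meta = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer:
            for sub in ent.subchains:
                meta[sub] = ent.name
    by_name = {}
    for chain in st[0]:
        poly = chain.get_polymer()
        if len(poly):
            sub = poly.subchain_id()
            if sub in meta:
                by_name[chain.name] = meta[sub]

    if len(set(by_name.values())) > 0 and len(by_name) == len(chains):
        # normalize metadata labels to 1..k in chain order
        order: dict = {}
        for ch in chains:
            lbl = by_name[ch.chain_id]
            order.setdefault(lbl, str(len(order) + 1))
            ch.entity_id = order[lbl]
        return
    # fallback: exact sequence identity
    order = {}
    for ch in chains:
        order.setdefault(ch.sequence, str(len(order) + 1))
        ch.entity_id = order[ch.sequence]


# ---------------------------------------------------------------------------
# Coordinate transforms


def apply_operator(
    chain: ChainRecord,
    op: SymOp,
    cell_shift,
    cell: CrystalCell,
) -> ChainRecord:
    """Return a copy of ``chain`` transformed by ``op`` plus a lattice shift.

    transform(x) = orthogonalize(rot · fractionalize(x) + tran + cell_shift)
    """
    frac = cell.fractionalize(chain.coords)
    moved = op.apply_frac(frac) + np.asarray(cell_shift, dtype=float)
    return chain.transformed(cell.orthogonalize(moved))
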