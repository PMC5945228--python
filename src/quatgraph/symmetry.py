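"""Point-group detection for assemblies.

Geometric route: candidate isometries are generated by superposing every
ordered pair of same-entity member chains (Kabsch); a candidate is a
self-isometry of the assembly if it permutes the whole chain set with
per-chain RMSD below tolerance.  This covers both crystallographic and
non-crystallographic (NCS) symmetry.  The collected proper rotations are
classified by group order and axis structure into C1, Cn, Dn, T, O or I.

Topological route (for abstract lattice graphs without coordinates): a
heuristic based on chain counts and isologous/heterologous edge content.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["detect_point_group", "infer_point_group_topological"]

DEFAULT_RMSD_TOL = 2.0  # Å per chain mapping
MAX_ORDER = 60


def _rotation_order(R: np.ndarray, tol: float = 1e-3) -> int | None:
    acc = np.eye(3)
    for k in range(1, MAX_ORDER + 1):
        acc = acc @ R
        if np.allclose(acc, np.eye(3), atol=tol):
            return k
    return None


def _superpose(a: np.ndarray, b: np.ndarray):
    """Best proper rotation + translation mapping a onto b (Kabsch)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    rmsd = float(np.sqrt(((a @ R.T + t - b) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def detect_point_group(member_coords, member_entities, tol: float = DEFAULT_RMSD_TOL):
    """Point group of a set of chains given matched coordinate arrays.

    ``member_coords``: list of (n_i, 3) arrays; same-entity chains must have
    equal atom counts in a consistent order.  Returns a label in
    {C1, Cn, Dn, T, O, I, none}.
    """
    n = len(member_coords)
    if n == 1:
        return "C1"
    sym_ops = _self_isometries(member_coords, member_entities, tol)
    if len(sym_ops) == 1:
        # no symmetry found: a complex with one copy per entity is a
        # legitimate (trivially C1) assembly; repeated entities that
        # nothing maps onto each other are a genuine symmetry failure
        counts: dict = {}
        for e in member_entities:
            counts[e] = counts.get(e, 0) + 1
        return "C1" if max(counts.values()) == 1 else "none"
    return classify_rotation_group([R for R, _ in sym_ops])


def _self_isometries(coords, entities, tol):
    n = len(coords)
    ops = [(np.eye(3), np.zeros(3))]
    seen = {_op_key(np.eye(3), np.zeros(3))}
    for i in range(n):
        for j in range(n):
            if i == j or entities[i] != entities[j]:
                continue
            if coords[i].shape != coords[j].shape:
                continue
            R, t, rmsd = _superpose(coords[i], coords[j])
            if rmsd > tol:
                continue
            if not _maps_set(coords, entities, R, t, tol):
                continue
            key = _op_key(R, t)
            if key not in seen:
                seen.add(key)
                ops.append((R, t))
    return ops


def _maps_set(coords, entities, R, t, tol) -> bool:
    """Does x -> Rx + t permute the member chains (entity-preserving)?"""
    n = len(coords)
    used = set()
    for i in range(n):
        moved = coords[i] @ R.T + t
        ok = False
        for j in range(n):
            if j in used or entities[i] != entities[j]:
                continue
            if coords[j].shape != moved.shape:
                continue
            rmsd = float(np.sqrt(((moved - coords[j]) ** 2).sum(axis=1).mean()))
            if rmsd <= tol:
                used.add(j)
                ok = True
                break
        if not ok:
            return False
    return True


def _op_key(R, t):
    return tuple(np.round(np.concatenate([R.ravel(), t]), 1))


def classify_rotation_group(rotations) -> str:
    """Classify a finite set of proper rotations by order and axes."""
    N = len(rotations)
    if N <= 1:
        return "C1"
    orders, axes = [], []
    for R in rotations:
        if np.allclose(R, np.eye(3), atol=1e-3):
            continue
        k = _rotation_order(R)
        if k is None:
            return "none"
        orders.append(k)
        rv = Rotation.from_matrix(R).as_rotvec()
        nrm = np.linalg.norm(rv)
        axes.append(rv / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0]))
    if not orders:
        return "C1"
    kmax = max(orders)
    if N == kmax:
        return f"C{kmax}"
    if N == 2 * kmax and kmax >= 2:
        # principal axis + perpendicular 2-folds -> dihedral
        principal = axes[int(np.argmax(orders))]
        n_perp = sum(
            1
            for k, ax in zip(orders, axes)
            if k == 2 and abs(float(np.dot(ax, principal))) < 0.1
        )
        if n_perp >= kmax or kmax == 2:
            return f"D{kmax}"
    if N == 12 and kmax == 3:
        return "T"
    if N == 24 and kmax == 4:
        return "O"
    if N == 60 and kmax == 5:
        return "I"
    return "none"


# ---------------------------------------------------------------------------


def infer_point_group_topological(
    n_chains_per_entity: int,
    has_isologous: bool,
    has_heterologous: bool,
    is_single_cycle: bool = False,
) -> str:
    """Heuristic point group for coordinate-free (abstract) assemblies.

    Treats the assembly as a homomer of u protomers (u = copies per entity;
    valid heteromeric assemblies have even stoichiometry).  Cyclic groups
    arise from heterologous interfaces alone; a mix of isologous and
    heterologous contacts in an even-sized assembly, or a closed ring of
    2-fold contacts, indicates a dihedral arrangement.  Open (tree-shaped)
    heterologous assemblies are asymmetric (C1).  Cubic groups (T/O/I) are
    not distinguishable from Dn without coordinates and report as Dn.
    """
    u = n_chains_per_entity
    if u <= 1:
        return "C1"
    if u == 2:
        return "C2" if has_isologous else "C1"
    if has_isologous and has_heterologous:
        return f"D{u // 2}" if u % 2 == 0 else "none"
    if has_isologous:  # only 2-fold contacts
        if is_single_cycle and u % 2 == 0:
            return f"D{u // 2}"
        return "C1" if not is_single_cycle else "none"
    # heterologous only: a closed ring is cyclic, an open chain asymmetric
    return f"C{u}" if is_single_cycle else "C1"
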