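"""Solvent-accessible surface area by the Shrake–Rupley method.

A fixed golden-spiral point set is used on every atom sphere, so ASA values
are fully deterministic (no RNG involved) and reproducible across runs —
a requirement for stable interface identifiers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_N_POINTS = 960
DEFAULT_PROBE = 1.4


def sphere_points(n: int = DEFAULT_N_POINTS) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


_POINT_CACHE: dict = {}


def _points(n: int) -> np.ndarray:
    if n not in _POINT_CACHE:
        _POINT_CACHE[n] = sphere_points(n)
    return _POINT_CACHE[n]


def atom_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area (Å²)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = _points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_r = ext.max()
    out = np.empty(n)
    for i in range(n):
        r = ext[i]
        neigh = tree.query_ball_point(coords[i], r + max_r)
        neigh = [j for j in neigh if j != i]
        surface = coords[i] + r * pts
        if neigh:
            nc = coords[neigh]
            nr = ext[np.asarray(neigh)]
            d2 = ((surface[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            acc = np.count_nonzero(~buried)
        else:
            acc = n_points
        out[i] = 4.0 * np.pi * r * r * acc / n_points
    return out


def residue_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    atom_res: np.ndarray,
    n_residues: int,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-residue ASA: sum of member-atom ASAs."""
    per_atom = atom_asa(coords, radii, probe=probe, n_points=n_points)
    out = np.zeros(n_residues)
    np.add.at(out, np.asarray(atom_res), per_atom)
    return out


# Theoretical maximum ASA (Å²) per residue in a Gly-X-Gly context
# (Tien et al. 2013, "theoretical" column), used for relative ASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ASA = 200.0


def max_asa(res_name: str) -> float:
    return MAX_ASA.get(res_name.upper(), DEFAULT_MAX_ASA)
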