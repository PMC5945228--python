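import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from quatgraph.interfaces import (
    classify_core_rim,
    cluster_interface_types,
    detect_isologous,
    find_interfaces,
)
from quatgraph.structure import CrystalCell, ChainRecord, Structure, read_structure, space_group_ops


def brute_force_contact_pairs(structure, cutoff=5.5, min_atoms=1):
    """Independent oracle: all-pairs distance scan over the explicit 3x3x3
    supercell, counting unordered contacting chain-image pairs that involve
    at least one identity-operator chain in the central cell."""
    images = []
    for ch in structure.chains:
        frac = structure.cell.fractionalize(ch.coords)
        for op in structure.space_group:
            for t in itertools.product((-1, 0, 1), repeat=3):
                coords = structure.cell.orthogonalize(op.apply_frac(frac) + np.array(t))
                images.append((ch.chain_id, op.op_id, t, coords))
    contacts = set()
    for ca, oa, ta, xa in images:
        if oa != 1 or ta != (0, 0, 0):
            continue
        tree_a = cKDTree(xa)
        for cb, ob, tb, xb in images:
            if (ca, oa, ta) == (cb, ob, tb):
                continue
            hits = tree_a.query_ball_tree(cKDTree(xb), cutoff)
            if sum(len(x) for x in hits) >= min_atoms:
                contacts.add(frozenset([(ca, oa, ta), (cb, ob, tb)]))
    return contacts


class TestFindInterfaces:
    def test_no_contact_across_large_cell(self):
        cell = CrystalCell(200, 200, 200, 90, 90, 90)
        ops = space_group_ops("P 1")

        def chain(cid, x):
            return ChainRecord(cid, "1", "AA", ["ALA", "ALA"], [1, 2],
                               np.array([[x, 0, 0], [x + 3, 0, 0]]),
                               np.array([0, 1]), ["CA", "CA"], ["X", "X"])

        s = Structure(cell, ops, [chain("A", 0.0), chain("B", 100.0)])
        assert find_interfaces(s) == []

    def test_c2_dimer_matches_supercell_oracle(self, c2_pipeline):
        s, found, _, _ = c2_pipeline
        assert len(found) == 1
        assert found[0].isologous
        oracle = brute_force_contact_pairs(s)
        # the single oracle pair is the 2-fold contact, found once (canonical)
        assert len(oracle) == 1
        (pair,) = oracle
        members = {m[:2] for m in pair}
        assert members == {("A", 1), ("A", 2)}

    def test_fiber_contact_has_unit_cell_shift(self, crystal_dir):
        s = read_structure(crystal_dir / "fiber.cif")
        found = find_interfaces(s)
        assert len(found) == 1
        f = found[0]
        assert f.chain_a.cell_shift == (0, 0, 0)
        assert f.chain_b.cell_shift == (1, 0, 0)
        assert f.chain_b.op_id == 1
        assert not f.isologous
        oracle = brute_force_contact_pairs(s)
        shifts = {tuple(sorted(m[2] for m in pair)) for pair in oracle}
        assert ((-1, 0, 0), (0, 0, 0)) in shifts or ((0, 0, 0), (1, 0, 0)) in shifts

    def test_interface_ids_ordered_by_area(self, hexamer_pipeline):
        _, found, _, _ = hexamer_pipeline
        areas = [f.area for f in found]
        assert areas == sorted(areas, reverse=True)
        assert [f.interface_id for f in found] == list(range(1, len(found) + 1))

    def test_no_duplicate_edges_after_canonicalization(self, hexamer_pipeline):
        _, found, _, _ = hexamer_pipeline
        keys = {(f.chain_a, f.chain_b) for f in found}
        assert len(keys) == len(found)
        for f in found:
            assert (f.chain_a.chain_id, f.chain_a.op_id, f.chain_a.cell_shift) != (
                f.chain_b.chain_id, f.chain_b.op_id, f.chain_b.cell_shift
            )

    def test_invariant_under_asymmetric_unit_rechoice(self, c2_pipeline):
        from quatgraph.structure import apply_operator

        s, found, types, _ = c2_pipeline
        moved = [apply_operator(ch, s.op(2), (0, 0, 0), s.cell) for ch in s.chains]
        s2 = Structure(s.cell, s.space_group, moved, "rechosen")
        found2 = find_interfaces(s2)
        assert len(found2) == len(found)
        for a, b in zip(found, found2):
            assert abs(a.area - b.area) < 0.5
            assert a.isologous == b.isologous


class TestCoreRim:
    def test_engineered_burial_fractions(self):
        bsa = np.array([50.0, 25.0, 0.0])
        asa = np.array([50.0, 50.0, 50.0])
        labels = classify_core_rim(bsa, asa, ["ALA", "ALA", "ALA"])
        assert labels == ["core", "rim", "surface"]

    def test_zero_isolated_asa_never_core(self):
        labels = classify_core_rim(np.array([1.0]), np.array([0.0]), ["ALA"])
        assert labels == ["buried"]

    def test_buried_residue_below_surface_cutoff(self):
        labels = classify_core_rim(np.array([0.0]), np.array([2.0]), ["TRP"])
        assert labels == ["buried"]  # 2/285 < 5% relative ASA


class TestClustering:
    def _iface(self, iid, contacts, area, ea="1", eb="1"):
        from quatgraph.interfaces import Interface, NodeRef

        return Interface(
            interface_id=iid,
            chain_a=NodeRef("A", 1, (0, 0, 0)),
            chain_b=NodeRef("B", 1, (0, 0, 0)),
            entity_a=ea, entity_b=eb, area=area,
            contacts=frozenset(contacts),
            core_a=[], core_b=[], rim_a=[], rim_b=[],
            isologous=False,
        )

    def test_identical_contacts_cluster_together(self):
        c = [(1, 2), (2, 3)]
        types = cluster_interface_types([self._iface(1, c, 500), self._iface(2, c, 480)])
        assert len(types) == 1
        assert types[0].member_ids == [1, 2]

    def test_disjoint_contacts_split(self):
        types = cluster_interface_types(
            [self._iface(1, [(1, 2)], 500), self._iface(2, [(7, 8)], 480)]
        )
        assert len(types) == 2

    def test_single_linkage_matches_connected_components(self):
        """Chained similarities 0.5-0.5-0.1 merge through the middle link."""
        a = [(1, 1), (2, 2), (3, 3), (4, 4)]
        b = [(3, 3), (4, 4), (5, 5), (6, 6)]      # J(a,b) = 1/3
        c = [(5, 5), (6, 6), (7, 7), (8, 8)]      # J(b,c) = 1/3, J(a,c) = 0
        types = cluster_interface_types(
            [self._iface(1, a, 500), self._iface(2, b, 490), self._iface(3, c, 480)],
            sim_cutoff=0.3,
        )
        assert len(types) == 1  # single linkage chains all three
        types = cluster_interface_types(
            [self._iface(1, a, 500), self._iface(2, b, 490), self._iface(3, c, 480)],
            sim_cutoff=0.4,
        )
        assert len(types) == 3

    def test_type_ids_by_descending_mean_area(self, hexamer_pipeline):
        _, _, types, _ = hexamer_pipeline
        areas = [t.mean_area for t in types]
        assert areas == sorted(areas, reverse=True)
        assert [t.type_id for t in types] == [1, 2, 3]
        assert [len(t.members) for t in types] == [3, 3, 6]


class TestIsologous:
    def test_exact_twofold_contact_is_isologous(self):
        contacts = frozenset([(1, 5), (5, 1), (2, 2)])
        assert detect_isologous(contacts, same_entity=True)

    def test_disjoint_faces_are_heterologous(self):
        contacts = frozenset([(1, 10), (2, 11)])
        assert not detect_isologous(contacts, same_entity=True)

    def test_different_entities_never_isologous(self):
        contacts = frozenset([(1, 1)])
        assert not detect_isologous(contacts, same_entity=False)

    def test_near_symmetric_contact_straddles_threshold(self):
        # 9 symmetric pairs + 1 asymmetric: transpose Jaccard = 9/11 > 0.8
        sym = [(i, i) for i in range(9)]
        contacts = frozenset(sym + [(20, 30)])
        assert detect_isologous(contacts, same_entity=True)
        # 8 symmetric + 2 asymmetric: 8/12 < 0.8
        contacts = frozenset(sym[:8] + [(20, 30), (21, 31)])
        assert not detect_isologous(contacts, same_entity=True)
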