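import numpy as np
import pytest

from quatgraph.enumeration import (
    annotate_point_groups,
    check_closed_symmetry,
    check_isomorphism,
    contract_entities,
    enumerate_superassemblies,
    extract_assemblies,
    validate_superassembly,
)
from quatgraph.lattice import graph_from_json
from quatgraph.oracles import brute_force_valid_sets, supercell_growth_is_closed
from quatgraph.symmetry import classify_rotation_group, detect_point_group

from conftest import graph_fixture, random_graph


def valid_sets(qg, **kw):
    return {sa.engaged for sa in enumerate_superassemblies(qg, **kw)}


class TestClosedSymmetry:
    def test_empty_engaged_set_is_valid(self):
        qg = graph_fixture("d3_hexamer")
        assert check_closed_symmetry(qg, frozenset()).valid

    def test_fiber_self_loop_fails_with_witness(self):
        qg = graph_fixture("fiber")
        res = check_closed_symmetry(qg, {1})
        assert not res.valid
        assert res.failed_rule == "closure"
        assert res.witness  # the offending cycle

    def test_verdicts_match_supercell_growth_oracle(self):
        rng = np.random.default_rng(77)
        for k in range(25):
            qg = random_graph(seed=int(rng.integers(1 << 30)), n=4)
            engaged = {t for t in qg.type_ids if rng.random() < 0.7}
            fast = check_closed_symmetry(qg, engaged).valid
            slow = supercell_growth_is_closed(qg, engaged)
            assert fast == slow, f"disagreement on seed-case {k}: {sorted(engaged)}"


class TestIsomorphism:
    def test_monomers_of_one_entity_are_isomorphic(self):
        qg = graph_fixture("non_isomorphic")
        assert check_isomorphism(qg, frozenset()).valid

    def test_dimer_plus_monomer_of_same_entity_invalid(self):
        qg = graph_fixture("non_isomorphic")
        res = check_isomorphism(qg, frozenset({1}))
        assert not res.valid and res.failed_rule == "isomorphism"

    def test_orthogonal_stoichiometries_exempt(self):
        doc = {
            "nodes": [
                {"id": "A_1", "chain": "A", "op": 1, "entity": "1"},
                {"id": "B_1", "chain": "B", "op": 1, "entity": "1"},
                {"id": "C_1", "chain": "C", "op": 1, "entity": "2"},
                {"id": "D_1", "chain": "D", "op": 1, "entity": "2"},
                {"id": "E_1", "chain": "E", "op": 1, "entity": "2"},
            ],
            "edges": [
                {"src": "A_1", "dst": "B_1", "type": 1, "interface": 1,
                 "xtal": [0, 0, 0], "isologous": True},
                {"src": "C_1", "dst": "D_1", "type": 2, "interface": 2, "xtal": [0, 0, 0]},
                {"src": "D_1", "dst": "E_1", "type": 2, "interface": 3, "xtal": [0, 0, 0]},
                {"src": "E_1", "dst": "C_1", "type": 2, "interface": 4, "xtal": [0, 0, 0]},
            ],
            "types": [{"id": 1, "p": 0.5}, {"id": 2, "p": 0.5}],
        }
        qg = graph_from_json(doc)
        # A2 dimer + B3 trimer: different shapes but no shared entity
        assert check_isomorphism(qg, frozenset({1, 2})).valid


class TestExtractAssemblies:
    def test_empty_set_gives_all_monomers(self):
        qg = graph_fixture("non_isomorphic")
        asms = extract_assemblies(qg, frozenset())
        assert len(asms) == 4
        assert all(a.size == 1 for a in asms)

    def test_hexamer_engaged_set_gives_one_assembly(self):
        qg = graph_fixture("d3_hexamer")
        asms = extract_assemblies(qg, frozenset({1, 2, 3}))
        assert len(asms) == 1
        assert asms[0].size == 6
        assert asms[0].stoichiometry == {"1": 6}
        assert asms[0].formula() == "A6"

    def test_rule4_violating_set_rejected(self):
        qg = graph_fixture("fiber")
        with pytest.raises(ValueError):
            extract_assemblies(qg, frozenset({1}))

    def test_offsets_independent_of_tree_up_to_global_shift(self):
        for seed in (1, 5, 9):
            qg = random_graph(seed, n=4, zero_translation=True)
            for sa in enumerate_superassemblies(qg):
                for asm in sa.assemblies:
                    offs = dict(asm.members)
                    # recompute from a different root: reversed node order
                    import networkx as nx
                    from quatgraph.lattice import component_offsets

                    sub = qg.engaged_subgraph(sa.engaged)
                    comp = set(offs)
                    off2, bad = component_offsets(sub, comp)
                    assert not bad
                    deltas = {tuple(np.array(offs[n]) - np.array(off2[n])) for n in comp}
                    assert len(deltas) == 1  # differ by one global shift only


class TestEnumeration:
    def test_c2_dimer_two_valid_sets(self):
        assert valid_sets(graph_fixture("c2_dimer")) == {frozenset(), frozenset({1})}

    def test_uncapped_fiber_only_monomer(self):
        assert valid_sets(graph_fixture("fiber")) == {frozenset()}

    def test_capped_fiber_dimer_is_valid(self):
        assert valid_sets(graph_fixture("fiber_capped")) == {frozenset(), frozenset({1})}

    def test_non_isomorphic_lattice_only_monomer(self):
        assert valid_sets(graph_fixture("non_isomorphic")) == {frozenset()}

    def test_d3_hexamer_full_power_set_valid(self):
        got = valid_sets(graph_fixture("d3_hexamer"))
        assert len(got) == 8  # every subset closes properly here

    @pytest.mark.parametrize("n_entities", [1, 2])
    def test_pruned_equals_brute_force(self, n_entities):
        for seed in range(30):
            qg = random_graph(seed + 1000 * n_entities, n=5, n_entities=n_entities)
            assert valid_sets(qg) == brute_force_valid_sets(qg), f"seed {seed}"

    def test_max_types_guard(self):
        qg = graph_fixture("d3_hexamer")
        with pytest.raises(ValueError):
            enumerate_superassemblies(qg, max_types=2)

    def test_every_result_passes_independent_revalidation(self):
        for seed in (3, 13, 23):
            qg = random_graph(seed, n=6)
            for sa in enumerate_superassemblies(qg):
                again = validate_superassembly(qg, sa.engaged)
                assert again.valid

    def test_invalidity_is_monotone_for_closure(self):
        """Any sampled superset of a rule-4-invalid set is also invalid."""
        rng = np.random.default_rng(5)
        for seed in range(10):
            qg = random_graph(seed, n=5)
            all_types = set(qg.type_ids)
            valid = valid_sets(qg)
            for sa_types in [set(t) for t in valid]:
                pass
            for _ in range(10):
                sub = {t for t in all_types if rng.random() < 0.5}
                res = check_closed_symmetry(qg, sub)
                if not res.valid and sub != all_types:
                    extra = rng.choice(sorted(all_types - sub)) if all_types - sub else None
                    if extra is not None:
                        assert not check_closed_symmetry(qg, sub | {int(extra)}).valid


class TestHeteromerContraction:
    def test_homomer_contraction_is_identity(self):
        qg = graph_fixture("c2_dimer")
        cg, mapping = contract_entities(qg)
        assert set(cg.g.nodes) == set(qg.g.nodes)
        assert mapping == {n: {n: (0, 0, 0)} for n in qg.g.nodes}

    def test_heterodimer_contracts_to_one_meta_entity(self):
        qg = graph_fixture("heterodimer_ab")
        cg, mapping = contract_entities(qg)
        assert cg.n_nodes == 1
        (meta,) = cg.g.nodes
        assert set(mapping[meta]) == {"A_1", "B_1"}
        assert len(cg.entity_labels) == 1

    def test_heterodimer_valid_sets(self):
        qg = graph_fixture("heterodimer_ab")
        got = valid_sets(qg)
        assert got == {frozenset(), frozenset({1})}
        sa = [s for s in enumerate_superassemblies(qg) if s.engaged == frozenset({1})][0]
        assert sa.assemblies[0].stoichiometry == {"1": 1, "2": 1}

    @pytest.mark.parametrize("n_entities", [2, 3])
    def test_contraction_equivalent_to_direct_enumeration(self, n_entities):
        for seed in range(20):
            qg = random_graph(seed + 7000 * n_entities, n=5, n_entities=n_entities)
            with_contraction = valid_sets(qg, use_contraction=True)
            direct = valid_sets(qg, use_contraction=False)
            assert with_contraction == direct, f"seed {seed}"


class TestPointGroups:
    def test_monomer_is_c1(self):
        qg = graph_fixture("c2_dimer")
        sas = enumerate_superassemblies(qg)
        annotate_point_groups(sas, qg)
        empty = [sa for sa in sas if not sa.engaged][0]
        assert {a.point_group for a in empty.assemblies} == {"C1"}

    def test_crystallographic_twofold_dimer_is_c2(self, c2_pipeline):
        s, _, _, qg = c2_pipeline
        sas = enumerate_superassemblies(qg)
        annotate_point_groups(sas, qg, structure=s)
        dimer = [sa for sa in sas if sa.engaged][0]
        assert dimer.assemblies[0].point_group == "C2"

    def test_d3_hexamer_detected_geometrically(self, hexamer_pipeline):
        s, _, _, qg = hexamer_pipeline
        sas = enumerate_superassemblies(qg)
        annotate_point_groups(sas, qg, structure=s)
        hexamers = [sa for sa in sas if sa.assemblies and sa.assemblies[0].size == 6]
        assert hexamers
        assert all(sa.assemblies[0].point_group == "D3" for sa in hexamers)
        trimers = [sa for sa in sas
                   if sa.assemblies and sa.assemblies[0].size == 3]
        assert all(a.point_group == "C3" for sa in trimers for a in sa.assemblies)

    def test_explicit_d3_operator_set_classifies(self):
        """Rotation set built from explicit D3 generators has order 6."""
        def rz(deg):
            t = np.radians(deg)
            return np.array([[np.cos(t), -np.sin(t), 0],
                             [np.sin(t), np.cos(t), 0], [0, 0, 1]])

        c2x = np.diag([1.0, -1.0, -1.0])
        rots = []
        for k in range(3):
            rots.append(rz(120 * k))
            rots.append(rz(120 * k) @ c2x)
        assert len(rots) == 6
        assert classify_rotation_group(rots) == "D3"

    def test_consequence_a_valid_assemblies_are_symmetric(self):
        """Every multi-chain assembly of a valid superassembly gets a
        point-group label other than 'none'."""
        for name in ("c2_dimer", "d3_hexamer", "heterodimer_ab", "fiber_capped"):
            qg = graph_fixture(name)
            sas = enumerate_superassemblies(qg)
            annotate_point_groups(sas, qg)
            for sa in sas:
                for asm in sa.assemblies:
                    assert asm.point_group != "none"

    def test_consequence_b_heteromers_have_even_stoichiometry(self):
        """Valid multi-entity assemblies contain equal counts per entity
        (holds when each entity has equal multiplicity in the lattice, as
        in a typical crystal; the generator is pinned accordingly)."""
        for seed in range(15):
            qg = random_graph(seed, n=4, n_entities=2, n_chains=4)
            for sa in enumerate_superassemblies(qg):
                for asm in sa.assemblies:
                    if len(asm.stoichiometry) >= 2:
                        assert len(set(asm.stoichiometry.values())) == 1


class TestDetectPointGroupDirect:
    def _cloud(self, seed=0):
        return np.random.default_rng(seed).normal(size=(8, 3)) * 2

    def test_single_chain_c1(self):
        assert detect_point_group([self._cloud()], ["1"]) == "C1"

    def test_c2_pair(self):
        cloud = self._cloud()
        flip = cloud @ np.diag([-1.0, 1.0, -1.0]).T + np.array([10, 0, 0])
        assert detect_point_group([cloud, flip], ["1", "1"]) == "C2"

    def test_c3_ring(self):
        def rz(deg):
            t = np.radians(deg)
            return np.array([[np.cos(t), -np.sin(t), 0],
                             [np.sin(t), np.cos(t), 0], [0, 0, 1]])

        base = self._cloud() + np.array([8, 0, 0])
        coords = [base @ rz(120 * k).T for k in range(3)]
        assert detect_point_group(coords, ["1"] * 3) == "C3"

    def test_unrelated_chains_give_none(self):
        a = self._cloud(1)
        b = self._cloud(2) + np.array([10, 0, 0])
        assert detect_point_group([a, b], ["1", "1"]) == "none"
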