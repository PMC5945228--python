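import math

import pytest

from quatgraph.enumeration import enumerate_superassemblies
from quatgraph.interfaces import InterfaceType
from quatgraph.lattice import graph_from_json
from quatgraph.pipeline import run_graph
from quatgraph.scoring import (
    merge_induced_equivalents,
    normalize_over_valid,
    predict,
    superassembly_probability,
    type_probability,
)

from conftest import graph_fixture, random_graph


class _FakeIface:
    def __init__(self, iid, p):
        self.interface_id = iid
        self.probability = p


def _type(ps):
    return InterfaceType(type_id=1, members=[_FakeIface(i + 1, p) for i, p in enumerate(ps)],
                         mean_area=100.0, entity_pair=("1", "1"), isologous=False)


class TestTypeProbability:
    @pytest.mark.parametrize("ps,expected", [([0.2, 0.4], 0.3), ([0.9], 0.9),
                                             ([0.1, 0.1, 0.7], 0.3)])
    def test_unweighted_mean(self, ps, expected):
        assert type_probability(_type(ps)) == pytest.approx(expected)

    def test_unscored_member_raises_with_ids(self):
        t = _type([0.5])
        t.members.append(_FakeIface(99, None))
        with pytest.raises(ValueError, match="99"):
            type_probability(t)


class TestSuperassemblyProbability:
    def test_single_type_two_outcomes(self):
        assert superassembly_probability({1}, {1: 0.8}) == pytest.approx(0.8)
        assert superassembly_probability(set(), {1: 0.8}) == pytest.approx(0.2)

    def test_uniform_probabilities(self):
        p = {i: 0.5 for i in range(1, 6)}
        assert superassembly_probability({1, 3}, p) == pytest.approx(0.5**5)

    def test_product_form(self):
        p = {1: 0.9, 2: 0.6, 3: 0.2}
        assert superassembly_probability({1, 2}, p) == pytest.approx(0.9 * 0.6 * 0.8)

    def test_per_type_not_per_instance(self):
        """A C3 ring's three interface instances count once: engaging the
        type scores p, not p^3 (instance products would punish cyclics)."""
        doc = {
            "nodes": [{"id": f"{c}_1", "chain": c, "op": 1, "entity": "1"}
                      for c in "ABC"],
            "edges": [
                {"src": "A_1", "dst": "B_1", "type": 1, "interface": 1, "xtal": [0, 0, 0]},
                {"src": "B_1", "dst": "C_1", "type": 1, "interface": 2, "xtal": [0, 0, 0]},
                {"src": "C_1", "dst": "A_1", "type": 1, "interface": 3, "xtal": [0, 0, 0]},
            ],
            "types": [{"id": 1, "p": 0.8}],
        }
        qg = graph_from_json(doc)
        sas = enumerate_superassemblies(qg)
        normalize_over_valid([sa for sa in sas if sa.valid], {1: 0.8})
        trimer = [sa for sa in sas if sa.engaged][0]
        assert trimer.prob_raw == pytest.approx(0.8)  # not 0.8**3 = 0.512
        assert superassembly_probability({1}, {1: 0.8}) != pytest.approx(0.8**3)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            superassembly_probability({1}, {1: 1.2})


class TestNormalization:
    def test_single_valid_outcome_gets_probability_one(self):
        _, preds = run_graph(graph_fixture("fiber"))
        assert preds[0].probability == pytest.approx(1.0)
        assert preds[0].engaged == frozenset()

    def test_direct_division(self):
        qg = graph_fixture("c2_dimer")
        sas = enumerate_superassemblies(qg)
        scored = normalize_over_valid(sas, {1: 0.432 / 0.48})
        by = {sa.engaged: sa.prob_norm for sa in scored}
        assert by[frozenset({1})] == pytest.approx(0.9)
        assert by[frozenset()] == pytest.approx(0.1)

    def test_complete_event_space_identity(self):
        """When every subset is valid the raw masses already sum to 1."""
        qg = graph_fixture("d3_hexamer")
        sas = enumerate_superassemblies(qg)
        assert len(sas) == 8
        p = {t: qg.types[t].probability for t in qg.type_ids}
        scored = normalize_over_valid(sas, p)
        for sa in scored:
            assert sa.prob_norm == pytest.approx(sa.prob_raw, abs=1e-12)


class TestMergeInduced:
    def test_hexamer_variants_merge_to_most_engaged(self):
        report, preds = run_graph(graph_fixture("d3_hexamer"))
        top = preds[0]
        assert top.engaged == frozenset({1, 2, 3})
        merged = {tuple(m) for m in top.merged_from}
        assert (1, 2) in merged and (1, 3) in merged and (2, 3) in merged
        # p1*p3 + p1*p2' ... : total mass of all hexamer-shaped outcomes
        expected = (0.95 * 0.6 * 0.9 + 0.95 * 0.4 * 0.9
                    + 0.95 * 0.4 * 0.1 + 0.05 * 0.4 * 0.9)
        assert top.probability == pytest.approx(expected)

    def test_disjoint_alternatives_not_merged(self):
        """Two different all-dimer superassemblies share stoichiometry but
        neither contains the other: they stay separate predictions."""
        report, preds = run_graph(graph_fixture("d3_hexamer"))
        dimer_sets = [pr.engaged for pr in preds
                      if pr.assemblies and pr.assemblies[0].size == 2]
        assert frozenset({1}) in dimer_sets and frozenset({2}) in dimer_sets

    def test_no_induced_interfaces_identity(self):
        report, preds = run_graph(graph_fixture("c2_dimer"))
        assert len(preds) == 2
        assert all(len(pr.merged_from) == 1 for pr in preds)

    @pytest.mark.parametrize("name", ["c2_dimer", "fiber", "fiber_capped",
                                      "non_isomorphic", "d3_hexamer", "heterodimer_ab"])
    def test_probability_conservation(self, name):
        _, preds = run_graph(graph_fixture(name))
        assert sum(pr.probability for pr in preds) == pytest.approx(1.0, abs=1e-9)

    def test_probability_conservation_random_graphs(self):
        for seed in range(10):
            _, preds = run_graph(random_graph(seed, n=5))
            assert sum(pr.probability for pr in preds) == pytest.approx(1.0, abs=1e-9)


class TestPredict:
    def test_dimer_wins_at_high_p(self):
        _, preds = run_graph(graph_fixture("c2_dimer"))
        assert preds[0].engaged == frozenset({1})
        assert preds[0].probability == pytest.approx(0.9)

    def test_monomer_wins_at_low_p(self):
        _, preds = run_graph(graph_fixture("c2_dimer"), type_overrides={1: 0.1})
        assert preds[0].engaged == frozenset()
        assert preds[0].probability == pytest.approx(0.9)

    def test_fiber_monomer_certainty(self):
        _, preds = run_graph(graph_fixture("fiber"), type_overrides={1: 0.99})
        assert preds[0].engaged == frozenset()
        assert preds[0].probability == pytest.approx(1.0)

    def test_non_isomorphic_predicts_monomer(self):
        _, preds = run_graph(graph_fixture("non_isomorphic"))
        assert preds[0].engaged == frozenset()
        assert all(a.size == 1 for a in preds[0].assemblies)

    def test_raising_engaged_type_probability_raises_rank(self):
        qg = graph_fixture("c2_dimer")
        low = run_graph(qg, type_overrides={1: 0.2})[1]
        qg2 = graph_fixture("c2_dimer")
        high = run_graph(qg2, type_overrides={1: 0.8})[1]
        rank_low = [pr.engaged for pr in low].index(frozenset({1}))
        rank_high = [pr.engaged for pr in high].index(frozenset({1}))
        assert rank_high < rank_low

    def test_deterministic_output(self):
        r1, _ = run_graph(graph_fixture("d3_hexamer"))
        r2, _ = run_graph(graph_fixture("d3_hexamer"))
        assert r1 == r2
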