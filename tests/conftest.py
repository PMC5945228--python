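import json
from pathlib import Path

import numpy as np
import pytest

from quatgraph.fixtures import make_crystal_fixture, make_graph_fixture
from quatgraph.interfaces import cluster_interface_types, find_interfaces
from quatgraph.lattice import build_lattice_graph
from quatgraph.structure import read_structure

CANNED_GRAPHS = [
    "c2_dimer",
    "fiber",
    "fiber_capped",
    "non_isomorphic",
    "d3_hexamer",
    "heterodimer_ab",
]
CANNED_CRYSTALS = ["c2_dimer", "fiber", "heterodimer_ab", "d3_hexamer"]


@pytest.fixture(scope="session")
def crystal_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("crystals")
    for name in CANNED_CRYSTALS:
        make_crystal_fixture(name, path=out / f"{name}.cif")
    return out


@pytest.fixture(scope="session")
def graph_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("graphs")
    for name in CANNED_GRAPHS:
        doc = make_graph_fixture(name)
        (out / f"{name}.graph.json").write_text(json.dumps(doc))
    return out


def graph_fixture(name, **kw):
    return make_graph_fixture(name, as_graph=True, **kw)


@pytest.fixture(scope="session")
def c2_structure(crystal_dir):
    return read_structure(crystal_dir / "c2_dimer.cif")


@pytest.fixture(scope="session")
def c2_pipeline(c2_structure):
    found = find_interfaces(c2_structure)
    types = cluster_interface_types(found)
    qg = build_lattice_graph(c2_structure, found, types)
    return c2_structure, found, types, qg


@pytest.fixture(scope="session")
def hexamer_pipeline(crystal_dir):
    s = read_structure(crystal_dir / "d3_hexamer.cif")
    found = find_interfaces(s)
    types = cluster_interface_types(found)
    qg = build_lattice_graph(s, found, types)
    return s, found, types, qg


def random_graph(seed, n=5, n_entities=1, **kw):
    return make_graph_fixture("random", seed=seed, n=n, n_entities=n_entities,
                              as_graph=True, **kw)
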