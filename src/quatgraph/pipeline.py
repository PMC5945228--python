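"""End-to-end orchestration: structure -> interfaces -> scores -> lattice
graph -> enumeration -> ranked prediction -> report files."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import gemmi
import numpy as np

from . import evo, interfaces as ifc, lattice, scoring
from .enumeration import (
    annotate_point_groups,
    enumerate_superassemblies,
)
from .structure import Structure, apply_operator, read_structure

log = logging.getLogger("quatgraph")

__all__ = ["RunConfig", "run_full", "run_graph", "build_report", "write_assembly_mmcif"]


@dataclasses.dataclass
class RunConfig:
    """All pipeline knobs; echoed into every report for provenance."""

    input: str | None = None
    format: str = "auto"  # mmcif | pdb | auto
    graph_json: str | None = None
    msa_dir: str | None = None
    probabilities: str | None = None  # JSON file with p overrides
    out_dir: str = "."
    cutoff: float = ifc.DEFAULT_CUTOFF
    min_area: float = ifc.DEFAULT_MIN_AREA
    core_cutoff: float = ifc.DEFAULT_CORE_CUTOFF
    surface_cutoff: float = ifc.DEFAULT_SURFACE_CUTOFF
    sim_cutoff: float = ifc.DEFAULT_SIM_CUTOFF
    n_samples: int = evo.DEFAULT_N_SAMPLES
    seed: int = evo.DEFAULT_SEED
    max_types: int = 32
    write_graphml: bool = False
    assembly_out: str | None = None
    verbosity: int = 0

    def __post_init__(self):
        if not (0 < self.core_cutoff <= 1):
            raise ValueError("core_cutoff must be in (0, 1]")
        if not (0 <= self.sim_cutoff <= 1):
            raise ValueError("sim_cutoff must be in [0, 1]")
        if self.cutoff <= 0 or self.min_area < 0:
            raise ValueError("cutoff must be > 0 and min_area >= 0")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("verbosity")
        return d


def _load_probability_overrides(path):
    """Accepts {"types": {...}}, {"interfaces": {...}} or a bare type map."""
    doc = json.loads(Path(path).read_text())
    if "types" in doc or "interfaces" in doc:
        return (
            {int(k): float(v) for k, v in doc.get("types", {}).items()},
            {int(k): float(v) for k, v in doc.get("interfaces", {}).items()},
        )
    return {int(k): float(v) for k, v in doc.items()}, {}


def _load_alignments(msa_dir, structure: Structure) -> dict:
    out = {}
    for entity_id, chain_ids in structure.entities.items():
        seq = structure.chain(chain_ids[0]).sequence
        for stem in (f"entity_{entity_id}", entity_id, chain_ids[0]):
            for ext in (".fasta", ".fa", ".aln"):
                p = Path(msa_dir) / f"{stem}{ext}"
                if p.exists():
                    out[entity_id] = evo.read_entity_alignment(p, entity_id, seq)
                    break
            if entity_id in out:
                break
    return out


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report files.

    Returns the report dict.  Raises with the failing stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.graph_json:
        qg = lattice.import_graph(config.graph_json)
        type_over = {}
        if config.probabilities:
            type_over, _ = _load_probability_overrides(config.probabilities)
        report, predictions = run_graph(
            qg, type_overrides=type_over, max_types=config.max_types
        )
        report["config"] = config.echo()
        _write_outputs(report, None, None, qg, predictions, config, out_dir)
        return report

    if config.input is None:
        raise ValueError("no input: provide a structure file or a lattice-graph JSON")

    stage = "read"
    try:
        structure = read_structure(config.input, config.format)
        log.info(
            "read %s: %d chains, %d entities, %d ops",
            config.input, len(structure.chains), len(structure.entities), structure.n_ops,
        )

        stage = "interfaces"
        found = ifc.find_interfaces(
            structure,
            cutoff=config.cutoff,
            min_area=config.min_area,
            core_cutoff=config.core_cutoff,
            surface_cutoff=config.surface_cutoff,
        )
        types = ifc.cluster_interface_types(found, sim_cutoff=config.sim_cutoff)
        log.info("%d interfaces in %d types", len(found), len(types))

        stage = "scores"
        type_over, iface_over = {}, {}
        if config.probabilities:
            type_over, iface_over = _load_probability_overrides(config.probabilities)
        alignments = _load_alignments(config.msa_dir, structure) if config.msa_dir else None
        scores = evo.score_interfaces(
            structure, found,
            alignments=alignments,
            probabilities=iface_over,
            n_samples=config.n_samples,
            seed=config.seed,
        )
        for f in found:
            f.probability = scores[f.interface_id].p
        p_by_type = {}
        for t in types:
            t.probability = (
                float(type_over[t.type_id])
                if t.type_id in type_over
                else scoring.type_probability(t)
            )
            p_by_type[t.type_id] = t.probability

        stage = "graph"
        qg = lattice.build_lattice_graph(structure, found, types)

        stage = "enumerate"
        superassemblies = enumerate_superassemblies(qg, max_types=config.max_types)
        for sa in superassemblies:
            if not sa.valid:
                log.debug("invalid %s: rule %s, witness %s",
                          sorted(sa.engaged), sa.failed_rule, sa.witness)
        annotate_point_groups(superassemblies, qg, structure=structure)

        stage = "score"
        predictions = scoring.predict(superassemblies, p_by_type)

        stage = "report"
        report = build_report(structure, found, types, superassemblies, predictions)
        report["config"] = config.echo()
        report["scores"] = {
            str(s.interface_id): {
                "gm": s.gm,
                "cs": None if s.cs is None else round(s.cs, 4),
                "p": round(s.p, 6),
                "flags": s.flags,
            }
            for s in scores.values()
        }
        _write_outputs(report, structure, found, qg, predictions, config, out_dir)
        return report
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_graph(qg, type_overrides=None, max_types: int = 32):
    """Topology-only pipeline for abstract lattice graphs.

    Per-type probabilities come from the graph JSON (overridable); point
    groups are inferred topologically.
    """
    for tid, p in (type_overrides or {}).items():
        if tid in qg.types:
            qg.types[tid].probability = float(p)
    p_by_type = {}
    for tid, info in qg.types.items():
        if info.probability is None:
            raise ValueError(
                f"type {tid} has no probability; supply one in the graph JSON "
                "or via overrides"
            )
        p_by_type[tid] = info.probability
    superassemblies = enumerate_superassemblies(qg, max_types=max_types)
    annotate_point_groups(superassemblies, qg, structure=None)
    predictions = scoring.predict(superassemblies, p_by_type)
    report = build_report(None, None, None, superassemblies, predictions)
    return report, predictions


# ---------------------------------------------------------------------------
# Report assembly


def _assembly_dict(asm) -> dict:
    return {
        "stoichiometry": dict(sorted(asm.stoichiometry.items())),
        "formula": asm.formula(),
        "pointGroup": asm.point_group,
        "size": asm.size,
        "members": [
            {"node": node, "cell": list(off)} for node, off in asm.members
        ],
    }


def build_report(structure, found, types, superassemblies, predictions) -> dict:
    top = predictions[0]
    report = {
        "pdbId": getattr(structure, "pdb_id", None),
        "interfaceTypes": [
            {
                "id": t.type_id,
                "p": round(t.probability, 6) if t.probability is not None else None,
                "meanArea": round(t.mean_area, 2),
                "isologous": t.isologous,
                "members": t.member_ids,
            }
            for t in (types or [])
        ],
        "interfaces": ifc.interfaces_to_records(found) if found else [],
        "validSuperassemblies": [
            {
                "engaged": sorted(sa.engaged),
                "assemblies": [_assembly_dict(a) for a in sa.assemblies],
                "probRaw": round(sa.prob_raw, 9),
                "probNormalized": round(sa.prob_norm, 9),
            }
            for sa in superassemblies
            if sa.valid
        ],
        "invalidCount": sum(1 for sa in superassemblies if not sa.valid),
        "prediction": {
            "engaged": sorted(top.engaged),
            "probability": round(top.probability, 9),
            "assemblies": [_assembly_dict(a) for a in top.assemblies],
            "mergedFrom": top.merged_from,
            "note": top.note,
        },
        "ranking": [
            {
                "rank": pr.rank,
                "engaged": sorted(pr.engaged),
                "probability": round(pr.probability, 9),
                "formulas": [a.formula() for a in pr.assemblies],
                "pointGroups": [a.point_group for a in pr.assemblies],
            }
            for pr in predictions
        ],
    }
    return report


def _write_outputs(report, structure, found, qg, predictions, config, out_dir: Path):
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    if found:
        import pandas as pd

        pd.DataFrame(ifc.interfaces_to_records(found)).to_csv(
            out_dir / "interfaces.tsv", sep="\t", index=False
        )
    lattice.export_graph(qg, out_dir / "graph.json", "json")
    if config.write_graphml:
        lattice.export_graph(qg, out_dir / "graph.graphml", "graphml")
    if config.assembly_out and structure is not None:
        asm = predictions[0].assemblies[0]
        # export the largest assembly of the top prediction
        for a in predictions[0].assemblies:
            if a.size > asm.size:
                asm = a
        write_assembly_mmcif(structure, asm, Path(config.assembly_out))


def write_assembly_mmcif(structure: Structure, assembly, path: Path):
    """Write one assembly's coordinates as mmCIF (chains renamed A, B, ...)."""
    st = gemmi.Structure()
    st.name = (structure.pdb_id or "assembly") + "_asm"
    c = structure.cell
    st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    names = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
    for node, offset in assembly.members:
        chain_id, op_id = node.rsplit("_", 1)
        src = structure.chain(chain_id)
        moved = apply_operator(src, structure.op(int(op_id)), offset, structure.cell)
        chain = gemmi.Chain(next(names))
        for ridx in range(src.n_residues):
            res = gemmi.Residue()
            res.name = src.res_names[ridx]
            res.seqid = gemmi.SeqId(src.res_ids[ridx], " ")
            for aidx in np.where(src.atom_res == ridx)[0]:
                atom = gemmi.Atom()
                atom.name = src.atom_names[aidx]
                atom.element = gemmi.Element(src.elements[aidx])
                atom.pos = gemmi.Position(*(float(x) for x in moved.coords[aidx]))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
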