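"""Evolutionary interface scoring.

Per-interface indicators:

* ``gm`` — geometry score: the number of interface-core residues over both
  sides of the contact (burial fraction >= 0.95).
* ``cs`` — core-surface score: a Z-score comparing the mean sequence entropy
  of the m core residues against a null distribution built by sampling m
  surface residues many times from the whole protein surface.

Sequence entropy is computed per alignment column over a 6-letter reduced
amino-acid alphabet {ACILMV} {DE} {FHWY} {GP} {KR} {NQST} using the natural
logarithm.  The two indicators feed a logistic model for the probability of
an interface being biologically relevant:

    p(gm, cs) = 1 / (1 + exp(-(-3.9 + 0.31*gm - 2.1*cs)))

The log base only rescales cs jointly with the trained coefficient, so it
must not be changed independently of the model.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

__all__ = [
    "EntityAlignment",
    "InterfaceScores",
    "reduce_alphabet",
    "column_entropy",
    "core_surface_zscore",
    "geometry_score",
    "interface_probability",
    "read_entity_alignment",
    "score_interfaces",
]

# Mirny 6-class reduced alphabet; each class keyed by a representative letter.
ALPHABET_CLASSES = ("ACILMV", "DE", "FHWY", "GP", "KR", "NQST")
_CLASS_OF = {}
for _cls in ALPHABET_CLASSES:
    for _letter in _cls:
        _CLASS_OF[_letter] = _cls[0]
NULL_CLASS = "-"

LOGIT_INTERCEPT = -3.9
LOGIT_GM = 0.31
LOGIT_CS = -2.1

DEFAULT_N_SAMPLES = 10_000
DEFAULT_SEED = 42


def reduce_alphabet(seq: str) -> str:
    """Map a sequence onto the 6-class reduced alphabet.

    Unknown letters, X and gaps map to the null class '-' and are excluded
    from entropy counts.
    """
    return "".join(_CLASS_OF.get(ch.upper(), NULL_CLASS) for ch in seq)


def column_entropy(column) -> float:
    """Shannon entropy (natural log) of one alignment column over the
    reduced classes; gap/null symbols are dropped from the counts."""
    reduced = [c for c in reduce_alphabet("".join(column)) if c != NULL_CLASS]
    if not reduced:
        return 0.0
    counts = np.unique(np.array(list(reduced)), return_counts=True)[1]
    freqs = counts / counts.sum()
    return float(-(freqs * np.log(freqs)).sum())


@dataclasses.dataclass
class EntityAlignment:
    """A pre-built MSA for one entity plus per-residue entropies.

    The query row (ungapped) must match the entity sequence; query-row
    residue k maps to alignment column ``query_columns[k]``.
    """

    entity_id: str
    rows: list  # aligned sequences, equal length
    query_index: int = 0

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        query = self.rows[self.query_index]
        self.query_columns = [i for i, ch in enumerate(query) if ch not in "-."]
        self._entropies = None

    @property
    def query_sequence(self) -> str:
        return "".join(
            self.rows[self.query_index][i] for i in self.query_columns
        ).upper()

    def residue_entropies(self) -> np.ndarray:
        """Entropy per query residue (one value per ungapped query column)."""
        if self._entropies is None:
            cols = []
            for i in self.query_columns:
                cols.append(column_entropy([row[i] for row in self.rows]))
            self._entropies = np.array(cols)
        return self._entropies


def read_entity_alignment(path, entity_id: str, entity_sequence: str | None = None) -> EntityAlignment:
    """Read a FASTA alignment; the query row is the row whose ungapped
    sequence equals the entity sequence (default: first row)."""
    from Bio import SeqIO

    rows, names = [], []
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        rows.append(str(rec.seq).upper())
        names.append(rec.id)
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    query_index = 0
    if entity_sequence:
        for i, row in enumerate(rows):
            if row.replace("-", "").replace(".", "") == entity_sequence.upper():
                query_index = i
                break
        else:
            raise ValueError(
                f"{path}: no alignment row matches the sequence of entity {entity_id}"
            )
    return EntityAlignment(entity_id=entity_id, rows=rows, query_index=query_index)


# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InterfaceScores:
    interface_id: int
    gm: int
    cs: float | None
    p: float
    flags: list = dataclasses.field(default_factory=list)


def geometry_score(interface) -> int:
    """gm: total core-residue count over both interface sides."""
    return len(interface.core_a) + len(interface.core_b)


def core_surface_zscore(
    core_entropies: np.ndarray,
    surface_entropies: np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    rng: np.random.Generator | None = None,
):
    """Z-score of the mean core entropy against surface-sampled means.

    Each of ``n_samples`` draws takes m = len(core) surface residues without
    replacement and averages their entropies.  Returns (cs, flags); when the
    score is undefined (no cores, pool too small, zero spread) cs falls back
    to 0 with an explanatory flag.
    """
    core_entropies = np.asarray(core_entropies, dtype=float)
    surface_entropies = np.asarray(surface_entropies, dtype=float)
    m = len(core_entropies)
    if m == 0:
        return None, ["no-core-residues"]
    if len(surface_entropies) < m:
        return None, ["surface-pool-smaller-than-core"]
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)
    # m smallest entries of random keys = uniform sample without replacement
    keys = rng.random((n_samples, len(surface_entropies)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    sample_means = surface_entropies[idx].mean(axis=1)
    std = float(sample_means.std())
    # zero spread (constant entropies up to float noise) leaves cs undefined
    if std <= 1e-9 * max(1.0, abs(float(sample_means.mean()))):
        return 0.0, ["degenerate-constant-entropy"]
    cs = float((core_entropies.mean() - sample_means.mean()) / std)
    return cs, []


def interface_probability(gm: float, cs: float) -> float:
    """Logistic probability that an interface is biologically relevant."""
    return 1.0 / (1.0 + math.exp(-(LOGIT_INTERCEPT + LOGIT_GM * gm + LOGIT_CS * cs)))


# ---------------------------------------------------------------------------


def score_interfaces(
    structure,
    interfaces: list,
    alignments: dict | None = None,
    probabilities: dict | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
    surface_cutoff: float = 0.05,
) -> dict:
    """Score every interface, returning {interface_id: InterfaceScores}.

    ``alignments`` maps entity id -> EntityAlignment.  ``probabilities``
    (user-supplied, keyed by interface id) override the model.  With no
    alignment for an entity, cs is unavailable and p falls back to the
    gm-only logistic value (cs = 0), flagged low-confidence.
    """
    from . import sasa as _sasa

    probabilities = probabilities or {}
    out = {}
    rng = np.random.default_rng(seed)
    for iface in interfaces:
        gm = geometry_score(iface)
        if iface.interface_id in probabilities:
            out[iface.interface_id] = InterfaceScores(
                iface.interface_id, gm, None, float(probabilities[iface.interface_id]),
                flags=["user-probability"],
            )
            continue
        cs, flags = None, []
        have_msa = alignments and (
            iface.entity_a in alignments and iface.entity_b in alignments
        )
        if have_msa and iface.asa_a is not None:
            core_ent, surf_ent = _entropy_pools(
                structure, iface, alignments, surface_cutoff
            )
            cs, flags = core_surface_zscore(core_ent, surf_ent, n_samples, rng)
        elif not have_msa:
            flags = ["no-alignment-low-confidence"]
        p = interface_probability(gm, cs if cs is not None else 0.0)
        if cs is None:
            flags = flags + ["cs-unavailable-gm-only"]
        out[iface.interface_id] = InterfaceScores(iface.interface_id, gm, cs, p, flags)
    return out


def _entropy_pools(structure, iface, alignments, surface_cutoff):
    """Core entropies and whole-surface pool entropies for one interface.

    The pool is the union of both chains' surface residues (relative ASA
    above the cutoff), with that interface's core residues excluded.
    """
    from . import sasa as _sasa

    core, pool = [], []
    for side in ("a", "b"):
        entity = getattr(iface, f"entity_{side}")
        chain = structure.chain(getattr(iface, f"chain_{side}").chain_id)
        ent = alignments[entity].residue_entropies()
        asa = getattr(iface, f"asa_{side}")
        cores = set(getattr(iface, f"core_{side}"))
        for ridx in range(chain.n_residues):
            if ridx >= len(ent):
                continue
            if ridx in cores:
                core.append(ent[ridx])
            elif asa[ridx] / _sasa.max_asa(chain.res_names[ridx]) >= surface_cutoff:
                pool.append(ent[ridx])
    return np.array(core), np.array(pool)
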