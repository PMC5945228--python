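"""Probabilistic ranking of valid superassemblies.

Each interface type i carries a probability p_i of being biologically
relevant (the mean over its member interfaces).  Treating types as
independent binary events, a superassembly with engagement vector
s_1..s_n has raw probability

    P(s) = prod_i [ p_i if s_i else (1 - p_i) ]

deliberately computed per *type*, not per interface instance — weighting
by instance count would bias scores toward high-order cyclic assemblies.
Probability mass on rule-violating combinations is redistributed by
normalizing over the valid superassemblies.  Superassemblies that differ
only by induced interfaces (removable without disconnecting any assembly)
describe the same quaternary structure and are merged: the variant with
the most engaged types is reported with the group's total probability,
which is the confidence of the call.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = [
    "ScoredPrediction",
    "type_probability",
    "superassembly_probability",
    "normalize_over_valid",
    "merge_induced_equivalents",
    "predict",
]


@dataclasses.dataclass
class ScoredPrediction:
    superassembly: object  # Superassembly
    probability: float
    rank: int
    merged_from: list  # engaged sets of the merged group
    note: str = ""

    @property
    def engaged(self):
        return self.superassembly.engaged

    @property
    def assemblies(self):
        return self.superassembly.assemblies


def type_probability(itype) -> float:
    """Mean probability over an interface type's members (unweighted)."""
    ps = []
    missing = []
    for iface in itype.members:
        p = getattr(iface, "probability", None)
        if p is None:
            missing.append(iface.interface_id)
        else:
            ps.append(p)
    if missing:
        raise ValueError(f"unscored interfaces in type {itype.type_id}: {missing}")
    return float(sum(ps) / len(ps))


def superassembly_probability(engaged, p: dict) -> float:
    """Eq-3 product over interface types (never per instance)."""
    prob = 1.0
    for tid, pi in p.items():
        if not 0.0 <= pi <= 1.0:
            raise ValueError(f"p_{tid}={pi} outside [0, 1]")
        prob *= pi if tid in engaged else (1.0 - pi)
    return prob


def normalize_over_valid(superassemblies, p: dict):
    """Fill prob_raw/prob_norm; normalized values sum to exactly 1."""
    for sa in superassemblies:
        sa.prob_raw = superassembly_probability(sa.engaged, p)
    total = sum(sa.prob_raw for sa in superassemblies)
    if total <= 0.0:
        raise ValueError(
            "zero total probability over valid superassemblies; "
            "check the per-type probabilities"
        )
    for sa in superassemblies:
        sa.prob_norm = sa.prob_raw / total
    return superassemblies


def merge_induced_equivalents(superassemblies) -> list:
    """Group superassemblies describing the same quaternary structure.

    Two valid sets are equivalent when one is a subset of the other and
    their assembly stoichiometry multisets coincide — i.e. the extra types
    are induced (their removal leaves every assembly connected).  Groups
    are the transitive closure of that relation.  Each group reports the
    member with the most engaged types (ties: larger raw probability, then
    lexicographically smallest set), with the summed probability.
    """
    n = len(superassemblies)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    keys = [sa.stoich_multiset() for sa in superassemblies]
    for i in range(n):
        for j in range(i + 1, n):
            if keys[i] != keys[j]:
                continue
            a, b = superassemblies[i].engaged, superassemblies[j].engaged
            if a <= b or b <= a:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(superassemblies[i])

    predictions = []
    for members in groups.values():
        rep = min(
            members,
            key=lambda sa: (-len(sa.engaged), -(sa.prob_raw or 0.0), sorted(sa.engaged)),
        )
        total = sum(sa.prob_norm for sa in members)
        predictions.append(
            ScoredPrediction(
                superassembly=rep,
                probability=total,
                rank=0,
                merged_from=[sorted(sa.engaged) for sa in members],
            )
        )
    _rank(predictions)
    return predictions


def _rank(predictions):
    """Rank by probability; ties prefer the smaller (more stable) assembly."""
    predictions.sort(
        key=lambda pr: (
            -pr.probability,
            pr.superassembly.total_chains,
            sorted(pr.engaged),
        )
    )
    for i, pr in enumerate(predictions, start=1):
        pr.rank = i


def predict(superassemblies, p: dict) -> list:
    """Normalize, merge induced equivalents and rank; item 0 is the call."""
    valid = [sa for sa in superassemblies if sa.valid]
    if not valid:
        raise ValueError("no valid superassemblies (the empty set should always be valid)")
    normalize_over_valid(valid, p)
    predictions = merge_induced_equivalents(valid)
    conservation = sum(pr.probability for pr in predictions)
    if not math.isclose(conservation, 1.0, abs_tol=1e-9):
        raise AssertionError(f"probability mass not conserved: {conservation}")
    top = predictions[0]
    if top.probability < 0.5:
        top.note = "low confidence: no alternative reaches 0.5 either" \
            if all(pr.probability < 0.5 for pr in predictions) else ""
    return predictions
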