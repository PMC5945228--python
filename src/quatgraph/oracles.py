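"""Brute-force reference implementations used for cross-checking.

These deliberately avoid the optimized code paths: enumeration loops over
every subset with no pruning and no contraction, and the closed-symmetry
check is replaced by explicit finite supercell growth.  They are meant for
validation on small inputs, not production use.
"""

from __future__ import annotations

import itertools
from collections import deque

from .lattice import QuotientGraph
from .enumeration import validate_superassembly


def brute_force_valid_sets(qg: QuotientGraph) -> set:
    """Validate all 2^n engaged subsets directly (no pruning, no contraction)."""
    type_ids = qg.type_ids
    valid = set()
    for r in range(len(type_ids) + 1):
        for combo in itertools.combinations(type_ids, r):
            if validate_superassembly(qg, frozenset(combo)).valid:
                valid.add(frozenset(combo))
    return valid


def _engaged_adjacency(qg: QuotientGraph, engaged):
    engaged = set(engaged)
    adj: dict = {n: [] for n in qg.g.nodes}
    for u, v, d in qg.g.edges(data=True):
        if d["type"] not in engaged:
            continue
        src = d["src"]
        dst = v if src == u else u
        t = d["tvec"]
        adj[src].append((dst, t))
        adj[dst].append((src, tuple(-x for x in t)))
    return adj


def supercell_component_size(qg: QuotientGraph, engaged, start, radius: int) -> int:
    """Size of the engaged component of (start, centre cell) inside a
    finite (2*radius+1)^3 supercell, built by BFS without wrap-around."""
    adj = _engaged_adjacency(qg, engaged)
    root = (start, (0, 0, 0))
    seen = {root}
    queue = deque([root])
    while queue:
        node, cell = queue.popleft()
        for other, t in adj[node]:
            c2 = (cell[0] + t[0], cell[1] + t[1], cell[2] + t[2])
            if any(abs(x) > radius for x in c2):
                continue
            nxt = (other, c2)
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return len(seen)


def supercell_growth_is_closed(qg: QuotientGraph, engaged) -> bool:
    """Closed-symmetry verdict by finite supercell growth.

    A finite assembly stops growing once the supercell exceeds its
    diameter (bounded by the node count times the largest edge
    translation); an infinite fiber or sheet keeps gaining members as the
    supercell expands.  Valid iff every node's component has identical
    size at the two test radii.
    """
    tmax = 1
    for _, _, d in qg.g.edges(data=True):
        tmax = max(tmax, max(abs(x) for x in d["tvec"]) or 1)
    n = qg.n_nodes
    r1 = n * tmax + 1
    r2 = r1 + 2 * tmax
    # one representative per quotient component: translates share sizes
    adj = _engaged_adjacency(qg, engaged)
    reps, seen = [], set()
    for node in qg.g.nodes:
        if node in seen:
            continue
        reps.append(node)
        stack = [node]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(o for o, _ in adj[x] if o not in seen)
    for node in reps:
        if supercell_component_size(qg, engaged, node, r1) != supercell_component_size(
            qg, engaged, node, r2
        ):
            return False
    return True
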