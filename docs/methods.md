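# Methods

## Crystal model and symmetry algebra

A structure is reduced to: a unit cell (orthogonalization matrix built
from the six cell parameters), the space-group operator list resolved from
the Hermann–Mauguin symbol via gemmi's symmetry tables (operators are
1-based in table order, identity always op 1), and the polymer chains of
the asymmetric unit. All symmetry algebra is done in fractional
coordinates; atom coordinates are Cartesian ångström. Composition and
inversion of operators are resolved back into the group *modulo lattice
translations*, returning the residual integer vector — this residual is
what becomes an edge's translation label. Operator lookup keys on both the
rotation and the fractional translation mod 1, so centred settings (C2,
I222, …) with repeated rotation parts resolve correctly.

Entities come from mmCIF metadata when present, else from exact sequence
identity at the SEQRES level (chains with unobserved residues are treated
as full-length for equivalence). Alternate locations keep the
highest-occupancy conformer; hydrogens and non-polymers are dropped;
nucleic-acid chains are parsed but excluded from interface analysis.

## Interfaces

Candidate contacts are every pair (chain i, identity) × (chain j, any
operator, lattice shift in the 3×3×3 neighborhood) with any heavy-atom
pair within 5.5 Å. A bounding-sphere test prunes the candidate list before
any surface computation. Each physical contact is kept once, in a
canonical orientation: for same-chain pairs the representative of
{(g,t), (g,t)⁻¹} with the smaller operator id (ties: lexicographically
larger shift, so a +a self-contact reports shift (1,0,0)).

Buried surface area is ASA(A) + ASA(B) − ASA(AB) with Shrake–Rupley ASA:
probe 1.4 Å, 960 sphere points per atom placed on a fixed golden-spiral
point set, making ASA deterministic without any RNG and hence interface
ids reproducible. Van der Waals radii are element-based; the fixture
pseudo-atom element X gets 1.9 Å. Contacts burying less than 35 Å² are
discarded as topological noise (configurable). Per-residue burial
classifies interface residues into core (bsa/asa ≥ 0.95) and rim; surface
residues are non-interface residues with relative ASA ≥ 5% of the
residue's theoretical maximum.

Interface *types* cluster contacts by single-linkage over the Jaccard
similarity of entity-level residue–residue contact sets (threshold 0.3;
for same-entity contacts the transposed orientation is also tried). The
published method does not state its clustering threshold or area floor;
both values here are package choices exposed in configuration. A contact
is *isologous* (2-fold, face-to-face) when its contact set is symmetric
under side-swapping: transpose-Jaccard ≥ 0.8.

## Evolutionary scoring

Sequence entropies are Shannon entropies (natural log) per alignment
column over the 6-class reduced alphabet {ACILMV} {DE} {FHWY} {GP} {KR}
{NQST}; gaps and X drop out of the counts. The log base is a fixed part
of the trained model: changing it rescales *cs* jointly with its
coefficient, so it is deliberately not configurable.

*gm* counts core residues over both interface sides. *cs* is a pure
Z-score: m core residues' mean entropy against the distribution of means
of m surface residues drawn without replacement 10,000 times (seeded
generator; draws are vectorized via random-key argpartition). The sampling
pool is the union of both chains' surface residues with that interface's
core residues excluded — whether the published procedure also excludes rim
residues is unstated; excluding core only is the package's reading.
Degenerate pools (no cores, pool smaller than m, zero spread) flag the
interface and fall back to cs = 0. The probability of biological
relevance is the fixed two-indicator logistic
p = 1/(1+e^{−(−3.9+0.31·gm−2.1·cs)}); its coefficients are treated as
frozen model constants, not retrained here. Without an alignment the
pipeline uses gm-only probabilities (flagged low-confidence) or accepts
user-supplied per-type/per-interface probabilities as JSON.

## Lattice graph

Every detected AU interface lifts to |G| unit-cell edges: composing each
group operator with the interface's (operator, shift) pair gives the
second endpoint and the residual integer translation. Self-inverse
(isologous) contacts generate each physical edge twice; a canonical edge
key deduplicates. Node count is exactly nChains × nOps; the edge multiset
is closed under the group action (a tested invariant). Translation vectors
are oriented source→target and negate on reverse traversal; self-loops
(chain contacting its own lattice translate) are first-class.

The cycle machinery is a BFS spanning-forest fundamental basis
(Paton-style; networkx's cycle basis does not handle labeled multigraphs
with self-loops). Rule 4 does not need explicit cycles: BFS assigns each
node a cell offset and any edge whose endpoints' offsets contradict its
translation witnesses a non-zero-net cycle; the explicit witness cycle is
reconstructed only for reporting.

An abstract "lattice-graph JSON" dialect (nodes with chain/op/entity,
edges with type and `xtal` vector, types with probabilities) enters the
pipeline directly, decoupling the topology engine from geometry. GraphML
export/import round-trips the same content.

## Enumeration

Subsets of interface types (numbered by descending mean area) are
traversed depth-first. Closed-symmetry failures prune their entire
subtree — adding edges can never remove the offending cycle — while
isomorphism failures only mark the set invalid, because rule-3 violations
are not monotone in general (an added type can merge non-isomorphic
components into one). The empty set is always valid. A guard refuses more
than 32 types.

Heteromers branch per greedy inter-entity type c (highest probability,
ties by area): the engage-branch contracts all c edges — merging each
c-connected node group into a meta-node with internal cell offsets, and
re-anchoring remaining translations so the cycle space is preserved —
while the disengage-branch deletes them; both recurse until graphs are
homomeric. Entities never linked by inter-entity types form orthogonal
blocks enumerated independently and combined as cross products. Meta-node
entity labels are isomorphism-invariant signatures (entity multiset plus a
Weisfeiler–Lehman hash of the internal contraction subgraph), and every
candidate set is finally re-validated on the uncontracted graph, so
contraction is an optimization, not an approximation: agreement with
unpruned brute force is part of the test suite and acceptance script. The
`contract_entities` surface (iterate to one meta-entity per block, with an
invertible node→offset mapping) is exposed for callers who want the
reduced graph itself.

Assemblies are the connected components of the engaged subgraph, lifted to
concrete cell offsets via the BFS tree (different roots shift all offsets
by a global constant only — tested). Each quotient component is one
representative of a lattice-translation orbit.

## Point groups

With coordinates, candidate isometries come from Kabsch superposition of
every ordered pair of same-entity member chains (CA atoms matched on
shared residue numbers); a candidate that permutes the whole chain set
with per-chain RMSD ≤ 2.0 Å is a self-isometry. This covers
non-crystallographic symmetry, which pure space-group bookkeeping would
miss (a P1 box holding an NCS hexamer has no non-trivial crystal
isometries at all). The collected proper rotations classify by group order
N and element orders: N = k_max → C_k; N = 2·k_max with perpendicular
2-folds → D_k; (N, k_max) = (12,3)/(24,4)/(60,5) → T/O/I. A multi-copy
assembly with no self-isometry reports "none" (with a warning — it should
be unreachable from a valid superassembly); a complex with one copy per
entity is trivially C1.

For abstract graphs a topological heuristic stands in: u = copies per
entity; u = 1 → C1; u = 2 → C2 iff an isologous edge is engaged;
heterologous-only single cycles → C_u (open chains → C1); isologous rings
and mixed iso/hetero assemblies with even u → D_{u/2}. Cubic groups are
not distinguishable from dihedral without coordinates and report as D_n.

## Scoring and prediction

Type probability is the unweighted mean of member-interface
probabilities. Superassembly probability is the per-type product (engaged
→ p_i, disengaged → 1 − p_i); normalization divides by the total over
valid superassemblies, restoring unit mass. Merging groups superassemblies
related by (subset relation ∧ equal assembly-stoichiometry multiset),
transitively closed — exactly "differ only by induced interfaces". Equal
stoichiometry multisets *alone* would wrongly merge disjoint alternatives
(two different all-dimer tilings), hence the subset condition. Each group
reports its most-engaged member (ties: larger raw probability, then
lexicographically smallest set) with the summed probability; rank ties
prefer the smaller assembly (the more stable species for equilibria).
Confidences are reported verbatim — they measure call confidence, not
binding strength.

## Synthetic fixtures

The generator covers every topological regime the rules distinguish, as
both abstract graphs and miniature crystals of rigid pseudo-atom clouds
(12–16 atoms, cloud radius ~2.2–2.6 Å, element X, one CA-named atom per
residue — large enough for meaningful BSA, small enough for instant ASA):

* `c2_dimer` — one chain straddling a crystallographic 2-fold (P2);
  expected call: C2 dimer at the supplied p.
* `fiber` — a chain touching its +a translate (P1, a = 8.2 Å): engaging
  the contact is an infinite filament; only the monomer is valid.
  `fiber_capped` is the contrast case: the same face-to-back contact
  between two NCS copies with no continuation. Under the four rules as
  stated this asymmetric dimer is *valid* (no cycle forms) and is labeled
  C1; the rules themselves do not reject capped heterologous dimers.
* `non_isomorphic` — four same-entity chains where each isologous type
  pairs only two of them: every dimer subset breaks isomorphism and the
  two-type set yields two differently-labeled dimers; only the monomer
  survives. This is the abstract form of a dimer that "wraps around" the
  cell without tiling it.
* `d3_hexamer` — two stacked C3 rings; geometry (ring radius 4.6 Å,
  half-height 2.3 Å, azimuthal offset 24°) tuned so exactly three types
  appear: straight 2-folds (3 members, largest), diagonal 2-folds (3),
  heterologous ring (6, smallest); one of the three is induced. Abstract
  twin probabilities 0.95/0.4/0.9 make the merged hexamer call 0.911.
* `heterodimer_ab` — two entities, one inter-entity type, for contraction.
* `random(n, seed)` — seeded random graphs (optionally multi-entity or
  zero-translation) for the oracle comparisons.

Every canned geometric fixture's end-to-end pipeline output equals its
abstract twin (valid sets, stoichiometries, point groups) — a tested
invariant. Synthetic alignments paint zero reduced-alphabet entropy on
designated conserved positions and uniform-random residues elsewhere.

What the fixtures do *not* emulate: real side-chain packing and interface
chemistry, partial occupancy and disorder, inter-chain conformational
variability between NCS copies, and realistic MSA phylogenetic structure.
Passing tests therefore demonstrate the correctness of the topology,
symmetry and scoring machinery, not field performance of the evolutionary
classifier on real homolog sets.

## Numerical choices and degenerate inputs

* ASA: 960 fixed golden-spiral points ⇒ ASA reproducible bit-exactly;
  interface areas change under re-choice of asymmetric unit only within
  sampling tolerance (< 0.5 Å² on fixture-sized chains, tested).
* Area ties when assigning interface ids break lexicographically by
  (chainA, chainB, shift).
* The Z-score guards: no core residues, pool < m, or zero sample spread
  (relative tolerance 1e-9) flag the interface instead of emitting NaNs.
* All-zero probability mass after filtering (every p ∈ {0,1}
  inconsistently) is an error, not a silent division by zero.
* Supercell-growth reference: a finite assembly's offsets are bounded by
  (node count × max translation entry), so equality of component sizes at
  radii n·t+1 and n·t+3 decides finiteness exactly.
* Random-seed plumbing: one seed drives fixture generation, cs sampling
  and the acceptance script; identical config ⇒ byte-identical reports.

## Known limitations

* Consequence "heteromeric assemblies have even stoichiometry" holds when
  each entity of a block has equal lattice multiplicity (the common
  case); lattices with unequal entity copy numbers admit valid uneven
  assemblies (e.g. A2B covering a 2:1 lattice), which the enumerator
  reports faithfully.
* Pseudosymmetric exceptions, steric-hindrance asymmetry, and filamentous
  biology that genuinely violates closed symmetry are out of scope: the
  rules are enforced strictly, with no relaxation path.
* Chains of one entity are matched residue-by-index for contact-set
  comparison; entities whose copies differ grossly in observed residues
  may cluster suboptimally.
* Homolog search and alignment construction are the caller's
  responsibility; only pre-built per-entity FASTA alignments are consumed.
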