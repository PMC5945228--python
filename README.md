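# quatgraph

Prediction of protein quaternary structure from crystal lattices.

About nine in ten PDB entries are crystal structures, and in each one the
biological assembly is hidden among a much larger number of incidental
crystal contacts. `quatgraph` addresses the second half of the interface
classification problem: given per-interface assessments of biological
relevance, decide *which combination of interfaces* forms the biological
assembly. It is aimed at crystallographers and structural bioinformaticians
who need a transparent, rule-based alternative (or complement) to
thermodynamic estimators for biological-unit assignment.

## The model

The crystal is represented as a **periodic quotient graph** (crystal net):
one node per chain image in the unit cell, labeled `A_1`-style by chain id
and space-group operator id; one edge per pairwise interface, labeled by
interface type and by an integer lattice-translation vector (the
Miller-index difference between the two chains). Though drawn in one cell,
the graph encodes every contact of the infinite crystal.

A **superassembly** is a choice of engaged interface types whose connected
components (the assemblies) tile the lattice. It is *valid* iff:

1. **Full coverage** — every chain belongs to exactly one assembly;
2. **Uniform composition** — all instances of a type are engaged together;
3. **Isomorphism** — assemblies with non-orthogonal stoichiometries
   (sharing an entity) are isomorphic as entity/type-labeled graphs — no
   co-crystals of the same molecule;
4. **Closed symmetry** — no combination of engaged operators yields a
   non-zero pure translation: every fundamental cycle of the engaged
   subgraph has zero net translation vector. This excludes infinite
   fibers and sheets and, together with rule 3, restricts valid
   assemblies to point-group symmetric ones (C<sub>n</sub>, D<sub>n</sub>, T, O, I).

Valid superassemblies are enumerated by depth-first traversal of the
power set of interface types with pruning (every superset of a
closed-symmetry failure is invalid) and, for heteromers, greedy entity
contraction that reduces the graph to an equivalent homomeric one.

Each interface type *i* carries a probability of biological relevance
p<sub>i</sub>, either supplied directly or computed from two indicators —
the geometry score *gm* (number of interface-core residues, burial
fraction ≥ 0.95) and the core–surface score *cs* (a Z-score of mean
core sequence entropy against surface-sampled means, entropies taken over
a 6-letter reduced amino-acid alphabet):

```
p(gm, cs) = 1 / (1 + exp(−(−3.9 + 0.31·gm − 2.1·cs)))
```

Treating types as independent binary events, a superassembly with
engagement vector s₁…sₙ scores

```
P(s) = ∏ᵢ  pᵢ  if sᵢ  else (1 − pᵢ)
```

(per *type*, not per instance — instance products would bias toward
high-order cyclic assemblies). Probability mass lost to invalid
combinations is redistributed by normalization over the valid set;
superassemblies differing only by induced (topologically redundant)
interfaces are merged, and the reported confidence is the merged,
normalized probability of the top-ranked quaternary structure.

## Worked example

Generate a synthetic crystal — six pseudo-protein chains arranged as a D3
hexamer with three interface types (two isologous 2-fold contacts, one
heterologous C3 ring) — and run the pipeline on its abstract lattice
graph, which carries per-type probabilities (0.95 / 0.4 / 0.9):

```
$ quatgraph fixture d3_hexamer -o fx --kind both
fx/d3_hexamer.graph.json
fx/d3_hexamer.cif
$ quatgraph predict --graph-json fx/d3_hexamer.graph.json -o out
prediction: engaged=[1, 2, 3] assemblies=A6 pointGroup=D3 confidence=0.911
```

All eight subsets of the three types are topologically valid here; the
four hexamer-shaped ones ({1,2}, {1,3}, {2,3}, {1,2,3}) describe the same
quaternary structure up to induced interfaces, so they merge: the set with
the most engaged types is reported and 0.911 is their summed normalized
probability. The ranked alternatives (monomer, three C2 dimer variants,
the C3 trimer pair) appear in `out/report.json` with their confidences.

A second fixture run from coordinates, overriding the detected interface
type's probability:

```
$ quatgraph fixture c2_dimer -o fx --kind crystal
fx/c2_dimer.cif
$ quatgraph interfaces fx/c2_dimer.cif -o ifc.tsv
id  typeId  chainA  chainB  operator  shift      area   isologous ...
1   1       A_1     A_2     2         [0, 0, 0]  94.65  True
$ quatgraph predict fx/c2_dimer.cif --probabilities p.json   # {"1": 0.85}
prediction: engaged=[1] assemblies=A2 pointGroup=C2 confidence=0.850
```

Here the single isologous contact across the crystallographic 2-fold gives
two valid outcomes — monomer and C2 dimer — and the dimer wins with
confidence 0.85 (the monomer keeps the remaining 0.15).

When per-entity FASTA alignments are supplied (`--msa-dir`), p values come
from the *gm*/*cs* logistic model above; without them the pipeline falls
back to gm-only scores, flagged low-confidence in the report.

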