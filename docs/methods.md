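# Methods

## Contact networks

A residue interacts with every residue having *any* atom within the
cutoff (default 6.0 Å).  All atoms present in the input participate —
crystal structures typically lack hydrogens, but if hydrogens are
present they are included; no representative-point (Cα or centroid)
reduction is applied, since a representative point only matters for
drawing, not for the all-atom distance rule.  Sequence-adjacent
residues are kept as contacts like any other pair.  Alternate
locations resolve to the highest-occupancy conformer; waters, ligands
and other heteroatoms are excluded; non-standard residues are dropped.
Contact search uses a k-d tree over all atoms and is verified in the
tests against an exhaustive all-pairs distance scan.

## Response times

The response time of residue *i* is the first timestamp at which
|ΔE_i(t)| ≥ the energy cutoff (default 0.01 kcal/mol), where ΔE is the
perturbed-minus-reference energy series.  The absolute value is used
because a perturbation can raise or lower a residue's energy and
either deviation is a response; this makes the table invariant under a
global sign flip of Δ, which the tests assert.  Residues that never
cross within the recorded horizon carry an `inf` sentinel and sort
later than every finite time in direction assignment.  Timestamps are
femtoseconds throughout; the readers validate units at the file
boundary.  The package is agnostic about which energy (kinetic,
potential, total) the series contains — it consumes whatever per-residue
series is supplied.

## Direction assignment

Each undirected contact becomes exactly one directed edge from the
earlier- to the later-responding residue, so the Initial network's
edge count equals the contact count.  Exact ties (possible at 1 fs
resolution) produce one edge directed toward the sequence-later
residue, i.e. from the sequence-earlier one; tie counts are reported
in the graph metadata so a user can judge how much of the orientation
is conventional rather than dynamical.  The tie rule is a declared
convention chosen for determinism — with all-distinct times the
Initial network is provably acyclic, and with ties it may contain
cycles, which downstream layering rejects explicitly.

## Pair-network pruning

The three steps (time filter at the target's response time; iterated
in-degree-0 deletion sparing the source; iterated out-degree-0
deletion sparing the target) are implemented literally, deleting all
eligible nodes per round and recomputing degrees between rounds.  Each
fixpoint is reached in at most |V| rounds and is deletion-order
independent; the tests check this against a re-implementation that
deletes one random node at a time.  On acyclic inputs the result
equals the induced subgraph on {v : source →* v and v →* target} of
the time-filtered network (double-reachability oracle, asserted over
100 random DAGs).  The time filter uses strict deletion ("larger
than"), so kept nodes satisfy t ≤ t(target).  On cyclic inputs the
iterative semantics is the ground truth and the oracle is not applied.
Intersection networks intersect *edge sets*, not induced subgraphs: a
common node pair may be connected in one pair network and not another,
and only universally shared edges survive.

## Layering and the propagation coefficient

"Deep-preference" layering is implemented as longest-path layering:
layer(v) = 1 + length of the longest directed path from the
in-degree-0 node set.  This places every node as deep as possible,
guarantees layer(u) < layer(v) for every edge, and makes the number of
layers equal the longest source→sink path plus one.  A breadth-first
(shortest-path) mode exists for sensitivity analysis only; it can
produce upward edges and is not used for PC.  Pass-through edges of
layer N are those with layer(u) < N < layer(v) — under longest-path
layering these are shortcuts that skip at least one full layer.

The propagation coefficient formula was reconstructed from its
verbal definition (numerator: pathway slots through node *i*, i.e.
m_i·n_i; denominator: all former-layer→later-layer pathway slots, i.e.
Σ_j m_j·n_j over the layer plus the l pass-through edges).  This is
the single most consequential reconstruction in the package.  Two
boundary conventions close the definition: first-layer nodes take
m := 1 (they receive the external perturbation through one virtual
inlet) and last-layer nodes take n := 1 (one virtual outlet).  This is
the minimal rule under which a sole source residue scores PC = 1.00,
matching the published value for the source residue, and under which
the within-layer identity Σ PC + l/(Σ m n + l) = 1 holds exactly —
both are asserted in the acceptance suite.  Degrees default to
full-network in/out-degrees; a `degree_scope="adjacent"` option
restricts them to edges touching the neighboring layers, since the
verbal definition does not fix this choice.

## Network statistics

Directed shortest paths define eccentricities over reachable nodes
only; the radius is the minimum *positive* eccentricity — on a digraph
with sinks the plain minimum would be 0, whereas the published tables
report radius 1, which is the reachable-only convention of the
Cytoscape NetworkAnalyzer this mirrors.  The characteristic path
length averages over connected ordered pairs, and the "shortest
paths (%)" denominator is n(n−1) ordered pairs: the three published
count/percentage triples (38329/447 → 19 %, 6063/150 → 27 %,
916/50 → 37 %) are consistent with this to integer rounding, which the
tests verify.  Mean neighbor count (2E/N) and the clustering
coefficient are computed on the underlying undirected adjacency; a
directed clustering variant is available behind a flag.  Percentages
are rounded to integer percent in reports for parity with the
published tables.

## Motif census

All weakly connected induced subgraphs of size 3 or 4 are enumerated
with the ESU algorithm and grouped by directed-isomorphism class via a
canonical adjacency-matrix label (lexicographically smallest
bit-serialization over node permutations — at most 24 permutations for
size 4, so brute force is exact and cheap).  Class labels are the
canonical bit strings, not the IDs of any particular motif tool; for
3-node classes the standard 13 connected triad-census names (021D …
300) are attached for readability, generated programmatically from
networkx's triad atlas.  Tests check the census against exhaustive
subset enumeration with pairwise isomorphism tests, and the 3-node
counts against networkx's independent triadic census.

## Enrichment probability

The chance that a random `sample`-subset of `population` residues
contains all `hits` annotated sites is computed in log-space
(log-gamma) in two algebraically identical forms — the combination
ratio C(sample, hits)/C(population, hits) and the hypergeometric mass
C(hits, hits)·C(population−hits, sample−hits)/C(population, sample) —
which must agree to 1e-12 relative tolerance at every call; the
acceptance suite checks the identity exhaustively for populations up
to 60 and at the published counts (447, 150, 21), where
p ≈ 4.1·10⁻¹¹.

## Surrogate dissipation

The generator stands in for the perturbed/reference MD pair with a
linear diffusion of an injected energy packet over the contact graph:
E_i(t+1) = E_i(t) + α Σ_{j∈N(i)} (E_j(t) − E_i(t)), recorded at 1 fs
steps.  Defaults: perturbation magnitude 1.0 kcal/mol at the source
residues at t = 0 (the analogue of the kinetic-energy kick), noise SD
0.002 kcal/mol per residue and step — small against the injected
energy, large enough to exercise the subtraction machinery — 200
steps, and α = 0.8/max-degree, inside the 1/max-degree stability bound
that keeps all update weights non-negative.  The perturbed and
reference runs share one noise stream per residue, so the paired
subtraction cancels noise exactly (an unshared-noise mode exists for
robustness testing).  Linearity buys provable test properties that the
real nonlinear energy flow does not have: exact conservation of total
energy, a strictly monotone wavefront on path graphs, and a strictly
minimal response time at the source.  What passing these tests shows
is therefore that the *network machinery* (direction assignment,
pruning, layering, PC, census) is correct — not that the diffusion
reproduces MD energetics, anharmonic effects, or the measured response
times of any real protein.

Synthetic structures are compact self-avoiding chains: consecutive
Cα 3.8 Å apart, non-consecutive Cα at least 4.0 Å apart, confined to a
sphere sized at 134 Å³ per residue (typical protein packing), with
four pseudo-atoms per residue at backbone-bond-length offsets.  At
n = 100 this yields 6 Å contact networks with mean neighbor counts in
the high single digits, the right order of magnitude for real
proteins; the chains have no secondary structure, domains, or
chemistry.

## Problem sizes and determinism

Verification suites run at desk scale: random DAGs of 60–120 nodes
(100 seeds for the pruning oracle), 25-node digraphs for the exhaustive
motif oracle, synthetic proteins of 30–100 residues, surrogate runs of
200–600 steps.  All randomness flows through explicit integer seeds
(numpy `SeedSequence` spawning in the acceptance script), and a
pipeline rerun with the same config and seed is byte-identical, which
a test asserts via the manifest's content hashes.

## Known limitations

- Real per-residue MD energy tables for the aspartokinase III study
  are not archived, so published pair-network sizes, union/intersection
  compositions, PC values and motif frequencies cannot be recomputed;
  the package validates those code paths by construction and property
  instead.
- The contact-count validation against the 2J0W/2J0X crystal
  structures requires downloading them; the corresponding tests fail
  without network access or local copies.
- mmCIF input, biological-assembly reconstruction and hydrogen
  addition are out of scope; conservation scores and structural-region
  annotations are consumed as an input table, never computed.
- Layer coordinates are not produced (no crossing minimization);
  layers and PCs are exact, drawing is left to external tools.
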