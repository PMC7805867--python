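# Methods

This note records the modeling conventions, parameter choices and
numerical decisions behind the package, and what the synthetic fixtures
do and do not establish about real wiring data.

## Connectome representation

A wiring diagram is a directed multigraph. Chemical synapses are single
directed edges (presynaptic → postsynaptic); a gap junction between two
neurons is represented as two directed edges, one in each direction,
with equal multiplicity. Multiplicity (the number of individual
contacts) must be a positive integer and becomes the edge weight.
Parallel edges between one ordered pair are kept as separate records and
sum wherever fields or energies are computed. Self-connections are
allowed and participate in both the local field (contributing
`w · s_i`) and the energy (contributing the constant `−w`, since
`s_i s_i = 1`).

Edge tables are delimited text; column names and whether gap junctions
are stored once (expanded on load) or twice (validated for reciprocity)
are configurable per dialect, because the published layouts differ.
Neuron order is first appearance in the table, stable across runs for
reproducibility. Serialization writes one row per chemical edge and one
row per gap pair; since an edge table cannot encode the original index
order, connectome equality is defined on the neuron *set* and the
name-keyed edge multiset, which is what a round trip preserves.

The default exclusion list removes the 20 pharyngeal neurons — a nearly
self-contained nervous system, with names taken from the classical
pharynx anatomy literature — plus VC6, CANR and CANL, which lack obvious
connections. The list is shipped as an editable text fixture, not
hard-coded, because the pharyngeal set comes from the anatomy
literature and users may wish to revise it.

## Weight normalization

Multiplicities are mapped to `w = min(m, cutoff) / cutoff` with
`cutoff = 44` by default, so weights lie in (0, 1] and the heavy tail
(multiplicities above the cutoff; 15 edges in the reference data) lands
exactly at 1. The alternative order of operations — divide by the
maximum multiplicity first, then clip — is available via
`normalize_weights(..., order="scale_first")` but is not the default,
because only the clip-first form puts clipped edges exactly at 1.

## Inhibition placement

An inhibition scheme negates exactly `k = round(fraction × M)` edge
weights (`M` = total edge count; rounding is half-away-from-zero so the
count is deterministic and documented), drawn uniformly without
replacement from the eligible pool: all edges (uniform), edges inside a
cluster (intra), or edges crossing clusters (inter). The fraction is
interpreted against the *total* edge count even in restricted modes, so
"30% inhibitory, inter-cluster only" concentrates the same number of
negative edges into the smaller pool; pool-relative semantics are a
config switch. Gap-junction pairs are negated independently by default
(each directed link counts as one connection); `couple_gap_pairs=True`
selects and negates reciprocal pairs jointly for electrophysiological
realism, with each pair counting 2 toward `k`. By default every
replicate seed redraws the sign pattern; a flag freezes the first draw
across replicates, since the original protocol does not state which was
done.

## Dynamics

The update rule sets a neuron to the sign of its local field — the sum
of `w · s_j` over its incoming edges, with `w` the behavioral weight
`clamp(w_original + w_delta, −1, 1)`. A zero field keeps the previous
state: the tie case is undefined in the source formulation, and keeping
state avoids injecting noise into attractor detection (it also makes
isolated neurons trivially stable, which the fixed-point oracle must
and does reflect). Weight indices are read so that the edge `j → i`
drives neuron `i`, matching the presynaptic/postsynaptic convention of
chemical synapses.

Relaxation performs `10 × n` single-neuron updates with targets drawn
uniformly at random (a fixed budget; an optional convergence check at a
configurable interval can stop early). On the networks used here the
final state is a fixed point in the large majority of cycles; the flag
is recorded per cycle rather than assumed. Internally the per-edge
structure is aggregated once per weight change into a dense incoming
matrix, which reproduces the multigraph edge sums exactly and keeps the
asynchronous loop fast; the exhaustive stable-state enumerator (the test
oracle) is guarded to n ≤ 20.

## Learning

A Hebbian step adds `rate × s_i s_j` to every edge's learned delta; the
original weights are never modified, so the reported energy of any fixed
state is invariant under learning, and a state and its global flip
reinforce identically. Clamping of the behavioral weight into [−1, 1]
is on by default; at the reference rates it rarely binds. Exact
consequences used as tests: one unclamped step lowers the behavioral
energy of the reinforced state by `rate × M`, and repeated reinforcement
of one state makes it a fixed point after finitely many steps.

Learning rates follow the edge-proportional rule
`rate × edges = const`, anchored at `1e-5` for the 5,588-edge whole
network. The reference per-cluster rates deviate from exact scaling by
up to ~4% (presumably rounding), so experiments take rates from
configuration, with the scaling helper available; the products across
all reference rows agree within 5%, which the suite asserts.

## Protocol and reporting

Each cycle resets all states iid uniform ±1. The phrase "initial
configuration with only positive values" in the source protocol is read
as describing the all-positive *weight* configuration before sign
assignment, not the states; a flag (`all_positive_first_state`) makes
the first cycle start from all-+1 states instead for users who prefer
the other reading. Energies are recorded once per cycle at the final
relaxed state, for the whole network and each monitored scope (clusters,
super-clusters, inter-cluster edges); the per-scope sums decompose
exactly: whole = Σ intra-cluster scopes + inter. Phase summaries use
the population SD; because it is unstated whether published summary SDs
pool cycles, replicates or both, all three reductions are available
(`over="all" | "replicates" | "cycles"`) with pooling as the default.
The attractor census groups identical final states, reports counts and
original-weight energies, and flags states absent from the before-phase
set — the generalization signature.

## Synthetic generator

The generator emulates the structural features the method depends on:
exact per-cluster intra-edge counts, exact per-cluster-pair inter-edge
counts, truncated Zipf-distributed multiplicities (default exponent 2.0
on support 1..81 — a modeling choice, the real exponent is not known to
us) so that the 44-cutoff actually clips, reciprocal gap pairs sharing
one multiplicity, and optional self-edges. It does **not** reproduce
real neuron identities, bilateral pair symmetry, degree–degree
correlations, or any anatomical statistic beyond the listed counts, so
green synthetic tests demonstrate the algorithm and its invariants, not
agreement with the biological wiring; the reference-data test exists
separately for that and requires the published tables.

The `table1_shape` preset mirrors the reference partition's shape: 279
nodes in clusters of 57/79/14/74/55 with 665/1107/115/1109/396
intra-cluster edges and 2,196 inter-cluster edges, gap fraction 0.3 and
1% self-edges — values chosen once as a realistic stand-in for the
reference topology.

## Problem sizes

The default protocol (1,000/1,000/1,000 cycles, 10 replicates) is what
the experiment driver ships with. The test suite and the acceptance
script run scaled-down versions as their own study conditions: the
modular-symmetric effect check uses 60 neurons in 3 clusters (360 edges,
all positive, edge-scaled rate) at 200/200/200 cycles over 10 seeds, and
the reference-shaped run uses 100/100/100 cycles over 10 seeds with 30%
inter-cluster inhibition. The self-optimization effect is comfortably
visible at these sizes (after-phase mean below before-phase mean in
10/10 replicates on the modular nets in the shipped configuration).

## Known limitations

- Inhibition is per-edge; per-neuron (Dale's law / neurotransmitter
  based) inhibition is out of scope.
- Only asynchronous binary dynamics are implemented — no synchronous
  mode, no continuous activations, no coupled/embodied simulation.
- The energy decomposition and Lyapunov guarantees hold as stated only
  for the conventions above (original-weight energy; symmetric
  aggregated behavioral matrix with non-negative diagonal for
  monotonicity). Directed connectomes are generally non-symmetric, so
  relaxations can cycle; the fixed-point flag makes this visible rather
  than hiding it.
- Shortest-path statistics treat the collapsed simple digraph as
  unweighted and average over reachable ordered pairs only; unreachable
  pairs are excluded rather than counted as infinite.
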