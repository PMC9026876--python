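# Methods

## Model

The pipeline treats a disease as a set of pathophysiological processes
("motives"), each represented computationally by its effector proteins on
an undirected protein-interaction network, plus a disease-in-general
pseudo-process handled identically. The working assumption — the one the
whole method stands or falls on — is that functional involvement shows up
as *graph proximity*: proteins participating in a process sit close to,
and interact densely with, that process's effectors.

The interaction map is multi-layer (physical, signaling, metabolic,
regulation), but all proximity computations run on the collapsed simple
graph: a pair interacting in k layers counts once topologically, and
regulation direction is kept only as metadata. The published description
gives the map one connected, undirected semantics for scoring, and hop
distances and walk probabilities would otherwise be distorted by duplicate
edges; self-loops are dropped at load for the same reason. Isoform
suffixes on accessions are stripped so all layers share one namespace.

## Scoring pathway

**Features.** For candidate c and effector set M: minimum and mean hop
distance from c to M; the probability at c of a random walk restarting
uniformly on M with probability r = 0.3 per step (solved exactly as a
sparse linear system; walkers on isolated nodes restart, so the
distribution always sums to 1); Jaccard overlap between N(c) and the union
neighborhood N(M); and log(1 + deg c), included so the predictor can learn
to discount hub proximity. A candidate that is itself an effector of M is
scored leave-one-out (removed from the seed set; its d_min is 0 by
membership). Unreachable distances are capped at (diameter of the largest
component + 1) — a finite value one step beyond any real distance — and a
candidate absent from the graph gets the sentinel vector (capped
distances, zero walk mass and overlap) plus a QC flag rather than an
error, since real candidate lists routinely contain unmapped accessions.

**Predictor.** A single-hidden-layer feed-forward network (8 logistic
units, logistic output) on the 5 standardized features, fit by L-BFGS with
a fixed seed. This is deliberately the smallest architecture that fits the
input: the published method names neural networks but no architecture, and
with five features the decision surface is simple — an internal check
shows plain logistic regression separates the synthetic truth tables
almost as well, so nothing hinges on network capacity. Training uses a
stratified 75/25 split to report held-out accuracy, then refits on the
full table. The trained model is stored as explicit weight matrices
(JSON), so prediction is a deterministic numpy forward pass independent of
the training library.

**Truth table.** Positives are all (effector, its process) pairs present
in the graph. Negatives are sampled degree-matched (same log2-degree bin,
nearest non-empty bin as fallback) at hop distance ≥ `min_neg_distance`
from the process's effector set, one per positive by default. Degree
matching at both training and calibration time is what keeps the score
from becoming a hub detector.

**Calibration.** Raw scores are converted to empirical p-values against a
permutation null: N = 999 random proteins from the candidate's log2-degree
bin (excluding the process's own effectors), scored through the same
features and predictor, with p = (1 + #{null ≥ raw}) / (N + 1). The +1
pseudo-count keeps p in (0, 1]; N = 999 makes the attainable p-grid
multiples of 1/1000, fine enough to resolve the 0.01 boundary. One null is
cached per (process, degree-bin) pair — a full per-candidate permutation
would redo identical work at this scale. The p-to-score map is piecewise
linear in log10 p through the published band anchors (0.01 → 92,
0.05 → 78, 0.15 → 63, 0.25 → 38), extended linearly in log10 p to
(0.001, 100) above and to (1.0, 0) below. All segments use the same
log-p interpolation rule — the published description fixes only the
anchors, and a single rule keeps the map strictly monotone with no
representable-p plateaus. Scores exactly on a band boundary take the upper
band (92 is Very high), following the prose definition ("≥ 92") over the
table's ">"; the convention is configurable.

By construction, a fresh degree-matched random candidate exceeds any band
boundary with probability equal to that band's nominal p (slightly less in
practice, because saturated predictor outputs produce ties and ties are
counted conservatively). This identity between score bands and
false-positive rates is what the acceptance script measures.

The published platform's own p-values are proprietary and undocumented;
the permutation construction here is this package's design, chosen to make
the printed score/p correspondence hold by construction rather than by
imitation.

## Prioritization rules

A protein is **strong** if any process score lands in the top three bands
(Very high / High / Medium-High), **medium** if its best band is Medium,
else low. The multimotive selection keeps proteins strong for ≥ 3
processes — by default counting the disease-in-general pseudo-process,
which is what admits transthyretin-like profiles (two named processes plus
the general one) — sorted by best score descending, ties broken by
accession (the printed table has no ties at two decimals; the tie-break
just fixes the order). Novel candidates are selected proteins that are
effectors of none of their scored processes. Published score tables are
sparse (only strong-band rows were printed), so all counting operates on
present rows only.

## Synthetic studies

`stenoprio.synth` generates the conditions the method assumes, with known
truth:

| parameter | default | meaning |
|---|---|---|
| n_nodes / edges_per_node | 500 / 3 | preferential-attachment network (seed edge, each node adds ≤ 3 edges) |
| k_motives / size | 4 / 8–15 | disjoint connected modules, densified to internal density ≥ 0.3 |
| rewire_fraction | 0.1 | fraction of internal module edges swapped in place (density kept, connectivity checked) |
| n_related_per_motive | 5 | new nodes wired into a module with 3 edges (distance 1) |
| n_unrelated | 20 | existing nodes ≥ 2 hops from every module |
| neg_per_pos / min_neg_distance | 1 / 2 | truth-table negative sampling |

Preferential attachment reproduces the heavy-tailed degrees of interaction
networks; the density floor makes modules genuinely proximal
neighborhoods, which is the structural assumption behind distance-based
scoring. Unrelated candidates are existing nodes, not new ones, so their
degrees are realistic for the degree-matched null. The separation
distances default to 2 hops because that is the largest satisfiable value
at these densities: at average degree ≈ 6, two hops from ~45 module nodes
already cover essentially all 500 nodes, so no node sits 3 hops from every
module. Consequently planted "unrelated" is a weaker condition than true
biological unrelatedness — passing recovery tests (AUROC ≥ 0.9 for related
vs unrelated) shows the pipeline resolves one-hop-attached from
two-plus-hop proteins on a small dense graph, not that it would rank a
real 20 000-protein interactome correctly.

What the generator does **not** emulate: multi-layer structure (all
synthetic edges are one layer), correlated noise in effector annotations,
candidates related to several processes at once, missing nodes, or
literature-curation bias in effector sets. Pipeline stage seeds are
derived from one master seed by fixed offsets, so studies, training, and
nulls are reproducible end to end; serialized bundles are byte-identical
across reruns.

## Numerical choices and degenerate inputs

- Random-walk systems are solved with a sparse direct solver and checked
  to sum to 1 (renormalized if accumulated error exceeds tolerance);
  a power-iteration oracle in the test suite agrees to 1e-8.
- A process whose single present effector is the candidate itself seeds
  the walk with the candidate (the leave-one-out set would be empty).
- Empty degree bins fall back to the nearest non-empty bin with a warning,
  both for negatives and for nulls.
- Empty candidate lists, header-only TSVs, and processes with no effectors
  in the graph degrade to empty outputs or skipped units with warnings;
  schema errors (unknown causal level, duplicate accessions, malformed
  edge lines) fail loudly with the offending token or line number.

## Problem sizes

Default test and acceptance runs use the 500-node study: truth tables of
~50 positives, nulls of 999 draws per (process, degree-bin), and 5000
fresh null draws per process for calibration checks. These sizes give
binomial standard errors of ~0.0014 on a 0.01 fraction, small enough to
resolve the top band, and run in seconds on one core.

## Limitations

- The published study's full inputs (interaction map, 168-effector list,
  126 × 9 score matrix) were never deposited; its headline per-process
  counts are verified for internal arithmetic, not recomputed. The
  packaged effector sets cover only what the printed strong-relationship
  table reveals.
- The calibration identity is exact only under the null sampler used to
  build it; a candidate population with systematically different degree
  structure shifts the realized false-positive rate.
- Scores for overlapping processes are computed independently; no
  multiple-testing adjustment is applied across the 9 processes, matching
  the published banding.
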