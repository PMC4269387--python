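# Methods

This note records the models, the numerical choices behind them, and what
the synthetic validation does and does not establish.

## Ladder graphs and conventions

A lexicon is normalized to uppercase A–Z tokens; words containing other
characters are skipped and reported.  One graph per letter length L: nodes
are words, edges join pairs at Hamming distance exactly 1.  Conventions
used throughout:

* **steps** of a ladder = number of intermediate words = edges − 1 (the
  two-step LOVE→HATE solution uses three edges);
* **capacity** of an L-letter word = 25·L, the degree it would have if
  every single-letter substitution produced a word;
* **V-word / C-word** by the first letter; the vowel set defaults to
  {A,E,I,O,U} with Y available via configuration (orthographic Y is
  vowel-like in many positions, but first-position Y words such as YAK are
  conventionally consonant-initial; both readings are defensible, so the
  choice is exposed);
* a stratum's "giant" structure is measured by its largest *connected
  component* (not a clique in the graph-theoretic sense).

Edge detection uses wildcard buckets (each word keyed L times with one
masked position), linear in total letters; a brute-force O(n²L) scan backs
it in the tests.

## Edge betweenness as a geodesic proportion

For each connected component let 𝒫 be the multiset of all shortest paths
between all unordered reachable pairs (tie multiplicity kept, adjacent
pairs contributing their single-edge geodesic).  B(e) is the fraction of 𝒫
containing e.  Including adjacent pairs and counting unordered pairs once
are choices 𝒫's informal definition leaves open; both only rescale B
uniformly, so every ranking-based use is unaffected.  The implementation
accumulates exact integer geodesic counts per edge from one BFS DAG per
source (σ counts forward, path counts backward), O(nm); results are exact
rationals.  Identity Σₑ B(e) = (mean geodesic edge count) is asserted to
1e−12 in the tests.

The top-fraction enrichment table classifies edges by endpoint word types
(CC/VV/VC) and exchanged letters (cc/vv/vc).  The top set is the
⌈f·|E|⌉ highest-B edges expanded across ties at the threshold; the
baseline is the mean classification of 100 seeded equal-size uniform draws
without replacement (draw count and seed configurable and reported).

## Kernel distance

With betweenness values pooled per component, the tail of their histogram
(Freedman–Diaconis bins, bins strictly right of the modal bin) is fitted
log-linearly with **count weights** (weight = bin count, the Poisson-
correct weighting): unweighted fitting lets single-count far-tail bins
flatten the slope and materially under-steepen the kernel.  The kernel is
κ(x) = exp(b·x)/a, the reciprocal of the fitted tail.  Degenerate inputs
(fewer than 10 values, zero spread, non-decreasing tail) raise with advice
to supply a manual kernel; any strictly increasing positive function can
stand in, and adjacent-pair distance *rankings* are invariant to that
substitution (asserted via rank correlation).

Pair distance = mean (default) or minimum over the geodesic collection of
the per-path cost Σ κ(B(e)).  Both modes satisfy all ordering constraints
that motivate the construction; they coincide whenever geodesics are
unique (e.g. on trees).  The mean is computed by dynamic programming over
the BFS DAG (no path enumeration), so the table is O(n·m) per source.
Cross-component distances are undefined (NaN).

## Temperature scales

Within-community pairs aggregate into a baseline bump of the pairwise-
distance density near the low end; each tail bump collects the separations
of one level of community structure.  Because the similarity exp(−d/T)
depends on d/T, scale structure lives on *ratios* of distances: the
density is therefore estimated on log10 distances (Gaussian KDE,
bandwidth factor 0.1 — a Silverman-type rule oversmooths strongly
multimodal inputs; 0.1 resolves bumps less than a decade apart), with
local maxima of prominence ≥ 1% of the density maximum counted as bumps.

The schedule spans the informative range geometrically:

* finest scale = the baseline bump location.  Below it, similarity decays
  within communities and partitions fragment into noise; at it, every
  separation sitting on the tail is still resolved.
* coarsest scale = (last tail bump)/e².  Ensemble experiments show a
  separation s "melts" (its two sides merge) at T ≈ s/3, so at this
  temperature every lesser separation has merged while the top-level
  split, whose pairs retain similarity ≈ exp(−e²) ≈ 10⁻³·⁵, survives.

`n_scales` temperatures are geometrically interpolated between the two
anchors.  When the density shows fewer than two bumps the schedule falls
back to upper quantiles (0.80/0.90/0.95/0.99) and says so in the result's
provenance.  Raw bump locations are always reported.

## Regulated random walks and community extraction

At temperature T the distance table becomes the weighted complete graph
W = exp(−d/T) (zero self-weight) and L(T) = D⁻¹W its row-stochastic
transition matrix.  One walk: start at a uniform random node; at each step
sample the current row restricted and renormalized to the surviving nodes;
remove a node once its visit count exceeds the threshold (default 5);
stop at ≤ 2 survivors.  After a removal the walk continues from the
removed node's row (a teleport-to-random-survivor variant is available).
The walk halts in at most n·(threshold+1) steps by construction.

Recurrence times (steps between consecutive removals) spike when the walk
first enters an unexhausted community.  Spikes are recurrence values
exceeding mean + 2 SD of the profile *excluding the first entry*: the
first recurrence counts the warm-up before any node reaches the threshold
and is an order of magnitude larger than in-community recurrence, so
including it in the baseline masks every true spike.  Runs between spikes
partition the removed nodes; each survivor joins the block to which its
transition row sends the most mass.

The ensemble connectivity matrix averages co-membership over n_walks
(default 100) independent walks, one spawned RNG stream per walk so
n_walks can grow without reshuffling earlier walks.  The community count
k = number of ensemble eigenvalues exceeding 1, capped (default 12): a
singleton contributes exactly its unit diagonal, and a coherent community
of size m contributes ≈ m × (mean co-membership), so eigenvalues above the
singleton baseline count genuine blocks.  (A largest-relative-eigengap
rule was evaluated and rejected: on hierarchical data it always selects
the dominant two-way split, blinding the lowest scale.)  Membership comes
from complete-linkage hierarchical clustering of 1 − ensemble cut into k
clusters — complete linkage because co-membership blocks are compact:
every within-community pair has high co-membership, so the community
diameter in 1 − C is small while single links across communities can be
noisy.

## The multiscale hierarchy

The pipeline runs per connected component (cross-component distances are
undefined) and per scale in increasing order.  Nesting is enforced by
majority-overlap: each community at scale Tₗ maps to the raw community at
Tₗ₊₁ holding most of its nodes, so coarser partitions are unions of finer
ones by construction.  Merge events are annotated with the scale at which
they occur; that scale acts as the realized distance between the merged
communities.  Determinism: one master seed feeds a spawned stream per
scale and per walk; identical seeds reproduce identical results bit-for-
bit.

## Synthetic data: what it emulates and what it does not

* **Planted ladder lexicons**: families of equal-length words filling a
  rook's-grid over two free letter slots (dense, connected), joined by
  designated bridge words sharing a free-slot tuple across families —
  exactly one inter-family edge per bridge, by construction.  This mirrors
  the dense-family/sparse-bridge structure of real strata but not their
  dendrites (chains of degree-1/2 words), unequal family sizes, or
  letter-frequency skew.
* **Planted-partition graphs**: standard Bernoulli stochastic block
  models with ground-truth labels.
* **Two-level hierarchy**: four dense Bernoulli blocks joined by *fixed*
  sparse bridge counts (2 within each superblock pair, 1 across).  Fixed
  counts, not a Bernoulli rate: many parallel bridges each carry little
  betweenness, so a rate-based sibling coupling is read by the kernel
  distance — correctly — as strong coupling, and the planted two-level
  structure dissolves.  The sparse-bridge regime is the one the method
  targets.

Passing these tests shows the pipeline recovers community structure when
separations are carried by few high-betweenness edges.  It does not show
robustness to overlapping communities, weight noise, or bridge-rich
couplings, and dictionary-scale behavior (dendrites, mingled communities)
is exercised only qualitatively.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| vowel set | A,E,I,O,U | word/change typing (Y configurable) |
| top_fraction | 0.05 | enrichment top set (ties expanded) |
| baseline replicates | 100 | random draws behind enrichment baseline |
| aggregation mode | mean | per-pair cost over the geodesic collection |
| KDE bandwidth factor | 0.1 | log-distance density for bump detection |
| bump prominence | 1% of max | peak filter |
| n_scales | 4 | temperatures per geometry run |
| visit_threshold | 5 | visits before a node is removed |
| n_walks | 100 | ensemble size per scale |
| spike rule | mean + 2·SD | recurrence spike threshold (warm-up excluded) |
| max_k | 12 | cap on extracted community count |

All are keyword arguments on the corresponding functions and CLI flags.

## Known limitations

* Betweenness and distances are exact but O(n·m) per component; intended
  for strata up to a few thousand nodes, not for web-scale graphs.
* The count-of-eigenvalues rule assumes co-membership blocks with mean
  coherence well above 1/size; very small communities (2–3 nodes) with
  noisy walks can fall under the singleton baseline and be absorbed.
* Scale selection assumes the distance distribution is multimodal; on
  structureless graphs it falls back to quantiles, and the resulting
  partitions mostly report k = 1 or 2 — which is the honest answer there.
* Walk partitions assign survivors heuristically; with pathological
  visit thresholds (≫ n) the walk removes nothing and the record is
  empty.
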