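# Methods

## Setting

All objects are simple, undirected, unweighted, connected graphs with
vertices 0..n−1. Throughout, m is the edge count, μ = m − n + 1 the
cyclomatic number, d(u,v) the shortest-path distance, s_v = Σ_u d(v,u) the
distance sum of a vertex, ρ the diameter, and S_j(v) the set of vertices at
distance exactly j from v. Disconnected input is rejected by every
distance-based operation rather than given sentinel values: the graph
classes under study are connected by construction, and silently encoded
infinities would poison the collision counts downstream.

## Graph classes

**Connected graphs.** One representative per isomorphism class of
connected simple graphs on n vertices, built by vertex augmentation: every
graph on n vertices arises from some (possibly disconnected) graph on n−1
vertices plus one new vertex with an arbitrary neighbourhood. Candidates
are de-duplicated by canonical certificate and connected survivors are
emitted in ascending certificate order, making runs reproducible and the
stream resumable. The augmentation base must retain disconnected graphs
(a connected graph's last vertex may be its only cut between components).
Certificates and automorphism generators come from igraph's BLISS
implementation; the test suite validates both against explicit
permutation-search oracles and closed-form labelled counts (connected-graph
recurrence), so the external solver is cross-checked rather than trusted.

**Alkane trees.** Free trees with maximum degree ≤ 4 — carbon skeletons of
alkane isomers. Enumeration uses the constant-amortised-time
Wright–Richmond–Odlyzko–McKay free-tree generator with the degree bound
applied as a per-tree filter. At the largest bundled scale (n = 19;
317,955 free trees, 148,284 alkanes) the filter pass costs seconds, so the
simpler post-hoc bound was preferred over an in-construction bound.
Streams keep the generator's own deterministic order: a global certificate
sort would force materialising classes that the pipeline is otherwise able
to process with constant memory (the n = 20–22 classes run to millions of
trees). Tree counts are validated against exhaustive Prüfer-sequence
enumeration (n ≤ 7) and the bounded-occupancy Prüfer counting identity
Σ n!/|Aut| = (n−2)!·[x^(n−2)] (Σ_{i<4} x^i/i!)^n (n = 8, 9).

## Descriptors

### Balaban-type indices

J(G) = m/(μ+1) · Σ_{(u,v)∈E} (s_u s_v)^(−1/2). The two information-
weighted variants replace s_v by u_v = s_v log₂ s_v − Σ_j g_vj · j log₂ j
(total information on the distance magnitudes seen from v, with g_vj the
count of vertices at distance j) and by the mean form u_v/s_v. Edge terms
are summed in sorted order so graphs with identical weight multisets give
bit-identical values — this matters when counting collisions.

### Information-functional entropies

A functional f > 0 on the vertices induces p(v) = f(v)/Σf and
I_f = −Σ p log₂ p ∈ [0, log₂ n], attained at log₂ n exactly when f is
constant (hence on every vertex-transitive graph). The scaled information
distance λ(log₂ n − I_f) is exposed as well; within a fixed-n class it is
a strictly decreasing affine map of I_f and therefore has the same tie
structure, so uniqueness results do not depend on which form is reported
(the plain entropy, λ = 1, is the canonical output).

Level weights c_1..c_ρ are materialised per graph from its diameter:
linear c_j = ρ−j+1, quadratic (ρ−j+1)², exponential e^(ρ−j), or a custom
positive vector with at least two distinct entries. Two graphs of equal
diameter share coefficients. For diameter-1 graphs (complete graphs) the
vector has a single entry; the two-distinct-entries rule is waived because
the entropy is forced to log₂ n regardless. Multiplying all coefficients
by a positive constant leaves every entropy unchanged (probabilities are
ratios); this scale-freedom is property-tested.

- **f_V(v) = Σ_j c_j |S_j(v)|** — the sphere functional.
- **f_P(v) = Σ_j c_j σ_j(v)** — σ_j(v) counts all shortest paths of length
  j starting at v (each geodesic separately, not one per target). On a
  tree the geodesic between two vertices is unique, so σ_j = |S_j| and
  f_P ≡ f_V vertex-by-vertex — which is why the sphere and path entropies
  have provably identical discriminative power on the alkane-tree classes,
  a fact the acceptance suite checks at n = 10.
- **f_ρ** — the degree–degree association functional. For each shortest
  path p = (v = v_0, …, v_j) starting at v, take the total variation of
  the degree sequence along it, TV(p) = Σ_i |deg(v_i) − deg(v_{i−1})|;
  sum over the level-j paths to get λ_j(v); compose exponentially:

      f_ρ(v) = α^( Σ_j c_j λ_j(v) ),   α > 0, default α = 2^(−1/2),
               c_j the linear weights ρ−j+1.

  The exponential composition is what makes the functional well defined on
  *every* graph: on regular graphs all degree differences vanish and
  f_ρ ≡ α⁰ = 1 (maximum entropy), where an additive composition would
  produce an all-zero functional. It is also what gives the index its
  discriminative power: exponent differences between vertices translate
  into probability *ratios*, so the induced distributions separate
  structurally similar graphs that leave every magnitude-based index
  unchanged. An additive variant (1 + Σ_j c_j λ_j) is provided as an extra
  for comparison.

The entropy-transcription choices above were fixed by requiring that the
package reproduce an extensive grid of published collision counts on the
5-, 6-, 7- and 8-vertex exhaustive classes; the sphere and path
functionals and all three weight schemes match that grid exactly
(twelve of thirteen values in scope; the one exception is analysed below).

### Numerical choices for f_ρ

Only ln f_ρ is ever materialised; entropies are evaluated with a shifted
softmax, so exponent totals far outside double range cannot overflow or
underflow. The default α = 2^(−1/2) has two components. The orientation
α < 1 (low weight to high-variation vertices) follows the convention of
the descriptor software tradition this index comes from. The magnitude is
a numerical-conditioning choice: entropies are compared to 12 significant
digits downstream, and the grouping outcome should not depend on the last
bits of a double. For |ln α| ≲ 0.35 the collision counts on every bundled
class are identical across 12-, 13- and 14-digit grouping; for larger
|ln α| (e.g. α = 1/2 or 2) the 8-vertex class develops grouping-precision
artifacts — near-ties created or destroyed by the final few ulps of the
entropy — and the counts drift by tens depending on the rounding. The
parameter is exposed for experimentation; the default sits safely on the
stable plateau.

One published figure is *not* reproduced: the degree–degree association
count on the 8-vertex class is reported in the literature as ndv = 385,
while this implementation's numerically stable count is 333 (invariant
across the full stable α-range and grouping precisions 12–14). The
surrounding evidence — exact reproduction of the same index on the 5-,
6- and 7-vertex classes and of all six sphere/path-functional counts on
the 8-vertex class — localises the discrepancy to the original pipeline's
finite-precision arithmetic at its particular exponent base, which
double-precision recomputation brackets (333 exact-math collisions;
474–581 when α^x is evaluated naively in doubles at α = 1/2 or 2; values
between appear exactly at rounding-boundary groupings). The acceptance
suite asserts the published value and is therefore expected to show this
single failure; the acceptance script reports the package's computed 333.

### Classical registry

The twenty classical indices follow the standard formulas (see the
registry's provenance strings). Where the literature circulates several
inequivalent definitions under one name, the adopted convention is
recorded there and the index participates in invariance and smoke tests
only: compactness is implemented as 4W/(n(n−1)) (W the Wiener index),
complexity index B as Σ_v deg(v)/s_v, and Bertz's connection complexity
with connection classes grouped by centre vertex. Integer-valued indices
(Zagreb 1/2, total adjacency, product of row sums, hyper-distance-path)
are computed in exact integer arithmetic — their collision counts involve
no tolerance at all. Partition entropies sum blocks in sorted order, so
they are bit-exactly permutation-invariant.

## Uniqueness evaluation

ndv(values) groups values after rounding to 12 significant digits and
counts members of groups of size ≥ 2; S = (N − ndv)/N. Significant-digit
(relative) rounding is the right scale for descriptor comparison because
genuine degeneracies arise from identical arithmetic on identical
invariant multisets and agree to the ulp, whereas accidental near-misses
agree only to the few digits near the top. Each report additionally
carries the counts at 10 and 14 digits; a disagreement flags a
tolerance-sensitive descriptor/class pair instead of silently adopting
one number. Note that significant-digit grouping is deliberately *not*
invariant under affine maps of the values (absolute resolution follows
magnitude); the monotone-transform invariance of ndv holds under exact
grouping and is tested there.

The stability analysis re-derives S on repeated random subsamples drawn
without replacement (seeded PCG64), summarised per sample size by median,
quartiles, and 2.5%/97.5% whiskers — the boxplot view in which an index's
uniqueness either holds up or collapses as the sample approaches the full
class. Sampling uses a group-id preindexing of the value list, so one
subsample costs a bincount.

## What the bundled runs do and do not show

Everything bundled is desk-scale: classes up to 11,117 connected graphs
and 148,284 trees. The published full-scale story — the Balaban index
retaining only ~20% sensitivity on the 11.7-million-graph 10-vertex class
while the degree–degree association entropy keeps ~95% — is consistent
with the trend visible at desk scale (J: S = 1.000 → 0.911 → 0.818 →
0.617 from n = 5 to 8, f_ρ: 0.71 → 0.86 → 0.96 → 0.97), but the package
does not recompute it; the generators and evaluation stream with constant
memory precisely so that such off-desk runs remain possible. These are
exhaustive *combinatorial* classes: uniform coverage of all graphs of a
size, with no chemical stability filtering, no heteroatoms, no bond
orders — conclusions transfer to real compound libraries only insofar as
those libraries sample the same skeleton space.

## Known limitations

- Canonical certificates and orbits rely on igraph/BLISS; correctness is
  established by oracle tests at small n, not by an independent in-package
  canonical labeller.
- The connected-graph generator materialises each level's full
  non-isomorphic set (12,346 graphs at level 8); level 10 (~12M) would
  need the checkpointing path rather than in-memory augmentation.
- The f_ρ transcription reproduces every published desk-scale collision
  count except the 8-vertex one discussed above; values of the index
  itself (as opposed to its collision structure) have no published
  reference to compare against at full precision.
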