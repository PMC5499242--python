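# Methods

## Network model

A structural connectome is an undirected weighted graph `G = {V, E}` on
`n` parcellated brain regions, stored as a symmetric nonnegative matrix
`W`. Two raw matrices feed the pipeline: streamline counts `M^NoS`
(tractography output, heavy-tailed, positive) and fractional anisotropy
`M^FA` (per-connection diffusion directionality in (0, 1)). Diagonals
are stored as 0 everywhere and self-connection is treated as undefined;
every formula excludes `i = j` explicitly. An infinite or otherwise
special diagonal would poison sums and shortest-path computations and
is never needed downstream.

### NoS-FA fusion

FA is min-max normalized **over the off-diagonal entries of edges that
exist in the NoS matrix**. Structural zeros are excluded from the
min/max: including them would pin the minimum at 0 on almost every real
matrix and let absent edges dominate the normalization. The fused
weight is the elementwise product. Two degenerate cases are handled
deliberately:

* constant FA (`max = min`): normalized FA is set to 1 on existing
  edges, so fusion degrades gracefully to the pure NoS network instead
  of erasing it through 0/0;
* the minimum-FA edge normalizes to exactly 0 and therefore drops out
  of the fused network. This is the literal consequence of the product
  rule; it removes one edge per network and is documented rather than
  patched.

Input matrices may be real-valued (probabilistic tractography);
integer NoS is not required. `validate_and_symmetrize` averages
asymmetries up to a relative tolerance (default `1e-8`) and rejects
anything larger, reporting the number of adjusted entries.

## The RC importance index

Let `D_i` be binary degree, `S_i = Σ_j w_ij` strength, `k̄` and `S̄`
their means over nodes. The mean-strength reading of `S̄` is a
normalization choice only — any constant here rescales all scores
uniformly and leaves the ranking untouched.

**Distances.** Edge length is `1/w` (more streamlines = shorter
distance); `d^w_ij` is the minimum over paths of the sum of edge
lengths, computed exactly with Dijkstra's algorithm
(`scipy.sparse.csgraph`). Disconnected pairs have `d = ∞` and
contribute 0 wherever an inverse distance is summed.

**Transfer efficiency.** `E_i^w` is a weighted local efficiency: the
sum of `1/d^w_jh` over ordered pairs of distinct neighbors `j, h` of
`i`, divided by `D_i (D_i − 1)` and by `n`. Distances are whole-graph
distances, not neighbor-subgraph distances. Nodes with `D_i ≤ 1` score
0 (the pair count vanishes). The `1/n` prefactor rescales every node
equally and is retained for fidelity to the index's printed form; it
never affects ranking.

**Contribution and evaluation matrices.** `H_BRIM` has off-diagonal
entries `D_i w_ij / (S̄ k̄²)` and diagonal 1; `H_RC` scales row `i` by
`E_i^w` and carries `E_i^w` on the diagonal. The final score is

```
RC_i = E_i^w · Σ_{j≠i} D_j w_ji E_j^w / (S̄ k̄²)
```

RC is nonnegative, zero exactly when `E_i^w = 0` or every neighbor has
zero efficiency, permutation-equivariant, and scales as `c²` under a
uniform weight rescaling `w → c·w` (E scales as `c`, the neighbor sum
as `c²`, `S̄` as `c`) — so rankings are scale-free. Ranks break ties by
ascending region index; hubs are the top `k` ranks (default 15, a
conventional hub-set size for this parcellation; exposed as a
parameter).

**Baseline.** Weighted betweenness uses the same `1/w` edge lengths,
unnormalized pair counts, endpoints excluded (Brandes algorithm via
networkx). Tests check both the RC pipeline and the baseline against
brute-force path-enumeration oracles that share no code with either.

## Network properties

* density: ordered connected pairs / `n(n−1)`;
* global efficiency: mean of `1/d^w` over ordered pairs;
* strength `S_i` (weighted, since the connectivity weights are the
  quantity of interest even where a binary indicator appears in
  shorthand);
* clustering `C_i = 2 t_i / (k_i(k_i−1))` with binary triangle counts
  `t_i` — the classic unweighted coefficient, used because no weighted
  variant is defined for this pipeline;
* nodal efficiency `E_i = Σ_{j≠i} 1/d^w_ij` — a per-node sum of inverse
  distances, **distinct from** the transfer efficiency `E_i^w` above;
  the two are exposed under different names to prevent conflation. The
  mean of `E_i/(n−1)` equals global efficiency exactly, which is
  asserted in tests.

## Vulnerability and targeted attack

Removing region `i` zeroes its incident edge weights; `n` stays fixed
and the node remains as an isolate, so property denominators never
shrink. Vulnerability is `V = (P − P′)/P` for `P` ∈ {density, global
efficiency}. For density this has the closed form `V = D_i/m`, asserted
exactly in tests. Attack curves zero regions cumulatively in rank order
(rank 1 first, default 15 steps — one region per step); both the
cumulative `V` relative to the intact network and the per-step
increment are emitted, since either convention may be wanted when
plotting. The random baseline averages curves over seeded uniform
orderings (default 100 repetitions; the seed is mandatory).

## Cohort comparison

Hubs are located **once** on a benchmark network — the elementwise mean
of the reference (healthy) group's matrices — and then applied to every
subject; a per-subject-hubs mode exists behind a flag for sensitivity
analysis. Mean aggregation was chosen for the benchmark as the simplest
estimator that preserves the group's edge-weight scale. Per subject,
global properties (mean strength, global efficiency, mean clustering)
and hub-local properties (strength, nodal efficiency, clustering
averaged over the hub set; means, not sums, so values are per-hub
interpretable) are computed, group means tabulated, percent reductions
`100·(ref − grp)/ref` reported to 2 decimals, and a one-way ANOVA run
per metric. ANOVA is computed from first principles (sums of squares,
`df = (g−1, N−g)`, p from the F survival function) because the result
object carries the full decomposition; it is cross-checked against
`scipy.stats.f_oneway` in the tests. Degenerate inputs are flagged
rather than erroring: `F = ∞` for zero within-group variance with
unequal means, NaN-with-flag when all observations are identical.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
dataset: 83 regions in 6 modules, edge probability 0.6 within modules
and 0.15 between, 15 planted hubs spread round-robin across modules.
Hubs receive inter-module edges at the intra-module probability and are
wired to each other with probability 0.9 — a rich club, the
organization real connectome hubs exhibit. Connectivity is guaranteed
by overlaying a uniformly random spanning tree. NoS weights are
log-normal(μ=3, σ=1) rounded to integers (heavy-tailed, positive, like
streamline counts); hub edges are multiplied by the hub-strength factor
(default 3) once per hub endpoint, so rich-club edges carry the factor
squared and the planted signal is topological as well as ponderal. FA
is Beta(4, 2) rescaled into [0.2, 0.8], independent of NoS by default
(a correlation knob exists because real FA and NoS correlate
positively).

Cohorts share one base connectome; each subject gets multiplicative
log-normal weight noise (σ=0.1) and small additive FA noise, then the
group's attenuation factor (healthy 1.00, siblings 0.95, patients 0.90;
sizes 60/83/62) scales every hub-incident weight once — so a 0.90
factor plants a ~10% hub-strength reduction, which the study pipeline
recovers within Monte-Carlo error. All randomness derives from a single
seed via fixed stream offsets, so topology, weights, FA and subjects
are independently reproducible.

**What passing tests do and do not show.** The generator produces
modular, hub-bearing, heavy-tailed networks, but not geometric
embedding, distance-dependent connection probabilities, measurement
artifacts of tractography (gyral bias, crossing-fiber dropout), or
realistic inter-subject topological variability (subjects share one
topology). Recovery results therefore validate the pipeline's
correctness and sensitivity, not its performance on real MRI cohorts.

## Numerical choices and problem sizes

Exact Dijkstra distances (no approximation); `inf` handled explicitly
everywhere inverses are formed. Rank ties break by ascending region
index. Matrices are validated (symmetry, nonnegativity, zero diagonal,
FA range) at construction. Brute-force oracle comparisons run on 200
random graphs of 4–8 nodes; parameter-recovery suites use 20 seeds at
the full 83-region scale and cohorts of 8–10 subjects per group, sizes
at which the full test suite completes in well under a minute while
exercising every pipeline stage at the reference network size.

## Known limitations

* The min-FA edge always fuses to weight 0 (one edge lost per network).
* Clustering is binary; a weighted clustering variant is out of scope.
* The group study assumes a shared parcellation across subjects and
  does not correct for multiple comparisons across metrics (none is
  applied by design; post-hoc pairwise tests are out of scope).
* Subject-level results from the original MRI cohort (absolute
  importance values, F statistics) are not reproducible without that
  cohort; only quantities derivable from the published group means, and
  synthetic-data properties, are asserted.
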