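# Methods

## Model

A weighted undirected network `(V, E, w)` with `w_xy = w_yx >= 0`, no
self-loops, and a fixed topology (the set of pairs with `w_xy > 0`;
weights below 1e-12 are treated as absent at construction) is read as a
Markov chain. The one-step walk measure at a non-isolated node is
`mu_x(y) = w_xy / d_x` with strength `d_x = sum_{y~x} w_xy`; there is no
lazy (self-mass) component. The ground metric for all transport
computations is the *unweighted* hop distance; weights enter only through
`mu_x`. Consequences used throughout:

- `mu_x` and everything derived from it are invariant under uniform
  rescaling of the weights.
- Pairs in different components have no curvature; they are skipped and
  counted, never silently zeroed.
- Node identifiers are opaque strings and every table is ordered
  lexicographically, so all outputs are byte-stable.

## Curvature

`kappa(x, y) = 1 - W1(mu_x, mu_y) / d(x, y)`, with W1 solved as an exact
linear program over couplings on the two supports (HiGHS, feasibility
tolerances 1e-9). Posing the LP on supports rather than the whole vertex
set makes the per-edge cost `O(deg^2)` variables. Only the optimal cost
is contractually deterministic; on symmetric graphs the optimal plan is
degenerate and any optimal vertex is acceptable. An independent
exhaustive oracle (`brute_force_w1`) enumerates transport-plan vertices
by recursive min-shipping over all cell orders; it is exponential and
restricted to combined supports of at most 6 points, which is what makes
it usable as a cross-check against the LP.

Non-adjacent pairs use the same formula with the pair's hop distance in
the denominator and the two one-step neighborhoods as supports; because a
graph is 1-geodesic, a curvature lower bound on edges extends to all
pairs, and network-level averages are taken over adjacent pairs only.

Nodal contractions: normalized scalar curvature `sum_y mu_x(y)
kappa(x,y)`, unnormalized `sum_y kappa(x,y)`, and the min/max over the
adjacent neighborhood. The walk's stationary measure `nu(x) = d_x / sum_z
d_z` is computed analytically (detailed balance), and the contraction
diagnostic tracks `W1(delta_x P^t, nu)` against the geometric envelope
`(1-k)^t` when the minimum adjacent curvature `k` is positive. Bipartite
graphs oscillate instead of converging; the diagnostic flags this rather
than failing.

## Entropy comparators

Local network entropy is the Shannon entropy of `mu_x` in natural log
(a log2 switch exists; the base cancels in the normalized variant),
normalized by `log deg(x)`. Degree-1 nodes take normalized entropy 0 by
the point-mass limit convention. Isolated nodes appear in tables with
missing values.

## From expression data to weights

Per topology edge, Spearman correlation (average-rank ties, computed as
Pearson on ranks) within one phenotype's samples maps to `w = (1 +
rho)/2` in [0, 1] — the standard transform that makes the walk
well-defined on correlation data. Two conventions keep pipelines alive
on awkward inputs, both logged: an exactly anticorrelated edge would get
`w = 0` and silently change the topology, so `rho` is floored at
`-1 + 1e-7`; and an undefined correlation (constant gene) becomes the
no-information weight 1/2 unless strict mode is on. Differential
co-expression standardizes the Fisher-z change,
`(z_T - z_N) / sqrt(1/(N_T-3) + 1/(N_N-3))`, with `|c| >= 1` clipped to
`1 - 1e-7` before `atanh`; per-gene differential expression sums the
edge values incident to the gene.

Topology builders: SIF rows filtered to one interaction type with both
endpoints inside the gene set (undirected, de-duplicated, self-loops
dropped); stoichiometric adjacency `A = MG^T MG` with `MG = S_P R`,
where `S_P` is the cofactor-pruned stoichiometric matrix, optionally
dropping reactions touching more than a cap (default interface: 4) of
distinct metabolites. Matrices are binarized before and after each
product so coefficients act as presence/absence only; reactions emptied
by pruning are kept as zero columns (they contribute nothing).

## Differential analysis

Aligned tables produce tumor-minus-normal deltas ranked descending with
lexicographic tie-breaks. The distribution summary reports the
difference of means (and the mean paired difference, identical for
aligned equal-size tables but both are reported) and, for each tail
fraction `q` in {0.001, 0.005, 0.01, 0.03, 0.05}, the difference of the
per-distribution means over the lowest/highest `ceil(qn)` values; a
non-default flag switches to tails of the paired differences instead.
The paired one-tailed Wilcoxon signed-rank test drops zero differences
(classic convention, not Pratt), averages tied ranks, uses the exact
sign-assignment null (subset-sum convolution over doubled ranks, exact
under ties) for up to 25 nonzero pairs and a normal approximation with
continuity and tie corrections beyond; an all-zero difference vector is
degenerate and reported as p = 1 with a warning.

## Ornstein–Uhlenbeck demonstration

`dx = -alpha x dt + sigma dW` has Gaussian transition laws with mean
`x0 e^{-alpha t}` and x0-independent variance
`sigma^2 (1 - e^{-2 alpha t}) / (2 alpha)` (Brownian limit `sigma^2 t`
below `alpha = 1e-12`). Equal variances make `W1 = |mean difference|`
(translation coupling), so `kappa = 1 - e^{-alpha t}` independent of the
starting points and of sigma. The curvature default `t = 1` reproduces
the reference values 0.6321 (`alpha = 1`) and 0.0952 (`alpha = 0.1`).
The simulator is Euler–Maruyama (pedagogical fidelity to the SDE); an
exact-transition sampler and a vectorized ensemble exist for moment
checks. The process is 1-dimensional by design.

## Synthetic data: what it emulates and what it does not

The generators reproduce the design of a two-phenotype co-expression
study at desk scale: a fixed sparse topology whose weights evolve
between phenotypes. Defaults — frozen once after a power analysis and
not revisited — are 20 genes, 40 Erdős–Rényi edges (average degree 4,
the sparse physical-interaction regime), base correlation 0.2, 100
samples per phenotype. At these settings a +0.4 planted correlation
shift is recovered in the top-5 of |differential co-expression| in ~95%
of replicates and the planted weight change is positive in ~100%; the
curvature change carries the planted sign in ~73% of replicates, so the
pre-registered acceptance threshold for that sign-agreement rate is 60%
(observed minus roughly two binomial standard deviations at 50
replicates).

Expression values are multivariate Gaussian with the base correlation on
topology edges and shifts on chosen edges in the tumor phenotype only.
Correlation matrices are repaired to positive definite by eigenvalue
clipping at 1e-6 and diagonal renormalization; if the repair moves any
entry by more than 0.1 the requested structure is rejected as
infeasible. Because the data are Gaussian, Spearman targets are only
approximately the planted Pearson values (the `(6/pi) arcsin(rho/2)`
gap), so the ground-truth sidecar stores the *realized* post-repair
correlations and recovery tests compare against those. The generator
does not emulate count marginals, batch effects, outliers or
heavy-tailed noise of real cohorts — passing recovery tests demonstrate
the machinery, not robustness to real-data artifacts.

Topology families for the curvature-vs-entropy comparison are
Erdős–Rényi (exact edge count), ring lattice (`2m/n` even), and
preferential attachment topped up or trimmed to the exact edge count —
three matched-size families (200 nodes, 400 unit-weight edges in the
reference experiment) differing only in structure: random, regular, and
heavy-tailed. At that size, 20 seeds per family order the families
identically by mean adjacent curvature and mean normalized entropy
(ring lattice > preferential attachment > Erdős–Rényi on both).

## Numerical conventions

- Measure masses must sum to 1 within 1e-12; the transport solver
  refuses mass mismatches beyond 1e-9 rather than renormalizing.
- Asymmetric adjacency input is averaged within 1e-9 and rejected
  beyond; duplicate reversed edge-list rows must agree within 1e-9.
- Curvature tables are serialized to 6 decimal places; every seeded
  command is byte-reproducible and writes a manifest echoing its full
  configuration.
- Problem sizes in the test suite (desk-scale graphs up to a few hundred
  nodes, 50-replicate recovery runs, 20-seed ensembles) were chosen so
  the whole suite runs comfortably on a single CPU.

## Known limitations

- Directed or signed networks are out of scope; weights must be
  nonnegative and symmetric.
- The ground metric is hop distance only; weighted shortest paths are
  deliberately not offered.
- Entropic/Sinkhorn approximations are not provided — the point of the
  package is the exact LP.
- Ricci flow on the weights (uniformizing curvature by evolving `w`) is
  a natural follow-up and is not implemented.
- The Wilcoxon test is applied once per network comparison, not per
  pair; no multiple-testing machinery is included.
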