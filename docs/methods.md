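# Methods

## The approximation

For an alignment of m sites and any tree T (topology plus branch lengths),
site independence gives LL(T) = Σᵢ LLᵢ(T), where LLᵢ(T) is the log-likelihood
of column i under a reversible substitution model. Across trees, the per-site
log-likelihood profiles are strongly correlated, so a small weighted subset of
sites can predict the total. `sitelasso` selects that subset by regression:

1. Generate η training trees — random stepwise-addition topologies with
   i.i.d. exponential branch lengths (mean 0.1) — and compute the η × m
   matrix X of exact per-site log-likelihoods. No branch-length or model
   optimization is applied to training trees; the rows are meant to span a
   broad region of tree space, not to be good trees.
2. Fit the positive-coefficient Lasso: minimize ‖y − β₀ − Xβ‖² + λ Σ βᵢ with
   βᵢ ≥ 0, where y holds the row sums (the exact tree log-likelihoods).
   Positivity makes the result usable as a site-weight vector for any
   likelihood engine that accepts positive weights.
3. Walk a 100-point log-scale penalty grid (max/min ratio 10⁷), whose maximum
   is the smallest λ that forces the all-zero solution, and keep the first
   (largest-λ) grid point whose non-zero fraction reaches the target ζ.
   The achieved fraction is reported; coefficients are never truncated to hit
   ζ exactly, because truncation would break the fitted model.

The selected sites i₁…i_τ with weights β and intercept β₀ define
LL(T) ≈ β₀ + Σₖ β_{iₖ} LL_{iₖ}(T); the intercept can be dropped during tree
search since it does not affect rankings.

Columns are centered and scaled to unit L2 norm before fitting (selection is
scale-free); y is centered but not norm-scaled, matching common Lasso-path
conventions. Weights and the intercept are mapped back to the original scale
analytically. Duplicate alignment columns are *not* collapsed before
training: identical sites are precisely the correlated predictors the Lasso
is expected to represent by one member, and selection must report original
site indices. Pattern compression is used only inside the likelihood engine.

## Likelihood engine

Felsenstein pruning over compressed site patterns with per-node scaling;
discrete-gamma rate heterogeneity with k equal-probability categories whose
rates are the conditional means of the Gamma(α, α) quantile slices,
renormalized to mean exactly 1 so branch lengths stay in
expected-substitutions units. Transition matrices come from the symmetric
eigendecomposition of the reversible rate matrix. Ambiguity codes are partial
(0/1) tip vectors over compatible states; fully ambiguous columns have
log-likelihood exactly 0 and zero variance across trees, so standardization
flags them and the Lasso never selects them.

Branch lengths are optimized coordinate-wise. A sweep walks the tree top-down
maintaining the conditional likelihood of the data above the current edge
(at its parent end) and below it (at its child end); in the eigenbasis of Q,
the likelihood as a function of that one branch reduces to
Σ g[p,c,e]·exp(λₑ t r_c), so each trial length costs O(patterns × k × states).
The one-dimensional maximization uses bounded Brent on log t over
[10⁻⁸, 100] — on the log scale the optimum of a typical branch sits
mid-interval, where the bounded search is reliable; on the linear scale it
can stall in the numerically flat saturation tail. Each single-edge step
maximizes the exact current-tree likelihood in that coordinate, so the total
log-likelihood never decreases. Sweeps stop when a full sweep gains < 0.01
log-likelihood units or after 32 sweeps (non-convergence returns the best
tree with a warning and `bl_converged=False`).

The gamma shape α is estimated by bounded Brent on log α over [0.02, 100]
(relative tolerance 10⁻³), alternated twice with branch-length optimization.
Empirical-Bayes site rates are posterior means over the k categories,
r̂ᵢ = Σ r_c P(site i | r_c) / Σ P(site i | r_c); the standardized copy uses
the sample (n−1) standard deviation — the denominator convention was an open
choice and is stated here so downstream thresholds are interpretable.

## Coordinate descent

The positive Lasso path is solved by cyclic coordinate descent with warm
starts along the decreasing grid. With unit-norm columns the coordinate
update is the one-sided soft threshold max(0, βⱼ + Xⱼᵀr − λ/2), the exact
one-dimensional minimizer, which makes the objective monotone per update.
Convergence: max coefficient update < 10⁻⁴ × max|β| after a full sweep;
between full sweeps the active set is iterated until stable. Coefficients
below 10⁻¹² of ‖y‖ are snapped to zero — at the grid maximum the threshold
is met with equality and float rounding otherwise leaves ~10⁻¹² jitter that
would spin forever against a purely relative criterion. Strongly correlated
column blocks can exhaust the 2000-sweep cap at a few mid-path grid points;
the path then continues from the best iterate with a warning, which matches
how practitioners run warm-started path solvers on such designs.

## Tree search

Greedy SPR hill-climbing. Neighbors within rearrangement radius 5 (edges
between the dissolved attachment point and the regraft edge; radius 1 equals
the NNI set) are scored lazily: the regraft edge is split in half, the pruned
subtree keeps its branch length, and the two merged edges are summed, so
total tree length is conserved and no optimization is run. The first neighbor
scoring > 0.1 above the current tree is accepted immediately (deterministic
preorder-prune/BFS-regraft order) and the scan restarts; if none qualifies,
the 50 best lazily-scored neighbors get full branch-length optimization, in
rank order, accepting the first that qualifies. Ties are broken by
enumeration order.

The two-phase variant runs that search first entirely under the Lasso
approximation (its candidate-optimization step maximizes the weighted
objective on the sampled sites — the alternative of skipping optimization in
phase 1 was an open choice; optimizing keeps the two phases structurally
identical). Phase 2 restarts from the phase-1 optimum: lazy scans stay on the
approximation, but candidate optimization and acceptance use the full
alignment. Final log-likelihoods of every strategy are reported on the full
alignment.

## Synthetic data and what it shows

The simulator evolves sites down a tree under the same models and the same
*discretized* gamma categories the engine evaluates, recording true rates,
categories and root states. Using discretized (not continuous) gamma in
simulation makes parameter-recovery tests free of discretization bias — that
error is tested separately against quadrature.

The default benchmark is the smallest study condition: 15 taxa, 2000 sites,
WAG with four categories and α = 0.93, branch lengths exponential with mean
0.1, training size η = 200 and ζ = 5% (the package's default η for real runs
is 2000 for ≤ 15 sequences and 4000 above, matching the sizes the method is
normally run at; the test suite and acceptance script use scaled-down
η so the full pipeline runs in minutes on one CPU). Search benchmarks use
8–12 taxa with 1000–4000 DNA sites.

What passing these tests does not show: synthetic alignments lack alignment
error, gaps in biased patterns, gene-tree discordance, and the length scale
(20 000–80 000 sites) of real phylogenomic matrices, where the approximation
is reported to be even more accurate (accuracy grows with m). Absolute
runtimes here say nothing about speedups at that scale; the package instead
verifies the structural claim — orders of magnitude fewer full-alignment
evaluations for the same final tree.

Two synthetic-scale caveats found while testing, both deliberate deviations
from naive expectations: (a) a *constant* alignment does not push the gamma
shape estimate to its upper bound — with positive branch lengths, rate
spread strictly helps constant columns (convexity of exp), so the
no-heterogeneity degenerate case is tested with data simulated under a
homogeneous rate instead; (b) the direction of the sampling bias toward
fast-evolving partitions is not stable on small two-partition fixtures
(saturation can flip it), so the partition tests assert inhomogeneous
sampling plus consistency with the partitions' mean standardized rates
rather than a fixed direction.

## Numerical choices and degenerate inputs

- Per-pattern scaling at every internal node; scalers accumulate in log space.
- Transition-matrix entries are clipped at 0 (eigendecomposition round-off);
  rows then sum to 1 within 10⁻¹⁰ without renormalization.
- ζ = 1 or all-site samples reproduce exact log-likelihoods identically.
- k = 1 gamma categories: site rates are all 1, the standardized vector is
  defined as 0 with a degenerate flag.
- Two-taxon trees (a single edge) are supported throughout the engine.
- Empirical (+F) frequencies use add-one pseudocounts over non-ambiguous
  characters, so no frequency is ever zero.
- The unreachable-ζ error reports the achievable fraction range: the target
  fraction is bounded above by the fraction reached at the grid minimum.

## Known limitations

- No invariant-sites category, codon models, or model selection.
- Partitioned analyses share branch lengths across partitions (only α and
  frequencies are unlinked); no per-partition rate scalers.
- The SPR search is single-strategy first-improvement; no TBR/NNI modes, no
  multi-start orchestration beyond calling it in a loop.
- The engine favors clarity over peak speed: no site-repeat caching below
  subtrees and no SIMD kernels.
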