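# Methods

This note documents the model, the algorithmic and numerical choices, and
what the synthetic benchmark does and does not establish.

## Model and assumptions

Gene expression is assumed log-linear in hidden transcription-factor (TF)
activities. With stages indexed by *t* and a designated control stage
(index 0), the relative expression of gene *i* is a product of activity
ratios raised to gene-specific control strengths:

E_i(t)/E_i(0) = ∏_j (TFA_j(t)/TFA_j(0))^{CS_ij}.

Taking log2 gives the bilinear form [E] = [S][A] with [E] (N × M) the log2
expression ratios, [S] (N × L) the control strengths and [A] (L × M) the
log2 activity ratios. The assumptions inherited from this form:

- regulation combines multiplicatively (additively in logs) with no
  saturation, cooperativity terms, or TF–TF interaction terms;
- the wiring (which entries of [S] may be nonzero) is known a priori and
  fixed during fitting;
- noise is treated as additive on the log2 scale.

Because any nonsingular diagonal [X] gives [S][A] = [S][X][X⁻¹][A], the
decomposition is at best unique up to per-TF scale and sign. Uniqueness of
the support-constrained factorization additionally requires the three
topology criteria (below).

## Identifiability criteria

1. The support pattern Z0, treated as a generic-valued matrix, has full
   column rank L.
2. For every TF, deleting its column and every gene it regulates leaves a
   pattern of full column rank L − 1.
3. L ≤ M, so the activity matrix can have full row rank.

Generic rank is evaluated numerically: the support is filled with random
nonzero values (uniform magnitude in [0.5, 1.5], random sign) and the
numerical rank taken; the maximum over 3 fillings is used. A generic
filling achieves the structural rank with probability one, so 3 fillings
make a false "rank-deficient" verdict vanishingly unlikely while keeping
the check cheap enough to run inside rejection-sampling loops. Note that a
*duplicated support column* is generically full rank — such topologies fail
through criterion 2 (removing either TF removes the shared targets),
not criterion 1.

Criterion 3 takes the number of conditions as an explicit argument rather
than inferring it, because a study may have more replicate profiles than
distinct stages and the binding constraint is the profile count.

`reduce_to_identifiable` prunes greedily: at each step the TF whose removal
most reduces the violation count is dropped (ties broken by fewest targets,
then lexicographic ID, for reproducibility), along with genes left
regulator-less. Greedy pruning is not guaranteed minimal, but the removal
log makes the funnel auditable and the result is always verified against
the checker.

## Prior construction

Candidate edges come from coexpression. After the differential-expression
filter (|linear FC| > 1.6 in ≥ 1 stage, i.e. |log2 ratio| > log2 1.6 ≈
0.678 — the threshold is configurable, and a flag switches to reading the
cutoff directly on the log2 scale), genes are hierarchically clustered with
complete linkage on the 1 − |r| correlation distance. An edge TF → gene is
admitted iff |r| > 0.9 **and** the gene co-occurs with the TF in the flat
clustering cut at height 0.1. The cut height is on the same 1 − |r| scale,
so the default pair (0.9, 0.1) is self-consistent; both are knobs. The
"sub-tree of the TF node" notion is operationalized as flat-cluster
co-membership because it makes the two conditions composable and gives a
single interpretable parameter. Negative correlations are admitted with
negative initial strength (anticorrelation reads as repression). The
trivial self-pair (a TF with its own row, r = 1) is excluded;
auto-regulation remains representable when independent evidence supplies
such an edge.

Constant expression rows have undefined correlation; those pairs are
reported and treated as r = 0.

## Solver

Alternating least squares on min ‖[E] − [S][A]‖_F, S ∈ Z0:

- **S-step**: each gene row is an independent ordinary least-squares
  problem restricted to its supported TFs (solved by `lstsq`; zeros off
  support are exact by construction, never thresholded).
- **A-step**: one unconstrained least squares for all columns at once.

Both half-steps are exact minimizers of the shared objective, so the
per-iteration objective is provably nonincreasing; this is asserted in
tests on every run. Convergence is declared when the relative objective
decrease falls below `tol` (default 1e-8) or at `max_iter` (default 1000).
Restart 0 initializes [S] at the prior's correlation-valued strengths —
the natural warm start, which also guarantees the final residual is no
worse than the initial correlation-strength solution; restarts 1..n−1
(default 10 total) draw [A] from a standard normal. The best final
objective wins.

### Gauge normalization

The canonical form fixes the diagonal gauge with three intrinsic rules:
(1) the control-stage activity entry is pinned to 0 — at any least-squares
optimum this already holds exactly, because the control column of [E] is
identically zero and the A-step solves that column independently, so the
shift is a no-op on fitted results and only cleans up externally perturbed
inputs (a genuinely nonzero control entry raises, since zeroing it would
change [S][A]); (2) each activity row is scaled to unit RMS over stages;
(3) the sign is chosen so each strength column has nonnegative inner
product with the prior's initial strengths (tie: the largest-magnitude
strength entry is made positive). These rules make normalization
idempotent and invariant to any prior diagonal perturbation, which is
tested directly. The "unit-activity-norm" convention applies rules 2–3
without the control-entry requirement.

### Bootstrap

Gene rows are resampled with replacement; a draw whose support pattern
fails identifiability is redrawn (up to 20 times per replicate; if fewer
than half of the replicates succeed the bootstrap aborts). Each refit is
aligned to the reference solution by the per-TF least-squares gauge scale
of its activity rows, strengths for all original genes are then re-solved
against the aligned activities (so every replicate yields a complete
strength matrix, including genes absent from the draw), and percentile
intervals are reported. Coverage of true strengths is verified on
simulation at log2 noise 0.2 (≥ 90% of supported strengths inside the 95%
intervals).

## Network assembly

Edge signs are the sign of the TF–gene expression Pearson correlation
(positive coexpression = activation); an exactly zero correlation falls
back to the fitted strength's sign and is logged. Signs are invariant to
positive rescaling of expression rows. Target genes are clustered on the
rows of the adjusted strength matrix (correlation distance, complete
linkage); bit-identical rows are forced to distance 0 so genes with equal
regulator profiles always co-cluster even where correlation distance is
undefined (constant or length-1 rows). TF–TF relations are reported
strictly as activity-trajectory correlations (|r| > 0.5, sign retained),
never as physical interactions; the buckets for TF-activity vs.
own-expression agreement are strong-positive (r > 0.5), strong-negative
(r < −0.5), weak (|r| ≤ 0.5) — the boundary value itself is weak. Curated
edges merge provenance-tagged and unweighted; a curated duplicate of a
fitted edge is kept once with provenance "both". Per-stage "expressed"
flags use |log2 ratio| against a configurable threshold, or external
detection flags when provided, since array-platform detection calls are
upstream of this package.

## Motif census

Connected induced subgraphs of size k ∈ {3, 4, 5} are enumerated exactly
with the ESU algorithm (each subgraph visited once, growth restricted to
exclusive neighbourhoods of nodes above the root's label). Classes are
canonical labels: the lexicographically minimal off-diagonal adjacency
bit-string over all k! permutations, brute-forced (k! ≤ 120) and cached —
simpler than refinement-based canonicalization and exhaustively verifiable
at these sizes. Self-loops are ignored for connectivity and labelling.
Signed-class labelling (sign characters in the bit-string) is available
behind a flag but off by default.

The null ensemble preserves in- and out-degree sequences exactly:
double-edge swaps (a→b, c→d) → (a→d, c→b), rejecting swaps that would
create self-loops or parallel edges; default 100 × |E| attempts, failures
skipped. Per class, z = (observed − null mean)/null sd (sd = 0 reported as
undefined) and the add-one empirical p = (1 + #{null ≥ obs})/(1 + n_random),
bounded below by 1/(n_random + 1). When ranking motifs, classes observed
fewer than 4 times are excluded: a single chance occurrence of a rare class
against a near-zero null produces an unstable, inflated z (the same
minimum-occurrence rule used by standard motif-detection tools).

## Synthetic data

The generator emulates the statistical structure of a staged developmental
course, not the biology:

- **Topology**: each gene draws `edges_per_gene` regulators uniformly
  without replacement; rejection sampling against the identifiability
  checker, capped at 1000 attempts — a cap failure signals genuinely
  infeasible parameters (e.g. every gene regulated by every TF).
  Strengths are uniform on ±[0.5, 1.0] with 30% negative by default.
- **Activities**: per-TF smooth Gaussian bumps peaking at a random interior
  stage ("single-peak", the default, mirroring stage-specific activation),
  monotone ramps, or flat; every row is shifted so the control-stage entry
  is exactly 0 and bounded by the amplitude (default 2 on the log2 scale).
  The default stage panel is the seven-stage pollen course
  (UNM, BCP, TCP, MP, HP, 0.5hr, 4hr) with MP as control.
- **Expression**: [S][A] plus i.i.d. Gaussian log2 noise (default sd 0.1)
  on the non-control columns; the control column stays exactly zero, as a
  ratio of the control stage to itself must. By default the expression
  table also carries one row per TF gene tracking that TF's activity plus
  the same noise, because prior construction and sign assignment need the
  regulators' own transcripts.
- **Planted-motif networks**: 40 background edges drawn uniformly among 50
  nodes plus 15 planted feed-forward loops. The background is deliberately
  sparse: at higher densities a degree-preserving null regenerates enough
  feed-forward loops by chance that the planted class is no longer
  enriched and the network would not be the "FFL-enriched" instance it
  claims to be (planted-class z ranges over roughly 2–6 across seeds at
  the default sizes).

What passing on this generator does *not* show about real data: the noise
model is homoscedastic Gaussian with no probe effects, detection limits,
missing values, or cross-laboratory batch structure; activities are smooth
and independent across TFs, whereas real regulators are correlated; the
prior support is exactly correct by construction, whereas a
coexpression-derived prior on real data contains false edges the solver
cannot remove (it can only shrink their strengths). Recovery numbers on
synthetic data are therefore upper bounds on real-data performance.

## Problem sizes and defaults

The verification battery uses 100 genes × 10 TFs × 20 stages for recovery
(noiseless and at log2 noise 0.1, 10 replicate simulations), 100 random
small instances for solver invariants, 100 random priors (N ≤ 15, L ≤ 5)
for the identifiability cross-check, 20 random digraphs (≤ 30 nodes) for
the enumeration cross-check, and 1000 randomizations for planted-motif
detection — sizes chosen so each property is exercised well clear of
trivial regimes while the whole battery runs in minutes on one core.

Key defaults: `fc_threshold` 1.6 (linear), `r_threshold` 0.9, `cut_height`
0.1, `tf_corr_threshold` 0.5, ALS `tol` 1e-8 / `max_iter` 1000 /
`n_restarts` 10, bootstrap `n_boot` 100 at level 0.95, motif `n_random`
1000. The pipeline derives all stage seeds from one master seed via
`numpy.random.SeedSequence`, and the run manifest records a SHA-256 per
artifact; reruns with the same config are byte-identical.

## Known limitations

- Greedy identifiability reduction may remove more TFs than a minimal
  repair would.
- ALS converges to a stationary point; restarts mitigate but do not
  eliminate local minima (the nonlinear-oracle cross-check bounds this on
  small instances only).
- The generic-rank test is probabilistic (error probability is zero only
  in exact arithmetic).
- The motif census is exact but exhaustive; it is intended for networks of
  a few hundred edges, not genome-scale graphs.
- Missing expression values are rejected, not imputed; the model has no
  missing-data mechanism.
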