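# Methods

## Model and assumptions

`fuzzylump` treats community structure as a model-reduction problem for
the random walk on a network. The walk on an undirected weighted graph is
reversible: its stationary distribution is degree-proportional and detailed
balance holds exactly. Both properties are load-bearing — the lumped chain
inherits detailed balance with respect to the aggregated masses μ̂, and the
objective's μ_x/μ_y weighting is the natural (reversibility-symmetric)
Hilbert–Schmidt metric in which the symmetrized transition operator
M^{1/2} P M^{-1/2} lives. Directed input is therefore rejected at load
time rather than silently symmetrized.

The fuzzy partition ρ and the reduced chain p̂ are optimized jointly.
The lifted matrix p̃ = ρ p̂ Λ (with Λ the conditional node distribution of
each cluster) always has stationary distribution μ, so the objective
J = Σ (μ_x/μ_y)(p_xy − p̃_xy)² compares two chains with the same invariant
measure.

### Norm convention

Two metrics are implemented: the stationary-weighted form above (default)
and the unweighted Frobenius norm (`weighting="frobenius"`). The weighted
form is the package's canonical convention; it is the one under which the
karate-club benchmark reproduces the published objective values
(4.0394/4.0389 for projections P1/P2) and per-member association
probabilities at printed precision. The Frobenius switch is kept for
comparison only.

### The optimal reduced chain for a fixed membership

For a **hard** membership the aggregation formula
p̂_kl = Σ μ_x ρ_k(x) p_xy ρ_l(y)/μ̂_k is provably the unique minimizer of J
over K×K matrices (the stationarity condition R'M(P−p̃)R = 0 is solved
exactly because R'MR is then diagonal). For genuinely fuzzy memberships
the exact unconstrained minimizer is p̂* = C⁻¹(R'MPR)C⁻¹M̂ with C = R'MR;
its rows sum to 1 but it can leave the probability simplex (on the karate
club it develops entries near ±2), which destroys the probabilistic
reading and the lumped detailed balance. The package therefore keeps the
aggregation formula as the canonical stochastic reduced chain
(`optimal_lumped`) and exposes the closed form separately
(`unconstrained_optimal_phat`) for analysis; the optimizer maintains p̂ by
projected gradient steps rather than by re-solving either form.

## Gradients

The partial derivatives of J are computed in closed form by matrix
calculus. With E = P − p̃, F = (μ_x/μ_y) ⊙ E, M = diag(μ), R = ρ:

* ∂J/∂p̂ = −2 R'FMR M̂⁻¹,
* ∂J/∂ρ collects the three dependence paths of the lift on ρ — the node's
  own membership row, the conditional distribution in the lift column, and
  the aggregated masses μ̂ inside the denominator — giving
  −2 [ F M R M̂⁻¹ p̂' + M F' R p̂ M̂⁻¹ − μ c' ] with
  c_m = Σ_x (Rp̂)_{xm} (FMR)_{xm} / μ̂_m².

The derivation is validated against central finite differences (relative
error ≤ 1e-4 asserted on 50 random instances; observed ≈ 1e-9). Agreement
with finite differences is treated as the authority for correctness.

## Optimizers and numerical choices

* **Learning rate** a = 1.5 (constant) by default. The value is set so
  that the karate-club fit converges in the order of 50–250 iterations
  (SDP 164/226, CGP 68/107 for P1/P2), matching the published iteration
  scale; a ≳ 2 makes steepest descent with the P1 projection oscillate
  without converging. An optional harmonic decay a_n = a/(1 + γn) keeps
  the step-sum divergent for users who want a vanishing schedule; it is
  off by default.
* **Momentum** b = 0.5 for CGP. This "reduced" conjugate gradient uses a
  constant momentum coefficient, not a Polak–Ribière/Fletcher–Reeves
  ratio; empirically it halves to quarters the iteration count of SDP at
  equal (a, tol).
* **Stopping test**: Frobenius norm of the membership change per iteration
  below tol = 1e-6 (the membership alone, not p̂, is monitored);
  max_iter = 10000, with a `converged` flag rather than an exception on
  expiry.
* **Projections**: P1 clamps to [0, 1] and renormalizes (an all-nonpositive
  row maps to the uniform vector, with a warning); P2 is the exact
  Euclidean simplex projection by iterated hyperplane projection, which
  terminates in ≤ K passes and matches the closed-form sorting algorithm
  to 1e-12. Ties are resolved identically for equal coordinates by
  construction.
* **Degenerate clusters**: a cluster whose aggregated mass μ̂_k reaches 0
  raises immediately (`DegenerateClusterError`) instead of being dropped;
  in practice this is the signal that the learning rate is too large. A
  >10× objective jump in a single step raises `DivergenceError` (with an
  absolute floor of 1e-12 so exact-reconstruction fixed points are not
  flagged on numerical noise).
* **Exact reconstruction**: with K = N and identity membership, J
  evaluates to ≤ 1e-25 rather than bitwise 0 — the aggregation divides
  and re-multiplies by μ, leaving rounding at the 1e-17 per-entry level.

## Initialization

The optimizer starts from a hard partition produced by alternating
minimization of the same J restricted to indicator memberships: (i) the
reduced chain is recomputed by aggregation; (ii) every node moves to the
cluster whose lifted row is closest to the node's own transition row in
the 1/μ-weighted norm, with μ_x weighting the node's contribution. Both
half-steps are exact minimizations, so J never increases between sweeps.
Clusters emptied by a sweep are repaired by moving in the worst-fitting
node. The best of 8 seeded random restarts is kept; with the seed fixed
the initialization is deterministic. On the karate club this
initialization already finds the basin whose fuzzy refinement yields the
published memberships; pure hard partitioning, however, misplaces member
10, which only the fuzzy refinement corrects.

## Synthetic benchmark

The planted-partition generator emulates the classic 128-node "ad hoc"
benchmark: K = 4 equal clusters of 32, expected degree 16, independent
Bernoulli edges with p_in = z_in/31 and p_out = z_out/96 where
z_in + z_out = 16. The default mixing is z_out = 2. Nodes that come out
isolated have their incident pairs re-drawn, which perturbs the degree
distribution negligibly. The generator produces Bernoulli (binomial-degree)
graphs only: no degree heterogeneity, no weights, no overlapping planted
clusters — so passing tests demonstrate recovery under the benchmark's
idealized conditions, not on heavy-tailed real-world networks.

At z_out = 2 the fitted memberships are nearly hard: most in-cluster
entries converge to 1 exactly (the simplex projection reaches the corner),
the majority rule recovers the planted partition exactly in 20/20 seeded
runs, and the mean/max row-wise l∞ deviation from the degree fractions is
≈ 0.05/0.11. Fuzzier regimes (larger z_out) move the in-cluster membership
peak below 1 at the cost of recovery sharpness.

## Evaluation statistics

* **Degree fraction** e_{x,k}: the fraction of x's edge weight landing in
  reference cluster k; rows sum to 1. A natural soft reference label for
  planted benchmarks, compared against ρ after aligning cluster labels by
  maximum-overlap (Hungarian) assignment.
* **Membership error**: per-node l∞ distance between ρ and e, aggregated
  as mean and max over nodes. The per-node norm is l∞ by convention here;
  with K small the choice barely matters.
* **Majority rule**: argmax per row, ties to the lowest cluster index
  (logged).

## Known limitations

* J is non-convex in (ρ, p̂): different initializations can land in
  different local minima (on the karate club a secondary basin at
  J ≈ 4.057 exists whose hardening equals the faction split directly; the
  k-means initialization avoids it). Multiple restarts of the
  initialization mitigate but do not eliminate this.
* The number of clusters K is a user input; no model selection is
  provided.
* Dense N×N linear algebra throughout: comfortable to a few thousand
  nodes, not engineered for very large sparse graphs.
* Directed, bipartite, and disconnected networks are out of scope
  (isolated nodes are a hard error; z_out = 0 benchmarks warn about
  disconnected blocks).
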