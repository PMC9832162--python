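# Methods

This note documents the models implemented in `epilayers`, the assumptions
behind them, the numerical choices, and what the validation suite does and
does not establish.

## Network description

A population is described statistically: `n` contact layers, each with a
degree distribution `P_i(k)` and either a whole-period transmissibility
`T_i ∈ [0,1]` (percolation framework) or a transmission rate `β_i` together
with a common recovery rate `γ` (dynamic framework, where `β_i/γ` plays the
role of a transmissibility and may exceed 1). Layers are assumed
independent: the joint degree pmf is the product of the marginals, so the
joint pgf factorises, `G(x) = Π_i G_i(x_i)`. Degree correlations between
layers, clustering, directed edges and degree-assortativity are all outside
the model.

### Degree distributions and truncation

Each layer is stored as a finite pmf over `0..K`, with `K` the smallest
degree at which the neglected tail mass falls below `tail_tol`
(default `1e-10`). This single knob controls the error of every downstream
truncated sum; closed forms (regular, Poisson, geometric) are used for pgf
values and first two derivatives and are cross-checked against the
truncated polynomials in the tests. Derivative support is capped at order
two; where a second derivative of an *excess* pgf is needed (the
near-critical expansion) it is computed as the second factorial moment of
the excess pmf rather than a third derivative of `G`.

The power-law family takes a hard cutoff `kmax` (renormalised
`k^-alpha` on `kmin..kmax`). A pure zeta tail at `tail_tol = 1e-10` would
truncate near `K ~ 1e6` for exponents around 2.5, which is unusable for
joint product grids; a hard cutoff is also the standard finite-network
convention.

Generating-function evaluations normalise by the same closed-form `G_i'(1)`
used in their numerators, so the all-ones point maps to exactly 1
regardless of truncation error — without this, downstream fixed-point
iterations can step infinitesimally outside `[0,1]^n`.

## Reproduction matrices

The threshold object is the `n×n` matrix `R_ij = T_j ∂G̃_i/∂x_j` at the
all-ones point: entry (i, j) is the expected number of onward layer-`j`
transmissions by a vertex that was itself reached along a layer-`i` edge.
**Orientation:** rows index the arrival layer, columns the onward layer.
The transposed convention appears in parts of the literature; all spectral
output (radius, threshold, growth rates) is invariant under transposition,
and the API documents the convention. Row sums give the per-layer
reproduction numbers `R₀(i)`, and `R₀` is their mean-degree-weighted
average.

The `H̃` kernel weights each term by the initial susceptibility of the
reached vertex and carries one extra factor `x_i`; with susceptibility
identically 1 it reduces to `x_i G̃_i`, so its matrix is `diag(T) + R^G̃`
(asserted to 1e-12 in the tests).

## Percolation solver

The fixed point `q_i = 1 − T_i + T_i G̃_i(q)` is solved by iteration from
`q = 0`. The map is componentwise monotone and maps the unit box into
itself, so iterates increase to the **least** fixed point — a deterministic,
derivative-free branch choice. "No outbreak" is declared when
`‖q − 1‖_∞ < 1e-8`. Default stopping tolerance is a sup-norm residual below
`1e-12` with a cap of `1e5` iterations; near criticality convergence is
linear with rate approaching 1, which the cap accommodates for the
parameter offsets used here (≥ 1e-3 from threshold). An optional relaxation
factor halves the step if the residual ever grows.

Transitions are located numerically: the spectral radius of `R^G̃` is
evaluated on a parameter grid and a sign change of `λ − 1` is bisected
(Brent) to `bracket_tol` (default 1e-6). No symbolic bifurcation analysis
is attempted; the eigenvalue criterion is the implemented test. The
near-critical expansion `1 − P ≈ c (T − T_c)` with
`c = 2 G'(1) / (G̃''(1) T_c²)` is provided for single-layer networks only,
where the scalar argument applies.

## Vertex-level SIR

The 3N-dimensional system is integrated as 2N equations (`r` eliminated by
the exact per-vertex conservation `s + x + r = 1`), with RK45 (the system
is non-stiff and this avoids dense Jacobian work at large N), `rtol = 1e-8`
/ `atol = 1e-10` defaults, and an early-stop event when total infection
mass falls below 1e-10. The mixed quantity
`H(v) = s_v exp((1/γ) Σ_i β_i Σ_{w~v,i} r_w)` is conserved along exact
trajectories; its drift is reported as an integration diagnostic and
asserted below 1e-6 at tight tolerances for vertices starting with
`r_v = 0` (where its normalisation is meaningful).

The final-size system `r_v = 1 − s_v(0) exp(−Σ_i (β_i/γ)(A_i r)_v)` is
solved by monotone iteration from `r = 1 − s_v(0)`, the initially
non-susceptible mass, so a seeded initial condition reaches the nontrivial
root. With `s0 ≡ 1` exactly, that start *is* the trivial root; an explicit
`interior_eps` start recovers the nontrivial branch where it exists. The
default ODE seeding is `x_v(0) = 1e-5` per vertex with `r_v(0) = 0` —
small enough not to perturb final sizes, large enough to keep integration
times short.

## Degree-based mean field

The reduced system is integrated in `w` coordinates
(`dw_i/dt = γ(1 − w_i − H̃_i(u))`, `u_i = e^{−β_i w_i/γ}`), not in `u`,
avoiding the logarithmic singularity at `u → 0⁺`; `u` and the edge-infected
fractions `v` are derived. Equilibria solve `w = 1 − H̃(u(w))` by monotone
iteration from 0; when the population starts fully susceptible and the
`H̃`-kernel matrix is supercritical the iteration restarts from `1e-6` to
climb to the nontrivial least fixed point (for a single layer the map is
increasing and concave, so that root is unique). Early growth is the
linearisation `γ^{-1} dw/dt = (1 − E[s(0)|layer]) + (R^H̃ − I) w`, solved
mode by mode; the Jacobian is always derived from the `w`-system directly.

The reduction from the joint-degree hierarchy to `n` equations is
algebraically exact given `w(0) = 0`; the test suite integrates both on a
truncated grid and checks agreement to 1e-6. Degree-class compartments are
reconstructed from `w` (closed-form `s_k`; `x_k` by integrating its scalar
balance driven by `w`, a strictly one-way coupling re-integrated jointly so
no interpolation error enters). The reconstruction grid is capped at 1e5
cells. Convergence of the reduced flow is proven by phase-plane arguments
only for `n ≤ 2`; for `n ≥ 3` it is monitored numerically, not assumed.

## Stochastic validation and its limits

The configuration-model sampler draws i.i.d. degrees per layer (one vertex
redrawn to fix stub parity), matches stubs uniformly, retries on
self-loops/multi-edges and finally erases offending pairs with a warning —
an `O(1/N)` perturbation of the degree distribution. Bond percolation opens
layer-`i` edges with probability `T_i` and measures reachability; on graphs
with ≤ 20 edges an exhaustive enumeration over all `2^E` states provides
exact values against which Monte Carlo is checked (3-SE criterion). The
Gillespie simulator is exact event-driven SIR.

Two conventions deliberately coexist: the percolation/ODE frameworks use
the whole-period transmissibility `T = β/γ`, while an exponential-duration
infectious period transmits across an isolated edge with probability
`β/(β+γ)`. These agree only to first order in `β/γ`. Cross-model
comparisons therefore either match per-edge probabilities exactly
(percolation vs bond-percolation simulation, same `T`) or run both models
at identical `(β, γ)` in a regime of small per-edge transmissibility and
moderate degrees where the gap is second-order. The scale comparisons use
two-layer Poisson ensembles at `R₀ = 2` — means (30, 15) at
`β = (0.04, 0.04)`, `γ = 1` on 500 vertices for the vertex ODE, and means
(25, 5) at `β = (0.06, 0.1)`, `γ = 1` on 10⁴ vertices for the reduced mean
field — sizes chosen so each stochastic comparison completes in seconds
while keeping sampling error well below the 5-percentage-point agreement
band. Stochastic comparisons condition on outbreaks (final size > 5%),
since the deterministic models have no extinction channel.

What passing these tests shows: the solvers agree with closed forms and
exhaustive enumeration where those exist, and the mean-field predictions
track exact stochastic simulation on large locally tree-like graphs in the
matched-transmissibility regime. What they do not show: accuracy on real
contact networks, which have clustering, degree correlations and community
structure that both frameworks ignore by construction, or on small/dense
graphs where the independence closure fails.

## Known limitations

- Mean-field exactness on finite graphs is not claimed anywhere; the
  ensemble-level comparisons use loose (±0.05) bands deliberately.
- The `β/γ` vs `β/(β+γ)` mismatch is inherent when comparing the ODE
  closure with event-driven simulation and is documented rather than
  resolved.
- Phase transitions are detected numerically (eigenvalue crossing +
  fixed-point behaviour), not proven.
- Power-law layers require an explicit cutoff; heavy tails with diverging
  second moments are outside the supported regime.
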