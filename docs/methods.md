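# Methods

## Model and assumptions

`costrain` implements an SIS system for N strains with co-colonization.
The 1 + N + N² compartments are susceptibles S, singly colonized I_i and
co-colonized I_ij (ordered by acquisition; same-strain double carriage
I_ii is a real compartment). Assumptions baked into the equations:

- equal transmission β and clearance γ for all strains and for single vs
  double carriage (strain-transcending clearance, no immunity);
- recruitment of susceptibles equals mortality (r = d), so the host
  population is closed and the compartments stay on the unit simplex;
- a co-colonized host transmits each of its two strains at half the total
  rate, so the fraction transmitting strain i is
  J_i = I_i + ½ Σ_j (I_ij + I_ji) and the force of infection is F_i = β J_i;
- strain identity enters only through K_ij, the factor by which current
  carriage of i rescales acquisition of co-colonizer j. Rows of K index
  the resident/colonizer, columns the incoming co-colonizer; K must be
  entrywise non-negative and finite.

Two-strain MOI is the cap: triple colonization, per-strain trait
differences in β or γ, host structure, and stochasticity are out of scope.

## Similarity decomposition

K_ij = k + ε α_ij with k = mean(K), ε = rms(K − k), A = (K − k)/ε. This
reference is non-unique; `decompose_interactions` accepts a user k and
recomputes ε against it. With the mean reference, mean(A) = 0 and
‖A‖_F = N hold identically (tested to 1e−10). A constant matrix has ε = 0:
A is set to zero by convention, the invasion matrix is zero and
frequencies freeze; the code never divides by ε.

## Fast timescale: the neutral model

At ε = 0 the aggregates close on themselves. For R0 = β/m > 1:
S* = 1/R0, T* = 1 − 1/R0, I* = m T*/(m + β k T*), D* = T* − I*,
μ = I*/D* = 1/(k (R0 − 1)). Single prevalence relaxes in closed form,
I(t) = I* + e^{−t(m+βkT*)}(I(0) − I*). The per-strain pair (I_i, J_i)
obeys a linear system with matrix

    A0 = [ −(m + β k T*)   m        ]
         [ −β k T* / 2     β k I*/2 ]

whose eigenvalues are 0 (the conserved frequency direction, eigenvector
∝ (I*, T*)) and tr(A0) = −ξ. We expose ξ = (m + βkT*) − βkI*/2 explicitly
since the fast decay rate sets the post-transient window (default 5/ξ)
used by the diagnostics. **Sign note:** some renderings of A0 show the
(2,1) entry with a positive sign; linearizing the aggregated equations at
I = I* gives −βkT*/2, and only that sign makes A0 singular as required by
frequency conservation. The implementation uses the negative sign and the
test suite pins det(A0) = 0 across random parameters.

The fast coordinates invert the basis [[2T*, I*], [D*, T*]]:
H_i ∝ I_i/I* − J_i/T* decays at rate ξ; z_i is conserved. After the fast
transient the three candidate frequency definitions J_i/T, I_i/I, D_i/D
coincide; the package uses J_i/T as the measured frequency of a full
trajectory because it is the best conditioned (T is the largest aggregate).
D_i is read symmetrically, D_i = ½ Σ_{j≠i}(I_ij + I_ji) + I_ii, so that
Σ D_i = D.

## Slow timescale: replicator dynamics

On τ = εt the frequencies obey dz_i/dτ = Θ z_i((Λz)_i − zᵀΛz) with
λ_i^j = α_ji − α_jj + μ(α_ji − α_ij) and
Θ = βT*I*D*/(2T*² − I*D*) = β(1 − 1/R0) μ/(2(μ+1)² − μ); both forms are
computed and cross-asserted. Three algebraically equivalent right-hand
sides (deviation form with q(z) = zᵀAz, payoff form with
M = μ(Aᵀ − A) + Aᵀ, invasion-fitness form with Λ) are exposed and tested
to 1e−12 agreement; the equivalence rests on the antisymmetric part
vanishing in the quadratic form. Θ defaults to its mechanistic value but
may be overridden (Θ = 1) for phase-portrait work, since it only rescales
time.

One published correspondence table lists the invasion matrix of an
antisymmetric-K structure as λ_i^j = 2μ α_ji; direct substitution of
α_ij = −α_ji, α_ii = 0 into the λ formula gives (2μ + 1) α_ji. We follow
the formula (the extra α_ji term comes from the resident-facilitation
part); the qualitative claim — Λ antisymmetric — is unaffected and is what
the structure classifier asserts.

## Numerical choices

- Full system: `scipy.integrate.solve_ivp` with LSODA, rtol 1e−8 /
  atol 1e−10 defaults (mildly stiff near the fast transient); state vector
  [S, I_1..I_N, I_11, ..., I_NN] row-major, stable across versions.
  Negative undershoots are clamped to zero on output only, never inside
  the RHS, and counted on the trajectory object. Host conservation is
  monitored to 1e−6 (warning) and tested to 1e−8.
- Replicator: LSODA with rtol 1e−10 / atol 1e−12. No extinction floor —
  the boundary is absorbing analytically. Output frequencies are
  renormalized when |Σz − 1| > 1e−12 (count recorded; raw drift kept as
  `max_sum_drift`, and `renormalize=False` returns the untouched solver
  output for conservation measurements).
- Initial conditions for full-vs-reduced comparisons are placed on the
  slow manifold (S = S*, I_i = I* z0_i, I_ij = D* z0_i z0_j); the
  reduction approximates slow dynamics only, so off-manifold starts are
  compared after the transient window.
- Edge classification treats |λ| ≤ tol as "marginal" rather than forcing
  the four-outcome taxonomy, which assumes λ_1²λ_2¹ ≠ 0.
- Structure classification uses relative Frobenius deviations with
  tolerance 1e−9 for the exact classes and 0.1 for almost-antisymmetric
  (no published value exists; both are user-settable). The ensemble
  generator's almost-antisymmetric perturbation defaults to 0.04 so that
  its relative deviation (≈ 2× the perturbation) lands inside that band.
- Invader/resident-driven constancy is measured on off-diagonal entries
  only: the zero diagonal is structural.

## Synthetic data

Random interaction matrices are i.i.d. Normal(k, ε) — the stated regime
for the random-matrix experiments is mean k = 1, standard deviation
ε = 0.1, which the generator adopts as defaults; the distribution family
is not specified anywhere, so normal is a documented choice. Draws below
zero are clipped with a warning, which shifts sample moments — realized
(k̂, ε̂) should always be taken from the decomposition, and all reported
quantities here do so. Canonical-ensemble Λ matrices use uniform entries
in [−1, 1] with zero diagonal, 30 replicates by default, and flat-Dirichlet
simplex starts (the start distribution is likewise unstated; flat is the
maximum-entropy choice).

What a green test establishes: the analytic identities, the reduction's
O(ε) accuracy and its ε-scaling on these synthetic worlds. What it does
not: realism of any particular K for a biological system — K is an input,
never inferred from data here — nor behaviour under unequal strain traits,
demographic noise or contact structure, all excluded by construction.

## Validation diagnostics

`approximation_error` integrates the full system and the reduced pipeline
from the same slow-manifold start and reports the sup-norm over time of
max_i |z_i^full − z_i^reduced| (plus the same norm over raw compartments
against the reconstruction). Over a descending ε ladder with the same A,
the error decreases monotonically; runs at ε = 0.3 stay bounded. No
convergence order is fitted — only monotonicity and boundedness are
claimed or tested.

`quasi_neutrality_test` reports, per time point, max_i |I_i/I − J_i/T|
and the product-law residual max_ij |I_ij − kR0[1 + k(R0−1)] I_i I_j|
normalized by D/N². Both are O(ε) post-transient; the prefactor identity
kR0[1 + k(R0−1)] = D*/I*² is exact and tested to 1e−10.

## Known limitations

- The replicator reduction says nothing about the fast transient of an
  off-manifold start; reconstruction holds S and T frozen at (S*, T*).
- For ε ≳ 0.3 the reduction degrades gracefully but no error bound is
  provided.
- Long-horizon attractors for N > 2 (limit cycles, heteroclinic networks,
  chaos) are recorded as trajectories, not detected or classified.
- The structure classifier reports the nearest canonical class; a matrix
  can be close to several — inspect the per-class deviations it returns.
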