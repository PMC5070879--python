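# Methods

## Signal model

Each voxel's diffusion-weighted signal is modelled as a three-compartment
mixture: two rank-2 Gaussian diffusion tensors (the crossing fiber
bundles) and an isotropic free-water pool,

    S(θ, j) = S0 Σ_i f_i exp(−b_j g_jᵀ D_i g_j),  i ∈ {1, 2, iso}.

The *estimated* model is constrained for identifiability: both tensors
share the axial diffusivity λ∥; each tensor is axially symmetric
(equal minor eigenvalues λ_{i,⊥}); D_iso is fixed to the body-temperature
free-water value 3.0×10⁻³ mm²/s; and the fractions close to one,
f_iso = 1 − f1 − f2.  Orientations use four angles: Rx(α1)Ry(α2) place
the crossing plane and Rz(α3 ± α4/2) are the in-plane rotations of the
two principal axes, making α4 the crossing angle.  Tensors are composed
as D_i = R_iᵀ E_i R_i with the principal axis on the local x-axis.  The
free parameter vector is

    θ = (λ∥, λ1⊥, λ2⊥, α1, α2, α3, α4, f1, f2),

diffusivities in mm²/s, angles in rad.  S0 is fixed to the mean of the
b = 0 measurements and the Rician noise level σ is a known input (for
real data: supplied directly or derived from a user-provided SNR).

A structural property worth knowing: because the axially symmetric
tensor depends only on its principal axis, and that axis is the first
row of Rx(α1)Ry(α2)Rz(·) — which does not involve α1 — the signal is
*exactly* independent of α1.  α1 matters only for the axially
*asymmetric* ground truths used in simulation.  Consequently the 9×9
Fisher matrix always has an α1 null direction; the prior's
regularization absorbs it, and `crlb_sd` reports NaN for α1 rather than
a meaningless bound.

## Likelihood

Magnitude MR data are Rician: p(s|ν,σ) = s/σ² exp(−(s²+ν²)/2σ²) I0(sν/σ²).
Measurements are independent across gradients, so the voxel
log-likelihood is the sum of per-measurement log densities, evaluated
with the exponentially scaled Bessel I0 (no overflow at any SNR).  The
b = 0 measurements are included — they are part of the measured profile
and constrain S0's consistency.  A measured intensity of exactly zero
has zero density; it maps to a large negative sentinel (−1e30) so
optimizers and acceptance ratios stay defined.

## Maximum likelihood

The MLE runs a quasi-Newton (L-BFGS) optimizer with the analytic
gradient (signal Jacobian chained through the Rician score) on an
unconstrained reparameterization: log-diffusivities, stick-breaking
fractions (t1 = σ(v8), f1 = t1, f2 = (1−t1)σ(v9)), raw angles.
Initialization is a log-linear single-tensor fit whose principal
direction and eigenvalues seed a duplicated-tensor start (α4 = 0.5 rad,
f1 = f2 = 0.4, f_iso = 0.2).  Because the likelihood is multimodal in
orientation, the fit is multi-start (default 5): the plain start, α3
rotated by π/4 and π/2, and two seeded jitters; the best likelihood
wins.  Non-convergence of every restart is reported with a warning,
never silently.

At true single-fiber configurations the dual-tensor likelihood is
degenerate along the exchange of volume fraction between two coinciding
tensors, and its actual maxima are overfit modes (a near-collapsed
split, or a moderate split with the second tensor absorbing noise and
the mild axial asymmetry of the simulated ground truth — 2–12 log-units
above the generating configuration, the expected magnitude for nine
fitted parameters).  A converged maximizer therefore does *not* produce
fraction estimates hovering near a balanced split; reports of that
behavior characterize incompletely converged optimizers on the flat
exchange ridge (we verified the ridge is flat to <1 log-unit).  This
package reports the converged optimum.

## Fisher-determinant (ARD) prior

For Rice-distributed data the expected information one measurement
carries about its noise-free intensity ν is Z(ν/σ)/σ², with Z the
expectation of the squared score.  Z(0) = 0, Z → 1 in the Gaussian
limit; it is precomputed by Gauss–Legendre quadrature on a dense SNR
grid (relative interpolation error < 1e-4 for v ≥ 0.01; the series limit
Z = v² covers smaller v).  The 9×9 expected information of the model is

    I(θ) = Jᵀ diag(Z(S_j/σ)/σ²) J,

with J the analytic Jacobian of the signal model.  The working prior is

    p(θ) ∝ det I(θ)^(−1/2),

evaluated in log space with a regularizer: the matrix is first
non-dimensionalized by the natural parameter scales (10⁻³ mm²/s for
diffusivities, 1 for angles and fractions) and then jittered by
1e-10 × mean(scaled diagonal) × Identity.  Scaling shifts log det by a
constant (irrelevant in Metropolis ratios) but is essential for the
regularizer itself: in raw units the diffusivity rows are ~10⁶-fold
larger, and a jitter set by them floods exactly the small eigenvalues
that encode whether a compartment is supported.  A Gaussian-information
variant (Z ≡ 1), the classical Jeffreys sign (det^{+1/2}) and the
Behrens fraction prior f⁻¹(1−f)⁻¹ are available as options for
comparison.

The prior is flat where a two-tensor model is identifiable (central
volume fractions, wide crossing angles) and rises steeply as f1 → 0 or
f2 → 0 (bathtub over the fraction simplex) and as α4 → 0 with equal
fractions (several log-units from 90° to below 10°).  One published
qualitative feature did not reproduce: the claim that at lower SNR the
α4-ramp begins at a larger angle.  The determinant's *scale* does drop
at lower SNR (σ^{-18} globally), but its normalized shape is exactly
σ-independent under Gaussian information and shifts by only ~0.4° (in
the opposite direction) with the exact Rician factor.  The
corresponding check is kept, and fails, in the acceptance suite.

## Sampler

Random-walk Metropolis–Hastings on the 9 natural parameters with fixed
per-parameter steps: 10⁻⁵ mm²/s (diffusivities), 10⁻² rad (angles),
10⁻² (fractions).  Proposals outside the domain — non-positive
diffusivities, fractions outside the ε-interior of the simplex
(ε = 10⁻⁶) — are rejected outright, preserving the symmetric kernel.
All posterior arithmetic is in log space.  Angles are not wrapped.

Chain length is counted in **accepted transitions**: burn-in ends after
2000 acceptances, the retention window closes at 5000 acceptances, and
the estimate is the arithmetic mean of *all* states inside the window
(rejections repeat the previous state, as the Metropolis estimator
requires).  Total proposals are capped at 4× the nominal length; chains
whose acceptance stalls before the window opens (typically chains
already sitting in the collapsed mode, where the prior wall rejects
almost everything) fall back to the mean over the second half of their
run.  A proposal-counting mode (`count="proposals"`: exactly N proposals,
mean over steps 2000..4999) is available; at the acceptance rates this
posterior produces (0.05–0.4) it shortens the effective chain by 3–10×
and leaves a substantial fraction of single-fiber chains un-collapsed
within the budget.  The accepted-counting convention reproduces the
reference Monte Carlo statistics and is the default.

Reproducibility: voxel k draws from its own generator seeded
`seed + k`, consuming nine normals then one uniform per step, so
vectorized multi-voxel runs are bit-identical to sequential single-voxel
runs and independent of batching or worker count.

## Synthetic data

`make_scheme` builds the canonical acquisition: 92 directions spread by
electrostatic-repulsion minimization (L-BFGS on the Coulomb energy from
a Fibonacci-sphere start, deterministic), reused on both shells
(b = 1000 and 3000 s/mm²), plus two b = 0 measurements — 186 in total.
Noise is Rician by construction (|S + n₁ + i·n₂|, n ~ N(0, σ²)); the
default SNR is 25 (S0 = 250, σ = 10).

The canonical crossing ground truth deliberately violates the fitted
model's constraints, as a mild model misfit: tensor 1 has eigenvalues
(1.48, 0.15, 0.12)×10⁻³ mm²/s (FA 0.90), tensor 2
(1.40, 0.40, 0.38)×10⁻³ (FA 0.67) — unequal axial diffusivities and
axially asymmetric perpendicular pairs.  The in-plane mean orientation
is α3 = 0.8π; the plane angles α1, α2 are redrawn uniformly from
[0, π) per realization; f_iso = 0.1.  Single-fiber sweeps hold
λ∥ = 1.48×10⁻³ and solve λ⊥ for a target FA
(FA = (λ∥−λ⊥)/√(λ∥²+2λ⊥²)), with f1 = 0.9, f2 = 0, f_iso = 0.1.

What the simulator does *not* emulate: spatial structure (each voxel is
independent), partial-volume gradients, eddy/motion artifacts,
multi-coil noncentral-χ noise, non-Gaussian (restricted) diffusion at
high b.  Passing tests therefore validate estimator behavior under the
model-plus-Rician-noise regime, not robustness to acquisition artifacts.

## Experiments and matching

Sweeps simulate n realizations per configuration (default 100; the test
suite uses 25 with correspondingly wider three-standard-error
tolerances), fit each by MLE, run the sampler from the MLE, and match
estimated to generating compartments by Frobenius similarity.  Matching
compares the *fraction-weighted* tensors f_i·D_i over both label
permutations: a compartment suppressed to f ≈ 0 contributes nothing to
the signal, so its tensor shape — which random-walks freely once the
likelihood no longer sees it — must not influence the assignment.
Shape-only matching is used when fractions are not supplied.
`front_evolution` propagates consistent compartment labels across a
voxel grid (breadth-first, 6-connectivity, lexicographic tie-break) for
map-level displays.

Problem sizes: the acceptance script runs 100 realizations per
configuration (one 45° crossing at true f1 = 0; single fibers at
FA = 0.95 and 0.3), about 10–15 minutes on one core; the pytest suite
runs the same pipelines at 25 realizations in a few minutes.

## Known limitations

* The det^(−1/2) prior rewards *any* degeneracy of the information
  matrix, not only vanished fractions: two tensors with coinciding
  shapes and orientations are exchange-degenerate at any fraction
  split, so that coalesced ridge is also prior-elevated.  On
  single-fiber data a long chain can therefore mix between the
  fraction-collapsed representation (f2 ≈ 0) and coalesced splits of
  the same fiber; voxel-level quantities (dominant-tensor FA, total
  anisotropic fraction) are stable across the two, but a fraction split
  between near-identical tensors is not individually meaningful.
* The MLE baseline is this package's own design (the published procedure
  is under-specified); its fraction statistics at degenerate
  configurations are optimizer-dependent, and the acceptance suite's
  balanced-split expectation for it fails honestly (see above).
* Only the mean over the retention window is reported; no convergence
  diagnostics beyond the acceptance rate and trace export.
* Two anisotropic compartments at most; no three-way crossings, no
  rank-1 (stick) compartments, no voxelwise σ estimation.
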