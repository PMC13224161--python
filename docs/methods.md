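# Methods

This note records the model, the dynamics, the sampling algorithms and the
numerical choices behind `natps`, together with what the test suite does and
does not establish.

## Model

The system is a single nuclear coordinate `q` (mass 1836.15 me, the mass of a
hydrogen atom) on two electronically coupled diabatic states,

    H(q) = [[ eps (q - x0)^2 / x0^2 ,  Vc ],
            [ Vc ,  eps (q + x0)^2 / x0^2 ]]

with defaults eps = 0.05 Ha, x0 = 1 bohr, Vc = 0.2 eps = 0.01 Ha.  All
quantities are atomic units; the only unit-bridging constant is
k_B = 3.166811563e-6 Ha/K.  The adiabatic surfaces are `Vbar(q) +- Vz(q)`
with `Vbar = (H11 + H22)/2` and `Vz = sqrt(((H11 - H22)/2)^2 + Vc^2)`; the
avoided crossing sits at q = 0 with minimum gap 2 Vc.  The barrier on the
lower adiabat relative to the diabatic well bottoms is

    Ea = (1 - Vc/eps) eps = 0.04 Ha,

which equals k_B T at T ~ 12.6 kK.  Two caveats worth recording:

* With the CODATA k_B above, Ea/k_B = 12,631.0 K; the commonly quoted figure
  of 12,632 K differs by 1 K at the printed precision.
* `Ea` references the diabatic well-bottom energy (zero).  The true minimum
  of the lower adiabat lies `Vc^2/(4 eps)` *below* zero (at
  `q^2 = x0^2 (1 - Vc^2/4eps^2)`), so the true well depth exceeds `Ea` by a
  relative `Vc^2 / (4 eps (eps - Vc))` — 1.25% at the default coupling, and
  below 1e-4 only for Vc < ~0.02 eps.  `barrier_height` implements the
  closed-form `Ea`; the residual is asserted exactly in the tests.

The eigenvector gauge is fixed globally by the mixing angle
`theta(q) = atan2(H12, (H11 - H22)/2) / 2`, which is smooth wherever the gap
is finite and `H12 > 0` (always, here).  The nonadiabatic coupling is
`d(q) = d theta/d q`, sharply peaked at the seam with width ~ `Vc x0 / 2 eps`
and total integral pi/2.

## Electronic state and propagation

The two-level wavefunction is stored as the adiabatic coefficient pair
`c = (c-, c+)`; the Bloch vector `S = (2 Re c+* c-, 2 Im c+* c-,
|c+|^2 - |c-|^2)` is derived on demand.  The active surface is `sign(Sz)`
with the measure-zero tie `Sz = 0` resolved to the lower state, identically
in both time directions.

Propagation over a nuclear step uses local diabatization: rotate into the
diabatic frame at the start geometry, integrate `i d/dt d = H(q(t)) d` with
a fourth-order Magnus propagator (two-point Gauss quadrature of `H`, exact
2x2 exponential via the Pauli decomposition) over `n_sub` substeps along a
linear-in-time path between the step endpoints, rotate back at the end
geometry.  Properties that follow by construction:

* exact unitarity (norm and spin-length drift are at machine precision);
* exact time-reversal symmetry: because the diabatic Hamiltonian is real
  symmetric, the reversed-path propagator equals the transpose of the
  forward one, which is precisely the conjugation symmetry `c -> c*`;
* fourth-order accuracy: at the production step `dt = 5 a.t.u.` the
  amplitude error per step against a brute-force integration of the
  adiabatic-frame Schroedinger equation (with derivative coupling, same
  path) is ~3e-8 at `n_sub = 2` and ~1e-10 at the default `n_sub = 8`.

The linear intra-step path is the same second-order-consistent choice the
velocity-Verlet nuclear update makes; the implied constant intra-step
velocity carries the entire derivative coupling, so the propagator needs no
separate momentum argument.

## MASH integration step

A step from a grid point is: (1) a trial velocity-Verlet update on the
active surface with concurrent electronic propagation; (2) if the trial ends
with `Sz` on the opposite hemisphere, Brent root search on the
sub-propagated `Sz(tau)` locates the crossing time to `xtol = 1e-10 a.t.u.`;
(3) the system is advanced exactly to the crossing, the hop is executed
there, and the remainder of the step is integrated on the resulting
surface.  Hop rules at the crossing (`Vz* = Vz(q*)`):

* down (upper -> lower): always allowed, `p'^2 = p^2 + 4 m Vz*`, sign of p
  preserved;
* up (lower -> upper): allowed iff the kinetic energy along the coupling
  direction (in 1D the full kinetic energy) is at least the gap `2 Vz*`;
  then `p'^2 = p^2 - 4 m Vz*`;
* frustrated up: the momentum component along the coupling is reversed
  (1D: `p -> -p`), the surface does not change, the electronic state is
  untouched.  Reversing the velocity flips the sign of `dSz/dt` (which is
  proportional to `v d Sx`), so `Sz` bounces off zero rather than crossing;
  no bookkeeping of a "mismatch" between `Sz` and the active surface is
  ever needed, and the event maps onto itself under time reversal.

At most one hop per step is assumed; a second sign change inside one step
raises an error instructing a smaller `dt`.  At the default `dt = 5` this
occurs about once per few million steps at the hottest conditions studied;
the run-level drivers treat the affected shot/trajectory as failed (shot
rejected; brute-force trajectory truncated at the event) and continue.

Locating the hop *inside* the step is what makes the composite map exactly
time reversible: each velocity-Verlet piece is self-inverse under momentum
reversal for any sub-step length, the hop maps are mutually inverse under
time reversal, and both time directions find the same crossing because the
trial (hop-free) dynamics crosses `Sz = 0` in both.  A 1000-step round trip
across hops recovers the initial point to ~1e-13; the conventional
end-of-step variant (`mash_step_naive`, kept as a diagnostic) accumulates
errors of order 0.1 on the same test.

### Energy conservation

The hop rescaling conserves the MASH energy `p^2/2m + Vbar + Vz sign(Sz)`
exactly; what remains is ordinary velocity-Verlet truncation, a *bounded
oscillation* of order `(w dt)^2 E / 8` with `w ~ 7.4e-3 a.t.u.^-1` the well
frequency.  Measured maxima over 1e4 steps of a hop-rich trajectory at
E ~ 0.07 Ha: ~1e-4 Ha at dt = 5, ~3e-6 at dt = 1, <1e-6 at dt = 0.5.  The
conservation tests therefore assert the 1e-6 bound at dt = 0.5 and the
~1e-4 scale at the production step; a tighter bound at dt = 5 would demand
a different integrator family, not different bookkeeping.

## Stationary distribution and brute force

The canonical density factorizes into Maxwell-Boltzmann momenta, a joint
`(q, hemisphere)` weight `exp(-beta(Vbar + s Vz))`, and a spin uniform on
the selected hemisphere (flat `Sz`, flat azimuth).  Positions are drawn by
tabulated inverse CDF on a 2^14-point grid covering everything within
30 k_B T of the lower-surface minimum (truncated tail mass ~1e-13).

Brute-force reference data are NVE trajectories started from fresh draws of
this distribution; reactive segments are all maximal stretches running from
the last point inside one basin to the first point inside the other with no
interior basin contact.  Basins are lower-adiabat configurations with
`q < -0.8` (A) and `q > 0.8` (B).  Two estimator choices matter for the
efficiency ratio (total steps / segments):

* trajectory length: segments-per-step converges once trajectories are much
  longer than the well recurrence time (~850 a.t.u. ~ 170 steps); the
  acceptance runs use 4,000-step trajectories, long enough for convergence
  but short enough that a minutes-scale budget spans O(100) independent
  energy draws (the dominant noise source, since one supercritical draw
  produces many correlated segments);
* stopping rule: budgets are fixed in advance.  Stopping "as soon as enough
  segments are found" ends preferentially right after productive draws and
  was measured to bias the ratio low by tens of percent.

## Transition path sampling

Shooting move: pick a point uniformly on the current path, perturb its
velocity by `v' = alpha v + sqrt(1 - alpha^2) dv` (`alpha = 0.9`, `dv`
Maxwell-Boltzmann at the run temperature; the kernel preserves the thermal
velocity distribution), keep `q` and the coefficients, propagate both time
directions until first basin contact (cap: 4,000 steps per side), and
accept with `h_A h_B min{1, L_old/L_new}` where `L` counts steps.  Because
the dynamics is deterministic, reversible and volume preserving and the
velocity kernel obeys detailed balance, the chain leaves the reactive path
ensemble invariant — verified empirically by the two-sample agreement of
transition times against brute force.

Candidates whose backward side lands in B are stored time-reversed (the
path ensemble is reversal symmetric); a strict-reject convention is
available behind `TPSConfig.reverse_accept=False`.  Interior basin checks
apply at stored grid points.  Rejected moves repeat the previous path in
the chain, and every estimator weights paths by chain multiplicity.  The
first 15% of each chain is marked burn-in and excluded from analysis.

The efficiency ratio for path sampling divides the total integration steps
of all shots (accepted, rejected and uncommitted) by the number of
*accepted* paths.  Per MC sample the same run costs a factor
acceptance-rate less (~0.5); both numbers are reported in run logs.  The
accepted-path convention is the one that stays nearly constant in
temperature (the cost per shot tracks the mean path length, which the
acceptance rate roughly cancels), matching the reference behavior.

Annealing runs chains down a descending temperature ladder, seeding each
chain with the final path of the previous one (reactivity is
temperature-independent, so the inherited seed stays valid).  With
`pilot_paths > 0` a short pilot estimates sigma_tau(T) and scales the
ensemble size as `N(T) ~ sigma_tau^2` to keep `sigma_tau/sqrt(N)` level.

## Analysis conventions

* Transition time: `tau = (steps) * dt` of a reactive path.
* Autocorrelation over MC steps uses the population (1/N) mean/variance so
  `C(0) = 1` exactly; the decorrelation length is the first lag with
  `C <= 1/e` (threshold configurable).
* Hop statistics count non-frustrated hops; frustrated events are tallied
  separately.  Since reactive paths start and end on the lower adiabat,
  successful hops per path are always even.  Independence-assuming
  hypothesis tests must respect two correlation scales: hops within one
  path share its history, and consecutive accepted paths are near-copies
  of their parents (even "distinct" paths).  The tests therefore cluster
  hops by path and thin the chain by its decorrelation length.
* State-resolved path densities are chain-weighted histograms normalized so
  lower + upper occupancy sums to one.

### The hop-angle distribution is not flat

The coherence angle `phi = atan2(Sy, Sx)` at the moment of hopping is
often described as structureless because the hop condition involves only
`Sz`.  That is not quite right: the crossing rate is

    dSz/dt = 2 v d(q) Sx,

which vanishes at `Sx = 0`, so the exact dynamics depopulates angles near
`+-pi/2` — real nodes, not artifacts of the angle definition.  Measured at
high statistics the histogram shows a deep hole near `-pi/2` and a surplus
near `+pi/2`, identically in the shooting ensemble and in unbiased
brute-force dynamics (hence not a reversal-bookkeeping effect).  The
structure obeys the exact invariance of the A->B ensemble under the mirror
(q -> -q, which swaps the diabats and shifts `phi` by pi) composed with
time reversal (`phi -> -phi`), i.e. the distribution is symmetric under
`phi -> pi - phi`, and that reflection symmetry — not flatness — is what
the tests assert as the robust form of the "no phi dependence" picture.  A
chi-square test against strict uniformity rejects at any well-powered
sample size and is retained, failing, as documentation of the tension.

## What the tests do and do not show

The synthetic conditions are exactly the reference conditions: the model above
at 12,000 K (ensemble composition, decorrelation), at `Ea = 3 k_B T`
(efficiency ratios), and along a 30,000 -> 1,000 K ladder (trend checks).
Statistical assertions use reduced but adequate sizes (6,000-move chains,
~500 effective samples, 6e6-step brute-force budgets).  The acceptance
script rebuilds the 12,000 K ensemble as three independent 8,000-move
replica chains and pools them: the chain mixes slowly between the
adiabatic and nonadiabatic path families, so replicas with independent
seed paths bound the composition estimate far better than one long chain;
the same replica pooling is used for the heavy-tailed efficiency-ratio
estimate.  Passing
them shows the integrator, sampler and chain are mutually consistent on
this 1D model; it says nothing about multidimensional systems, real
molecular Hamiltonians (the integrator is written against the general
two-state interface, but only the 1D model is exercised), decoherence
corrections, or rate constants — waiting times in the basins are not
sampled, so no kinetics beyond the path ensemble itself is available.

## Known limitations

* One nuclear dimension in the concrete model; the coupling "direction" is
  the single coordinate axis.
* Double crossings of `Sz` inside one step abort the step rather than being
  resolved recursively (rare at dt = 5; vanishes with smaller dt).
* Velocity-Verlet energy conservation at dt = 5 is ~1e-4 Ha at hop-capable
  energies (see above).
* The brute-force and shooting drivers assume the two-basin topology of the
  double well; multi-basin generalizations would need a different indicator
  structure.
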