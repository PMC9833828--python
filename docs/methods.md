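# Methods

## The model

Cells in a confluent monolayer are described by the area/perimeter energy
H = Σᵢ [λ_A(Aᵢ − A₀)² + λ_P(Pᵢ − P₀)²] with configurations weighted by a
Boltzmann factor at an effective temperature T (k_B = 1). T subsumes thermal
and active fluctuations; the perimeter term encodes cortical contractility
(λ_P Pᵢ²) and effective adhesion (−2λ_P P₀ Pᵢ). Because the cortex dominates
cell shape and the aspect ratio is dimensionless, the area term is treated
as satisfied when deriving shape statistics; the simulator tests this
assumption directly (the time-averaged area-term energy changes by under a
percent when λ_A is quadrupled, and the fitted α is λ_A-independent).

The aspect ratio is r = s₁/s₂ with s₁² ≥ s₂² the eigenvalues of the
gyration tensor; s² = s₁² + s₂² and, for a uniform cell of area A,
s² = A(r + 1/r). The squared gyration radius of a closed-loop boundary
follows P(s²) ∝ s³ e^{−α̃ s²}; the cubic power comes from the double
degeneracy of the lowest nonzero eigenvalue of the periodic connectivity
matrix of the boundary — a geometric fact independent of all model
parameters. The change of variables at fixed area gives

P(r) = (1/N)(r + 1/r)^{3/2}(1 − 1/r²) e^{−α(r + 1/r)},  r ≥ 1, α = α̃A.

The scaled area a = A/Ā follows the unit-mean Gamma law
P(a) = μ^μ/Γ(μ) a^{μ−1}e^{−μa} with μ = ν + 5/2, where ν is the exponent of
the phenomenological confluency constraint f(A) ~ A^ν; ν is system-specific
and recoverable only through a fitted μ.

## Numerics

**Normalization.** Substituting t = r + 1/r collapses the density onto a
truncated Gamma integrand, giving the closed form N = α^{−5/2} Γ(5/2, 2α)
(upper incomplete gamma), equivalently Γ(5/2)/α^{5/2} −
(2^{5/2}/(5/2))·₁F₁(5/2, 7/2, −2α) by Kummer's identity — note the ₁F₁
route loses digits to cancellation at large α. The authoritative value is
nonetheless computed by adaptive quadrature of the scaled integrand
∫₀^∞ (u+2)^{3/2}e^{−αu}du (u = t − 2, rescaled by v = αu so the integrand
is O(1) at any α), with the closed form evaluated as a cross-check; a
warning fires if they disagree beyond 1e−6 relative. All α-dependent
exponentials are handled in log space with the constant e^{−2α} factored
out, keeping every quantity finite for α well beyond 10⁵ (experimental fits
reach α ≈ 12.5).

**Moments and inversion.** E[r^m] uses the substitution r = 1 + x/√α, which
keeps the integrand O(1)-scaled at all α (absolute tolerance 1e−12). The
mean is strictly decreasing in α; `alpha_from_mean` inverts it by Brent
root-finding on log α ∈ [log 10⁻³, log 10⁶], with the attainable-mean
interval bounded explicitly by evaluating the mean at α = 10⁻³. Round-trip
accuracy is better than 1e−6 relative across α ∈ [1, 50].

**Sampling.** The t-substitution also yields an exact CDF,
F(r) = 1 − Γ(5/2, α(r+1/r))/Γ(5/2, 2α), so sampling is exact inverse-CDF
via `gammainccinv` — vectorised and deterministic under a seed — rather
than a tabulated grid. When Γ(5/2, 2α) underflows (α ≳ 300) the CDF and
quantiles fall back to quadrature/bisection on the scaled density. A
rejection sampler (mixture envelope of an exponential and a Gamma(5/2)
component in u = t − 2) is kept in the test suite as the independent
oracle; agreement is checked by two-sample KS.

**Universal curve.** The sd–r̄ table is built on 50 α values derived from
evenly spaced means spanning r̄ ∈ [1.2, 2.0] (the experimentally relevant
window; the law itself fixes the curve, the window only selects the fitted
segment) and the linear approximation is ordinary least squares on those
points, giving slope 0.710 and intercept −0.747. An α-even grid over the
same window shifts the coefficients by about 0.02; the mean-even grid is
the package default and is what the acceptance script reports.

**k-Gamma limit.** Dropping 1/r against r reduces the algebraic factor to
r^{3/2}, so the scaled distribution limits to a k-Gamma with k = 5/2. The
exponent is derived symbolically (sympy limit of the log-log slope); the
numeric confirmation regresses the de-exponentiated tail on log r over
r ∈ [5, 20] at α = 5, giving 1.489 — the residual 1/r² corrections keep it
slightly below 3/2 at finite r. Fitting the k-Gamma form to the exact
scaled curves by weighted least squares (Poisson-proportional weights
w = 1/p, floored at 10⁻³ of the peak, on a 400-point grid over r_s ∈ (0, 6])
gives k = 2.21 at α = 3.060 and k = 2.68 at α = 12.496: the spread around
5/2 seen across experiments is the predicted signature of near- (not
strict) universality.

## Fitting

`AspectRatioModel` maximises the likelihood by bounded scalar optimisation
on log α ∈ [log 0.05, log 10³]; since the likelihood depends on the data
only through the sufficient statistic mean(r + 1/r), each fit costs a few
dozen normalization evaluations. The mean-inversion estimator is reported
alongside; on well-specified data the two coincide within error. Standard
errors are nonparametric bootstrap (200 seeded resamples by default).
Goodness of fit is the KS distance against the fitted CDF — reported, never
used to reject. Samples identically 1 put the MLE at the α → ∞ boundary and
are flagged, not raised. `ScaledAreaModel` rescales to a = A/mean(A) (making
the estimate exactly scale invariant) and solves the fixed-mean Gamma score
equation log μ − ψ(μ) = −mean(log a). Binned-curve fits (digitised
literature histograms) use weighted least squares as above.

## Morphometry

Pixels are unit squares with centers at integer (row, col); the gyration
tensor about the centroid carries a +1/12 diagonal correction per axis so
single-pixel-wide cells are non-degenerate, and s₁² + s₂² equals the mean
squared pixel distance from the centroid plus 1/6 exactly. Perimeter is the
count of mismatched 4-neighbor bonds attributed to each cell on both sides
of a bond — the same convention the simulator uses, so measured and
simulated perimeters are directly comparable. Cells touching the image
border are flagged and excluded from ensemble statistics by default
(truncation biases r upward); periodic masks wrap cells across the border,
so confluent Voronoi or CPM masks should either be measured with the border
included or consumed through the simulator's own periodic-aware
measurement. Rasterized-ellipse validation: measurement error decreases
with resolution (≈2% at a 20 px semi-major axis, <0.5% at 40 px) and is
rotation-stable within 2% at ≥30 px.

## The simulator

Metropolis dynamics on periodic square (4-neighbor) or hexagonal
(6-neighbor, axial coordinates) lattices. One sweep = rows·cols attempted
moves; an attempt draws uniform random sites until a boundary site (≥1
differing neighbor) is found, proposes the label of a uniformly chosen
differing neighbor, and accepts with min(1, e^{−ΔH/T}). Moves that would
annihilate a cell are rejected, as are moves that would locally disconnect
the source cell (its same-label neighbors on the surrounding ring must form
a single cyclic block) — the theory's regime of interest is compact cells,
for which r is well defined. Label 0 is medium and carries no energy terms
(single-cell mode). Area and perimeter caches are updated incrementally and
verified against full recomputation to 1e−9 after every run; the RNG is
numba's generator, seeded per run for bit-reproducible trajectories.

Because proposals are restricted to boundary sites, detailed balance holds
only approximately — the standard situation for CPM dynamics. On a 2-cell
toy system with exhaustively enumerated states the long-run energy-level
occupancy matches the Boltzmann weights to a total-variation distance of
about 0.06: close enough that the effective-equilibrium description the
theory rests on is self-consistent at our parameters.

Initialization is a nearest-seed Voronoi tessellation under the periodic
metric (cartesian embedding for the hexagonal lattice). Equilibration is
monitored by an energy plateau: the run is flagged if the difference
between the last two quarter-means of the equilibration trace exceeds both
a relative tolerance (default 1%) and three standard errors of the quarter
mean — at desk scale (64 cells) thermal fluctuations of the total energy are
a few percent, so a noise-blind threshold would flag every equilibrated run.

Relaxation times use the self-overlap Q(t) = (1/N)Σᵢ θ(a₀ − |Δrᵢ(t)|)
averaged over time origins, with centroids tracked periodic-aware and
unwrapped between samples; τ solves Q(τ) = 1/e with log-time interpolation.
The overlap length defaults to a₀ = 1 lattice unit. A trajectory that never
decays returns τ = ∞ (frozen) or the largest lag flagged as a lower bound.

## Synthetic data and what passing tests show

The generators emulate the statistical structure the analysis assumes:
`model_samples` draws (r, a) i.i.d. from the analytic laws — the canonical
recovery fixture; `ellipse_grid_mask` rasterizes ellipses of known aspect
ratio (center-inclusion test) as the measurement oracle; `voronoi_mask`
provides confluent periodic label images. None of them reproduce spatial
correlations between neighboring cells, segmentation errors, or cell
division/apoptosis present in real microscopy, so passing recovery tests
demonstrates correctness of the estimators and measurements, not robustness
to real-data artefacts. The simulator closes part of that gap: its cells
are spatially correlated through confluency, and the fitted α and μ still
behave as the theory predicts (α linear in λ_P and 1/T, decreasing in P₀,
independent of λ_A; μ increasing with λ_A, independent of λ_P).

## Problem sizes

Desk-scale defaults chosen for the verification suite: 64 cells of target
area 40 on a 64×40 periodic square lattice, 1500 equilibration and 2000
production sweeps sampled every 10 sweeps (≈13k per-cell shape samples per
run, pooled over configurations). These are the smallest sizes at which the
parameter dependencies above are resolved cleanly against Monte Carlo
noise; the analytic-side checks (quadrature, recovery at n = 10⁵) are
independent of them. Simulated aspect-ratio ensembles at these sizes carry
time correlations between samples, so bootstrap errors from pooled samples
understate run-to-run variability; tests comparing fitted parameters across
runs allow for this.

## Known limitations

* Strict proportionality α ∝ λ_P/T through the origin is not observed at
  desk scale: the fitted α vs λ_P line is strongly linear (R² > 0.99) but
  has a positive offset, consistent with a pixelation floor on measurable
  shape anisotropy for 40-site cells. The linearity, not the zero
  intercept, is what the verification suite asserts.
* The printed closed form for N is retained only as a cross-check; at
  α > 350 it switches to an asymptotic expansion of Γ(5/2, 2α).
* No vertex-model, Voronoi-dynamics or phase-field simulators; no cell
  division or apoptosis; no shape-index distribution; 2D only.
* The relaxation-time definition (self-overlap with a₀ = 1, time origins at
  every sample) is a stated package convention; other overlap lengths
  rescale τ smoothly but monotonicity in α is insensitive to the choice.
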