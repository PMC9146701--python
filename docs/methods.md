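# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical decisions, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Couette flow and the forward solver

The cell is a concentric-cylinder geometry with inner radius 10 mm, outer
radius 11 mm (1 mm gap) and configurable height (default 40 mm; the height
cancels from every fitted quantity as long as torque and stress use the
same value). The inner cylinder rotates, the outer is fixed — standard
strain-controlled rheometer operation. A nominal applied shear rate maps
to rotor rate through the narrow-gap convention Ω = γ̇·(R_o−R_i)/R_i.

The generator solves the inverse problem for a Herschel–Bulkley fluid: for
an imposed Ω it finds, by bracketed Brent iteration, the torque T whose
stress field σ(r) = T/(2π r² H) integrates through the constitutive law to
the rotor rate, Ω = ∫ γ̇(r)/r dr over the sheared band. Where σ(r) < τ₀
the material is arrested; when the yield radius r_y = √(T/(2π H τ₀)) falls
inside the gap the profile shows shear localization — a flowing inner band
and a stationary outer band. Velocities are then ω(r) = ∫ᵣ γ̇/s ds with
adaptive quadrature (the integrand vanishes continuously at r_y, so plain
`quad` handles the endpoint). The returned torque satisfies
σ(R_i)·2πR_i²H = T to machine precision, and the Newtonian special case
matches the analytic Couette profile to ~1e-15 relative.

Profiles are sampled on 21 uniform points (≈50 μm over the 1 mm gap,
matching the imaging resolution of a rheo-MRI velocimetry experiment).
Zero rotation with a yield-stress fluid is degenerate — any torque up to
the yield limit is statically admissible — so the solver returns the limit
2πR_i²Hτ₀ with an explicit `at_yield_limit` flag.

## Shear-rate reconstruction

The local shear rate in azimuthal flow is γ̇(r) = |r·d(v/r)/dr|; forming
v/r first (an exact algebraic identity) leaves one numerical derivative,
which a Savitzky–Golay filter computes with window 7 and polynomial order
1 — the standard smoothing choice for ~20-point rheo-MRI profiles. Rigid
rotation maps to exactly zero shear, unlike the naive |dv/dr|.

Endpoints are not truncated: the first and last three points use one-sided
polynomial fits over the terminal 7 points. These one-sided fits are cubic
(interior order + 2) rather than linear: a one-sided *linear* fit carries an
O(h) curvature bias precisely at the walls, where a Couette profile bends
fastest — measured at up to 4.3% shear-rate error at the inner wall —
whereas the cubic endpoint leaves a worst-case 0.4% stress error across a
(τ₀ ∈ {0…300} Pa) × (n ∈ {0.3…1}) grid of noiseless round trips. The cost
is higher noise amplification in the outer half-window on noisy data.

Points with γ̇ below 0.05 s⁻¹ (configurable) are masked before flow-curve
assembly; this is the velocimetry noise floor, and it also removes the
arrested band of localized profiles. The mask is applied to the *estimated*
shear rate, so an endpoint estimate that overshoots the floor can survive
masking with an inflated relative error — visible as the single >1% point
in extreme shear-thinning round trips.

## Herschel–Bulkley fitting

At fixed flow index n the law σ = τ₀ + K γ̇ⁿ is linear in (τ₀, K) with
non-negativity constraints, so both fitters profile the pair out exactly
with NNLS and reduce the fit to a 1-D search over n ∈ (0.02, 2]: a 45-point
grid scan followed by bounded refinement to xatol 1e-12. This replaces
jittered multi-starts of a 3-parameter solver with something strictly
stronger — the inner problem is solved globally at every n, there are no
start points, ties cannot occur, and the global-n fit trivially satisfies
"joint residual = sum of per-curve fits clamped at the shared n". Noiseless
synthetic curves are recovered to 1e-6 relative or better.

Parameter uncertainties are 1σ values from the Gauss–Newton covariance
(J^T J)⁻¹ scaled by the residual variance, with the analytic Jacobian
(∂σ/∂n = K γ̇ⁿ ln γ̇, taken as 0 at γ̇ = 0).

The single-curve fit of one narrow-gap profile is weakly identified: the
LFC spans only a factor ~2.5 in shear rate, so (τ₀, K, n) trade off and
even noiseless reconstructions return τ₀ a few percent high with n biased
toward 0.5. This is a property of the measurement, not the optimizer, and
it is exactly why the pipeline fits the whole shear-treatment series with
one shared n — the decaying τ₀ᵗ across curves is what pins the index.
Residual bias in the recovered τ₀ series remains a known limitation of
single-rate narrow-gap velocimetry (the series endpoint recovers ~49 Pa
where the generating decay reaches 44 Pa in the default configuration);
the breakdown *rate* kₛ is insensitive to it.

The dimensionless representation divides the viscous stress τ_v = K γ̇ⁿ by
the droplet Laplace-pressure scale: τ̃_v = τ_v R/σ_i against the capillary
number Ca = μ γ̇ R/σ_i. The material constants (interfacial tension σ_i,
continuous-phase viscosity μ, droplet radius R) are user inputs with no
defaults hidden in results — they rescale axes only, so curves generated
with equal (K, n) collapse whatever τ₀ does.

## Structural kinetics

τ₀(t) = (τ₀,₀ − τ₀,ₑ)/(kₛ t + 1) + τ₀,ₑ is fitted by bounded least
squares, parametrised as (τ₀,ₑ, Δτ = τ₀,₀−τ₀,ₑ, kₛ) ≥ 0 so the physical
ordering is a box constraint. Start values: first observation, last
observation, 1/median(t). The fit is unit-agnostic — kₛ is reported in the
inverse of the supplied unit and the JSON record carries the unit name
explicitly, because a 0.012 rate over a 500-minute experiment is only
meaningful as "per minute" and silent conversion would be worse than none.

Two flags guard interpretation: `flat-series` (kₛ unidentifiable; the fit
returns kₛ = 0 with the constant level) and `equilibrium-unreached`
(kₛ·t_max < 0.1: the plateau τ₀,ₑ is an extrapolation, matching shear
treatments that never reach steady viscosity within the observation
window).

At 5% multiplicative noise and 20 time points over 500 min, the median of
recovered kₛ over 50 replicates is unbiased (within ~2% of truth), while
individual replicates scatter with ~25% median absolute error — kₛ trades
off against the decay amplitude. Summary statistics of replicated series
are therefore the quantity to report, and the per-fit 1σ uncertainties
reflect this width honestly.

## Droplet sizing

The single-sphere kernel is the Gaussian-phase-approximation attenuation
for diffusion inside an impermeable sphere, with eigenvalues α_m R given by
the extrema of the spherical Bessel function j₁ (located by sign-change
scanning plus Brent on x J'₃/₂(x) − J₃/₂(x)/2; first root 2.0816, spacing
→ π). The series uses 50 roots by default; a tail estimate (last term ×
n_roots, since terms fall at worst like 1/x²) raises a named error above
2% of the sum. For a(Δ+δ) < 0.1 the numerator switches to its fifth-order
Taylor expansion — the exponentials otherwise cancel catastrophically,
which matters during fits whenever the optimizer explores large radii.
The free-diffusion limit approaches Stejskal–Tanner like √(DΔ)/R
(boundary-layer fraction ~3√(DΔ)/R): 3.4% at R = 50√(DΔ), 1% only beyond
R ≈ 200√(DΔ). The motional-narrowing limit (R ≪ √(Dδ)) returns E → 1.

The droplet-size distribution is volume-weighted lognormal in diameter
with median D₃,₃ (the volume-weighted geometric mean diameter, in μm) and
log-domain width α. α is treated as dimensionless throughout — a lognormal
width has no length unit even where instrument software prints one.
Because the NMR signal is itself volume-weighted, the decay is the plain
average of the sphere kernel over this density: 64-node Gauss–Legendre on
ln d ∈ μ ± 4α, converged to <1e-4 against node doubling. α = 0 reduces
exactly to the single sphere.

Fits run over (ln D₃,₃, α) with bounds (0.1, 100) μm × (0, 2], three
deterministic starts, and the oil self-diffusivity held at 4×10⁻¹² m²/s
(rapeseed-oil-like) by default; a free-D_oil fit is available but weakly
identified at 32 gradient steps. Fixing D_oil is an identifiability
choice, not a claim of irrelevance: at D₃,₃ ≈ 3.4 μm and Δ = 211 ms the
droplets sit in the crossover regime R² ~ DΔ, and a ±25% D_oil error
shifts D₃,₃ by 8–30%. The fixed value should come from a bulk-oil
measurement. A decay with min E ≥ 0.7 is rejected as under-encoded, and a
fit pinned at the upper diameter bound is flagged `unrestricted`
(free-liquid behaviour).

The emulated bench-top acquisition uses Δ = 211 ms, δ = 2 ms and 32
gradient steps up to 3 T/m — δ and the gradient range are assumed
instrument constants (configurable), chosen so droplets in the relevant
size range (3–8 μm) attenuate to E ≈ 0.2–0.36. Noiseless round trips recover
(D₃,₃, α) to better than 1%; with 0.5% additive noise the median D₃,₃
error over 50 replicates is ~1%.

## D-T₂ inversion

Kernels K₁ = exp(−b(g)D), b = γ²g²δ²(Δ−δ/3), and K₂ = exp(−t/T₂) are
built on log-spaced grids, default 64 points each over D ∈ [10⁻¹³, 10⁻⁸]
m²/s and T₂ ∈ [1 ms, 3 s] — wide enough for both the aqueous peak
(~9×10⁻¹⁰ m²/s) and the apparent oil component (~4×10⁻¹² m²/s). The
emulated acquisition is 32 gradient steps 0.1–6.6 T/m (δ = 1 ms,
Δ = 200 ms) and a 256-echo CPMG train at t_E = 2.2 ms.

The program min ‖K₁ F K₂ᵀ − S‖² + λ‖F‖², F ≥ 0, is solved after SVD
compression of both kernels (singular values above 1e-8 of the maximum are
kept; exponential kernels leave ~10–15 components, and with the threshold
at machine precision compression is exact — verified against uncompressed
NNLS to 1e-6 on small instances). The solver is FISTA projected gradient
with adaptive restart; with λ > 0 the objective is strongly convex, so the
minimizer is unique and the iteration is run to a 1e-9 relative step
tolerance (20k iteration cap).

λ = "auto" applies the discrepancy principle: the noise level is estimated
from first differences of the tail of the highest-gradient echo train
(÷√2, robust to residual trend), and λ is bisected in log scale until the
compressed-space residual matches σ√(r₁r₂). λ can always be set explicitly
for exact reproducibility of a figure.

Peak extraction thresholds cells below 0.1% of the maximum, labels
8-connected regions, keeps regions holding ≥1% of total mass, and reports
each region's maximum-cell coordinates, log-domain centroid and
mass-weighted mean T₂. The water peak is the region with the highest D
(free-water-like mobility), ties broken toward larger mass; its T₂,w is
the mass-weighted linear mean over the region. Oil-region amplitudes are
deliberately not quantified: restricted oil diffusion is non-exponential,
violating the inversion's kernel assumption, and produces spurious
structure — only its qualitative position is meaningful. The synthetic
surfaces are built exponential by construction, so tests of the inversion
are tests of the inversion, not of that model error.

The 1D water diffusion length is reported as √(2DΔ) ≈ 19 μm at
D = 9×10⁻¹⁰ m²/s, Δ = 200 ms — the convention is stated because 2DΔ
without the root is dimensionally a squared length, and quoted
order-of-magnitude values in the field sometimes drop the root.

The T₂,w–concentration calibration is ordinary least squares with r²,
requiring ≥3 concentrations; a negative slope (protein release shortens
T₂,w) is expected for these systems but not enforced.

## Synthetic data: what it does and does not emulate

The generator reproduces the *information structure* of the four
measurements — resolution, gap coverage, yielding behaviour, encoding
ranges, exponential/restricted decay shapes — with seeded Gaussian noise
(additive in absolute units, or multiplicative as a fraction; every
random operation requires an explicit seed and regenerates bit-identically).
It does not model MRI physics (slice profiles, chemical shift, relaxation
weighting of velocimetry), droplet coalescence dynamics (size change is an
input, not simulated), stimulated-echo amplitude factors, temperature
drift, or rheometer inertia/slip. Passing tests therefore demonstrate that
the *analysis* recovers what the models generate at realistic noise, not
that the models exhaust real instrument data.

## Problem sizes

Default test and acceptance runs use 21-point profiles, 6–7 curve time
series, 20–50 noise replicates, 32×256 D-T₂ surfaces on 64×64 grids, and
50-root eigenmode series — sizes chosen to match the emulated experiments
while keeping the full suite around half a minute on one core.

## Known limitations

- Single-curve HB fits from one narrow-gap profile are structurally
  degenerate (see above); use the global-n series fit.
- The τ₀ series recovered through velocimetry carries a small systematic
  offset from SG smoothing near the walls; kₛ is robust to it, τ₀,ₑ less so.
- The ILT reports no per-peak uncertainty beyond the λ-sweep behaviour;
  Laplace inversion error bars would require resampling machinery out of
  scope here.
- CSV schemas are deliberately rigid (unit-bearing headers); instrument
  vendor binaries must be exported to tabular form upstream.
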