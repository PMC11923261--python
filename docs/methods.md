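# Methods

## Model and coordinates

The walker-foothold complex is shorter than the persistence length of
double-stranded DNA, so its free end samples a hemispherical shell rather
than a Gaussian-chain cloud.  All densities are expressed with the foothold
tether at the origin, z ≥ 0 out of plane, and the binding target on the +x
axis at (a, 0, 0); the trench axis is x.  Lengths are in nm, times in s and
energies in kT, so the stiffnesses appear only as the products βk, βk′, βk″
(nm⁻²) — the code never separates β from k.

Four designs are modelled by unnormalized densities (module `geometry`):

* **baseline** — `z · exp(−βk/2(‖r‖−L)²)`: a harmonic shell at the mean
  complex length L with a Rayleigh-type z prefactor from surface tethering.
* **tail** — the shell Gaussian times a damped sine series
  `Σₙ sin(nπz/z_max) exp(−βk/2 (nπ/(βk′ z_max))²)` on 0 ≤ z ≤ z_max:
  slit confinement by a stiff double-stranded tail.  The series replaces
  the z prefactor; each design's formula is implemented exactly as stated,
  without harmonizing prefactors across designs.
* **trench** — the baseline density times `cos(πy/h_max)` on
  |y| ≤ h_max/2 (the single-mode form; the full cosine series with its own
  stiffness βk″ is available as `trench_series`, with βk″ a free parameter
  that has no established value).
* **combined** — tail × trench cosine factor; this product is bistable in
  x at the reference parameters.

Series are truncated at N = 20 terms.  Truncation can produce small
negative lobes; these are clipped to zero to preserve non-negativity, and
`clipped_mass_fraction` reports the clipped mass (identically zero at the
reference parameters, where the damping leaves the sums positive).

Reference parameters (the 36-bp cartwheeling walker with a 12-bp tail,
`walker36_params()`): βk = 5 nm⁻², L = 11.5 nm, βk′ = 0.75 nm⁻²,
z_max = 12.5 nm, h_max = 9 nm; transport D = 5·10⁷ nm²/s (50 μm²/s) and
reactivity κ = 1 nm/s; contact distances ε ∈ {2, 3.5, 5} nm.

## Radial reduction and normalization

About the target, target-centered spherical polars (θ ∈ [0, π/2],
φ ∈ [0, π] using y-mirror symmetry) give the radial density

    ρ² P_eq(ρ) ∝ ρ² ∫∫ P(x(ρ,θ,φ), y, z) sinθ dθ dφ,

with the steric constraints acting as indicator (Heaviside) factors that
are already built into the hard-zero support of the densities.  The
Jacobian sinθ is included so that ρ²P_eq is the true probability density of
the target distance — the property the samplers and the stepping-time
relation both rely on (verified in the tests against distance histograms of
sampled clouds and against brute-force Cartesian shell binning).

The theory integrates to +∞; the implementation truncates at
ρ_max = a + L + 6/√(βk), beyond which the shell Gaussian carries < 10⁻⁹ of
the mass, and normalizes ∫ρ²P_eq dρ = 1 on [ε, ρ_max].  The normalization
domain is a choice of this implementation (the unnormalized theory leaves
it open); because stepping-rate ratios divide two Szabo times, the choice
cancels in the reaction-limited regime.  The grid is 400 log-spaced points
starting at ε, concentrating resolution where e^{βU} blows up.  Angular
integration defaults to a fixed 128×128 tensor Gauss-Legendre rule,
vectorized over the whole grid with the a-independent factors precomputed
once (`radial_sweep`); per-ρ adaptive quadrature is retained as a
cross-checked option.  The fixed rule agrees with the adaptive one to
better than 10⁻⁵ and makes the (scenario, a, ε) sweeps ~100× faster.
Radial densities below 10⁻³⁰⁰ of the maximum are marked unreachable
(βU = +∞) and treated as reflecting walls.

## Stepping times

`szabo_mfpt` evaluates both terms of the radiation-boundary mean
first-passage relation by cumulative trapezoid on the ρ grid (inner
integral precomputed once, O(n)).  With ρ²P_eq normalized, e^{−βU} = ρ²P_eq
and the rebound term is 1/(κ ρ²P_eq(ε)); the flat-potential closed form
(b−ε)²/(3D) + (b−ε)/κ is reproduced to < 0.1% at 400 grid points.  The
initial condition is the Boltzmann distribution in U(ρ) throughout; the
caveat that a walker entering a bistable trench is more likely to start in
the far well (which would lengthen real stepping times) is noted but not
modelled.  The regime diagnostic D√(βk)/κ evaluates to ≈ 1.1·10⁷ at the
reference parameters with κ = 10 nm/s — the code reports the formula value.
Headline enhancement factors are maxima of the normalized rate
τ_baseline/τ_scenario over a ∈ [8, 16] nm in 0.25 nm steps (the quoted
"fourfold"/"threefold" factors are stated without fixing a; the max-over-a
convention is this package's recorded choice).

## Synthetic clouds and fitting

`sample_free_end` draws i.i.d. positions by rejection sampling from a
uniform envelope over the support bounding box (envelope constant: coarse-
grid density maximum × 1.2).  The clouds emulate the *distribution* of
coarse-grained trajectory point clouds; they deliberately carry no temporal
correlation, so tests passing on them say nothing about autocorrelation-
sensitive quantities (none are used downstream).  Draws are bitwise
reproducible given (scenario, params, n, seed).

`fit_parameters` minimizes the Pearson-weighted squared difference between
the three 1-D marginal histograms of a cloud (Freedman-Diaconis binning
computed on the cloud, padded by half the data span with empty bins so that
model mass outside the observed support is penalized) and the model's
bin-averaged marginals, with Nelder-Mead in log-parameter space (positivity
by construction, deterministic restarts).  The 1/model weights (floored at
10⁻³ of the peak) reflect the multinomial bin variance; they roughly halve
the scatter of the recovered shell stiffness relative to unweighted least
squares.  Two safeguards address a spurious
shallow basin of the truncated slit series (at z_max far above the data
support the clipped 20-term sum degenerates into a truncation-spike profile
that loosely imitates the data): a deterministic second start with the
support parameters snapped to the cloud extent, and a bounded 1-D
coordinate pass per parameter before the joint simplex, which steers the
search into the correct valley instead of letting it slide along the
ridge.  All stages are deterministic given cloud and init.
Least squares on marginals is a design choice of this package — the
functional forms themselves were selected empirically, so the objective is
not canonical.  `fit_annulus` is an exhaustive search over concentric
radius pairs (default grid step 0.05 nm) for the minimal-area annulus
containing the requested fraction (90%) of the in-plane projection,
centered on the tether axis, ties broken toward smaller R_max then larger
R_min.  `detect_modes` boxcar-smooths over 5 grid points and requires peak
prominence ≥ 2% of the maximum, enough to suppress series ripple while
resolving the two wells of the combined design.

## Brownian-dynamics oracle

`simulate_fpt` integrates the overdamped Langevin dynamics on βU(ρ) with
Euler-Maruyama (default step √(2D dt) = 0.02 nm), reflecting at ρ_max and
at unreachable-region walls, and a partially absorbing contact boundary:
each proposed crossing of ε reacts with probability p = √π · κ√(dt/D).
The √π prefactor is the calibration constant of this propose-reflect
scheme: from a locally uniform density the per-step contact fraction is
√(D dt/π) per unit density, and requiring the rebound time (1/p)·E[gap] to
equal the continuum (b−ε)/κ on the flat potential fixes C = √π.  The
constant is frozen in the code and pinned by a calibration test.

At the reference reactivity the expected rebound count is ~2·10⁹ per
trajectory, so the chain is never stepped to absorption.  Instead the
simulator uses an exact renewal decomposition of the same chain: a
trajectory is one BD first-passage leg from a Boltzmann start plus a
Geometric(p) number of first-return excursions from the boundary.  The
mean excursion time is measured from a long reflecting run which
accumulates the *exact one-step contact probability*
Φ((ε − ρ − v dt)/√(2D dt)) of its own transition kernel
(Rao-Blackwellized contact counting — unbiased for the same rate, lower
variance); per-trajectory rebound totals are then synthesized from the
geometric counts by CLT aggregation, which is exact to O(N^{−1/2}) with
N > 10³ always.  Direct ("naive") stepping is used automatically whenever
the expected rebound count is below ~2000, and is what the closed-form
absorbing-limit tests exercise.

The precision of the renewal estimate is limited by the domain mixing
time: the excursion-rate error floor is ~√(T_mix/T_simulated) regardless of
estimator, which at the default budgets (≲ 1.6·10⁹ reflecting steps per
potential, chosen to keep the four-scenario comparison under ten minutes on
one core) gives a shared systematic error of roughly 3–8% on the scenario
potentials and < 1% on the flat potential.  This error is reported as
`FPTSample.se_systematic` and included in the 3-standard-error comparisons;
it is the honest resolution of the oracle at desk scale.

## Pipeline

`run_pipeline` executes sample → fit (optional) → rates → oracle
(optional) from a single YAML config and writes a manifest with the config
snapshot, package version, seeds, output paths and per-stage status; a
failed stage is recorded and propagated as a non-zero exit, never
downgraded.  Deterministic outputs reproduce bit-identically from the
manifest's config; stochastic stages reproduce given the recorded seeds.

## Known limitations

* Volume exclusion from neighboring footholds is neglected, as in the
  underlying theory; comparisons are relative rates between designs.
* ε lumps the entire toehold reach into one contact distance; no
  sequence-level thermodynamics or strand-displacement chemistry.
* The i.i.d. cloud generator cannot stand in for time-correlated
  trajectories where error bars on fitted parameters matter.
* Coarse-grained-simulation-specific findings (e.g. the minimal tail length
  needed to suppress out-of-plane motion) require molecular simulation and
  are outside the scope of this package.
* The wide-trench limit reaches the baseline only as (π/h_max)²⟨y²⟩/2 → 0:
  at h_max = 10·L the residual is still ~1%; limit checks are therefore
  performed at h_max = 10³ nm.
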