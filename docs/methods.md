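# Methods

## Model

`doublering` implements a recurrent rate network of motor cortex in
which each neuron is characterized by four selectivity coordinates
`x = (θA, θB, ηA, ηB)`: a preferred direction and a degree of
participation in a *preparatory* map A and an *execution* map B. Firing
rates obey

    τ dr(x,t)/dt = −r(x,t) + [I_tot(x,t)]₊ ,

with a threshold-linear transfer and time constant τ = 25 ms (default;
the inference results are insensitive within 10–100 ms, which the test
suite checks as a regression). The total input is the sum of a
recurrent term with coupling kernel

    J(x, x′) = j0 + jsA ηA ηA′ cos(θA−θA′) + jsB ηB ηB′ cos(θB−θB′)
               + ja ηB ηA′ cos(θB−θA′)

(primes presynaptic; `j0` uniform, typically inhibitory; `jsA`, `jsB`
symmetric direction-specific amplitudes; `ja` asymmetric map-A→map-B)
and an external input

    I_ext(x,t) = C0(t) + CA(t) ηA + CB(t) ηB
                 + εA(t) ηA cos(θA−Φ) + εB(t) ηB cos(θB−Φ),

with Φ the encoded target direction and εA, εB ≥ 0. The population
density factorizes into an angular part
`ρd(θA,θB) = (1 + χ cos(θA−θB)) / 4π²` — the recorded population is well
described by χ = 2/3 — and independent participation marginals on
[0, 1], represented non-parametrically by samples (a reflected Gaussian
KDE with Silverman bandwidth is provided for smoothing/resampling).
Rates and input currents carry arbitrary rate units; every validated
quantity is a unit-free ratio.

## Order parameters and mean-field dynamics

The macroscopic state is `(r0, rA, rB, ψA, ψB)` — the mean rate, the
participation-weighted first circular harmonics of the activity profile
in each map, and the bump phases — plus the auxiliary
participation-weighted means `(r0A, r0B)` that close the inference
problem. Their dynamics are exact population averages of the rectified
total input. One printed source equation for the auxiliary pair decays
the wrong variable (`−rA` where only `−r0A` is consistent with the
auxiliary parameters' own definition and fixed point); the implemented
equations use `−r0A`, `−r0B`.

**Numerical evaluation.** With cosine couplings and cosine-tuned inputs
the total input at fixed participation is a constant plus one cosine per
map. The integral over one map's angle is therefore available in closed
form — the Fourier coefficients (harmonics 0–2) of a rectified cosine —
leaving a one-dimensional integral over the other angle, evaluated by a
periodic trapezoid rule (spectrally accurate; default 96 points), and a
participation integral over a product grid of midpoint-quantile atoms
per marginal (default 10 per marginal). In the fully linear
(above-threshold) regime the scheme is exact; in rectified regimes it
agrees with a brute-force 4-D Riemann sum to better than 1e-4 relative
(tested). Density moments (⟨η⟩, ⟨η²⟩ and the derived coefficients
F_AA = ⟨ηA²⟩/2, F_BB = ⟨ηB²⟩/2, F_AB = (χ/4)⟨ηA⟩⟨ηB⟩) are defined from
the quadrature atoms, so closed-form fixed-point expressions and the
integrator are mutually consistent to machine precision. A
`PopulationDensity.from_paired_atoms` constructor carries the empirical
participation pairs of a concrete finite network, which is the correct
mean-field counterpart of that realization (participation moments of a
small set of sampled pairs differ appreciably from the parent
distribution, and the mean-field limit keeps the realized pairs fixed).

Integration uses fixed-step RK4 with step ≤ 1 ms (inputs are piecewise
constant per bin; adaptive steppers would complicate reproducibility).
Below an amplitude floor of 1e-9 a bump phase is undefined and its
derivative is frozen. An optional numba-compiled kernel computes the
batched right-hand side; the pure-numpy implementation is the reference
and the two are compared in the tests.

**Stationary states and stability.** Under constant untuned input the
homogeneous rate is `r0 = (C0 + ⟨ηA⟩CA + ⟨ηB⟩CB)/(1−j0)` (amplitude
instability at j0 ≥ 1). Its stability against bump formation is
governed by the 2×2 amplitude block of the Jacobian; the implemented
trace and determinant conditions were verified symbolically against
that block and numerically against finite-difference Jacobian
eigenvalues on coupling grids (zero disagreements required by the
acceptance suite). The Turing boundary `jsB*(jsA; ja)` is found by
bisection to 1e-6; for uniform participation and jsA = ja = 0 it is
exactly jsB* = 2. Stationary bumps are computed by damped fixed-point
iteration (damping 0.5, tolerance 1e-10, at most 10,000 iterations)
with the phase pinned at a seed angle; stability of the bump branch
itself is out of scope.

## Finite-size simulation

Networks of N = Nθ·Nη neurons place Nθ angular coordinates equally
spaced along lines θA−θB = const, with the line offsets at the midpoint
quantiles of the offset marginal `1 + χ cos` — a deterministic
construction whose empirical joint distribution matches the angular
density (the construction leaves open how many lines to use; the
default factors Nθ near its square root, and the quantile placement is
the package's reading of "spacing that matches the density").
Participation pairs are drawn i.i.d. from the empirical marginals, one
set of Nη pairs shared by all angular blocks. The coupling matrix is
never formed: it is a uniform term plus four outer products, so the
recurrent drive needs five population sums per step (O(N)); a dense
path exists for small networks as a test oracle. Integration is
Euler–Maruyama at 0.5 ms with the Ornstein–Uhlenbeck input noise
(decay γ = 75 /s, diffusion amplitude σn = 0.35, stationary variance
σn²/2γ) updated exactly per step. One stated source unit for σn
(Hz/s) is dimensionally unusual for an OU diffusion amplitude; the
package treats σn as rate-units·s^(−1/2), which reproduces the stated
stationary variance. Conditions (the 8 target directions) are
integrated as a batch; trials get independent noise streams spawned
from one seed.

Data-side order parameters approximate the population integrals by
sums over neurons, with the bump phase taken as the condition's target
angle (default; robust to angular heterogeneity) or estimated
self-consistently from the first harmonic — the two agree within 2% on
bump states, and the self-consistent mode falls back to the target
angle (flagged) when the harmonic amplitude is below floor.

## Fitting couplings and inputs to order parameters

Given observed `(r0, rA, rB, r0A, r0B)` in Δt = 5 ms bins, the inner
problem reconstructs the five input parameters bin by bin: the state is
initialized to the data at the first bin, inputs to zero; for each bin
the mean-field ODEs are evolved one bin under candidate constant inputs
and the inputs minimize the squared mismatch of the five observables —
each normalized by that series' time-mean, implemented verbatim even
though the normalization is dimensionally heterogeneous (it divides by
the mean, not the squared mean) — plus an L1 penalty `λ Σ|u|` with
εA, εB ≥ 0, warm-started from the previous bin. The reported E_rec
averages the per-bin mismatch from the second bin; E_ext is the mean
total input magnitude; E_tot = α·E_rec + E_ext.

The per-bin subproblem is solved by damped Gauss–Newton. The bin map
from inputs to end-of-bin observables is affine wherever the whole
population stays above threshold, so a secant Jacobian (probe step
≈ 0.25 × the observation scale, escalated ×8 when the rectification
dead zone makes probes uninformative — below threshold the local
gradient with respect to inputs vanishes) is exact there and is reused
across bins until its linear predictions degrade. Each Gauss–Newton
step solves the five-dimensional L1 problem exactly by enumerating
sign/support patterns (each pattern is a smooth quadratic solved
directly; minimum-norm on singular blocks is the deterministic
tie-break), with KKT-based early exit from the warm pattern. The outer
level searches the coupling box (defaults j0 ∈ [−5, 1), jsA, jsB ∈
[0, 6], ja ∈ [0, 3]) with a Latin-hypercube sample (always including
the feedforward corner) followed by a Nelder–Mead polish, within a
total budget of inner solves (default 200); all evaluated candidates
are kept for degeneracy maps.

**Calibration and identifiability.** The default λ = 1e-3 exists to
prevent pathologically large balancing inputs; it deliberately shrinks
weak untuned map-specific components into the homogeneous term, so
per-series recovery studies use the weak-penalty limit (λ = 1e-5),
where a noise-free forward model is recovered to well under 5% NRMSE
per series. Two structural degeneracies matter when comparing coupling
candidates: (i) `j0·r0(t)` is exactly absorbed by `C0(t)` for any
trajectory, and (ii) weakening any coupling is exactly compensable by
extra nonnegative input. Consequently E_rec alone cannot order
weakened candidates (both runs sit at the solver floor), while
strengthened tuned couplings are caught by E_rec through the ε ≥ 0
constraint. The identifiability protocol therefore generates data with
zero untuned inputs (so every perturbation needs extra input) and
compares E_tot with a reconstruction-weighted α (5e4), under which the
generating couplings strictly dominate all ±50% single-coupling
perturbations. With a small α the search instead selects a recurrent
solution whose external input cost is below the purely feedforward
reconstruction — the energy argument for recurrence.

## Data-side tuning analysis

Spike trains are smoothed with a Gaussian kernel (sd 25 ms, truncated
at ±4 sd, edges renormalized by local kernel mass); each trial's three
task intervals (target→go, go→movement, movement) are linearly rescaled
to their across-trial mean durations before averaging (piecewise-linear
interpolation; the source describes the normalization without fixing
the interpolation rule). Epochs default to 300 ms windows starting
100 ms after target onset and 50 ms before movement onset (half-open,
configurable). Tuning curves are fit as `a + b cos(θ − Φ)` by least
squares on {1, cos, sin} (exact on the 8 equispaced targets);
participation is `η = b / max(b)` over the population (a robust
99th-percentile variant is available, off by default, for the
occasional η ≈ 1 outlier).

Circular statistics follow the standard resultant-vector definitions
(variance S = 1 − R). The circular correlation coefficient uses
marginal mean directions; when either marginal resultant is below 0.1
the mean directions are statistically undefined (near-uniform
marginals, as for preferred directions under this model) and the
centers are estimated jointly from the concentrated mean offset of the
pairs. This leaves the coefficient's population value for the
correlated angular density at χ/2 and makes the estimator concentrate;
with marginal centering the estimator does not converge at all under
uniform marginals (its dispersion stays O(1) in n).

The preferred-direction variability bootstrap bins single-trial
activity into 160 ms bins (3 per task epoch, 7 for the whole task),
z-scores per neuron and bin across conditions and trials — the reading
adopted for the ambiguous "z-scored across conditions": it makes bins
exchangeable while preserving tuning — computes each neuron's circular
variance of per-bin preferred directions, and resamples the NW×n
entries of each neuron-condition matrix with replacement (B = 1000) to
form the null of the median variance.

## Population geometry

Epoch matrices divide each neuron by its standard deviation over all
times and conditions and mean-center across conditions, then
concatenate conditions (N × T·C). The alignment index is the fraction
of preparatory variance captured by the top-K movement PCs, with K
defaulting to the number of components reaching 90% of movement-epoch
variance (computed, never hard-coded). Its Monte-Carlo null draws
random K-frames as orthonormalized `C^{1/2}·Gaussian` with C the
covariance of the concatenated two-epoch activity — directions sampled
with probability weighted by the occupied space's spectrum; the exact
weighting follows the cited Monte-Carlo procedure and is a documented
interpretation. CCA reduces each population to its own 90%-variance PC
count and computes the canonical spectrum by whitened SVD (cross-checked
against scikit-learn). jPCA fits the best skew-symmetric generator
`Ṁ = R·M` in the antisymmetric basis with centered differences (the
source does not state the difference scheme; centered was chosen) and
no soft-normalization preprocessing. The EMG readout is a per-muscle
LASSO with intercept, 10 folds of randomly partitioned non-consecutive
time points, NMSE = residual variance / signal variance, and a cap of
1000 randomly chosen predictor units.

## Synthetic sessions

The generator emulates an instructed-delay center-out session: hold
500 ms, delay uniform 1.0–1.5 s, a 100 ms reaction time, movement
uniform 0.25–0.35 s; 8 targets; default 141 visible units subsampled
from a 1600-neuron network; participation marginals Beta(2, 4)
(skewed toward weak participation with a strongly tuned tail, as in the
normalized-amplitude distributions of recordings); OU noise at the
standard level. Three input-schedule regimes mirror the qualitatively
distinct solutions: *feedforward* (no direction-specific recurrence,
tuned inputs in both epochs), *near-critical* (map-B coupling at 90% of
its Turing-critical value, weak tuned execution input amplified by
recurrence), *supercritical* (130% of critical; untuned input shifts a
self-sustained bump). Schedule shapes are smooth piecewise-linear
ramps — configuration, not claims. Poisson spiking is optional; the
rate-trace path is the default. Every session stores its ground truth
and is bit-reproducible from its seed.

What the generator does *not* emulate: recording artifacts (drift,
unit splits), non-cosine tuning families, kinematic covariates, and
structural heterogeneity in the couplings. Passing tests therefore
demonstrate internal consistency of the pipeline on model-consistent
data, not robustness to those features of real recordings.

## Validation protocol sizes

The standard protocols (in `doublering.validation`, used by both the
test suite and `scripts/acceptance.py`) use: 20 random sub-critical
parameter sets for the fixed-point check; a 10×10 coupling grid for the
Jacobian oracle; N = 4000 (500×8) zero-noise networks over 2 s for the
mean-field comparison; 2 s of 5 ms bins (400 bins) for input recovery
and identifiability; a 141-unit, 10-trial session for the tuning
round-trip; 141 units and 1000 null draws for the subspace geometry;
1e5 density draws for the circular-correlation oracle. These sizes keep
each protocol well-resolved while the full suite completes in minutes.

## Known limitations

- Bump-branch stability and drift under coupling heterogeneity are not
  analyzed (no closed forms are available in the source framework).
- The greedy per-bin inner fit is a filter, not a smoother: it does not
  revisit earlier bins, so isolated kink-crossing bins can retain small
  residuals.
- j0 is identifiable only through the energy term (see above); reported
  couplings along compensable directions should be read jointly with
  the inferred inputs.
- The alignment-index null's covariance weighting follows one published
  procedure; other weightings shift the null's location (not the
  qualitative orthogonality conclusion).
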