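# Methods

This note records the models implemented in `atpex`, their assumptions,
the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## Binodal curve of the alcohol–salt two-phase system

An ethanol–ammonium-sulfate mixture in water splits into an alcohol-rich
top phase and a salt-rich bottom phase above a critical composition. The
boundary (binodal) is modelled by the empirical relation
`w1 = exp(a + b·√w2 + c·w2 + d·w2²)` with mass fractions stored as
fractions in [0, 1]. Two fitting spaces are exposed because the choice
is genuinely open: an exact linear least-squares solution for ln w1
(log-linear), and nonlinear least squares on w1 itself, initialised from
the log-linear solution. The default is nonlinear-on-w1, because the
R²/AAD quality metrics are conventionally reported on w1; on noiseless
data the two coincide.

A caution for users interpreting fitted constants: on the working range
w2 ∈ [0.02, 0.35] the basis (1, √w2, w2, w2²) is strongly collinear.
At 1 % multiplicative noise on 20 points the linearised standard errors
are roughly 28 %, 11 %, 172 % and 14 % of |a|, |b|, |c|, |d|. The curve
is recovered to well under the noise level, but the individual constants
— especially c — are not separately identifiable at realistic scatter.
Tests therefore assert curve recovery and coefficient recovery relative
to the analytic standard errors, not naive percentage bands.

A point exactly on the binodal is classified **two-phase**: the curve is
operationally the first composition at which phase separation is
observed, and screening applications want the boundary inclusive.

## Partition, recovery and purity statistics

For top/bottom concentrations C_T, C_B (mg/L) and volumes V_T, V_B:
K = C_T/C_B; Y_T = 100·C_T·V_T/(C_T·V_T + C_B·V_B); Y_B is returned as
100 − Y_T so the pair sums to 100 exactly in floating point. When
C_B = 0 the partition coefficient is unbounded and the library raises a
domain error rather than returning infinity, keeping every numeric
output finite and serialisable; the CLI renders this case as
"unbounded". `implied_volume_ratio` inverts Y_T = 100·K·R/(K·R + 1) for
R = V_T/V_B, which lets published (K, Y) pairs be checked for mutual
consistency when phase volumes are not reported. All percentages are
computed at full precision; rounding to report-style decimals happens
only at the presentation layer, so chained statistics (e.g. percent
increases of purities) do not accumulate rounding error.

## Intraparticle diffusion in a finite bath

### Model

Solute content Cs(x, t) in a spherical particle obeys Fick's second law
with effective diffusivity De (m²/s); the particle ensemble — N
identical spheres with total volume Vp = m_solid/ρ and area A = 3·Vp/r —
sits in a well-stirred bath of volume V whose concentration C_L(t) rises
by the surface flux balance −De·A·∂Cs/∂x|_r = V·dC_L/dt. Initial
conditions: uniform loading Cs = cs0, clean bath C_L(0) = 0. Assumed:
spherical geometry, no reaction or degradation, a uniform bath, elapsed
time as the model clock (the 5 s on / 5 s off sonication duty cycle is
not resolved), and no surface resistance. The last assumption is closed
as interfacial equilibrium Cs(r, t) = k·C_L(t); k defaults to 1
(concentration continuity) and is exposed for sensitivity studies.

The behaviour is governed by the capacity ratio α = V/(k·Vp) and the
dimensionless time τ = De·t/r²; at equilibrium a fraction α/(1+α) of the
initial solute is extracted. The reference bath (2.5 g solid in 50 mL)
has α = 20, i.e. equilibrium extracts 95.2 % of the loading. cs0
defaults to the value that makes the equilibrium yield 18 mg/g.

### Numerics

The radius is discretised into cell-centred finite volumes (default 60
cells) with fluxes on the faces and the bath as one extra ODE state;
the stiff system is integrated with SciPy's BDF method (rtol 1e−8) and a
banded-plus-border Jacobian sparsity pattern. The discretisation is
conservative by construction — inter-cell fluxes telescope, so discrete
total mass is exact up to integrator tolerance; measured mass-balance
errors are at machine precision (~1e−15 relative), far inside the 1e−6
contract asserted in the tests. The surface Dirichlet value k·C_L is
applied over the half-cell distance, formally first order at that one
face; against the analytical oracle the solution is accurate to ~5e−5
relative at 240 cells and ~1e−3 at 60, with the error shrinking under
grid refinement.

The independent oracle is Crank's eigenfunction series for a sphere in a
well-stirred solution of limited volume:
M_t/M_∞ = 1 − Σ 6α(1+α)·exp(−q_n²τ)/(9 + 9α + q_n²α²), with q_n the
positive roots of tan q = 3q/(3 + αq²), bracketed in (nπ, nπ + π/2) and
solved by Brent's method (64 roots by default, ample for τ ≥ 0.01). The
series shares no code with the finite-volume path.

### Inverse estimation of De

De is estimated by bounded scalar minimisation (Brent) of the RMSE
between simulated and observed yields, searched on log₁₀(De) over
(1e−12, 1e−8) m²/s by default: the objective is smooth and unimodal in
practice, and the log scale equalises sensitivity across decades. Fits
landing within 1e−3 decades of a bound are flagged. A flat (all-zero)
curve is rejected as degenerate. Identifiability caveat: De is only
determined by samples taken during the transient. Once a curve has
plateaued, the equilibrium level is fixed by mass balance alone and
carries no information about De; estimating a diffusivity from an
equilibrated curve amplifies noise without bound. The recovery tests
therefore use designs whose nine sampling times span τ ≈ 0.03–0.7.

### Geometry calibration of the reference bath

Only the ratio De/r² is observable from a kinetics curve, so the model
radius and the diffusivity scale form a joint convention that must be
chosen once. The package pins the De scale to the published quadratic
response surface De×10¹⁰ = −1.599 + 0.02055·AED + 0.1213·T −
6.285e−5·AED² − 6.25e−5·T² − 7.966e−5·AED·T (AED in W/L, T in °C; valid
on AED ∈ [41.1, 111.2], T ∈ [20, 40], where it is positive and
increasing toward the high-AED/high-T corner), and then calibrates the
effective diffusion length so that this De scale reproduces the
reported kinetics shape — a fast rise over the first 20 min and 85–99 %
of equilibrium at 60 min across the factorial box. That gives
r_eff = 2.0 mm. The sieved particle radius (~0.2–0.3 mm; median size
671.67 µm) would, combined with the same De scale, equilibrate every
curve within ~2 min, which contradicts the observed hour-long kinetics;
wetted pomace aggregates, so an effective length above the dry sieved
size is physically expected. Users modelling their own system should
set r to their measured effective length and interpret fitted De on
that scale.

## De(AED, T) response surface

Ordinary least squares of De×10¹⁰ on the six-term quadratic basis
(1, AED, T, AED², T², AED·T), requiring at least six rows spanning two
levels of each factor and a full-rank design. R² follows the shared
metrics convention. Evaluation outside the calibration box emits a
warning rather than an error — extrapolation is sometimes wanted, but
the quadratic has no validity claim there.

## Neural-network yield surrogate

A single-hidden-layer feedforward network y = purelin(LW·tansig(IW·x_s +
b1) + b2) with min-max scaling of inputs and output to [−1, 1] fitted on
the training split. Training minimises MSE with L-BFGS from seeded
uniform(−0.5, 0.5) initial weights, 4 restarts, early stopping on
validation RMSE with patience 50 iterations; the restart with the best
validation RMSE wins, and the whole procedure is bit-reproducible for a
fixed seed. The split defaults to 70/15/15 train/validation/test by
seeded shuffle. Hidden-size selection trains each candidate with the
same seed (hence identical splits) and picks the lowest validation
RMSE, breaking ties toward the smaller network. A constant-yield target
is handled, not rejected: the network learns the constant, RMSE ≈ 0,
and R² is flagged undefined (zero observed variance).

The packaged reference network (8 hidden neurons, output bias −1.0773)
reproduces a published weight set for this extraction system. Its
original input/output scaling was never published, so the loader
attaches min-max scaling over the experimental ranges (AED
[41.1, 111.2] W/L, T [20, 40] °C, time [0, 60] min) with identity output
scaling; the file and loader document this as non-authoritative. The
row layout (three input weights, one hidden bias, one layer weight per
row) is inferred from dimensional necessity: 3 inputs, 8 hidden units,
1 output.

## Shared fit metrics

R² = 1 − SSE/SST, RMSE = √(SSE/n) with n the full vector length (no
degrees-of-freedom correction), and AAD = 100·mean(|pred − obs|/obs) in
percent. R² is flagged `None` when the observations have zero variance
and AAD when any observation is exactly zero; the remaining metrics are
still returned.

## Synthetic data: what it emulates, and what passing tests show

The generators emulate the study design: 20 binodal node points over
w2 ∈ [0.02, 0.35]; a full-factorial kinetics grid at AED ∈ {41.1, 63.5,
96.1, 111.2} W/L × T ∈ {20, 30, 40} °C × times {2.5, 5, 10, 15, 20, 30,
40, 50, 60} min, with De per cell from the response surface and curves
from the diffusion model; and partition samples with prescribed K and
volume ratio. Noise is multiplicative Gaussian truncated at zero —
assay error on positive quantities is roughly proportional, and an
additive model could produce negative yields. Every generator is a pure
function of (config, truth): identical seeds give byte-identical
tables.

What the synthetic data do **not** emulate: model mismatch. Real pomace
has a particle-size distribution, a two-stage washing-then-diffusion
character, possible degradation, and bath hydrodynamics that vary with
sonication — the generator draws from the same model family the fitters
assume. Passing recovery tests therefore demonstrate the correctness
and conditioning of the estimation machinery, not that the diffusion
model is an adequate description of any particular real extraction.
Likewise the ANN tests show the surrogate can represent the (smooth)
diffusion response; they say nothing about noise structure in real
factorial experiments beyond the multiplicative model used.

## Problem sizes and runtime

Defaults were chosen so the whole chain runs comfortably on one CPU: 60
radial cells for fitting (240 when demonstrating oracle convergence),
nine-point time grids, a 108-row factorial table, 4 training restarts.
The full demo pipeline (12 inverse-De fits, surface refit, ANN
training) completes in ~10 s; the complete test suite in about a
minute.

## Known limitations

- The boundary condition applies equilibrium partitioning at the
  surface; film mass-transfer resistance is not modelled (k_interface
  is a constant, not a rate).
- The 5 s on/off duty cycle is collapsed into elapsed time; if
  diffusion enhancement acts only during bursts, fitted De values are
  duty-cycle-averaged.
- The quadratic De surface is a response-surface summary, not a
  mechanistic law; it must not be extrapolated far outside the
  calibration box (it goes negative for small AED and T).
- Reference-network predictions are structurally faithful but not
  numerically authoritative, because the original scaling is unknown.
- Binodal constants are reported with analytic standard errors in mind;
  comparing individual constants across studies without accounting for
  the basis collinearity is not meaningful.
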