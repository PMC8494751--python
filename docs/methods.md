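# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `paraft`. It is written for users who want to know what the
package computes, why the defaults are what they are, and what the synthetic
validation does and does not demonstrate.

## Forward physics and its 2-D discretization

Under pulsed illumination and the assumption of ideal point transducers, the
initial pressure `p0(r)` equals the absorbed optical energy `H(r) = Γ φ μ_a`,
and the pressure recorded at a detector is (up to constants) the time
derivative of the integral of `p0` over the sphere of radius `v_s t` around
the detector. `paraft` works in the 2-D analog: the integration surfaces are
circles, and all physical constants (the Grüneisen parameter, the `1/4π`
solid-angle factor) are absorbed into a single scale `1/(2π v_s)` used
identically by the analytical phantom signals and by both discretized models,
so model-versus-analytical comparisons are scale-consistent. Fluence is
treated as spatially constant (no fluence model is included), so reconstructed
images are proportional to `μ_a` in arbitrary units.

Two sparse discretizations of the circular-integration operator are provided.
Both produce `M = (1/(2π v_s)) · D_t · W`, where `W` holds non-negative arc
weights and `D_t` is a per-detector temporal derivative (symmetric central
difference in the interior, first-order one-sided at the record ends; the
stencil is recorded in the model metadata).

* **Curve-sampling (dimmi).** The integration circle is clipped to the field
  of view, `n_curve_samples` points are placed uniformly in angle along the
  clipped arc, and each point deposits its arc element onto the four
  neighboring pixel centers by bilinear interpolation. Coordinates are
  clamped to the pixel-center hull at the FOV edge, so the total row weight
  equals the in-FOV arc length. Default `n_curve_samples = 2·max(Nx, Ny)`,
  i.e. at least Nyquist along the longest arc chord. The dense angular
  sampling acts as an anti-aliasing filter, which is why this model is more
  accurate than the exact-arc model on coarse grids.
* **Exact arc length (cdmmi).** All crossings of the circle with the grid
  lines (including the FOV border) are solved in closed form; each angular
  interval between consecutive crossings lies in exactly one square cell and
  contributes `ρ·Δθ` to that cell, treating the pixel value as constant over
  the cell. Row sums therefore equal the in-FOV arc length to machine
  precision — an invariant the test suite checks against an independent
  crossing computation that uses only the four FOV border lines.

The two discretizations converge to arc integrals of *different* image
interpolants (bilinear versus piecewise-constant), so at a fixed resolution
they agree only to O(pixel size) (a few percent at 50×50) no matter how fine
the curve sampling; the gap shrinks with resolution. This is a property of
the discretizations, not an implementation artifact.

## Analytical phantom

The phantom primitive is a paraboloid absorber,
`p0(r) = A (1 − |r−c|²/R²)` on a disc of radius `R`. For this profile the
line integral over a circle of radius `ρ` centered at a detector has a closed
form, and so does its radial derivative, giving the exact point-detector
signal. The radial derivative is continuous but has square-root kinks at the
tangency radii `|D±R|`; within one time sample of those radii the
implementation switches to a five-point central difference of the arc
integral (step `v_s·dt/100`) to avoid evaluating the closed-form derivative
at its singular points. Random phantoms draw source count, radii, amplitudes,
and positions uniformly (defaults: 1–8 sources, radii 2–15 % of the FOV,
amplitudes 0.5–2), rejection-sampled until all discs are inside the FOV and
pairwise disjoint — disjointness is what makes superposition of the per-source
closed forms exact.

## Solvers

* **LSQR** implements the standard Golub–Kahan recurrence (with the usual
  damping rotations when a Tikhonov weight is set) and tracks the relative
  residual per iteration; the trace is non-increasing. Defaults: 50
  iterations, tolerance 1e−6. Early stopping is the regularizer: the
  tomographic systems are ill-conditioned and iterating to numerical
  convergence amplifies discretization error. The implementation is
  cross-checked against `scipy.sparse.linalg.lsqr` iterate-for-iterate in the
  tests.
* **Non-negative solver (nnapcg).** Accelerated projected gradient
  (FISTA-style momentum) with a fixed `1/L` step, `L` estimated by power
  iteration on `MᵀM` from a deterministic start vector, and a function-value
  restart: if an accelerated step would increase the objective, momentum is
  reset and a plain projected-gradient step is taken from the previous
  iterate, which cannot increase the objective. Every iterate is projected
  onto the non-negative orthant, so the output never contains a negative
  pixel. The published description of the original algorithm is not detailed
  enough to reproduce its exact iteration, so the contract here is
  behavioral — non-negativity, monotone objective, and agreement with an
  active-set NNLS oracle on small systems — rather than structural.
* **Universal backprojection**, 2-D adaptation: `b(r) = Σ_d w_d [2p(t) −
  2t ∂p/∂t]` at the time of flight, linearly interpolated, with
  `w_d = 1/n_detectors`. The absolute scale is arbitrary (images are in a.u.).

## Signal preconditioning

Fixed order: energy calibration → per-transducer mean subtraction → Wiener
deconvolution → band-pass → water-absorption compensation → temporal
regridding. Deconvolution precedes band-passing because Wiener deconvolution
assumes white noise, which a band-pass filter would violate. Stages can be
toggled but not reordered. Choices the instrument literature leaves open:
the impulse response defaults to none (stage is an identity) because any real
kernel is instrument-specific; the Wiener noise-to-signal ratio defaults to
0.1; the band-pass is a 4th-order Butterworth applied forward–backward
(zero phase), default band 50 kHz–7 MHz — the contract is the attenuation
behavior, not the filter family. The water table ships approximate
near-infrared pure-water absorption values (Hale & Querry-type compilations)
on a 700–900 nm grid; default path length 3 cm.

## Multispectral filtering and unmixing

The sliding-window filter emits, at each frame, the most recent image of each
wavelength (nothing until every wavelength has been seen once). The Kalata
fixed-gain filters derive their gains from the tracking index Λ:
for the α/β filter `r = (4 + Λ − √(8Λ + Λ²))/4`, `α = 1 − r²`,
`β = 2(2−α) − 4√(1−α)`; for the α filter the first-order steady-state
relation `Λ² = α²/(1−α)` gives `α = (−Λ² + √(Λ⁴+4Λ²))/2`. Every frame
time-updates all channels (identity for α; `x̂ += v̂·Δt` for α/β using the
global frame cadence); the measurement update touches only the incoming
frame's channel, with the trend gain scaled by the time since that channel's
last measurement. Closed-form checks used in the tests: steady-state noise
variance ratio `α/(2−α)` for the α filter; ramp lag `slope·Δt·(1−α)/α` for α
and zero for α/β.

Unmixing inverts `I = E C` per pixel by pseudoinverse or by non-negative
least squares; the non-negative route reuses the projected-gradient
iteration, vectorized across all pixels, and is checked against
`scipy.optimize.nnls` per pixel. `SO2 = HbO2/(HbO2+Hb)` is NaN where the
denominator is exactly zero; unconstrained estimates may leave [0, 1] and are
passed through unclipped so that downstream analyses can flag them. The
shipped HbO2/Hb table contains approximate molar absorption coefficients
digitized from standard published compilations on a 10 nm grid (700–900 nm),
linearly interpolated; users can override it with a CSV. Because the
synthetic generator and the unmixer share this table, its absolute accuracy
does not affect any synthetic result.

## Synthetic gas challenge: what it emulates and what it does not

The dynamic generator emulates a wavelength-cycled acquisition during a
breathing-gas challenge: paraboloid total-hemoglobin absorbers whose oxygen
saturation relaxes mono-exponentially toward a plateau selected by a
rectangular inhaled-gas waveform; frames cycle through
[715, 730, 760, 800, 830, 850] nm with optional per-wavelength oversampling;
data are forward-projected through the exact-arc model and i.i.d. Gaussian
noise is added. Ground-truth concentration maps, SO2 maps, and the waveform
are stored alongside the data.

Default study conditions (36 frames = 6 cycles, 10 s frame period, switches
at 120 s and 240 s): the transition time constant is 6 s, preserving the
~20:1 plateau-to-transition ratio of a real challenge — the ratio that
waveform correlation is sensitive to. A 36-frame record cannot
simultaneously keep the cycle period much shorter than the transition, so
that second ratio is sacrificed; consequently transition-cycle staleness, not
intra-transition kinetics, bounds the attainable correlation (~0.5 even for
noiseless data). Noise defaults to 0.5× the RMS signal (sinogram SNR 2),
representative of unaveraged single-shot frames; the tracking index defaults
to 2, making the α filter's memory comparable to the transition time at the
60 s per-channel cadence. Under these conditions the constrained chain
(non-negative reconstruction, α filter, constrained unmixing) achieves higher
median SO2-versus-waveform correlation than the unconstrained chain, and its
advantage grows with noise; at sinogram SNR ≳ 3 the two chains are at parity
because the filter's lag then costs as much as its smoothing gains.

What passing these studies shows: the operators, solvers, filters, and
statistics are internally consistent and behave as their closed forms
predict, and the constrained chain's qualitative advantages (no negative
values, bounded SO2, better waveform correlation under noise) reproduce on
data whose ground truth is known. What it does not show: robustness to
fluence inhomogeneity, acoustic attenuation and heterogeneity, finite
transducer apertures, motion, or spectra mismatch — none of which the
generator emulates.

## Gas-response model

The 7-parameter response model is a piecewise mono-exponential:
baseline `b`, a rise of amplitude `A₁` and rate `k₁` starting at switching
time `τ₁`, and a fall of amplitude `A₂`, rate `k₂`, time `τ₂`. The exact
functional form used by the original analysis is not published in detail;
this parameterization is reconstructed from the named outputs (baseline,
amplitudes, rates, switching times) and should be read as this package's
definition. Fitting uses bounded trust-region least squares with a
derivative-based initializer and two fallback starts; switching times are
bounded to the record; a fitted `τ` earlier than a known stimulus onset sets
the `noncausal` flag; constant series yield a degenerate fit (amplitudes 0)
rather than an error. The fit requires at least 50 samples; per-pixel fitting
of short records is intentionally rejected.

## Study problem sizes

The validation studies are scaled to run on a single CPU in minutes: the
forward-model accuracy protocol uses 10 random phantoms per resolution in
{30, 50, 100} with 64 detectors and 512 samples; the reconstruction-quality
protocol uses the same resolutions with 256 detectors — reconstruction
quality at the finest grid is only attributable to the solver and model when
the array samples that grid adequately; with 64–128 detectors the trend is
dominated by angular-undersampling streaks — and the gas challenge uses a
50×50 grid with 32 detectors and 256 samples. The synthetic-geometry
defaults in `paraft.datamodel` (128 detectors on a 270° arc of 40 mm radius,
1500 m/s) are package conventions, not properties of any instrument, and are
fully configurable.

## Determinism

All randomness flows through explicit integer seeds (`numpy` Generator).
Dataset stores and pipeline outputs are written with HDF5 object timestamps
disabled, so identical inputs produce byte-identical files; the parallel map
over frames uses a static, order-preserving schedule, making pipeline outputs
independent of the worker count at the byte level. The provenance record
contains the fully resolved configuration, package version, input content
hash, and seeds; re-running from it reproduces the outputs exactly.
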