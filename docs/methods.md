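# Methods

`mtbundle` analyses the multiscale dynamics and structure of microtubule
bundles driven by the minus-end-directed motor kinesin-14 under varying
depletant (PEG) concentration.  The package has four analysis stages —
photobleach-line kinetics, tracer velocity statistics, strain-rate fits, and
SAXS lattice modelling — and a synthetic-data generator that produces every
input from known ground truth, so each stage can be validated by parameter
recovery.

## Bundle kinematics model

Two limiting microscopic behaviours are modelled, with a mixing parameter
`alpha` interpolating between them.  Filament `i` at axial position `x`
moves with

    v_i = alpha * p_i * V + (1 - alpha) * gamma_par * x~ + eta

* **Pure sliding** (`alpha = 1`): half the filaments move at `+V`, half at
  `-V` (polarity `p_i`), the signature of coherent antiparallel sliding.
  Polarities are initialised exactly half/half (interleaved, one extra `+1`
  for odd counts) rather than Bernoulli, so the sliding limit is noise-free.
  Polarity flips are a Poisson process at the reversal rate `k` (per-step
  flip probability `1 - exp(-k dt)`); a warning is issued when
  `dt > 0.1/k`.
* **Pure extension** (`alpha = 0`): telescoping growth at axial strain rate
  `gamma_par` relative to the bundle centre.  In `linear` growth mode the
  material coordinate `x~` is frozen at `t = 0` (velocities constant, marker
  separations affine in time, matching the linear fits used for strain-rate
  estimation); in `exponential` mode `x~` is the instantaneous position, so
  separations grow as `exp(gamma t)`.  Both modes exist because measured
  extension looks linear over the accessible separations while telescoping
  mechanics implies exponential amplification; `linear` is the default for
  recovery tests.

The per-step deterministic update integrates the affine velocity field
exactly (`x -> c/g + (x - c/g) e^{g dt}` for the exponential mode), so both
limits are free of time-discretisation error.  Velocity jitter `eta`
(`noise_sigma`, nm/s) is added as an independent Gaussian displacement per
step.  Filament lengths are log-normal; from a stated mean and mode the
parameters follow in closed form,

    sigma^2 = (2/3) ln(mean/mode),   mu = ln(mode) + sigma^2,

with defaults mean 4.9 um, mode 2.8 um.

## Kymograph rendering

A kymograph frame is the sum over filaments of a box of the filament length
centred at its position, convolved with a Gaussian PSF (default sigma
0.30 um), sampled at 0.325 um/px every 2 s.  These imaging defaults are the
package's own choices of plausible confocal settings; they are configurable.
At the bleach time the label density along each filament is multiplied by
`1 - depth * G(x)`, where `G` is a pair of Gaussian notches (default FWHM
1.5 um, depth 0.6, centres 15 um apart).  Notches are Gaussian rather than
top-hat to mimic diffraction-limited line bleaching, and the notch pattern
is imprinted in *material* coordinates, so it is carried along by the
filaments afterwards — this is what makes bleach marks split under
antiparallel sliding.  Pixel values are Poisson counts with expectation
`photons_per_px` at the unbleached plateau (default 2000, i.e. ~2% shot
noise); `photons_per_px = None` renders a noiseless float image.

Bundles are rendered dense (default 12000 filaments over a 100 um span,
~600 filaments overlapping each axial point) because a real bundle packs
many filaments into each optical column.  The residual ~4% coverage
fluctuation moves with the filament populations and therefore survives
flat-fielding; it is the dominant noise source in the bleach analysis, which
the tracking is designed to tolerate.  What the generator does **not**
emulate: bundle curvature and drift, out-of-focus background, photobleaching
of the label over time, and detector read noise.  Recovery results on this
synthetic data therefore bound the pipeline's algorithmic error, not its
robustness to those real-world effects.

## Bleach-line pipeline

1. **Flat-field**: each frame is divided by the mean pre-bleach profile
   (requires >= 3 pre-bleach frames).
2. **Dip detection**: the profile is inverted about its median, smoothed
   (Gaussian, sigma 1 px), and local maxima above `5 x MAD` (with a 2%
   absolute floor so numerically flat profiles yield nothing) are refined by
   Gaussian fits.  A dip's weight is its integrated deficit, amplitude x
   width — bleach marks are intensity deficits and the weight of a band is
   not defined operationally elsewhere, so this integral is the package's
   definition.
3. **Tracking**: the first post-bleach frame must contain exactly two dips.
   Each mark is followed with a fitting window around its centre of mass
   (capped at the midline between marks).  Per frame, one- and two-Gaussian
   models are fitted; a mark is declared split when the two-Gaussian model
   wins by delta-BIC > 10 *and* the children are separated by >= 2 FWHM,
   for 5 consecutive frames (all thresholds configurable).  Accepted child
   positions are gated by frame-to-frame continuity (`max_step`, growing
   with gaps so a bad lock recovers); a mark whose deficit fades below 20%
   of its initial amplitude for > 3 frames is truncated with a warning.
   A persistent third residual dip between split children flags regime
   coexistence.
4. **Kinetics**: per frame each mark's centre of mass weighs the two band
   positions by their integrated deficits, `COM = (L1 I1 + L2 I2)/(I1+I2)`
   (an unsplit mark's COM is its dip position exactly).  `L_cen` is the
   distance between the two COMs and `V_cen` its OLS slope; `L_split` is
   the mean intra-mark child separation and `V_split` its OLS slope over
   post-onset frames, reported only when both marks split.  Standard errors
   come from the regression.  `V_cen` is reported as the raw slope, with the
   initial mark spacing available separately (whether a normalised extension
   speed is wanted is left to the caller).
5. **Splitting fraction**: the fraction of bundles classified `split` or
   `coexisting`, with a Wilson 95% interval.

Coordinates are um from the left image edge with pixel centres at
`(index + 0.5) * pixel_size`.

## Tracer statistics

Tracks (a labelled subset of filaments, default 1 in 10^4) are projected on
their principal displacement axis; velocities are finite differences
(default lag 1).  The autocorrelation

    C(tau) = < V(t) V(t + tau) >_{t, tracks} / < V^2 >

is computed *without* per-track mean subtraction by default: reversal-rich
tracks have near-zero mean and the negative lobe of C is the reversal
signature (a `subtract_mean` flag is provided).  The 95% band is a bootstrap
over whole tracks (1000 resamples, seeded) — the CI method is the package's
choice.  The slowness exponent `S_c` (s/um) is the exponential
maximum-likelihood rate, `1/mean`, of the pooled absolute deviations
`|V(t) - Vbar|` with `Vbar` the per-track time-average velocity; a
log-linear histogram fit is returned alongside for comparison, and
all-constant velocities yield `S_c = inf` with a degeneracy flag.  Strain
rates are OLS slopes of `L(t)/L_o` versus `t` with a 95% prediction
interval; the transverse extent is measured as the FWHM of the transverse
intensity profile.

For a telegraph velocity process the analytic autocorrelation is
`exp(-2 k tau)`, which the simulated reversal process reproduces up to the
per-step discretisation `(2 e^{-k dt} - 1)^{tau/dt}` — at the default
`k dt <= 0.05` the difference is under 0.01 and is absorbed by the test
tolerance.

## SAXS forward model

A microtubule is a long hollow cylinder (defaults r_out 12.5 nm, r_in
8.4 nm, consistent with the ~22 nm real-space peak of the measured form
factor).  For parallel rods much longer than `1/q` the orientationally
averaged intensity is

    I(q) = K * exp(-q^2 sigma_d^2) / q *
           < | sum_j F_j(q, psi) e^{i q r_j . u(psi)} |^2 >_psi

with the annular cross-section amplitude `F` (filled-ellipse transforms
`2 J1(u)/u` weighted by areas, normalised to 1 at q = 0), rod centres `r_j`
on the cross-sectional lattice, and a Debye-Waller factor for Gaussian
lattice disorder.  Disorder is modelled as Debye-Waller damping rather than
ensemble averaging over displaced lattices, for determinism and speed; peak
widths are additionally controlled by the small rod count.  The azimuthal
average uses uniform quadrature on `[0, pi)` (the integrand is pi-periodic,
so the uniform rule is spectrally accurate; 720 nodes by default, and the
aliasing error at 96 nodes is already below 1e-15 for these geometries,
which the fitter exploits).  Identical circular rods use the closed-form
fast path `|F|^2 sum_jk J0(q d_jk)`; the two paths agree to < 1e-6 and are
cross-checked in the tests.

Lattices: hexagonal — centre rod plus shells at spacing `L_h` (default 7
rods); rectangular — a grid at `L_a x L_b` with the convention
`L_a <= L_b` (default 2 x 3 = 6 rods; the most-square factorisation is used
for other counts).  The published models use "< 10" rods without stating
the arrangement, so these defaults are the package's choices.  For the
rectangular phase the rods are elliptical: depletant-induced pressure
buckles the circular cross-section, and close packing fixes the outer
semi-axes at half the lattice constants (10.1 nm along `L_a`, 13.6 nm along
`L_b`, all rods sharing one orientation); the inner ellipse is similar to
the outer, scaled so the wall area equals the circular reference wall area
(the published figure inset does not print the radii, so this is a
reconstruction).  Internal q unit is nm^-1; A^-1 values convert by x10.
Coexistence is an incoherent mixture `w I_hex + (1-w) I_rect`.

Detector utilities: `q = (4 pi / lambda) sin(theta/2)` per pixel with
`theta = arctan(r * pixel / distance)`, equal-width bins over the
instrument window [0.075, 2.185] nm^-1, per-bin standard error, silver
behenate calibration (`d = 5.8376 nm`), and background subtraction
`I - scale * I_bg` with quadrature error propagation (negative values are
retained, not clipped).

## SAXS fitting

Weighted least squares `sum ((I_obs - I_model)/sigma)^2`.  The model is
linear in the per-phase scales and in the background (constant +
`A q^-p`), so those amplitudes are profiled out by non-negative linear
least squares at every evaluation of the nonlinear parameters (lattice
constants in [30, 60] / [15, 35] nm, disorder in [0, 5] nm, background
exponent in [0, 4]).  The nonlinear search is bounded trust-region least
squares from a seeded Latin-hypercube multi-start (default 6 starts).
Parameter uncertainties come from the local quadratic approximation at the
optimum.  Model selection uses `BIC = chi^2 + k ln n`; the coexistence
model must beat both single phases by delta-BIC > 10 (guarding the
one-extra-parameter model against winning on noise), and single-phase
candidates within delta-BIC 2 raise an ambiguity flag.  The mixture weight
is reported as the hexagonal share of the fitted phase scales.  The
published choice between coexistence and single-phase descriptions at
intermediate PEG is not stated; the BIC rule is this package's criterion.

## Default study conditions

| quantity | value | origin |
|---|---|---|
| splitting speed, 0% PEG | ~45 nm/s (filament speed V = 22.5 nm/s) | measured |
| axial strain rate gamma_par | 8.5e-4 (0% PEG), 1.1e-3 (1% PEG) 1/s | measured |
| transverse strain rate gamma_perp | -2.5e-4 (0%), -5.0e-4 (1%) 1/s | measured |
| hexagonal spacing L_h | 45.8 nm (+-5 nm) | measured |
| rectangular constants | {20.2, 27.2} nm, convention L_a <= L_b | measured (the two published statements swap the labels; the unordered pair is used) |
| filament lengths | log-normal, mean 4.9 um / mode 2.8 um | measured |
| bleach lines | 2 lines, 15 um apart | measured protocol |
| tracer fraction | 1 in 10^4 | measured protocol |
| q window | [0.075, 2.185] nm^-1, lambda 0.154 nm, 3.4 m | instrument |
| pixel size / frame interval | 0.325 um / 2 s | package choice (not published) |
| photons per pixel | 2000 | package choice |
| lattice disorder sigma_d | 1.0 nm | package choice (modest thermal disorder) |

The published slowness values are internally inconsistent between text
(1.19 / 2.90 s/um) and figure caption (0.19 / 0.29 s/um); the package does
not resolve this and no recovery check depends on those values (the
slowness estimator is validated on synthetic exponential samples instead).

## Numerical choices and degenerate inputs

* `q = 0` is excluded from scattering grids with a warning (1/q factor).
* Empty radial-average bins are NaN with a zero count.
* Background subtraction refuses extrapolation beyond the background's
  support.
* Gaussian dip fits fall back to moment estimates when the optimiser fails;
  a frame where both window fits fail counts toward track loss.
* `fit_curve` falls back to unit weights when fewer than 50 points carry
  positive sigma, and refuses curves with fewer than 50 valid points.
* Ties in dip association are broken by the continuity gate (nearest
  accepted positions); `L_a`/`L_b` are sorted into the `L_a <= L_b`
  convention after fitting.

## Problem sizes

Recovery workflows default to: 800 filaments (idealised noiseless bundle) or
12000 (noisy renderings) over 100 um, 260 s at 2 s frames; 5 seeds for the
noisy splitting-speed average; 500-point q grids with peak Poisson SNR 30
and 20 seeded replicates for the hexagonal-spacing sweep; 1e5 samples for
the length distribution.  These sizes keep every individual check at the
seconds-to-a-minute scale while leaving the recovered parameters' sampling
error well inside the stated tolerances.

## Known limitations

* The bleach pipeline assumes the bundle is aligned with the image axis
  (as in the experimental protocol); there is no re-orientation step.
* No particle detection/linking from raw movies — tracks are inputs.
* The scattering model omits axial (monomer-repeat) peaks, instrument
  smearing beyond bin averaging, and arbitrary hierarchical geometries.
* Each curve is fitted independently; there is no global multi-curve
  (PEG-series) fit.
* The coexistence classification from kymographs (third residual line) is
  heuristic and tested only qualitatively.
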