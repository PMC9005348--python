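# Methods note

This note records the forward model, the default parameters and why they
were chosen, what the synthetic-data generator does and does not emulate,
the numerical choices, and the known limitations. Everything quantitative
below is computed by the package; run the worked example in `README.md` or
the test suite to regenerate the numbers.

## 1. Forward model of Ca²⁺-dependent photo-switching

### Binding

Equilibrium occupancy follows a single-site Hill isotherm

```
f(ca) = ca^n / (kd^n + ca^n)
```

with dissociation constant `kd` (µM) and Hill coefficient `hill_n`
(default 1). Only the Ca²⁺-bound pool is bright and photo-switchable; the
free state contributes a constant dim signal `eps_free · (1 − f) ·
brightness` and does not switch.

### Switching kinetics

Bulk OFF-switching is modelled as a **two-species mixture**: the switchable
pool decays during 488-nm illumination as

```
S_sw(t′) = f · [ α · e^(−σ_fast · I · t′) + (1 − α) · e^(−σ_slow · I · t′) ]
```

with the mixing weight tied to occupancy, `α = f(ca)`. This is the minimal
mechanism that makes the *effective* (single-exponential) decay constant a
monotone function of Ca²⁺: at saturation the fast species dominates
(τ → 1/(σ_fast·I)), at low occupancy the slow species does. The identity of
the two species (conformational vs protonation sub-populations) is not
modelled; only their kinetic signature is.

During 405/420-nm phases both species recover toward the ON state at rate
`σ_on · I`. Switching rates scale **linearly** with intensity `I`;
saturation of the photo-switching rate is deliberately not modelled.

Additional terms: an additive, non-modulating `dark_offset` (detector and
residual background, not scaled by fluence) and multiplicative photo-fatigue
— the switchable amplitude shrinks by `fatigue_per_cycle` at every ON→OFF
phase boundary after the first.

### Time base

Samples live on the pulse grid (pulse index / pulse rate; default 10 Hz) and
are averaged in blocks of `pulses_per_frame` consecutive pulses into frames;
a frame's timestamp is the mean time of its pulses. Frames never straddle
phase boundaries (validated at construction). The tomography preset is ten
cycles of 120 pulses at 488 nm plus 120 pulses at 420 nm, with 3-pulse frame
averaging by default.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| `kd` | 72 µM (`er_sensor`) / 0.35 µM (`oa_sensor`) | ER-lumen–matched affinity; cytosolic-range affinity placing the transition inside the 0–39 µM calibration ladder |
| `hill_n` | 1 | single-site binding unless configured otherwise |
| `brightness` | 100 a.u. | signal scale only; all analyses are scale-invariant |
| `eps_free` | 0.1 | dim non-switchable free state (small but nonzero) |
| `sigma_fast` | 1.0 s⁻¹/a.u. | sets the saturating decay to τ = 1 s at unit intensity, resolved by 10-Hz pulsing |
| `sigma_slow` | 0.3 s⁻¹/a.u. | ~3× separation from the fast species: large enough for a measurable τ–Ca²⁺ dose response, small enough that single-exponential effective fits remain well conditioned |
| `sigma_on` | 5.0 s⁻¹/a.u. | ON recovery essentially completes within each 420-nm phase |
| `fatigue_per_cycle` | 0.005 (presets) | low photo-fatigue; 0 in the base type |
| `dark_offset` | 0.5 a.u. (presets) | small non-modulating residual |

These values are *study conditions* for the synthetic experiments: they were
fixed once, from the physics above, before the tests were written, and the
tests then characterise the pipeline under exactly these conditions.

## 2. Synthetic-data generator

What it emulates:

* **Titrations** — equilibrium signal `dark_offset + brightness·[eps_free +
  (1−eps_free)·f(ca)]` with multiplicative Gaussian replicate noise of a
  given CV.
* **Spectrometer decay series** — per concentration, `n_rep` (default 6)
  simulated 488-nm decays averaged and max-normalised.
* **Tomography phantoms** — tube cross-sections (sensor at set free-Ca²⁺
  levels, blood as static absorber) in a 2-D image; local fluence
  `I(x,y) = exp(−mu_eff · depth)` measured from the illumination side scales
  *both* the switching rates and the signal amplitude (linear optoacoustic
  regime); blood pixels emit `strength · I` constant in time; background is
  0; additive Gaussian frame noise; ground-truth layout embedded in the
  output.

What it does **not** emulate: acoustic propagation and transducer response,
tomographic reconstruction artifacts, motion, multispectral unmixing,
diagonal illumination (depth is axis-aligned by convention), photoswitching
saturation, and shot-noise statistics (noise is additive Gaussian).

All generators are bit-reproducible under a fixed integer seed; the pipeline
fans one master seed out per stage via a CRC-32 hash of the stage name.

## 3. Analysis stages and numerical choices

* **Exponential fits** — unweighted least squares of `A·e^(−t/τ) + y₀`
  (Levenberg–Marquardt via `scipy.optimize.curve_fit`, tolerance 1e−10, at
  most 10⁴ evaluations), with a log-linear initial τ estimate. A fit is
  flagged `valid=False` — never an exception — when the amplitude falls
  below a floor of 3× the trace noise estimate (1.4826·MAD of first
  differences / √2).
* **Global biexponential fits** — variable projection: per-trace amplitudes
  and offsets are solved linearly for any rate pair, and a Nelder–Mead
  search runs over the two shared log-rates only, multi-started around the
  best global single-exponential rate. Because the single-exponential model
  is nested (equal rates), the reported biexponential residual is never
  larger than the single-exponential one.
* **Pixel classification** — two measures per pixel: (i) the magnitude of
  the cycle frequency (`n_cycles` periods per record) of the mean-subtracted
  frame spectrum divided by the summed magnitude of all non-DC frequencies,
  and (ii) the r² of a free-offset exponential fit to the cycle-averaged
  488-nm decay. The mask is `score ≥ theta_f AND r² ≥ theta_r` (defaults
  0.2 / 0.8). The r² polarity is configurable
  (`switchable_r2_high=False` selects `r² ≤ theta_r`) because the verbal
  description of this filter is ambiguous; the default requires switchable
  pixels to fit the exponential *well*.
* **τ maps** — cycle-averaged 488-nm decays fitted with the offset **fixed**
  to the y₀ obtained from a reference ROI on the highest-Ca²⁺ sample
  (free-offset fit of the ROI-mean trace). Cycle averaging before fitting
  (rather than concatenated fitting) reduces per-pixel noise by √n_cycles.
* **Dose–response calibration** — 4-parameter logistic in
  `c = log₁₀(ca/µM)`:
  `τ(c) = τ_min + (τ_max − τ_min) / (1 + 10^((c − log_ec50)·h))`.
  With endpoint fixing, `(τ_min, τ_max)` are *solved linearly* at every
  candidate `(log_ec50, h)` so that the curve passes **exactly** through the
  measured τ at the two anchor concentrations, and only `(log_ec50, h)` are
  optimised (Levenberg–Marquardt, multi-start in slope). A 0 µM anchor is
  the `c → −∞` limit and reduces to pinning the zero-Ca²⁺ asymptote.
  Inversion is closed-form; τ outside `(τ_min, τ_max)` clamps to the
  corresponding endpoint with a flag.
* **Binding-curve fit** — Hill isotherm by bounded least squares; standard
  errors from the linearised covariance (no bootstrap). A fitted Kd more
  than two orders of magnitude outside the titrated range raises an
  unidentifiability error.
* **SRM analyses** — pump-probe cycles are averaged, fitted biexponentially
  (same variable-projection machinery) and summarised by the
  amplitude-weighted average rate `(A₁k₁ + A₂k₂)/(A₁ + A₂)` and the
  end-of-phase plateau as a fraction of initial fluorescence. FWHM values
  come from a two-Gaussian + constant fit (`FWHM = 2√(2 ln 2)·σ`). The
  dual-Gaussian PSF mixes a 50-nm and a 175-nm FWHM Gaussian with the wide
  peak at 10% of the narrow peak (peak-matched by default; area-matched
  selectable), truncated at ±3σ of the wide component and normalised to unit
  sum. Richardson–Lucy deconvolution uses symmetric (reflective) padding in
  the forward convolution and the *exact adjoint* of that padded operator in
  the correction step, which makes the total intensity of the estimate equal
  to that of the input after every iteration (verified to 1e−6 in the
  tests); default 5 iterations.

## 4. Limitations

* τ is a **relative** Ca²⁺ readout: fluence scales the local switching
  rates, so uncorrected depth-dependent attenuation biases τ upward with
  depth (the generator reproduces this confound; the pipeline does not
  correct it).
* The two-species mixing rule (`α = f`) is a convention; any monotone
  mapping from occupancy to species weights yields qualitatively identical
  behaviour, and the calibration stage absorbs the difference.
* Effective-τ fits of genuinely biexponential decays are summary statistics,
  not rate estimates; they are validated against a grid-search oracle, not
  against the generating rates.
* A 0 µM sample has no measurable decay in this model (the free state does
  not switch), so kinetic calibration ladders must use buffered nonzero
  concentrations, with 0 µM representable only as the fixed `τ_max`
  endpoint of the dose–response.
* Gaussian additive noise approximates detector noise only; photon shot
  noise and reconstruction-correlated noise are out of scope.
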