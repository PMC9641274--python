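# Methods

This note records the models, parameter choices and numerical conventions
behind `thzburn`, and what the synthetic testbed does and does not show
about real measurements.

## Measurement model and simulator

A reflection-mode THz-TDS imager pressed against skin through a dielectric
window records, per pixel, an electric-field trace containing the
air/window reflection at `tau1` and the window/tissue reflection at
`tau2`. The simulator models the probing pulse as a peak-normalised Ricker
pulse (negative second derivative of a Gaussian): single-cycle, exactly
DC-free, with amplitude spectrum ∝ f²·exp(−2π²σ²f²). The width parameter
σ is set from the *intensity-envelope* FWHM (`pulse_width`, default 2 ps,
σ = FWHM / 2√ln 2 ≈ 1.2 ps), putting the spectral peak at
1/(πσ√2) ≈ 0.19 THz — inside the 0.1–1 THz band such scanners use.
Halving the width doubles the spectral peak exactly.

The tissue reflection is the pulse filtered in the frequency domain by a
two-parameter response `rho · exp(−beta·f)` (f in THz): `rho` a broadband
reflectivity scale, `beta` a spectral-tilt rate. This is deliberately the
simplest family that produces a severity-ordered feature contrast; it is
*not* a biophysical (e.g. Debye) model of skin hydration, and the default
ladder

| class | rho | beta (1/THz) |
|-------|-----|--------------|
| H     | 0.85 | 0.3 |
| SPT   | 0.70 | 0.9 |
| DPT   | 0.55 | 1.8 |
| FT    | 0.40 | 3.0 |

is a design choice, not an estimate from porcine data. Because ESER is
invariant to the overall amplitude of the gated trace, `rho` largely
cancels; the monotone decrease of mean in-band ESER with severity is
driven by `beta`: a steeper tilt narrows the reflected band, stretches the
gated pulse in time, raises the coefficient entropy, and lowers E/H.

Per site, one global integer-sample timing shift (uniform in
±`drift_max`, default 8 samples) emulates mechanical drift; per pixel,
white Gaussian noise is added at `snr_db` (default 30 dB, relative to the
clean trace's mean power). Biopsy pixels additionally receive a
Fabry–Perot echo (`fp_amp`, default 0.5 of the tissue pulse) delayed by
`fp_delay` (default 6 ps) — the signature of the air gap a punch biopsy
leaves. Corner pixels are flagged invalid (housing vignetting). The air
reference is the bare air/window reflection at 20 dB better SNR.

Two scales are provided. The full-scale default samples 6144 points at
dt = 0.01 ps (Nyquist 50 THz), so the 25-ps gate holds 2500 samples and
level-12 trees reproduce the conventional in-band sub-bands n = 10–80
(0.122–0.989 THz). `demo_config()` samples 1024 points at dt = 0.05 ps
with a 12.8-ps gate (256 samples) for level-8 trees — the scale used by
the test suite and the end-to-end benchmarks, chosen so a full experiment
runs in seconds while exercising identical code paths. `tau1` = 14 ps
(full) / 8 ps (demo) leaves room for the symmetric gate around the air
reference's principal reflection.

Label generation respects the histology thresholds (dermal-burn depth:
H = 0, SPT < 60, DPT ∈ [60, 90], FT > 90 %) and draws day-28
re-epithelialisation negatively correlated with severity (H always 100%;
SPT mostly healed; FT never). A *null* configuration — identical
`(rho, beta)` for every class — is the intended way to calibrate
chance-level behaviour; the strictly-decreasing-`rho` validation applies
only when all four ladder rungs are configured, precisely so that null
scenarios remain expressible.

### What the simulator does not emulate

Dispersion and etalon effects of the imaging window, rough-surface and
Mie scattering (only their *mitigation* — spatial averaging — is
implemented), spatially heterogeneous burns within a site, timing-jitter
beyond a global integer shift, and any physiological relation between the
spectral response and actual tissue water content. Passing tests
therefore demonstrate the correctness and statistical sanity of the
*analysis*, not clinical performance on real wounds.

## Conditioning

- **Band-pass** (0.1–1 THz): zero-phase frequency-domain mask, unity in
  band with raised-cosine tapers of width 10% of each band edge, zero
  beyond. Zero phase keeps the reflection peaks where gating expects
  them; out-of-band tones are suppressed below 1%.
- **Alignment**: integer-sample circular shifts maximising the
  cross-correlation of the gated first reflection against a template. The
  default template is the site median (per-pixel jitter); the pipeline
  aligns against the band-passed air reference, which carries no site
  drift, so the generator's global shift is recovered too. Sub-sample
  interpolation is deliberately not attempted. A pixel whose reference
  gate is identically zero cannot be aligned and is marked invalid.
- **Biopsy detection**: energy in a gate bracketing the expected echo
  (`tau2 + fp_delay` − 2.5 … + 3.5 ps), thresholded at
  median + k·MAD over the site with the normal-consistent MAD scaling
  (k = 5 ≈ five robust standard deviations). The strict `>` comparison
  keeps a noise-free uniform site fully valid. Corners are always
  invalid.
- **Gating**: Blackman window of 25 ps (demo: 12.8 ps) centred on the
  absolute-amplitude peak of the tissue reflection, cropped to the window
  support — output length is fixed at `round(width/dt)` samples. For a
  cube, the centre is located on the valid-pixel *mean* trace so every
  pixel keeps a shared time axis (after alignment the peaks coincide; a
  shared centre avoids one-sample jitter from noise). A gated trace
  carries its gate in metadata and re-gating with the same spec is a
  no-op: a literal second multiplication would square the window, so
  idempotence is provided at the contract level, which is what "gating an
  isolated pulse again changes nothing" can soundly mean.
- **ROI averaging**: non-overlapping 5×5 tiles; a tile containing any
  invalid pixel is dropped entirely (averages are always over exactly 25
  pixels, keeping observations commensurate). Overlapping/sliding ROIs
  would inflate the effective sample size with near-duplicate
  observations and undermine the ROI-level split, so they are not
  offered.

## MODWPT

Implemented from scratch (no installed package provides it): the circular
recursion over levels with the n-mod-4 filter-selection rule, which both
compensates the spectral flip of high-pass branches and delivers the
terminal sub-bands in sequency order — sub-band n nominally occupies
[n, n+1]·f_Nyq/2^J. Daubechies coefficient values come from PyWavelets;
the maximal-overlap rescaling is 1/√2, the unique choice that makes
|G̃(f)|² + |H̃(f)|² = 1 and hence the transform exactly energy-preserving
(a ½ rescaling fails this by a factor 2 per level; the tests pin the
conservation to 1e-8 relative). Boundary handling is circular — the
standard maximal-overlap convention, required for exact conservation, and
benign here because the Blackman gate drives the trace to ≈0 at both
ends. When only selected sub-bands are requested, only ancestral branches
are evaluated (pruned tree), and nodes of a level sharing a filter are
processed as one batched array operation; pruned results equal the
corresponding full-tree rows bit for bit.

The independent oracle used in tests multiplies the input DFT by the
cascade product of up-sampled filter transfer functions — a different
algorithm and domain, agreeing with the cascade to better than 1e-9.

## ESER features

Entropy uses the natural logarithm (the deconvolved ratio is provably
base-invariant, which the tests check in nats vs bits). The energy-ratio
denominator is the energy of the gated, band-passed trace fed to the
transform — within this pipeline that *is* the original signal, and it
makes E sum to exactly 1 over a full tree. A sub-band holding less than
1e-12 of the input energy is declared degenerate: its probability
sequence is undefined, so H := 0 and ESER := 0, flagged — features stay
finite without inventing information. The air reference is conditioned
identically to tissue (band-pass, then the same-width Blackman gate on
its principal reflection) so the element-wise ratio cancels the
instrument response coherently; a degenerate air sub-band among the
selected indices is an error naming the sub-band, never a silent NaN.

Sub-band selection: either an explicit index range (default 10–80 at
J = 12) or all sub-bands whose nominal passband overlaps a frequency
interval. The two agree up to edge sub-bands whose passbands straddle the
interval boundaries.

## Classification

- Severity thresholds are read as SPT < 60 ≤ DPT ≤ 90 < FT (the middle
  interval closed, consistent with the strict outer inequalities) and
  healing FR exactly at 100% closure.
- Splits are stratified 80/20 at ROI level — with unbalanced classes an
  unstratified 20% draw can lose a class entirely. A class with fewer
  than two observations cannot be split and raises.
- Model selection is one exhaustive search over SVM hyperparameters ×
  wavelet × level, by minimum mean five-fold CV misclassification loss
  (stratified, seeded folds); ties go to the first candidate in grid
  order. The "validation" metrics reported are the winner's five-fold
  estimates; the final model is refit on the full training set.
- Kernel scale follows the K(x,y) = exp(−‖x−y‖²/s²) convention
  (gamma = 1/s²); the polynomial kernel uses coef0 = 1 so lower-order
  terms are present. Default grids are 7-point log grids over 10⁻²…10²
  for scale and box constraint — the tuned quantities are fixed, their
  grids are a package choice.
- Features are z-scored per sub-band inside each fitted pipeline, so
  scaling statistics see training folds only. Cohort-level feature
  matrices are cached per (wavelet, level) — ESER is computed per
  observation with no cross-observation statistics, so the cache cannot
  leak labels or test data; a label-permutation canary in the acceptance
  tests confirms chance-level behaviour.
- Probabilities: binary and one-vs-all models use a Platt-style sigmoid
  fitted on training folds (`CalibratedClassifierCV`, `ensemble=False`);
  the one-vs-one coding has no native probability, so per-class decision
  scores are shifted to be non-negative and normalised to sum to one —
  adequate for argmax prediction and rank-based AUC, not for calibrated
  risk. One-vs-all instantiates 4 binary learners on the four-class task,
  one-vs-one 6.
- Metrics: sensitivity, specificity, accuracy and ROC-AUC in percent;
  AUC is scikit-learn's tie-aware implementation (normalised
  Mann–Whitney). Multiclass metrics are one-vs-rest per class plus plain
  overall accuracy. Single-class ground truth is an error, not a silent
  100%.
- Decomposition levels are restricted to 8–13 and polynomial orders to
  2–20 by grid validation; deeper trees cost memory and time without
  adding in-band resolution at these sampling rates.

Site-level (rather than ROI-level) splitting would be the stricter
protocol — ROIs of one site share drift and tissue response — and is not
offered as an evaluated mode; the end-to-end benchmarks inherit whatever
optimism ROI-level splitting carries, which the null calibration bounds.

## Problem sizes of the shipped benchmarks

The test suite and the acceptance script run at the demo scale: 25×25-px
sites (21 usable ROIs after corner masking), 256-sample gated traces,
level-8 trees with ~24 in-band sub-bands, 5 split iterations, and reduced
tuning grids (Gaussian kernel, 3 scales × 2 box constraints, db1/db3 at
J = 8). The severity-ladder check runs at the full default scale (2500
gated samples, J = 12, sub-bands 10–80). These sizes are the package's
own choice of a fast, convincing demonstration; all knobs scale up through
the public API and the CLI configuration.

## Known limitations

- The simulator's effect sizes are free parameters; accuracy numbers on
  synthetic data characterise the pipeline, not the clinical method.
- One-vs-one probabilities are normalised scores, not calibrated.
- Alignment is integer-sample only.
- The HDF5 layout follows the dotTHz spirit (per-measurement groups,
  time-axis attributes) but is not a byte-level implementation of that
  specification; no proprietary vendor formats are read.
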