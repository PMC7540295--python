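# Methods

## The measurement model

A quenched sample from a nucleobase-cleavage reaction, measured in a
UV-transparent 96-well plate over 250–350 nm in 1 nm steps, obeys
additive absorbance:

    A(λ) = c_N R_N(λ) + c_B R_B(λ) + b(λ) + ε(λ)

where R_N, R_B are the alkaline reference spectra of the nucleoside and
its nucleobase, b(λ) is background (plate, protein, solvent or a flat
shift) and ε is measurement noise. The assay's key structural fact is the
isosbestic point of base cleavage: a wavelength λ_iso where both species
share one extinction coefficient. Dividing a background-free spectrum by
A(λ_iso) cancels the total analyte amount — and with it dilution and
pipetting variation — leaving a pure shape whose decomposition gives mole
fractions directly. Conversion is x = c_B/(c_N + c_B); by symmetry,
swapping the two references maps x to 1 − x.

Assumptions: exactly two absorbing analytes; reference and sample spectra
recorded under the same quench/pH condition; backgrounds additive and
either subtractable (a matching blank) or confined outside the fitting
window; analytes stable over the analysis window.

## The fit

`UnmixingModel` solves min ‖A − c_N R_N − c_B R_B‖² subject to
c_N, c_B ≥ 0 (active-set NNLS). Non-negativity is enforced in the solver,
not by post-hoc clipping, because clipping one coefficient biases the
other; an unconstrained variant exists for diagnostics. Least squares is
unweighted over the fit range. There is no offset term by default —
baseline-shifted samples are excluded, not repaired — but
`fit_offset=True` adds a free flat column (bounded-variable least
squares) for exploratory use.

Standard errors are ordinary LS covariance with σ² = RSS/(n − p); the
conversion SE uses the delta method on c_B/(c_N+c_B). Both are reported
as NaN when a coefficient sits on the non-negativity boundary, where the
linear approximation is invalid.

An independent oracle, `brute_force_unmix`, scans conversion on a uniform
grid, profiling out the total amount analytically at each grid point. It
spans the same non-negative quadrant but shares no code with the solver;
tests require agreement to the grid resolution.

For pairs without an isosbestic point (ribavirin-like), the two-wavelength
mode solves the exact 2×2 response system at two calibration wavelengths
(condition-number guarded); the one-wavelength mode additionally needs the
known total amount. Negative solved amounts are clipped and flagged
`clipped` here, since an exact solve has no constrained variant.

## Preprocessing order and QC

Fixed order: subtract blanks → estimate/flag baseline → restrict to the
fit range → normalize at λ_iso. Normalization must come last so it sees
background-free absorbance at the isosbestic point.

- **Baseline estimator.** Mean absorbance over the analyte-free window
  (spectral extension + 5 nm, up to 350 nm]; ≥ 5 grid points required.
  Beyond the spectral extension neither analyte absorbs, so anything
  there is background. Flag when the offset strictly exceeds 0.10 AU;
  flagged samples are excluded from fits (the bench remedy is
  remeasurement in a different well — no manual spectral repair).
- **Noise floor.** Normalization refuses when A(λ_iso) ≤ 0.05 AU: at
  typical noise σ ≈ 0.002 AU this caps the normalization-induced
  relative error at ~4 %. Not an instrument constant; override per run.
- **Signal-to-background.** Peak |signal| / peak |background| over the
  fit window must stay above 5 (the "background below 20 % of signal"
  rule of thumb); below it the sample is flagged `low_snr`, not dropped.
- **Restricted windows.** Solvent backgrounds (DMSO/DMF-like) rise
  steeply below ~280 nm; fitting only the information-rich tail (for a
  uridine-like pair, 265–295 nm) sidesteps them provided λ_iso lies
  inside the window.
- **Fit-quality flags.** `poor_fit` when RMS residual > 0.01 normalized
  units; `coef_sum_anomaly` when |c_N + c_B − 1| > 0.10 after isosbestic
  normalization. Both thresholds are this package's own calibration:
  clean synthetic data never trips them, 20 %-background data does.

## Series and equilibrium

`check_isosbestic_constancy` computes (max − min)/median of the raw
A(λ_iso) across a series; a constant-volume series should show only
noise, and a single mis-pipetted sample appears as a step (warn above
0.10 relative — the acceptable drift is not standardized anywhere, so
this default is ours).

`detect_equilibrium` fits a straight line in every trailing window of 5
points and declares the plateau at the earliest time from which all later
windows have |slope| < 1e-4 s⁻¹; the equilibrium conversion is the mean
over the plateau. Flagged points are excluded from slope fits and the
mean but stay in the series. The detection time is monotone
non-increasing in the slope tolerance. Samples older (since quench) than
a reference's stability window (e.g. ~600 s for base-sensitive
fluorinated purines) are flagged `stability`, not dropped.

## The synthetic world

The generator emulates what the method assumes, not a spectrograph:

- **Band shapes.** One or two Gaussians per component. The nucleobase is
  rescaled so the two shapes are exactly equal at the designed isosbestic
  wavelength, guaranteeing the crossing (verified by a sign-change scan).
  The default pair mimics thymidine/thymine: λmax 266/290 nm, isosbestic
  278 nm, spectral extension 320 nm, pH 13 quench. A uridine-like pair
  (262/281, iso 271, extension 310) serves the restricted-window cases.
- **Noise.** i.i.d. Gaussian, σ = 0.002 AU by default — realistic for
  plate readers at the assay's typical 0.5–0.8 AU peak signals.
- **Pipetting jitter.** Multiplicative lognormal (log-sd 0.05), on by
  default in reaction series so that the normalization's central claim
  is exercised rather than assumed.
- **Backgrounds.** Four archetypes: plate (≈0.03 AU at 300 nm, curving
  up toward 250 nm), flat shift (default 0.12 AU), protein (Gaussian
  tail centered at 280 nm) and solvent (monotone rise below a cutoff,
  exactly zero above it).
- **Kinetics.** First-order approach x(t) = x_eq(1 − e^{−kt}); defaults
  x_eq = 0.8, k = 0.01 s⁻¹, sampled every 30 s to 3000 s. The horizon is
  chosen so the plateau-mean truncation bias of the equilibrium detector
  is below 1e-3 on the noiseless curve.

Everything is seeded and bit-for-bit reproducible, and every simulated
dataset is returned with its ground-truth conversions.

What a green test on this world does **not** establish: correctness on
real instrument artifacts (wavelength miscalibration, stray light,
detector nonlinearity), non-Gaussian lineshapes, pH-drifting spectra
(chlorinated purine scaffolds above pH 11 are only representable here as
a metadata constraint), correlated noise, or more than two absorbing
species.

## Numerical choices

- Grid handling: references are linearly interpolated onto the sample
  grid, only inside their own range — extrapolation is an error. At 1 nm
  spacing of smooth bands this is loss-free in practice.
- References are stored normalized (1 at the active isosbestic point)
  with the pre-normalization scale recorded, so raw spectra are
  recoverable.
- Two listed isosbestic points (5-ethynyluridine-like): default is the
  point with the larger common absorbance (better normalization S/N);
  an explicit override always wins.
- Collinearity guard: reference shapes correlating > 0.999 over the fit
  range are rejected as indistinguishable.
- Baseline flag comparison is strict (> 0.10 AU, not ≥).
- The spectra CSV round-trips exactly: written at full float repr
  precision, parsed with round-trip float conversion.

## Known limitations

- Two components only; transglycosylation mixtures with three or more
  simultaneous absorbers are out of scope.
- No absorbance-to-concentration calibration: conversions are mole
  fractions of the modeled pair, not absolute concentrations.
- No smoothing, derivative spectroscopy or scatter correction — the
  workflow deliberately avoids manual spectral processing.
- The equilibrium detector reports the plateau of the sampled curve; a
  reaction still drifting slower than the slope tolerance will read as
  equilibrated.
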