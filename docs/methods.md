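# Methods

## Model

The quantification model is linear throughout. A chromatogram is a detector
signal sampled on a strictly increasing retention-time grid (minutes); the
default synthetic grid uses the common instrument cadence of one point
every 0.5 s (0.00833 min) starting at 0.00667 min. For analyte *j* at
concentration `c_j` (mM), detector *i* records a peak whose integrated area
over a fixed retention window is `m_ij·c_j`, where `m_ij` is the
calibration slope (signal·minutes per mM, signed). Mixtures superpose:
the area vector of a mixture is `A = M·C`. Solving that system is the whole
method; no peak-shape fitting, baseline modeling, or retention-time
alignment is involved.

Two physical facts shape the implementation. First, calibration lines pass
through the origin by construction (`m = Σ a_i c_i / Σ c_i²`), because a
blank produces no peak; fitting a free intercept and discarding it would
let noise leak into the slope. Second, slopes may be negative or nearly
zero: an analyte that absorbs less UV light than the mobile phase (glycerol
at 210/270 nm) produces a genuine negative peak, and its near-zero 270 nm
slope is kept as fitted — the matrix diagnostics, not the individual fit,
decide whether the system is solvable.

## Integration

Areas are computed by the trapezoidal rule on the native grid, which is
exact for the piecewise-linear signal model and — the property the method
depends on — exactly linear in the signal. Window endpoints that fall
between samples are handled by linear interpolation, making the area
continuous in the window bounds. No baseline or blank subtraction is
applied by default; the raw signal, negative lobes included, is what the
linear model describes. An optional linear-baseline subtractor
(`subtract_linear_baseline`) exists for drifting instruments but is never
invoked implicitly.

## Numerical choices

- Rank is decided from singular values with relative tolerance 1e-10 of the
  largest singular value; the condition number is the 2-norm ratio of
  extreme singular values.
- A solvable but ill-conditioned matrix (condition number > 1e6) is solved
  with a warning: at that conditioning, 0.1% area noise can become total
  concentration error.
- Square systems are solved by LU factorization rather than forming M⁻¹
  explicitly; with more detectors than analytes the least-squares solution
  is used, and it reduces to the square solve when the extra rows are exact
  linear consequences.
- Negative solved concentrations are returned and flagged, never clipped:
  truncation would silently hide calibration faults.
- Reported values follow a 3-significant-figure convention (`round_sig`);
  `additivity_check` optionally applies the same rounding to the component
  sum so discrepancy percentages match figures quoted at 3 s.f.
- The Faraday constant is fixed at 96485 C/mol so charge-bookkeeping
  examples are exact. The Ag/AgCl→RHE conversion defaults to a 0.197 V
  reference offset and a 0.059 V/pH Nernst term, both overridable.
- Percent errors use the true (nominal) concentration as denominator.

## The synthetic generator

`synth` emulates what the linear model assumes about real chromatograms:
unit-area Gaussian peaks (or exponentially modified Gaussians for tailing)
at fixed retention times, scaled by signed per-(analyte, detector) response
factors times concentration, plus optional linear baseline drift and
seeded additive Gaussian noise on the trace. It does **not** model column
physics (van Deemter broadening, temperature effects, gradient elution),
retention-time jitter between injections, detector saturation, or the slow
spontaneous conversion of glycerol into oxidation products during
separation. Passing tests therefore demonstrate that the algebra and its
implementation are correct under the model's assumptions — not that those
assumptions hold on any particular instrument, where retention drift and
chemistry can add percent-level area discrepancies.

`make_gor_scenario` fixes the default study conditions: five analytes
(glycerol, DHA, FA, glycolaldehyde, glyceraldehyde) eluting at 13.6, 13.8,
14.4, 13.1, and 12.0 min with widths of 0.07–0.10 min, so the glycerol and
DHA peaks merge; three quantification channels (refractive index, UV at
210 and 270 nm) integrated over 13.2–15.5 min; and the two validation
mixtures, glycerol/DHA/FA at 500/5/5 mM (the concentration regime of a
typical photoelectrolysis experiment) and at 100/100/100 mM. The
refractive-index response factors are anchored to the benchmark
single-analyte areas (500 mM glycerol → 177, 5 mM DHA → 1.57, 5 mM FA →
0.319 counts·min); UV factors follow the qualitative detector behaviour —
glycerol weakly negative at 210 nm and almost null at 270 nm, DHA and FA
comparable at 210 nm, FA's 270 nm sensitivity 0.2% of DHA's. FA's
retention time (14.4 min) and the UV factor magnitudes are fixture choices
where no measured value exists; the resulting matrix has condition number
≈ 5, comfortably solvable. A fourth channel (UV 205 nm) ships with response
factors exactly proportional to the 210 nm channel, providing a deliberate
rank-2 configuration for exercising the solvability diagnostics. Scenario
noise defaults to zero — the noise-free limit is the baseline condition;
noisy studies set `noise_sd` (trace noise) or perturb areas directly.

Calibration series default to 100–500 mM for glycerol and 1–10 mM for the
products, spanning the concentrations the validation mixtures use.

## Design choices where the design was open

- Window truncation: the integration window clips < 1e-6 of each peak, and
  because calibration and mixture areas are truncated identically, the
  truncation cancels exactly in the calibrate→solve round trip.
- Determinism: every random draw flows through a `numpy` Generator seeded
  from the model's `seed`, so simulated data is byte-reproducible through
  the CSV writer (which emits 6 significant digits — the declared
  interchange precision).
- Problem sizes: the verification suites use 1000 random 3×3 systems and
  100 noise replicates per mixture, enough to pin the solve's numerical
  behaviour while keeping the full suite under a few seconds.
- The CLI is a thin veneer: every subcommand calls the same library
  functions the examples use, with exit codes 0 (success), 2 (input
  error), 3 (numerical failure such as a rank-deficient calibration).

## Known limitations

- Only the square (k detectors, k analytes) and tall cases are supported;
  fewer detectors than analytes is rejected outright rather than
  regularized.
- Uncertainty reporting stops at the residual norm and condition number;
  no error propagation from calibration scatter to concentrations.
- The product metrics assume all quantified amounts are non-negative;
  flagged negative concentrations must be resolved upstream before
  selectivity or Faradaic efficiency is computed.
- Experimental headline selectivities from real photoelectrolysis runs
  cannot be reproduced here: they require the raw instrument chromatograms
  and cell parameters that are not part of this package's inputs.
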