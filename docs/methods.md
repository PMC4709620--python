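# Methods

## The system being modelled

The pipeline emulates a reversed-phase HPLC-UV plasma assay for
clopidogrel (CLP), its carboxylic acid metabolite (CCA) and atorvastatin
(ATV), quantified against an ibuprofen internal standard (IS), followed
by one-compartment pharmacokinetic analysis of patient plasma profiles.
The four peaks elute at 9.663 (CCA), 10.998 (ATV), 11.802 (IS) and
12.682 (CLP) minutes within a 20-minute run; plasma is sampled pre-dose
and at 0.25, 0.5, 1, 3, 6, 9 and 12 h after oral dosing.

## Simulation model

**Chromatograms.** Each peak is a Gaussian of width σ (minutes) or, with
tail constant τ > 0, an exponentially modified Gaussian
(`scipy.stats.exponnorm`, K = τ/σ). The EMG choice lets the simulator
produce non-unit tailing factors and so exercise the suitability code;
`retention_time` is the Gaussian component centre, and a tail shifts the
apex slightly later, as it does physically. Peak areas are specified in
signal·seconds while the time axis is minutes; the generator deposits
area/60 per minute so that the numerically integrated area equals the
specified one. Baseline noise is additive Gaussian (detector noise is
approximately signal-independent at these absorbances). Default peak
σ = 0.05 min and area 50 signal·s give plate counts in the 4·10⁴ range —
sharper than a typical 250 mm column, but the suitability metrics are
scale checks, not instrument reconstructions.

**Concentrations.** Plasma curves follow the Bateman solution of the
one-compartment oral model, Cp(t) = A(e^(−Ke·t) − e^(−Ka·t)) with
A = F·D·Ka/(V(Ka − Ke)). The degenerate case Ka = Ke has a different
functional form (A·Ke·t·e^(−Ke·t)) and is rejected rather than silently
substituted. Assay noise is multiplicative lognormal with unit mean and
specified CV (default 5%): concentrations stay positive and the CV is
scale-free, matching how assay imprecision is reported. Values below the
LLOQ are retained but flagged censored. All randomness flows from one
explicit integer seed per call (`numpy.random.default_rng`); there is no
global state.

**Simulated patients.** The packaged config gives three patients the
elimination constants, peak times and peak concentrations of the
clinical magnitudes the assay was built for (CLP Ke ≈ 0.6–1.0/h with an
early 0.25 h peak near 0.1 µg/mL; CCA Ke ≈ 0.13–0.23/h peaking near
1 h at 3–5 µg/mL; ATV Ke ≈ 0.07–0.08/h peaking at 2.5–3 h below
0.2 µg/mL). Ka is derived by inverting tmax = ln(Ka/Ke)/(Ka − Ke)
(Brent's method) and A from the peak concentration, so the ground truth
is exactly consistent with the model. Per-analyte LLOQs are 0.008 (CLP),
0.01 (CCA) and 0.005 (ATV) µg/mL.

What the simulation does *not* reproduce: matrix effects, carryover,
gradient retention shifts, detector nonlinearity, between-run drifts and
real biological departure from one-compartment kinetics. Passing tests
therefore demonstrate the correctness of the arithmetic and estimators
under the stated model, not assay performance on real extracts.

## Chromatographic measurement

Local maxima come from `scipy.signal.find_peaks` with both a height and
a prominence threshold (prominence filtering keeps baseline noise from
fragmenting a peak). For each apex the baseline anchors are the signal
minima toward the neighbouring apexes (or the trace ends); the baseline
is the straight line between the anchors, and the integration bounds are
where the baseline-corrected signal falls to 1% of the apex height or
the anchor, whichever comes first — bounding at 1% rather than at the
anchors prevents EMG tails from dragging in baseline, while keeping the
baseline anchored at the valleys avoids clipping peak area. Retention
time and height are refined by a three-point parabola around the apex;
widths at 50% and 5% of the corrected height are linearly interpolated
between bracketing samples. Baseline correction makes every measurement
invariant to a uniform signal offset.

The suitability conventions are pharmacopeial, each a single switchable
constant: half-height plate count N = 5.54(tR/W₀.₅)², USP tailing
T = W₀.₀₅/(2f), and base-width resolution with Wb = (4/2.3548)·W₀.₅
from the Gaussian relation. Limit semantics: Rs strictly above 2.0, T at
or below 2.0, N strictly above 2000. S/N uses twice the peak height over
the peak-to-peak excursion of a linearly detrended blank window (at
least 20 samples); a noiseless blank makes S/N undefined and is an
error.

## Calibration

Unweighted ordinary least squares of the analyte/IS area ratio on
concentration (`scipy.stats.linregress`); 1/x² weighting is available
but off by default since no weighting scheme is part of the reference
procedure. Back-calculation inverts the line and *flags* out-of-range
results instead of rejecting them — censoring decisions belong
downstream. LOD and LLOQ are derived from the *height* response slope,
not the area slope, because S/N is a height quantity; with
S/N = 2h/n_pp this gives LOD = 3·n_pp/(2·slope_h) and
LLOQ = 10·n_pp/(2·slope_h), so LLOQ/LOD = 10/3 identically.

## Validation arithmetic

Recovery = 100·mean/nominal; RSD = 100·SD/mean with the sample
(n−1) SD — the convention is not observable from published tables,
which print mean ± SD pairs, so reproduction of those cells is
convention-independent. The ±15% acceptance rule is applied inclusively
(a drop of exactly 15% passes), the common reading of bioanalytical
guidelines. Reports round recovery to whole percent and RSD to two
decimals; full precision is kept internally. Stability, robustness and
degradation tables reuse the same arithmetic; condition labels are
opaque strings.

## Pharmacokinetic estimation

Fitting is done in base-10 logarithms with Ke = −slope·ln10, matching
the classical decadic-slope presentation (the factor is ln10 =
2.302585…, of which 2.303 is the print rounding). Terminal points are,
by default, all quantifiable points strictly after the observed maximum
— deterministic and transparent. The alternative `best_r2` rule (the
usual λz suffix search maximising adjusted r²) is available and is the
better choice when absorption is slow enough to contaminate the first
post-peak samples; on the 0–12 h schedule both rules recover Ke with
median error well under 1% on noiseless profiles.

The method of residuals forms r(t) = 10^(b + m·t) − Cp(t) at the
quantifiable points before the first terminal-fit time and fits their
decadic log-slope; Ka = −slope·ln10. A residual that is nonpositive (or
within float tolerance of zero) means the back-extrapolated line does
not dominate there — a model violation, reported as an error rather than
patched. If the residual rate comes out *below* the terminal rate the
two are not identifiable from curve shape (flip-flop kinetics); the
larger rate is reported as Ka and the result flagged. Explicit terminal
and absorption point sets can be supplied through `PKConfig` for manual
(graphical-method-style) analyses.

AUC₀–t uses linear trapezoids over quantifiable points (log-linear-down
is deliberately not the default: the reference procedure states the
plain trapezoidal rule); AUC₀–∞ adds C_last/Ke. t½ = ln2/Ke and
tmax = ln(Ka/Ke)/(Ka − Ke) hold as exact identities in every result.

## Problem sizes and numerical choices

The parameter-recovery study uses 200 noiseless profiles with Ke
log-uniform on [0.07, 1.0]/h (the clinical range above) and Ka/Ke
uniform on [3, 20], on the eight-point clinical schedule. Draws whose
observed peak lands at 6 h or later leave fewer than three later samples
and are correctly refused by the estimator (~5% of draws); medians are
taken over the estimable ones. Chromatograms are simulated at 5–20 Hz
over 20 min (6 000–24 000 points), ample for sub-0.01-min retention
accuracy via parabolic refinement. Width interpolation is linear;
integration tolerance on synthetic Gaussians is ≲0.5% of area.

## Known limitations

- No deconvolution of overlapping peaks; heavily fused peaks fail the
  retention-window search and surface as missing-analyte failures.
- The residual method needs ≥2 quantifiable pre-terminal points; fast
  eliminators censored early (CLP-like profiles) are reported as
  unestimable, mirroring real sparse-data limits.
- Single detector channel; no gradient retention modelling (the mobile
  phase program is metadata only).
- One-compartment, first-order kinetics only; no lag time, no
  multi-compartment fits, no population modelling.
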