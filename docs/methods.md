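# Methods

`hemequil` implements three quantitative workflows for characterizing the
oligomeric state and heme coordination of plant non-symbiotic hemoglobins
(and self-associating heme proteins generally), together with seeded
simulators that provide ground truth for every stage. This note records the
models, the assumptions behind them, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Monomer–dimer equilibrium from fast-exchange SEC

**Model.** A protein in rapid monomer/dimer exchange elutes from a
gel-filtration column as a *single* peak at the equilibrium-weighted
position between the monomer volume `Vm` and the dimer volume `Vd`. With
the standard log-linear column law (log10 MW linear in elution volume), the
apex `Ve` maps to a percent dimer

    %D = 100 * (2**((Vm - Ve)/(Vm - Vd)) - 1)

and the effective exchange-averaged mass is `MW = A*(1 + %D/100)` for a
monomer of mass `A`, so the apparent mass sweeps from `A` to `2A` as
concentration rises. Total concentration is carried in **dimer
equivalents**, `Dtot = [M]/2 + [D]`; mass action `Kd = [M]^2/[D]` then gives

    Kd = Dtot * 0.04 * (100 - %D)^2 / %D .

Taking logs, `y = log10(%D/(0.04*(100-%D)^2))` against `log10 Dtot` is a
straight line of slope 1 that crosses zero at `Dtot = Kd` (where
%D ≈ 60.96). The estimator fixes the slope to 1 by default — the
unconstrained slope is always computed and reported as a model diagnostic,
with a warning beyond |slope−1| > 0.15 — because the slope is theory, not a
free parameter; a free-slope variant is available (`fix_slope=False`).
A direct nonlinear ("hyperbolic") fit of %D versus `Dtot` in `log10 Kd` is
provided as a cross-check; on clean data the two agree to 1e-6 relative.

**Dilution correction.** Samples dilute on-column; each injection's
correction factor is its peak width at half height divided by the injected
volume (100 µL by default), and `Dtot_corrected = Dtot_loaded / factor`.
The per-injection measured factor is used by default; a fixed global
override is available.

**Assumptions.** Two species only (no higher oligomers), exchange fast on
the chromatographic timescale (single peak), and a log-linear column over
the working range. Points with %D outside [1, 99] carry no usable
equilibrium information under the log transform and are excluded with a
warning; when *every* point is below 1 %D the estimator raises
"no association detected" — the correct call for a monomer-only species
such as AHb2, not a failure.

**Peak metrics.** The trace baseline is the median of the first and last 5%
of samples (instrument offsets are common; the choice is ours). The apex is
refined by a parabola through the three samples around the maximum, the
FWHM by linear interpolation of the half-maximum crossings; ties at the
maximum resolve leftmost with a warning. A disjoint region above half
maximum of at least 3 samples raises a multi-peak error; shorter excursions
are treated as noise so that trace-level jitter near the half-max level
cannot abort an analysis. Because a 3-point parabola on a finely sampled
noisy trace is jitter-prone, the chromatogram-to-equilibrium-point pipeline
smooths each trace with a centered 19-point adjacent average first (about a
quarter of the half-height width of the default synthetic peaks). Boxcar
smoothing adds `w^2/12` to the peak variance, inflating the measured FWHM
by <1% at that setting — negligible against the log-scale concentration
correction it feeds. The window is a keyword argument wherever it applies.

## SEC calibration

Ordinary least squares of log10(MW/kDa) on elution volume over ≥3
standards; apparent mass by inverting the line. The fit uses raw elution
volumes, not the partition coefficient Kav — a Kav formulation needs
measured void/total volumes, which the simulators do not model. A
non-negative slope (big proteins eluting later) is flagged as non-physical.
Extrapolation beyond the standards ±10% of their span warns.

## Ferguson-plot mass estimation

For each protein, the retardation coefficient `Kr` is minus the OLS slope
of `100*log10(100*Rf)` against gel concentration %T (≥3 gels); `Kr ≤ 0`
flags a non-sieving species. The standard curve is OLS of log10(Kr) on
log10(MW); the unknown's mass inverts it. All logs are base 10 — any fixed
base is internally consistent and cancels in the round trip. Ideal Ferguson
behavior is assumed throughout (no gel-to-gel mobility corrections);
densitometry from gel images is out of scope — Rf values are inputs.

## Pentacoordinate fraction from deoxy visible spectra

A ferrous-deoxy spectrum of a partly hexacoordinate globin is modelled as a
two-endmember mixture of a pure hexacoordinate reference (deoxy-AHb2-like:
resolved α/β bands near 555/528 nm with a valley near 540 nm) and a pure
pentacoordinate reference (E7L-like: one broad band near 558 nm). Two
estimators are exposed, and the choice is deliberate — the underlying
published procedure is not fully specified:

* **ratio** — the A555/A540 band ratio of a mixture is a *rational*
  function of f, `r(f) = (f*P555 + (1-f)*H555)/(f*P540 + (1-f)*H540)`, so
  the inversion uses the references' absolute (post-normalization) band
  values, not just their ratios. Solutions outside [0, 1] are clipped with
  a warning.
* **unmix** — non-negative least squares of the spectrum onto the two
  references over 500–600 nm; `f = a/(a+b)`. The free total weight absorbs
  concentration and pathlength, so the estimate is exactly invariant to
  positive scaling of the input. An optional unconstrained constant-offset
  term handles baseline shifts (off by default: with both endmembers
  strictly positive and broad, an offset column is nearly collinear with
  them and slightly degrades noise behavior).

References are area-normalized to 1 over 450–650 nm by default so the
endmembers are commensurate; value-at-wavelength or no normalization are
options. Both estimators recover f exactly on noiseless mixtures and agree
within |Δf| < 0.02 at 0.5% spectral noise.

## Two-state thermal melt

The reported midpoint of a CD-monitored unfolding scan is modelled with the
minimal standard form: linear folded/unfolded baselines joined by a
Boltzmann sigmoid, `f_u(T) = 1/(1 + exp((Tm - T)/w))`. This functional form
is our documented assumption — the measurement it emulates reports only Tm.
Initialization: Tm at the steepest (smoothed) derivative, w = 2 °C,
baselines from the first/last 10% of points. Because a straight line
satisfies the model degenerately, "no transition detected" is raised
post-fit when the midpoint lands within 2% of the scan edges, the width
exceeds half the scanned span, or the step amplitude at Tm is below 10% of
the total signal excursion. These thresholds are heuristics for degenerate
inputs, not tuned quantities. Noiseless recovery is exact to <0.01 °C over
Tm ∈ {40, 50, 65, 80} °C.

## Synthetic data: what it emulates, and what it does not

The simulators generate the *forward* versions of every model above, with
seeded noise; every generator is a pure function of its arguments
(bit-reproducible; a master seed spawns independent per-item streams via
`numpy.random.SeedSequence`, all below 2^31).

* **SEC**: Gaussian peaks on a 6–10 mL grid (0.01 mL step, ~80 samples per
  FWHM), apex from the equilibrium %D at the dilution-corrected
  concentration, FWHM = dilution_factor × load volume, height proportional
  to load, additive noise of 1% of peak height by default. Presets encode
  the four studied species: Kd = 1.2 µM (ferrous-oxy AHb1, 12 log-spaced
  loads over 0.07–85 µM, dilution factor 8), 11 µM (ferric, 0.1–300 µM,
  factor 8), 876 µM (T45A, 1–1000 µM, factor 7) and a monomer-only AHb2
  control (0.1–60 µM, factor 6). The ferric and T45A concentration windows
  are our choices, scaled to bracket each Kd with the oxy design's
  12-point log-spaced layout.
* **Column geometry**: the real column's volumes are unpublished; the
  default places the line log10 MW(kDa) = 3.0 − 0.2·Ve so the AHb1
  monomer (18.034 kDa) and dimer (36.068 kDa) elute at 8.719 / 7.214 mL.
  Configurable via `ColumnModel`.
* **Gels**: `Rf = 0.9·10^(−Kr·%T/100)` with `Kr = 0.5·MW^0.7`,
  multiplicative log-normal Rf noise. The constants are plausible, not
  measured.
* **Spectra**: fixed Gaussian-band reference shapes (hexa: α 555 nm σ 6,
  β 528 nm σ 9; penta: broad 558 nm σ 20; both on a weak broad background),
  mixed at the preset f and given additive noise relative to the spectrum
  maximum. Coordination presets interpolate f linearly in log10
  concentration between the anchor points (wild type 13% at 1 µM → 65% at
  190 µM; T45A flat at 26%).
* **Melts**: the two-state model on a 20–100 °C grid at 0.25 °C steps.

What passing these benchmarks shows: the estimators invert their forward
models correctly and are robust at realistic noise. What it does not show:
behavior on real traces with drifting baselines, asymmetric (tailing)
peaks, column non-ideality (the real AHb2 elutes as ~23 kDa against a
17.9 kDa true mass — deliberately not reproduced), stray-light or
scattering distortions of spectra, or reference spectra that are themselves
imperfectly pure. The unmixing window, normalization and offset options
exist precisely for such data.

## Known limitations

* Single-peak chromatograms only; slow-exchange (two-peak) kinetic SEC and
  higher-order oligomers are out of scope.
* The Manning estimator's per-point variance is strongly %D-dependent; the
  fixed-slope average weights points equally, which is slightly suboptimal
  near the exclusion window edges.
* Ferguson analysis assumes ideal size-only sieving; charge effects are
  not modelled.
* The melt fit reports a width parameter, not a calorimetric enthalpy; no
  baseline curvature is supported.
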