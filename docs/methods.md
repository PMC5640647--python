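# Methods

This note records the models behind magflow, the defaults and why they
were chosen, what the synthetic cytometer does and does not emulate, and
the numerical conventions a user should know before trusting a number.

## Instrument model and data representation

The package targets a single-laser benchtop cytometer with five
area-signal channels: FSC-A and SSC-A (forward/side scatter; proxies for
cell size and granularity), FL1-A (green, 533/30 band-pass: BOX,
Pyr-546, PG-SK, Syto9), FL3-A (red, 670 long-pass: PI) and FL4-A
(far-red, 675/25 band-pass: Syto62). Event tables store intensities on
the **linear** scale as the single source of truth; all log-scale work
(display, threshold placement, mixture fitting) applies
`log_display(x) = log10(max(x, 1))` at use time. The clip at 1 arbitrary
unit keeps the transform defined at zero and mimics how sub-unit signals
pile on the axis of a log dot plot.

Because BOX, Pyr-546 and PG-SK are all read on FL1, one stained sample
cannot simultaneously report viability, PHA and iron. The pipeline
therefore treats a *condition* as up to three separately stained
aliquots (BOX/PI co-stain, Pyr-546, PG-SK), named individually in the
run configuration.

File formats: the FCS writer emits FCS 3.1, single dataset,
little-endian 32-bit float data, `$PnE/0,0/` (linear); this keeps the
writer unambiguous and round-trips intensities within float32 precision
(~1e-7 relative). The reader additionally accepts FCS 3.0 and integer or
double data in either byte order. The CSV dialect is a header of channel
names preceded by `#key=value` metadata lines, 10 significant digits,
with an optional `true_label` column for synthetic data (FCS cannot
carry per-event text labels, so they survive CSV round-trips only).
Acquisition metadata that was never recorded stays `None` and any
defaulted field is listed in `assumed`; volumetric counting refuses both
rather than silently using a guess.

## Synthetic cytometer

Each subpopulation is a per-channel log-normal cloud: channel `c` is
`10^x, x ~ Normal(mu_c, sigma_c)` (log10 units). Log-normality is the
canonical first-order description of cytometric fluorescence and scatter
distributions and renders realistic one- and two-mode histograms with
two parameters per channel. A scenario is a mixture of such populations;
composition is drawn **once per scenario** from a multinomial (not
per-event), so realised fractions concentrate tightly around their
specification at fixture size and downstream recovery tests are not
flaky. All generators consume one explicit integer seed through
`numpy.random.default_rng`; there is no global random state, and
identical (spec, seed) pairs give bit-identical tables.

Default locations in the packaged registry (log10 units): negative
fluorescence 1.5, positive fluorescence 3.5 (two decades of separation,
as in well-optimised staining), spread 0.25; liquid-culture scatter
FSC 2.3/SSC 2.0 with spread 0.15; plate-grown scatter FSC 2.7/SSC 2.4
with spread 0.30 (larger, filamentous, polydisperse cells). The
viability panels use healthy 88 %/injured 6.5 %/dead 3.5 % for actively
growing cultures, 35/40/22.5 % for starving ones (midpoints of the
reported ranges for these physiological states), 5 % healthy for the
ethanol-killed control, and a 17.5 % PI⁺ fraction for plate-grown cells;
the small BOX⁻ PI⁺ remainder (~2 %) closes each mixture to 1.

Staining physics:

* **Pyr-546 kinetics** — saturation `1 − exp(−k·t)` with default
  `k = 0.2 s⁻¹`, chosen so staining is ≥95 % complete by 15 s and gains
  <2 % between 70 and 300 s, matching the observed near-immediate
  saturation of PHA staining at 0.5 µg·mL⁻¹. The saturation multiplies
  the FL1 intensities of PHA-bearing populations.
* **PG-SK quenching** — Stern–Volmer, `F = F₀/(1 + K_SV·[Fe])`, the
  standard first-order model for collisional/static quenching; no
  functional form is prescribed by the source observations, so the
  simplest monotone law with one constant is used.
* **Paired OD readings** — `OD_⊥ = OD_base(1+ε)`,
  `OD_∥ = OD_⊥·(1 + a·m)·(1+ε′)` with alignment contrast `a`, magnetic
  fraction `m`, and independent multiplicative noise of CV `noise_cv`,
  so the noiseless C_mag is exactly `1 + a·m`. This linear model spans
  the observed range (C_mag 1 to ~2) without modelling coil optics or
  shape-dependent scattering anisotropy.

What the generator does **not** emulate: spectral spillover and
compensation (single relevant dye per detector), doublets and pulse
height/width, instrument drift, autofluorescence correlations between
channels, Mie scattering, or magnetosome crystal physics. Passing tests
therefore demonstrate that the analysis correctly inverts the assumed
statistical structure — they do not validate staining chemistry or
optics on real cultures.

## Gating

Quadrant cuts are the nearest-rank percentile (default 99.5) of an
unstained control's FL1 and FL3, requiring ≥100 control events.
Nearest-rank (`ceil(p·n/100)`-th order statistic) is exactly
reproducible and testable against enumeration, unlike interpolated
percentiles. A value exactly equal to a cut counts **negative**; the
boundary convention matters for exact tests and is fixed here once.
BOX⁻ PI⁺ events are reported as "anomalous" and never folded into the
dead fraction, since that staining pattern has no established
physiological reading. With the 99.5th-percentile convention, a sample
distributed like the control loses ~0.5 % per channel to false
positives, so a scenario generated with 88 % healthy events classifies
at ≈87 %; recovery-to-specification tests therefore either use
mid-separation cuts (where misclassification is ~1e-5) or compare
against the gated expectation.

The noise gate retains events with FL4 (Syto62, DNA-positive) or FSC
above a cut and records the retained fraction in the table metadata.

## Quantification

MFI is the arithmetic mean on the linear scale — the instrument-software
default reading of "mean fluorescence intensity" — and dispersion is the
coefficient of variation (sample SD over mean, n−1 denominator). The CV
interpretation is a deliberate resolution of ambiguous dispersion
semantics in the source material: a covariance of a single channel is
not meaningful as an error bar.

Subpopulation detection fits Gaussian mixtures with k = 1 and k = 2 to
log-displayed intensities by EM (scikit-learn backend, 10 random
restarts, tolerance 1e-6, seeded) and selects k by BIC. BIC's complexity
penalty reliably rejects the second component on unimodal data at the
25 000-event scale used here; 200 events is the floor below which the
fit refuses. Components are returned ordered by mean.

The iron index is `fold_quench = MFI_reference / MFI_sample` with the
reference the iron-free condition; given a quench model the estimate is
`[Fe] = (fold_quench − 1)/K_SV`. Because both MFIs share the same
log-normal spread, the σ-dependent factor cancels in the ratio and the
estimator is unbiased under the generator's assumptions.

Count calibration is least squares **through the origin**
(`slope = Σ od·conc / Σ od²`), because the relation is expressed as a
per-OD equivalence; R² is computed as `1 − SS_res/SS_tot` with SS_tot
about the mean concentration (so a proportional fit can in principle
score below an intercept model — honest about lack of fit). Fits require
≥3 pairs with ≥2 distinct OD values. The packaged constants
(1.16×10⁹ cells·mL⁻¹, 1.03×10⁹ with Syto62, 3.3×10⁸ CFU·mL⁻¹ per OD₅₆₅)
ship with `n_points = 0` and a provenance note to distinguish them from
fits performed on data.

Volumetric counting is `n_events · dilution / (flow_rate·duration/60)`
converted to mL, with flow rate in µL·min⁻¹ and duration in seconds.

## C_mag

`C_mag = OD₅₆₅(∥)/OD₅₆₅(⊥)`; scale-invariant by construction, 1 for
non-magnetic suspensions. The magnetic/non-magnetic call uses a
tolerance of 0.05 above unity by default: the boundary must sit below
the ~1.1 reading of a very weakly magnetic culture while absorbing
spectrophotometer noise; no noise floor is prescribed by the assay
itself, so the tolerance is configurable.

## Pipeline

`run_sample` composes read → optional noise gate → thresholds →
viability → scatter summary → per-stain MFIs → iron index → calibrated
concentration → C_mag, annotating any stage failure with the stage name
and recording inputs, thresholds, percentile, calibration and package
version in the report's provenance block. Reports serialise to JSON with
sorted keys, so identical inputs give byte-identical reports; the report
schema carries an explicit version (currently 1). `compare_conditions`
emits a long-format (condition, metric, value, dispersion) table with a
stable metric set, preserving input order; replicates are treated as
separate reports (aggregation is left to the caller, since no single
aggregation convention fits all designs).

The packaged condition series (`headspace_conditions`,
`medium_shift_conditions`) encode the two multi-condition experiments as
generator parameter sets: the headspace series varies terminal OD
(0.45→1.6), C_mag (2.0→1.02), viability (90→60 % healthy), Pyr-546
location (falling) and PG-SK location (minimal at the most aerobic
condition); the medium-shift series encodes the pre-transfer culture
(C_mag 1.71, PHA-rich) and its 24/48-h trajectories with and without
iron (>3-fold Pyr-546 drop in iron-replete medium by 24 h; decay to
~65 % and C_mag → 1.2 without iron).

## Problem sizes and tolerances

Packaged scenarios default to 25 000 events — the per-sample acquisition
size of the workflows this package supports — and run in milliseconds;
mixture fits at that size take a few seconds each. Statistical test
tolerances follow from the generators: label-fraction recovery within 3
binomial standard deviations; closed-form checks (kinetics, quenching,
noiseless C_mag, calibration on exact data) at 1e-10 to 1e-12 relative;
moment-matching checks (log-normal mean and CV at n = 1e5) within 2 %;
mixture parameter recovery within ±0.03 (weights) and ±0.05 log10
(means) at n = 25 000, allowing one failure in twenty seeds; iron
round-trip within 10 %.

## Known limitations

* Quadrant thresholds assume the unstained control shares the sample's
  autofluorescence distribution; matrix effects are not modelled.
* The Stern–Volmer constant is dye-lot and buffer dependent; absolute
  iron estimates are only as good as the calibrated `K_SV`, and the
  package otherwise reports the dimensionless fold-quench.
* MFI-based PHA and iron readouts are relative; absolute PHA mass and
  absolute iron content require reference chemistry outside this
  package's scope.
* No compensation/spillover handling and no doublet discrimination
  (area signals only).
* The mixture detector considers at most two components by design.
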