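# Methods

This package estimates leaf biochemical and photosynthetic traits of wheat
(nitrogen per area N_area, leaf dry mass per area LMA, SPAD, V_cmax25, J,
and the ratio V_cmax25/N_area) from full-range leaf reflectance
(350–2500 nm) using partial least squares regression (PLSR), with the
photosynthetic trait labels obtained by inverting A–C_i gas-exchange curves
through the Farquhar–von Caemmerer–Berry (FvCB) model. This note records
the models, the numerical choices, and what the synthetic world does and
does not establish.

## Spectral pre-treatment

Full-range field spectroradiometers (ASD FieldSpec class) stitch three
detectors; at the junction wavelengths the apparent reflectance steps
discontinuously. The pipeline corrects these splice jumps per instrument at
its junction wavelengths — 1000 and 1800 nm for one instrument, 1000 and
1830 nm for another; both layouts are handled identically.

**Jump correction algorithm.** The software originally used for splice
correction does not document its algorithm, so the package makes its own
choice: *additive offset correction*. Processing junctions left to right,
the segment beyond a junction is shifted by a constant so that its first
point matches the linear extrapolation (least-squares line through the last
5 points) of the preceding segment. This preserves each segment's shape
exactly, never alters the reference segment below the first junction, is
idempotent, and is exact for locally linear spectra; for curved spectra the
residual error is of the order of the local second derivative (≪1e−6 for
leaf-like smoothness). A multiplicative variant (segment rescaled by the
ratio instead of shifted) is available behind a flag for instruments whose
splice error is gain-like. Continuity after correction is judged by
|r(j+1) − r(j)| ≤ 3 × median |Δr| over the 20 points below the junction.

**Outlier rule.** A spectrum is kept iff its reflectance at 800 nm lies in
[0.35, 0.6]; values strictly below 0.35 or strictly above 0.6 mark
implausible leaf spectra (bad clip contact, stray light). Bounds are
inclusive because removal is defined by the strict inequalities. Removed
records are always reported with the measured value and the violated bound.

**Window and averaging.** Only 400–2400 nm (2001 wavelengths) enters the
regression; the noisy instrument edges are discarded. Repeated scans of one
leaf are averaged pointwise within (genotype, experiment, repetition).
Default stage order is jump correction → replicate averaging → outlier
filter → trim; the order of filter and averaging is not externally
determined, so it is configurable, and filtering commutes with trimming
(800 nm survives the trim).

## FvCB inversion of A–C_i curves

Net assimilation is modelled as

    Ac = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko))
    Aj = J (Ci − Γ*) / (4 Ci + 8 Γ*)
    A  = min(Ac, Aj) − Rd

on a C_i basis (infinite mesophyll conductance). The hard minimum is the
default; a hyperbolic-minimum smoothing parameter θ ∈ (0, 1) is available
but off. Triose-phosphate limitation is not modelled. Kinetic constants
(Kc, Ko, Γ*) follow Arrhenius responses exp[E (T − 25)/(R·298.15·(T+273.15))]
referenced to 25 °C, so each evaluates exactly to its 25 °C value at 25 °C.
The shipped default set is the widely used generic C3 (tobacco-derived
in vivo) set: Kc25 = 404.9 µmol mol⁻¹ (E 79.43 kJ mol⁻¹), Ko25 = 278.4
mmol mol⁻¹ (E 36.38), Γ*25 = 42.75 µmol mol⁻¹ (E 37.83), E_Vcmax = 65.33.
Wheat-specific in vivo Rubisco kinetics exist in the literature but are
deliberately not bundled; users supply them as an `FvCBKinetics` object
(`source_label="wheat"`). Results that depend on the kinetics (Vcmax, J,
Vcmax25) are conditional on the chosen set.

**Fitting.** (Vcmax, J, Rd) minimise the summed squared residuals of A
under the min-of-limitations model, via bounded trust-region least squares.
Rd is bounded to [0, 5] µmol m⁻² s⁻¹ (its treatment is a fitting choice; it
can be fixed instead). Initialisation: Vcmax₀ from the Rubisco-limited
equation on the three lowest-C_i points, J₀ from four times the high-C_i
plateau mean; 5 multistarts jittered ±40% with a fixed seed. Each point is
labelled Rubisco- or RuBP-limited at the optimum, and the label counts are
reported.

**Identifiability.** J is estimable only if at least one point is actually
RuBP-limited. In field-like conditions (leaf temperature 15–35 °C), a cold
leaf with a high J/Vcmax25 ratio can be Rubisco-limited over the entire
C_i ladder: Vcmax falls with temperature while J (defined here relative to
Vcmax25) does not, so Ac < Aj everywhere and the likelihood is flat in J
above a bound. The fitter warns when a curve has no point beyond
C_i = 600 µmol mol⁻¹; recovery experiments condition J checks on the truth
having a RuBP-limited point. Median-based summaries over many curves are
robust to the residual unidentifiable fraction.

**Temperature normalisation.** Vcmax25 = Vcmax / exp[E_Vcmax (T − 25)/
(R·298.15·(T+273.15))]; exact identity at 25 °C, monotone (Vcmax25 < Vcmax
for T > 25), and an exact round trip with the forward map. Supported leaf
temperature range 0–50 °C. Normalisation compresses the trait range (at-
temperature values spread further than 25 °C values), which is why the
normalized trait is the preferred screening target.

## PLSR

The estimator is PLS1 via NIPALS: X (reflectance) and y (one trait) are
mean-centered — no unit-variance scaling, the chemometric convention for
spectra, where the variance structure across wavelengths is informative.
Per component: weight w ∝ Xᵀy, score t = Xw, loadings p = Xᵀt/tᵀt and
q = yᵀt/tᵀt, then rank-one deflation. The k-component model collapses to
one coefficient per wavelength, b = W(PᵀW)⁻¹q, plus intercept
ȳ − x̄ᵀb; coefficient-form and score-form predictions agree to ~1e−12.
One model per trait (univariate response only). The component budget is
capped at 30 by default (chosen counts in practice land between ~10 and
~25 on real data, lower on clean synthetic data).

Requested components are limited by k ≤ n − 1 (k ≥ n is a rank error); at
k = n − 1 the fit interpolates the centered training data and coincides
with the minimum-norm least-squares solution, which is the oracle
equivalence the tests exercise. On exactly low-rank data the sequential
extraction stops when the residual covariance vanishes: strict contexts
raise, cross-validation silently truncates (extra components cannot change
the predictions).

**Cross-validation.** RMSEP-CV(k) is assembled from out-of-fold predictions
over all folds (each sample predicted exactly once), so
PRESS(k) = n·RMSEP-CV(k)² holds as an identity. One NIPALS decomposition
per fold serves all candidate k. Default: 10-fold with whole genotypes
sharing a fold (repetitions of one genotype are correlated; record-level
folds leak and are available only as an explicit option). The selected
component count is the argmin of RMSEP-CV, ties toward fewer components; a
one-standard-error parsimony rule is behind a flag, default off.

**Band restriction.** The 400–900 nm variant simply drops columns outside
the band before fitting; 501 wavelengths remain. Traits whose signatures
weight the SWIR lose accuracy under restriction — on the synthetic world
this reproduces the qualitative ordering (chlorophyll-like traits hold up
best).

**Serialization.** Models freeze to JSON with coefficients, centering,
component count and the full preprocessing recipe (junctions, filter
bounds, trim, band), so a frozen model is self-describing. A 2-column
wavelength/coefficient CSV (intercept in a comment header) supports
published external coefficient tables, including sparse ones; on import the
centering is folded into the intercept.

## Validation design

Records are split by *whole experimental repetitions per genotype*, never
by individual records, so every multi-repetition genotype appears on both
sides (target ≈55% of records in training; with 2 repetitions per genotype
the achievable fraction is exactly 50%). Single-repetition genotypes go to
training with a warning. Statistics on the held-out side:

    bias (%) = 100 (mean ŷ − mean y) / mean y
    REP  (%) = 100 · RMSE(y, ŷ) / mean y

both unit-free. R² defaults to the squared Pearson correlation of observed
vs predicted; the 1 − SSres/SStot form is computed alongside and both are
reported, since the two diverge for miscalibrated predictors. Residual
diagnostics fit per-experiment OLS slopes of residual on predicted and on
observed: a variance-underfitting model shows ≈0 against predicted but a
positive slope against observed (exactly (1 − s) for shrinkage factor s).

**Ratio traits.** `ratio_trait_comparison` trains (a) one model on
y_num/y_den directly and (b) separate models whose predictions are divided,
on the same split with per-model CV component selection. When the spectrum
encodes the ratio itself and the denominator carries spectrum-independent
variation, route (a) wins — the behaviour the package's generator
constructs and the tests assert directionally.

## Synthetic world

The generator is statistical, not a radiative-transfer leaf model; it
reproduces the data features the pipeline logic depends on and nothing
more. Baseline: visible ≈0.05–0.11 with a green bump at 550 nm, red edge
to an NIR plateau ≈0.47 (inside the 800 nm plausibility window), water
troughs at 1450/1940 nm, declining SWIR2. Four smooth signatures
(chlorophyll, NIR structure, SWIR1, SWIR2; pairwise |r| < 0.95) carry the
trait information: per record, four latent trait z-scores (genotype effect
80% of variance, repetition noise 20%, inter-trait correlation 0.5,
truncated at ±3 sd) are mixed through a well-conditioned random 4×4 map
into signature weights at 0.03 reflectance units per sd. Traits are exact
linear functions of the latents scaled into their ranges — SPAD 10–60,
LMA 25–80 g m⁻², N_area 0.5–3 g m⁻², V_cmax25 23–280 µmol m⁻² s⁻¹ (the
last is an observed range; the others are generator defaults spanning
realistic field-survey axes) — plus Gaussian noise of 2% of the range.
Spectral noise is smooth (41-point moving-average of white noise, sd 0.002)
because instrument noise is band-correlated; a white-noise option remains.
Optional additive jump artifacts (+0.02/−0.015 at the junctions) exercise
the splice correction.

Defaults (60 genotypes × 4 repetitions, the noise levels above) define a
high-signal regime: validation R² ≥ 0.97 with |bias| < 1% for every trait.
A green pipeline test on this world establishes that the machinery is
correct and leak-free — it does *not* establish field-data performance,
where nonlinearity, structural variation unrelated to traits, and
instrument drift push R² for photosynthetic traits well below biochemical
ones. The truth object stores the exact linear map, so tests can check that
fitted coefficient vectors correlate (|r| > 0.9) with the true functional.

A–C_i sets draw Vcmax25 uniformly in [23, 280], Tleaf in [15, 35] °C,
J = ratio·Vcmax25 with ratio in [1.3, 2.0], Rd in [0.5, 2], on a 10-level
C_i ladder from 50 to 1500 µmol mol⁻¹ with Gaussian noise sd 0.5 on A.

## Known limitations

- The FvCB fit treats the curve's mean leaf temperature as exact and does
  not propagate gas-exchange measurement error into Vcmax/J uncertainty.
- No mesophyll-conductance transform is applied by default (C_i basis); a
  user-supplied fixed-gm option exists but its functional form is the
  user's responsibility.
- The PLSR path has no wavelength selection, no penalised variants, and no
  multi-response mode, by design.
- The generator cannot produce spectra whose trait information is nonlinear
  in reflectance; a pipeline green on it can still miscalibrate on real
  leaves.
- The aperture-area helper assumes a true ellipse; the physical mask
  cut-out is close to, not exactly, elliptical.
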