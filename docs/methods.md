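# Methods

This note records the scientific and numerical choices behind `leafsignal`:
what each stage computes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Spectra and preprocessing

A `Spectrum` holds strictly increasing wavelengths (nm) and non-negative
reflectance relative to a barium-sulphate white standard.  Reflectance is
deliberately not clamped to [0, 1]: relative to a diffuse white standard,
specular leaf surfaces can exceed 1, and downstream code tolerates this.
The canonical working grid is 300–700 nm at 1 nm, the usual measurement
range of field spectrometry for insect vision.

White/dark normalisation computes `(raw − dark) / (white − dark)` with the
dark reading defaulting to zero; the white standard must exceed dark at
every wavelength, and noisy raw counts below dark are floored at 0.
Missing reflectance rows are dropped (and counted), never interpolated.
Resampling is linear interpolation with extrapolation forbidden.

**Smoothing.** Spectra are smoothed by least squares with a piecewise cubic
of 30 equal sections over 300–800 nm.  We read "piecewise cubic" as a cubic
regression spline with C² continuity at the 29 interior knots (a B-spline
least-squares fit via `scipy.interpolate.make_lsq_spline`), the standard
smoother of this form; independent per-section cubics would be
discontinuous at section boundaries and were not implemented (one
behaviour, no flag).  The continuous reading also guarantees the
nested-model property the tests rely on: a single global cubic lies inside
the spline space, so the spline's residual sum of squares can never exceed
the global cubic's.  When data stop at 700 nm the sections span the
available range instead, with a warning.  At least 4 data points per
section are required.  Smoothing is an optional pre-step, off by default:
whether published quantum catches were computed from smoothed or raw
spectra is not determinable, and raw spectra are the safer default.

Peak normalisation divides by the maximum reflectance within ±30 nm of the
chlorophyll reflectance peak near 550 nm, making spectra comparable by
shape; it is exactly scale invariant.

## Receptor model

Spectral sensitivities are built from a single peak wavelength with the
Govardovskii A1 visual-pigment nomogram, α band only, peak-normalised.
The α band suffices because the β band contributes little above 300 nm for
the pigments used here, and opponency ratios are dominated by the α peak.
Constants are transcribed once in `receptors.py` and unit-tested against an
independent transcription.

Peak wavelengths: aphid UV 325, B 460, G 530 nm (*Myzus persicae* values,
standard surrogates for *B. brassicae*); butterfly pale-red 620 and
deep-red 640 nm.  The butterfly UV/B/G peaks are not uniquely fixed by the
eye-physiology literature for this purpose; defaults of 360/450/563 nm are
provided as configuration (sourced from pierid eye physiology) and are
overridable per receptor.

Quantum catch is the trapezoidal integral of reflectance × illuminant ×
sensitivity on the shared 1 nm grid; it is exactly linear in reflectance,
so all catch ratios are invariant to uniform scaling of the spectrum
(illumination intensity).  No von Kries/receptor adaptation is applied:
the colour metrics are raw catch ratios (B:G, PR:G, DR:G) and brightness
(the green catch, an achromatic channel).

**Illuminant.** Default is flat (equal quanta): the field illumination is
unknown, all analyses are within-study comparisons, and flat is the
minimal assumption.  CIE D65 (energy table × λ, peak-normalised) is
available by flag, and the ordering/invariance properties are verified
under both.

## Presence GLMM

Herbivore presence/absence per plant is modelled as Bernoulli with
logit link, fixed colour effect(s), and random intercepts for population
nested within county.  Estimation is maximum likelihood with a Laplace
approximation (`glmm.py`), written for this package because no installed
Python library offers a Laplace-ML binomial mixed model; the implementation
is validated against `lme4::glmer` on a frozen dataset (coefficients and
log-likelihood agree to ~1e-3).  ML rather than REML is used so that
deviance differences between nested fixed structures are valid
likelihood-ratio statistics; a term's test is χ² = Δdeviance on 1 df.
Random effects are profiled out by an inner damped Newton iteration (the
random vector is only counties + populations), and the outer optimisation
over (β, log σ_county, log σ_pop) uses L-BFGS-B with log σ bounded in
[log 1e-4, log 20]; the log-determinant is computed in the
boundary-stable form log det(I + ZᵀWZ·D).  Degenerate responses
(all 0/all 1), non-convergence and |β| > 15 (separation) are flagged, not
silent.

Colour predictors are z-scored before fitting — the scale of a catch ratio
is arbitrary and standardisation conditions the optimisation; coefficients
are reported on both scales.  Marginal R² follows the Nakagawa–Schielzeth
decomposition for logit models: var(Xβ) / (var(Xβ) + σ²_county + σ²_pop +
π²/3).

Backward deletion drops the term with the largest deletion p while it
exceeds α = 0.05 (ties broken by declared order, later term first), with
rows fixed once at the global model's complete cases so all nested fits
share identical data; a forward-selection counterpart is provided as a
cross-check.  VIF screening (1/(1−R²), flags at 3 and 10) guards the
multi-predictor models.  Aphid analyses exclude Kent via a county filter,
since the aphid does not occur there.

## Multiplicity and nonparametrics

Benjamini–Hochberg step-up control is applied per analysis family:
q = 0.05 for the correlation screens, q = 0.1 for the presence models
(a deliberately more permissive level for low-power field effects).  The
implementation wraps `statsmodels` `fdr_bh` and is property-tested against
a literal step-up/envelope oracle.  Spearman correlations use average
ranks and the large-sample t approximation, pairwise-complete per cell.

The exact two-tailed binomial test uses the doubling rule
min(1, 2·min(P(X≤k), P(X≥k))), which at p₀ = ½ coincides with the
point-probability rule.  Mann–Whitney reports the U statistic of the first
sample; Wilcoxon matched-pairs reports the positive-rank sum with zero
differences dropped.  Both use exact enumeration for ≤ 12 (combined)
untied observations and the tie-corrected normal approximation with
continuity correction otherwise; the exact branches are tested against
full enumeration oracles.

Performance comparisons are one-way linear models at the plant level
(larvae sharing a plant are averaged first — the plant is the experimental
unit); time-type and area-type responses use natural logs with no offset
(zeros are an error, not log(x+1)).  Relative growth rate is
(ln m₂ − ln m₁)/(t₂ − t₁) over the full first-to-last weighing interval,
in mg/mg/day; with four weighings other interval conventions exist, but
the two-point form is the documented and frozen choice.  Proportions use a
binomial GLM with Pearson-χ²/df dispersion and a dispersion-scaled F test
(quasibinomial).

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Spectra.** Three archetypes on 300–700 nm: a chlorophyll-dominated
  green leaf (550 nm reflectance peak, absorption troughs near 430 and
  662 nm, red edge beyond ~700 nm), a bluish leaf adding a broadband
  400–500 nm wax term (Gaussian at 455 nm), and a reddish leaf adding a
  logistic ramp above ~600 nm.  Components are additive with log-normal
  amplitude jitter, multiplicative intensity noise (σ = 0.08) and fine
  1 nm noise (σ = 0.01), clipped to [0, 1.2].  This is phenomenological —
  no radiative-transfer (PROSPECT-style) physics, no specular/diffuse
  separation — so passing tests demonstrate correct *pipeline* behaviour,
  not leaf optics.
* **Survey.** 4 counties × 3 populations × 40–50 plants (≈ 540, matching
  a large single-season survey); archetype mix 30/50/20 % bluish/green/
  reddish.  Glucosinolate concentrations are log-normal with Spearman-level
  dependence on one driving colour channel each, imposed by a Gaussian
  copula on normal scores (target Spearman ρ converted to the latent
  Pearson scale by 2·sin(πρ/6)); default signs follow each compound's
  dominant field correlation and default magnitudes the reported values.
  Rank-level control is used because the analyses are rank-based.  True
  field marginals of glucosinolates are unpublished; log-normal is an
  assumption and labelled as such.  Presence is drawn from the logistic
  model with county/population intercepts (σ = 0.3/0.5) and a single
  colour coefficient, default 0.39 on the z-scale — the value giving
  marginal R² ≈ 0.04, i.e. the "small colour effect" regime; the helper
  `logit_effect_for_marginal_r2` inverts the R² formula.  Chemistry is
  assayed on a 4–15 plant subsample per population and C:N on ~33 % of
  plants, mirroring realistic assay budgets; the aphid is absent from Kent.
* **Experiments.** Choice trials are Bernoulli with randomised sides.
  Larval performance uses plant-level normal draws at the published group
  means with SEM-implied SDs and two larvae per plant; aphid totals are
  log-normal with beta-binomial morph/mortality counts (intra-class
  ρ = 0.05) to carry overdispersion.

A fixed seed makes every generator output bit-identical.

## Validation sizes and numerical tolerances

Oracle comparisons use 1e-9–1e-12 relative tolerance; the pigment-template
oracle is an independent transcription evaluated pointwise.  The
simulation suites use 200 replicates for null LRT calibration (full-size
surveys; the observed rejection rate must fall inside the binomial 95 % CI
of 0.05), 100 replicates for marginal-R² recovery (±0.03), three full
surveys (24 cells) for correlation-sign recovery at |ρ| = 0.3, and 100
spectra per archetype for the opponency-ordering checks under both
illuminants.  These sizes give the properties enough resolution while
keeping the default suite fast; all are ordinary constants in the tests.

## Known limitations

* The receptor model omits screening/filtering pigments (relevant to
  pierid red receptors), ocular media transmission, and receptor-noise
  discrimination modelling (ΔS/JND).
* The GLMM supports Bernoulli responses and nested random intercepts
  only — exactly the presence analyses — not random slopes, crossed
  designs or binomial totals.
* The generator has no induced-defence time dynamics, seasonality or
  spatial autocorrelation beyond the nested intercepts.
* LRT p-values for variance components (as opposed to fixed effects) are
  not provided; boundary issues would bias them.
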