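# Methods

## Thermodynamic model

The package models equilibrium chemical denaturation of a protein that
populates a molten-globule intermediate: a three-state scheme N↔I↔U with
two sequential transitions, each described by the linear extrapolation
method (LEM), ΔG([D]) = ΔG⁰ − m·[D].  The LEM's linearity in denaturant is
an assumption, not a derived result; it is the standard treatment for
GdnHCl unfolding and is adopted here without denaturant-activity
corrections.  Populations follow from Boltzmann weights relative to N
(w_N = 1, w_I = exp(−ΔG_NI/RT), w_U = exp(−(ΔG_NI+ΔG_IU)/RT)), normalised.
A two-state model (f_I ≡ 0) is provided as the degenerate limit, used for
model selection.

Energies are kcal/mol throughout, with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹
and a default temperature of 298.15 K (25 °C, the incubation temperature
of the equilibrium experiments the model describes).  The exponent in
K = exp(−ΔG/RT) is clamped at |x| = 700 to stay inside double precision;
clamped evaluations warn, since K is then saturated (~10±304) rather than
exact.

### The observable

The measured signal is treated as the population-weighted mean of
per-state baselines, Y([D]) = Σ_s f_s(b_s + s_s[D]).  For λmax readouts
the per-state baseline slopes default to zero (λmax plateaus are flat in
practice); linear slopes are supported because fluorescence-intensity
signals commonly need them.  Treating λmax as a linear mixture observable
is a deliberate approximation: physically the observed peak is the maximum
of a mixture of emission bands, not the weighted mean of their centres.
The synthetic spectra generator quantifies the gap (below) so the
approximation's cost is measured, not assumed.

## λmax extraction

Spectra are restricted to a declared window (default 300–450 nm).  The
default extraction refines the discrete intensity maximum with a parabola
through the maximum and its two neighbours, giving sub-grid precision from
1-nm instrument sampling without assuming a band shape; `argmax` (ties
broken toward the lower wavelength, deterministically) and an
intensity-weighted `centroid` over points ≥ 80% of the peak are
alternatives.  A maximum on the window edge is an error rather than a
silent result — an edge maximum means the window clipped the band.  How a
given instrument reads λmax (smoothing, interpolation) is generally
unknown; the parabolic default is this package's choice.  Note that
3-point parabolic refinement on a broad band (σ ≈ 20 nm) amplifies
intensity noise into several tenths of a nm of vertex jitter; the centroid
method is the robust choice for noisy spectra.

## Fitting

`fit_curve` minimises the residual sum of squares over the model's free
parameters (two transitions' ΔG⁰ and m, plus three baselines for the
three-state model: 7 parameters, +3 with slopes) using scipy's
trust-region-reflective least squares with box bounds: m ∈ (10⁻⁴, 100]
kcal mol⁻¹ M⁻¹, ΔG⁰ unbounded, baselines confined to the observed signal
range ± one span.  Convergence tolerances are 10⁻¹⁰ (ftol/xtol/gtol) with
up to 2000 iterations.  Starting values come from a deterministic
heuristic: N/U baselines from the means of the first/last 15% of points,
transition midpoints from the 25%/75% crossings of the signal span, the
intermediate baseline from the signal midway between the two midpoint
guesses, m-values starting at 6 and 4 kcal mol⁻¹ M⁻¹ (field-typical for
the two transitions of a ~30 kDa protein) and ΔG⁰ = m·Cm.  A curve whose
span is below 4× a robust noise floor (estimated from second differences)
is rejected as transition-free.  If the first start fails, five seeded
jittered restarts are tried and the best kept; non-convergence is reported
via `converged=False` with the last iterate, never raised silently.

Standard errors default to the Jacobian covariance (JᵀJ)⁻¹·rss/(n−p);
case-resampling bootstrap (seeded) is available because the provenance of
published ± values on such tables is often unstated — both interpretations
are supported.  A numerically rank-deficient Jacobian (singular-value
ratio < 10⁻¹⁰, e.g. an invisible intermediate) sets `identifiable=False`
and warns; ΔG_NU error propagation uses the full covariance
(var_NI + var_IU + 2cov).  Cross-variant covariance is assumed zero
(independent fits), and curves are fit individually — no global shared-m
fitting — to mirror per-variant reporting of m-values.

Model selection compares two- and three-state fits by AICc (small-sample
AIC, k counting the residual variance; appropriate at the 20–30 points of
a typical titration).  ΔAICc < 2 is reported as ambiguous with the
two-state model preferred on parsimony.

## Synthetic data

The generator emulates what the analysis assumes: signal = model + iid
Gaussian noise (no concentration-dependent heteroscedasticity), and raw
spectra as population-weighted sums of unit-amplitude Gaussian bands
(σ = 20 nm) centred at the state baselines, on a 1-nm grid.  Defaults are
chosen to match the study conditions of the HCAII Pro237 panel: 31
concentrations evenly spaced over 0–3 M GdnHCl (covering both midpoints,
≈0.9 and ≈2.0 M), λmax noise 0.3 nm.  The true experimental grid and noise
level were not published; these are plausible stand-ins, fixed once.  The
λmax plateaus 336/341/355 nm for N/I/U are generator defaults — typical
Trp-fluorescence values for a folded protein, a molten globule and an
unfolded chain — not measured values, and are overridable.  All randomness
flows through explicit integer seeds (numpy `default_rng`).

What passing tests show, and what they do not: parameter recovery on this
synthetic data validates the estimator under the model's own assumptions
(iid Gaussian noise, exact LEM, linear observable).  Real titrations can
violate all three — sloped baselines, correlated instrument drift,
aggregation at intermediate denaturant — so recovery here bounds
implementation error, not experimental error.

The one quantified model-vs-physics gap: λmax extracted from noiseless
synthetic spectra deviates from the weighted-mean forward model by up to
≈0.35 nm in the transition regions (where two bands are comparably
populated) and < 0.2 nm on the plateaus, at the default band width.  This
is the mixture-peak vs weighted-mean approximation; it is asserted as a
< 0.5 nm property in the tests.

## Stability analysis

ΔG_NU⁰ = ΔG_NI⁰ + ΔG_IU⁰ exactly (linearity of the LEM makes the sum hold
at every concentration).  The mutation effect is
ΔΔG_NU = ΔG_NU(reference) − ΔG_NU(mutant), so positive values mean
destabilizing; this sign convention matches the published positive ΔΔG
values for destabilizing Pro237 mutants (the table caption's literal
subtraction direction would give the opposite sign and is not followed).
The significance threshold for "destabilizing" defaults to 2 kcal/mol,
configurable.  Literature-only records (a ΔΔG with no component free
energies, like P237H) pass through the table with `source="literature"`.

Predictor comparison matches variants by label and reports Pearson r,
RMSE and the maximum absolute deviation.  Only two predictor values are
used as fixtures (P237H: 1.03, P237I: 1.22 kcal/mol) because only those
two were published numerically; with n = 2 the Pearson r is degenerate
(±1) and the meaningful outputs are the deviations.  r is NaN when either
series is constant.

## Problem sizes and determinism

The stochastic-recovery check runs 100 seeded replicates of the reference
variant at σ = 0.3 nm on the default 31-point grid — enough for the mean
estimate's standard error (≈0.1 kcal/mol for ΔG_NI) to sit well inside the
±0.6 kcal/mol acceptance band.  Every random draw in tests, examples and
the acceptance script is seeded; the acceptance script derives all its
seeds from its single `--seed` argument.

## Known limitations

- No folding kinetics, thermal denaturation (ΔCp, Gibbs–Helmholtz),
  >3-state schemes, or denaturant-activity corrections.
- No global multi-curve fitting with linked parameters, and no Bayesian
  posteriors; uncertainties are asymptotic or bootstrap.
- No inner-filter/Raman corrections or spectral deconvolution; spectra
  enter only through λmax.
- The λmax-as-linear-observable approximation above.
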