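# Methods

This note documents the models, the synthetic-data generator, the fitting
procedures and the numerical choices behind `lovkin`, in the spirit of a
package methods appendix.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Compartment models of the irradiation run

All populations are dimensionless fractions of the total FMN (initial
total 1); absolute concentrations (the experiments emulate 25 µM protein)
enter only through amplitude scale factors.  Irradiation time `t` is seconds
from the first laser pulse; within-pulse decays live on a separate
microsecond axis.

**Scheme 1 (C450A).**  A linear chain of first-order steps,
prot →(k1) prot* →(k2) water →(k3) bleached, with

- f_prot = e^(−k1 t)
- f_prot* = k1 t · exp[x1, x2]
- f_water = k1 k2 t² · exp[x1, x2, x3],  xᵢ = −kᵢ t
- f_bleached = 1 − (sum of the others)

where exp[·,·] and exp[·,·,·] are first and second divided differences of
the exponential.  This is algebraically the Bateman solution, but the
divided-difference form evaluates stably for *any* rate spacing: the first
difference uses `expm1` from the larger node (no cancellation, no overflow),
and the second difference recurses over sorted nodes with a confluent Taylor
branch when the total node spread is below 1e−7 (error O(spread²) ≈ 1e−14).
There is therefore no special-casing of k1 = k2 etc. beyond this kernel; the
closed forms agree with a tight-tolerance LSODA integration to better than
1e−6 for random rate triples including relative rate gaps of 1e−9 and exact
ties (tested).

Reference rate constants: 1/k1 = 9000 s (protein oxidation), 1/k2 = 1000 s
(release from the oxidized protein; one rate constant for all oxidation
levels), 1/k3 = 3260 s (photobleaching of free FMN, measured on a
FMN + apoprotein control).  Rates outside characteristic times of
10–10⁵ s trigger a validation warning (configurable off), since the model
describes the minutes-to-hours regime.

**Scheme 2 (wild type).**  Only two triplet components are resolved, so the
oxidized-protein pool is identically zero and release is treated as
immediate upon oxidation.  Two interchangeable forms:

- *empirical_linear* (default): f_prot = max(0, 1 − s·t) with the released
  flux feeding the water pool, which bleaches at k3.  Closed form, matching
  the observation that the intact-pool amplitude falls linearly by ~50% over
  75 min (default slope 0.5/4500 s⁻¹).
- *autocatalytic*: d f_prot/dt = −(seed_rate + k_auto·f_water)·f_prot —
  free FMN is the efficient ¹O₂ producer, ¹O₂ drives oxidation, oxidation
  releases more FMN.  Defaults (seed_rate 6e−5 s⁻¹, k_auto 6e−4 s⁻¹ per unit
  fraction) were chosen so the trajectory depletes ~50% quasi-linearly over
  4500 s (a linear fit outperforms an endpoint-matched exponential, tested).
  A configuration with both coefficients zero is rejected as degenerate.

`populations_ode_oracle` integrates either scheme's rate equations with
LSODA at rtol 1e−10 / atol 1e−12; it exists for tests and cross-checks only.

## 2. Microsecond observables

**Triplet transient absorption** (633 nm probe): Σᵢ Abs⁰ᵢ e^(−t/τ_T,i), one
term per pool, amplitudes proportional to pool populations (the proportion
constant per pool — extinction × collection efficiency — is a free scale).

**Singlet-oxygen phosphorescence** (1270 nm band): each triplet pool feeds
the ¹O₂ population, giving per pool A·τ_Δ/(τ_Δ−τ_T)(e^(−t/τ_Δ)−e^(−t/τ_T)),
evaluated as A·(t/τ_T)·exp[−t/τ_Δ, −t/τ_T] so the equal-lifetime point is
regular (limit A·(t/τ)e^(−t/τ), relevant in practice because the aqueous
triplet lifetime 2.7 µs and τ_Δ ≈ 2.7–3.3 µs genuinely collide).  One τ_Δ is
shared by all pools within a measurement set: ¹O₂ diffuses out of the ~3.5 nm
protein quickly and spends essentially its whole lifetime in water; this
assumption is adopted, not re-derived.  Useful identities: the single-pool
peak time is ln(τ_T/τ_Δ)·τ_Tτ_Δ/(τ_T−τ_Δ) and the time integral is
Σ Aᵢ·τ_Δ (both tested against numerics).

The instrument response is treated as a delta function: 5–7 ns excitation
pulses against µs lifetimes, three orders of magnitude apart, so no
reconvolution is performed.

**Band-pass background subtraction.**  The emission is recorded through
three consecutive 50 nm windows (1200–1250, 1250–1300, 1300–1350 nm); the
optical-train background is assumed to vary slowly — to first order linearly
— across them, so net = mid − (low + high)/2 removes any wavelength-linear
background exactly (the window centers are equally spaced).  The net trace
may be negative per bin, its counting statistics are no longer Poisson, and
the subtraction-propagated variance (mid + (low+high)/4) is attached as
metadata for optional weighting.

**Dark-state adduct recovery** (wild type only): 447 nm absorbance recovers
as baseline + A(1 − e^(−t/τ_rec)) after a bleaching flash; the
adduct-competent FMN fraction is the post/pre amplitude ratio.

## 3. The synthetic-data generator

The generator emulates the study conditions: one 75-minute irradiation at
10 Hz (475 nm, 5–7 ns pulses) producing

- 18 transient-absorption curves, one per consecutive 2500-pulse block
  (block midpoints at 125, 375, … 4375 s), sampled 0–400 µs at 0.1 µs;
- 6 phosphorescence measurement sets (12.5 min each = three windows × 2500
  pulses), 50 ns bins;
- emission spectra (free-FMN reference, pre- and post-irradiation);
- pre/post adduct-recovery traces (wt);
- a free-FMN + apoprotein bleaching control (single aqueous pool, constant
  2.7 µs lifetime, amplitudes on e^(−k3 t)).

Noiseless generator output reproduces the forward models *exactly* (tested
bit-for-bit for absorbance; phosphorescence expectation traces carry float
counts flagged `expectation` in metadata, since measured counts are
integers).  Identical config + seed gives byte-identical data; every
generator op draws from its own seed substream.

Study-condition parameter defaults (values the analysis is expected to
recover): τ_T^prot = 57 µs (C450A) / 1.50 µs (wt); τ_T^prot* drifting
linearly 32 → 23 µs across the run; τ_T^water = 2.7 µs fixed; τ_Δ linear in
set index, 2.7 → 3.0 µs (C450A) and 2.6 → 3.3 µs (wt); Φ_water = 0.57,
Φ_prot(C450A) = 0.07, Φ_prot*(C450A) = 0.20 (not separately analyzed — the
oxidation level keeps changing), Φ_prot(wt) = 0 (the wild-type signal is
fully explained by solution-phase production); bound/free absorbance ratio
at 475 nm defaults to 1 (a free config input — the true ratio is not
published; the yield's sensitivity to it is reported alongside the
estimate); post-irradiation free-emission fractions 0.45 (wt) / 0.25
(C450A); adduct-competent fraction 0.40 with τ_rec = 70 s (a typical
AsLOV2-scale dark-recovery constant; the analysis only requires both traces
to share it).

Emission bases are synthetic log-normal bands (bound peak 500 nm, free peak
520 nm; the wild type's bound emission quenched ×0.25 by adduct formation).
The exact band shape is irrelevant to the unmixing mathematics and is
labelled synthetic.

**Noise defaults and what they mean.**  Oscilloscope noise is Gaussian,
σ = 0.012 OD on a unit-amplitude signal.  This was calibrated during
generator design so that the *entire* staged inference stays informative:
the study conditions attach a ±2 µs uncertainty to the 57 µs lifetime, and
at σ ≈ 0.04–0.05 the recovered shared lifetime indeed scatters on that
scale — but then the per-curve pool amplitudes (57 µs vs ~30 µs components
are nearly collinear) become too noisy to support the rate-constant and
quantum-yield stages that these same conditions assume to succeed.  We
therefore read the ±2 µs as including systematic (model/constraint)
uncertainty rather than pure statistical noise, and chose the lower σ; at
this level the shared-lifetime statistical precision is ~0.2–1 µs.  Photon
counts are Poisson
(variance/mean within [0.8, 1.2] pooled over bins with ≥50 expected counts,
tested over 20 seeds) with a count scale giving peak net signals of order
10²–10³ per bin, which reproduces per-set τ_Δ uncertainties of ~±0.1–0.2 µs,
the scale of the reported ±0.2 µs.  The optical background is an
exponentially decaying rate (300 counts/bin at t=0, 8 µs) shared by the
windows with a ±10% linear tilt; a quadratic option raises the signal window
by 1% so the subtraction's linearity assumption can be violated on purpose
(the residual bias is then curvature × background, < 1% of the signal peak
under the defaults, tested).  The phosphorescence record length (80 µs) and
bin width (50 ns) are engineering choices — the source experiments do not
state them; 80 µs is long enough to separate the 57 µs and ~30 µs triplet
feeds, which a 30 µs record is not.

## 4. Fitting

**Global triplet fit.**  Each lifetime is declared shared, per-curve, or
fixed.  The solver is variable projection: for a trial lifetime vector the
per-curve amplitudes are the exact NNLS solution (non-negativity is a hard
constraint, so a spurious pool pins at 0, never negative — tested), and a
trust-region least-squares runs over the log-lifetimes only (bounds keep
them positive; 8-point log-spaced coarse scan initializes each shared
lifetime).  Uncertainties come from the Gauss–Newton covariance on the log
scale, delta-mapped; amplitude uncertainties from the per-curve linear
covariance at the fitted lifetimes.  A pool whose amplitude sits within
noise of zero on ≥90% of curves raises an over-parameterization flag.

The per-curve oxidized-pool lifetime is genuinely unidentifiable while that
pool is nearly empty (early irradiation: fraction ~0.01–0.05); left fully
free it occasionally drifts up into collinearity with the shared 57 µs
lifetime and swaps that curve's pool amplitudes.  An optional trend
regularizer (off by default) adds penalty residuals w·Δ²(log τ*) across the
irradiation series — second differences, so a smooth (linear) drift is
essentially unpenalized while a lone runaway value is pulled onto its
neighbours' trend.  The end-to-end pipeline enables it with w = 5
(configurable); w was calibrated against generator truth on the recovered
lifetime and amplitude series.

**Global phosphorescence fit.**  Triplet lifetimes enter fixed (from the
absorption fit, interpolated at the set midpoints); per set, amplitudes are
NNLS and the one free τ_Δ is a 1-D bounded search (0.5–20 µs), so "global"
is exact per-set profiling.  τ_Δ is independent per set (it is allowed to
evolve); fits are unweighted by default, with optional per-bin
inverse-variance weights from the subtraction-propagated Poisson variance —
weighting matters mainly for significance statements about near-zero
amplitudes, where the unweighted linear stderr is mis-calibrated under the
heteroscedastic early-time background noise.  Sets whose total net counts
fall below a floor (default 50) are flagged and skipped, not fitted.

**Staged rate fits.**  k3 is supplied externally (bleaching control) or
fitted from a control series; k1 by a single-exponential fit of the
intact-pool amplitude series (baseline fixed at 0); k2 by least squares of
the chain curves to the oxidized-pool and water series with k1, k3 held
fixed, the per-pool proportionality constants profiled out linearly.  All
stages use a soft-L1 robust loss (f_scale 5% of the series maximum, or 2σ
when per-point uncertainties are attached), because amplitude series
distilled from global fits occasionally contain one unresolved-pool outlier;
noiseless recovery remains exact since zero residuals are unaffected by the
loss.  An optional joint refinement of (k1, k2) over all series exists; the
staged estimates are the default and the two agree within uncertainties at
small noise (tested).  Scheme 2 replaces the k1/k2 stages with a linear
depletion-slope regression.

**Unmixing.**  Non-negative least squares of the observed spectrum on the
(resampled) free/bound bases over their common wavelength support; fractions
are the normalized weights; cosine similarity > 0.999 between bases sets an
ill-conditioning flag.

**Quantum yield.**  Φ_prot = 0.57 · (slope_prot/slope_water) / r_475, where
each slope is the origin-constrained regression of the per-set
phosphorescence amplitude on the corresponding pool fraction averaged over
the set interval (fractions from the *fitted* rate constants in the
pipeline).  The formula is invariant under joint rescaling of the slopes; a
value above 1 is clipped with a warning.  The pipeline reports the yield's
sensitivity to r_475 (0.5×/1×/2×) because that ratio is a configuration
input, and excludes from the rate series any curve whose per-curve lifetime
collapsed onto the shared one (fewer than 8 surviving curves falls back to
using all).

**Release fractions.**  The kinetic estimate is f_water + f_bleached at the
end of irradiation (interpolated on the trajectory; extrapolation is
refused); the spectral estimate is the unmixed free fraction.  Both are
reported individually plus an inverse-variance-weighted mean when
uncertainties are available (otherwise unweighted) — the combination rule is
a package choice, labelled as such in the output.

## 5. Pipeline, I/O, reproducibility

`run_pipeline` chains acquire (simulate or load) → triplet fit → background
subtraction + phosphorescence fit → rate fits → unmixing → yield/release,
logging per-stage wall time and convergence; a stage failure halts with the
stage name, keeping earlier outputs.  Traces and spectra travel as CSV with
`# key=value` headers (CRLF/LF-agnostic; non-integer photon counts are a
parse error unless the expectation flag is present); the manifest JSON
records the config echo, every output file with its SHA-256, the seed and
the package version.  All randomness flows through the config seed.

`scripts/acceptance.py` recomputes the headline quantities from scratch.
Stochastic estimators are reported as means over 3–5 replicate experiments
(replicate seeds derived from `--seed` through `SeedSequence`); the
replicate counts are fixed in the script and are part of its measurement
protocol.  Problem sizes match the study conditions throughout (18 curves ×
4000 points, 6 sets × 1600 bins, etc.); the full script completes in tens of
seconds on one CPU.

## 6. What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
Gaussian oscilloscope noise, Poisson counting, smooth near-linear spectral
backgrounds, pool amplitudes exactly proportional to model populations, and
lifetimes drifting exactly on the configured schedules.  Real data deviate
from all of these: model mismatch in the pool decomposition, non-ideal
backgrounds, drifting laser power, oxygen depletion, and inner-filter
effects are absent here.  Parameter-recovery results therefore validate the
*implementation* of the estimators under the stated model, not the model's
adequacy for any particular laboratory dataset.  Known limitations: the
wild-type Scheme 2 is phenomenological (the empirical and autocatalytic
forms bracket, but do not derive, the true release law); amplitude
uncertainties ignore the NNLS active-set truncation; and the quantum yield
inherits, linearly, whatever error sits in the assumed 475 nm absorbance
ratio.
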