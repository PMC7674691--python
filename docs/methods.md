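# Methods

## Scope and model structure

`thyret` quantifies the uncertainty of the thyroid retention function
m(t) — the activity in the thyroid per unit acute intake of radioiodine —
for five intake scenarios: inhalation of 5 μm and 1 μm AMAD aerosols
(F-type absorption), elemental/inorganic iodine vapor (SR-1, F-type, 100%
deposition), organic iodine vapor (SR-1, V-type, 70% deposition), and
ingestion of total-diet iodine (f₁ = 1).  Calculations are for I-131
(physical half-life 8.0252 d); because only biological parameters carry
uncertainty, the scattering factors transfer to other iodine isotopes.
Only acute intakes are modelled; chronic-intake convolution, dose
coefficients, and the revised ICRP 130/137 models are out of scope (the
older models remain the basis of most operational dosimetry systems, which
is precisely where these uncertainty numbers are needed).

All biokinetics are first-order: the state vector q of compartment
activities evolves as dq/dt = A q, where A holds the transfer rates r_ij
(d⁻¹) off-diagonal and minus each column's total outflow plus the physical
decay constant λ on the diagonal.  Sink compartments (urine, faeces,
environment, exhaled air) stay in the state vector, so
exp(λt) · Σ_i q_i(t) ≡ 1 is a machine-precision invariant used as a
regression guard (`activity_balance`).

### Respiratory tract (inhalation)

Regional deposition fractions (ET₁, ET₂, BB, bb, AI) are the sampled
parameters; particle transport uses the fixed ICRP 66 reference rates
(AI₁→bb₁ 0.02, AI₂→bb₁ 0.001, AI₃→bb₁ 10⁻⁴, AI₃→LN 2·10⁻⁵, bb₁→BB₁ 2,
bb₂→BB₁ 0.03, seq→LN 0.01, BB₁→ET₂ 10, BB₂→ET₂ 0.03, ET₂→oesophagus 100,
ET_seq→LN 0.001, ET₁→environment 1 d⁻¹).  The BB/bb deposit is split into
sequestered (0.7%), slow (half of the remainder) and fast fractions; the AI
deposit is split 0.3/0.6/0.1 across AI₁₋₃.  The uncertainty of the
clearance rates themselves is not published in a usable form; the
configuration exposes distribution slots for them, defaulting to point
masses at the reference values.  This is defensible because F-type
dissolution (s_p = 100 d⁻¹) dominates: varying the slow-cleared fraction
over [0.1, 0.9] moves 24 h retention by < 1% (tested).

F-type absorption transfers material to blood at s_p from every
particle-bearing compartment except ET₁ (which clears only to the
environment).  Elemental vapor deposits 100% of the intake with the
regional fractions renormalized to sum to 1 and no AI deposit; organic
vapor (V-type) transfers its sampled deposited fraction to blood
instantaneously, modelled as an initial condition in blood with the
remainder exhaled.  Material swallowed from ET₂ enters the oesophagus,
split fast/slow in the same proportion as the oral-cavity outflow (90/10
at reference).

### Alimentary tract (ingestion and swallowed material)

Transfer rates follow the ICRP 100 chain (oral cavity → oesophagus
fast/slow → stomach → small intestine → right/left colon → rectosigmoid →
faeces) with log-normal uncertainties derived from published uncertainty
factors.  Absorption to blood occurs from the small intestine at
λ_B = f₁·λ_SI/(1−f₁), which preserves the SI transit rate λ_SI while
absorbing the fraction f₁ (verified by long-time integration).  At the
reference f₁ = 1 the colon path is dropped and SI→blood is set to λ_SI,
preserving the SI residence time.  f₁ is sampled from a triangular
distribution on (0.9, 1.0, 1.0).

### Systemic model

The three-compartment iodine model: blood iodide, thyroid, rest of body.
The loss constants are biological half-times in days (the triangular modes
— 0.25 d blood, 12 d body — are the familiar reference half-times; reading
them as rates would give a thyroid clearing in minutes).  Rates are
fraction × ln2 / half-time: blood→thyroid f_blt·ln2/k_bl, blood→urine
(1−f_blt)·ln2/k_bl, thyroid→rest ln2/k_t, rest→blood f_bbl·ln2/k_b,
rest→faeces (1−f_bbl)·ln2/k_b.

Two parameter sets are distinguished deliberately.  The *reference* curve
uses the ICRP 67 defaults (uptake 0.3, blood 0.25 d, thyroid 80 d, body
12 d, recycled fraction 0.8) — the basis of published reference retention
functions.  The *sampled* curves use the published uncertainty
distributions, whose central values differ (uptake GM 0.267, thyroid
half-time mode 113 d).  The reference value therefore sits above the
ensemble median, which is the point of the percentile-rank diagnostic.

The thyroid uptake fraction's log-normal LN(0.267, 1.47) has ~3·10⁻⁴ of
its mass above 1; such draws are physically impossible for a fraction and
are rejected and redrawn, as are aerosol deposition vectors that are
negative or sum above 1.

## Solver

q(t) = exp(At) q(0) is evaluated from one eigendecomposition of A per
system, reused across all time points.  When the rate matrix is defective —
which happens exactly at the reference parameters, where the three colon
segments share the rate 2 d⁻¹ — the eigenvector matrix fails a
reconstruction-residual check (relative residual > 10⁻¹⁰) and the solver
falls back to scaling-and-squaring matrix exponentials per time point.
Sampled parameter sets have almost surely distinct rates and take the fast
eigendecomposition path; the two paths agree to < 10⁻⁹ and the matrix
solution matches a stiff Radau integrator to < 10⁻⁸ relative (tested).
The default time grid is hourly from 1 h to 96 h, then 6-hourly to 30 d;
rates are internally d⁻¹ and the public time unit is hours.

## Monte Carlo propagation

Latin hypercube sampling: for each parameter the unit probability interval
is divided into n equal strata, one draw per stratum at a uniformly random
position within the stratum (midpoints would truncate the tails), and
strata are permuted independently across parameters (the study design
states no correlation structure, so parameters are independent).  n = 1000
parameter sets are drawn once and each yields a *full* retention curve, so
trajectories are coherent in time and plateau statements are meaningful;
per-time independent resampling would both forbid them and multiply cost.
At n = 1000 the mean relative standard error of the ensemble mean over the
grid is ~1.3%, below the 2% convergence criterion.

Per time point the ensemble is summarized by the log-scale moment
estimates (GM, GSD) and a probability-plot R² (squared correlation of
sorted log values against normal plotting positions); empirical 5/50/95
percentile bands use linear order-statistic interpolation.  Scattering
factors condense GSD(t): `sf_before_24h` is the mean over hours 1–10
inclusive (early thyroid measurements are taken as soon as possible after
an incident), `sf_after_24h` the mean over the 48 h–30 d plateau, where
GSD(t) is flat.  Values are reported raw and, for table comparison,
rounded to the nearest 0.05.

## Intake estimation

Under per-point log-normal errors with scattering factor SF_i, the
log-likelihood is quadratic in ln I, so the maximizer is available in
closed form: ln Î = Σ w_i ln(M_i/m_i) / Σ w_i with w_i = 1/ln²(SF_i).  A
numeric maximization of the product likelihood is kept as a test oracle
and agrees to 10⁻⁸ relative.  SF_i combines the measurement SF (typical
1.2 for high-energy gamma counting) with the retention-function SF in log
quadrature; the retention-function SF switches from the before-24 h to the
after-24 h value at exactly t = 24 h, with the boundary point using the
after value.  Retention curves are interpolated linearly in (t, ln m)
between grid points, respecting the near-exponential shape; measurements
outside the grid raise rather than extrapolate.

Goodness of fit is the log-scale chi-square Σ [ln(M_i/(Î·m_i))/ln SF_i]²
with n−1 degrees of freedom when the intake was fitted (n when fixed); the
convention is not universal, so p-values are best used comparatively.
With all SF_i = 1 (exact data) the estimator degenerates to the plain
geometric mean; mixing exact and noisy points is rejected.

The early-phase bias model divides measurements taken before 24 h by a
multiplicative factor (default 1.35, the mean measured-to-calculated ratio
of normalized thyroid uptake within the first day reported from human
%RAIU data).  Correction is never applied silently, refuses to run twice
on the same point, and the underlying literature uptake tables are inputs
(`compute_bias` on two normalized %RAIU curves), not bundled data.

## Synthetic data

The generator emulates exactly the error structure the estimator assumes:
M_i = I · m(t_i) · bias^{[t_i<24 h]} · ε_i with ln ε_i zero-mean normal and
log-sd √(ln² SF_M + ln² SF_m).  It therefore validates the estimator
(unbiasedness on the log scale, theoretical spread ln SF/√n, 90% interval
coverage 0.90 ± 0.03 — all tested at 1000 replicates), but it cannot
detect model-structure error: real bioassay data have time-correlated,
possibly non-log-normal residuals and an intake time that is itself
uncertain.  Passing recovery tests show the statistical machinery is
correct, not that the biokinetic model is.  The bundled worked-example
fixture stores the printed corrected activities (83, 158 Bq) verbatim:
they are not exactly the original values divided by 1.35, suggesting a
time-dependent correction in the source; recomputing them would not
reproduce the published corrected-fit intake.

## Design choices on open points

* **UF→GSD** uses the one-sided 95% quantile z = 1.645: it is the only
  convention that reproduces the tabulated conversions UF 2 → GSD 1.52 and
  UF 1.5 → GSD 1.28.
* **Organic-vapor total deposition** is cited to literature but not
  printed; the default LN(0.70, 1.15) is a configurable placeholder whose
  central value matches the stated 70% deposition.
* **Degrees of freedom** for the fitted-intake chi-square: n − 1.
* **Plateau window** 48 h–30 d and **early window** 1–10 h inclusive; the
  source text specifies "within 10 h" and "do not change thereafter"
  without exact windows.
* **Seeds**: every stochastic routine takes an explicit seed or Generator;
  stochastic validation checks run three seeds and compare means.

## Known limitations

* With the fractional-split systemic model above, the plateau GSD of the
  retention ensemble is bounded below by the thyroid-uptake-fraction GSD
  (1.47), because late retention is exactly proportional to that fraction
  and the other parameters only add variance.  Our propagated spreads are
  accordingly somewhat higher than previously published scattering-factor
  tables derived from the same input distributions (plateau values
  1.47–1.52 vs 1.40–1.50; early values 1.67–1.71 vs 1.55–1.60; 24 h
  ingestion GSD 1.48 vs 1.41), and the reference-curve percentile at 24 h
  is correspondingly lower (~59th vs 68th).  Alternative readings of the
  rate construction (e.g. holding the urinary loss fraction at its
  reference value, or proportional SI absorption splitting) were examined
  and each moves some of these statistics toward the published values
  while moving others away; no first-order formulation reproduces all of
  them simultaneously.  The implementation keeps the standard ICRP
  formulation and reports what it propagates.
* Parameters are sampled independently; real biokinetic parameters
  (e.g. thyroid mass, uptake fraction and half-times) are correlated in
  ways the published distributions do not quantify.
* The first-order kinetics assumption itself biases the first day (hence
  the bias-correction machinery); within-day retention values carry the
  largest uncertainty and should be treated accordingly.
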