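# thyret

Uncertainty quantification of thyroid retention functions for radioiodine
internal dosimetry.

After an intake of radioiodine (inhalation or ingestion), the intake
activity *I* is estimated from thyroid counter measurements *M_i* via the
bioassay (retention) function *m(t)* — the predicted thyroid activity per
unit acute intake.  Published retention functions are single curves, but
the biokinetic parameters behind them are uncertain, and that uncertainty
propagates directly into the intake and dose estimate.  `thyret` is a
library for dosimetrists and radiation-protection researchers that makes
this uncertainty explicit:

* **Biokinetic models** — the ICRP 66 respiratory tract model, ICRP 100
  alimentary tract model and ICRP 67 three-compartment systemic iodine
  model, assembled into a first-order compartment system
  `dq_i/dt = Σ_j r_ij q_j − q_i Σ_j r_ji − λ q_i` and solved as
  `q(t) = exp(A t) q(0)` by eigendecomposition (with a scaling-and-squaring
  fallback for defective rate matrices).
* **Monte Carlo propagation** — Latin hypercube sampling of the published
  parameter uncertainty distributions (normal / log-normal / triangular;
  uncertainty factors converted as `GSD = exp(ln UF / 1.645)`), one full
  retention curve per parameter set, and per-time log-normal summaries.
* **Scattering factors** — the per-time geometric standard deviation GSD(t)
  of the retention distribution, condensed into a *scattering factor* SF_m
  before 24 h (mean GSD over hours 1–10) and after 24 h (plateau GSD).
* **Maximum-likelihood intake estimation** — per-point SFs combined in log
  quadrature, `SF_i = exp √(ln² SF_M + ln² SF_m)`; the likelihood maximizer
  is the weighted geometric mean of the implied intakes `M_i / m_i` with
  weights `1 / ln² SF_i`, with a log-scale chi-square goodness of fit and an
  optional early-phase bias correction `M_corrected = M / bias` for
  measurements within the first day.
* **Synthetic bioassay data** — series with the assumed multiplicative
  log-normal error structure, for estimator validation.

## Worked example

Four thyroid measurements after inhalation of a 5 μm I-131 aerosol
(110, 210, 470, 460 Bq at 2, 4, 24, 48 h), fitted with the reference
retention curve (`examples/03_intake_estimation.py`):

```
measurement uncertainty only:
  intake =    4710 Bq   chi2 = 6.56  p = 0.087
with retention-function uncertainty (corrected data, combined SFs):
  intake =    4034 Bq   chi2 = 0.18  p = 0.980
applying the uncertainty lowers the estimate by 14% and raises the fit p-value
```

With measurement uncertainty alone (SF 1.2 per point) the early, unstable
measurements dominate and the fit is barely acceptable (p = 0.087).
Dividing the sub-24 h measurements by the early-phase bias and combining the
measurement SF with the retention-function SF (1.6 before 24 h, 1.5 after)
down-weights those points: the intake estimate drops and the fit becomes
good (p = 0.980).

Propagating the parameter distributions for ingestion
(`examples/02_uncertainty_propagation.py`, n = 1000, seed 42):

```
24 h retention distribution: GM = 0.215, GSD = 1.482, R^2 = 0.999
reference-parameter value 0.238 sits at the 59th percentile of the ensemble
scattering factors: before 24 h = 1.70, after 24 h = 1.48
mean relative standard error of the MC mean: 1.32% (converged below 2%)
```

The 24 h retention is log-normally distributed to very good approximation;
the deterministic reference curve sits above the ensemble median because the
reference thyroid uptake fraction (0.3) exceeds the geometric mean of its
uncertainty distribution (0.267).

A thin CLI mirrors the pipeline:

```sh
thyret propagate --route ingestion --n 1000 --seed 42 --out summary.csv --sf-out sf.json
thyret fit-intake --measurements meas.csv --route aerosol-5um \
    --sf-before 1.55 --sf-after 1.45 --bias-correct --out result.json
thyret simulate-bioassay --route aerosol-5um --intake 5000 --times 2,4,24,48 --out meas.csv
thyret bias --measured measured_raiu.csv --calculated calculated_raiu.csv
```

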