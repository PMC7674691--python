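"""Estimator validation on synthetic bioassay series.

Generates 1000 artificial measurement series (true intake 5000 Bq,
multiplicative log-normal noise combining measurement SF 1.2 and curve SF
1.5) and refits each with the true retention curve.  The weighted
geometric-mean estimator is unbiased on the log scale and its nominal 90%
interval covers the true intake at the nominal rate.  A second run applies
an uncorrected early-phase bias of 1.35, showing the resulting systematic
overestimation.
"""

import thyret as th

curve = th.reference_retention(th.Route.AEROSOL_5UM)

spec = th.SyntheticSpec(scenario=th.Route.AEROSOL_5UM, intake_bq=5000.0,
                        times_h=(2, 4, 24, 48), sf_meas=1.2, sf_m_true=1.5, seed=11)
res = th.recovery_experiment(spec, 1000, retention=curve)
print(f"calibrated noise:  GM of estimates = {res.gm:6.0f} Bq (true 5000), "
      f"GSD = {res.gsd:.3f}, 90% interval coverage = {res.coverage_90:.2f}")

biased = th.SyntheticSpec(scenario=th.Route.AEROSOL_5UM, intake_bq=5000.0,
                          times_h=(2, 4, 24, 48), sf_meas=1.2, sf_m_true=1.0,
                          early_bias=1.35, seed=11)
res_b = th.recovery_experiment(biased, 1000, retention=curve)
print(f"uncorrected early bias 1.35: GM of estimates = {res_b.gm:6.0f} Bq — "
      "early-phase underestimation of the model inflates the fitted intake")
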