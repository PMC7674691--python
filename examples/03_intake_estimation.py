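"""Maximum-likelihood intake estimation with and without curve uncertainty.

Uses the bundled worked example: four thyroid measurements (2, 4, 24, 48 h)
after inhalation of a 5 um I-131 aerosol.  The first fit uses measurement
uncertainty only (SF 1.2 per point); the second uses the printed
bias-corrected early activities together with combined scattering factors
(1.6 before 24 h, 1.5 after), which down-weights the unstable early points.
The corrected fit lowers the intake estimate by roughly 17% and markedly
improves the goodness of fit.
"""

import thyret as th

curve = th.reference_retention(th.Route.AEROSOL_5UM)
original, corrected, combined_sfs = th.worked_example_fixture()

res_orig = th.estimate_intake(original, curve)
res_corr = th.estimate_intake(corrected, curve, sf_combined=combined_sfs)

print("measurement uncertainty only:")
print(f"  intake = {res_orig.intake_bq:7.0f} Bq   chi2 = {res_orig.chi2:.2f}  "
      f"p = {res_orig.p_value:.3f}")
print("with retention-function uncertainty (corrected data, combined SFs):")
print(f"  intake = {res_corr.intake_bq:7.0f} Bq   chi2 = {res_corr.chi2:.2f}  "
      f"p = {res_corr.p_value:.3f}")
change = 100 * (1 - res_corr.intake_bq / res_orig.intake_bq)
print(f"applying the uncertainty lowers the estimate by {change:.0f}% and "
      "raises the fit p-value")
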