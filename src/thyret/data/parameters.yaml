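# Default biokinetic parameter values and uncertainty distributions for
# radioiodine thyroid-retention modelling.
#
# Distribution entries: {kind: normal, mean, sd} | {kind: lognormal, gm, gsd}
#                       | {kind: triangular, min, mode, max} | {kind: fixed, value}
# Rates are in d^-1, half-times in days, deposition values are fractions of
# the inhaled or ingested amount.

radionuclide:
  name: I-131
  half_life_d: 8.0252

# Regional deposition in the ICRP 66 respiratory tract (fraction of intake).
deposition:
  aerosol_1um:
    ET1: {kind: normal, mean: 0.17, sd: 0.035}
    ET2: {kind: normal, mean: 0.22, sd: 0.045}
    BB:  {kind: normal, mean: 0.013, sd: 0.0023}
    bb:  {kind: lognormal, gm: 0.018, gsd: 1.21}
    AI:  {kind: lognormal, gm: 0.10, gsd: 1.23}
  aerosol_5um:
    ET1: {kind: lognormal, gm: 0.33, gsd: 1.2}
    ET2: {kind: lognormal, gm: 0.41, gsd: 1.22}
    BB:  {kind: lognormal, gm: 0.025, gsd: 1.61}
    bb:  {kind: lognormal, gm: 0.014, gsd: 1.85}
    AI:  {kind: lognormal, gm: 0.053, gsd: 1.6}
  # Vapors: alveolar-interstitial uptake is negligible; regional fractions are
  # renormalized at build time (elemental vapor deposits 100% of intake).
  vapor_elemental:
    ET1: {kind: lognormal, gm: 0.071, gsd: 1.31}
    ET2: {kind: lognormal, gm: 0.28, gsd: 1.20}
    BB:  {kind: lognormal, gm: 0.24, gsd: 1.44}
    bb:  {kind: lognormal, gm: 0.38, gsd: 1.32}
  vapor_organic:
    ET1: {kind: lognormal, gm: 0.075, gsd: 1.28}
    ET2: {kind: lognormal, gm: 0.29, gsd: 1.19}
    BB:  {kind: lognormal, gm: 0.24, gsd: 1.44}
    bb:  {kind: lognormal, gm: 0.36, gsd: 1.34}

# Total deposited fraction for vapors.  Organic iodide (V-type) transfers its
# deposited fraction to blood effectively instantaneously; the spread of its
# total deposition is a configurable log-normal.
total_deposition:
  vapor_elemental: {kind: fixed, value: 1.0}
  vapor_organic: {kind: lognormal, gm: 0.70, gsd: 1.15}

# ICRP 100 alimentary tract transfer rates (d^-1).  GSDs derive from
# uncertainty factors (UF 2 -> 1.52, UF 1.5 -> 1.28, one-sided 95%).
hatm:
  rates:
    oral_to_oesophagus_fast: {kind: lognormal, gm: 6480, gsd: 1.52}
    oral_to_oesophagus_slow: {kind: lognormal, gm: 720, gsd: 1.52}
    oesophagus_fast_to_stomach: {kind: lognormal, gm: 12343, gsd: 1.52}
    oesophagus_slow_to_stomach: {kind: lognormal, gm: 2160, gsd: 1.52}
    stomach_to_si: {kind: lognormal, gm: 20.57, gsd: 1.28}
    si_to_rc: {kind: lognormal, gm: 6, gsd: 1.28}
    rc_to_lc: {kind: lognormal, gm: 2, gsd: 1.28}
    lc_to_rs: {kind: lognormal, gm: 2, gsd: 1.28}
    rs_to_faeces: {kind: lognormal, gm: 2, gsd: 1.28}
  # Fractional absorption of iodine from the small intestine.
  f1: {kind: triangular, min: 0.9, mode: 1.0, max: 1.0}
  f1_reference: 1.0

# Three-compartment systemic iodine model (blood / thyroid / rest of body).
# Loss constants are biological half-times in days; transfer rate =
# fraction x ln2 / half-time.
systemic:
  distributions:
    f_blt: {kind: lognormal, gm: 0.267, gsd: 1.47}       # thyroid uptake fraction
    f_bbl: {kind: triangular, min: 0.823, mode: 0.914, max: 1.000}  # body->blood fraction
    k_t_d: {kind: triangular, min: 67.8, mode: 113, max: 158}       # thyroid half-time
    k_b_d: {kind: triangular, min: 9.6, mode: 12, max: 14.4}        # rest-of-body half-time
    k_bl_d: {kind: triangular, min: 0.0025, mode: 0.25, max: 0.4975}  # blood half-time
  # Reference (deterministic) curve uses the ICRP 67 defaults.
  reference:
    f_blt: 0.3
    f_bbl: 0.8
    k_t_d: 80.0
    k_b_d: 12.0
    k_bl_d: 0.25

# ICRP 66 particle-transport clearance (fixed reference rates, d^-1).  Slots
# are distribution entries so literature uncertainties can be supplied via a
# config override; the defaults are point masses at the reference values.
hrtm:
  transport_rates_per_d:
    ai1_to_bb1: {kind: fixed, value: 0.02}
    ai2_to_bb1: {kind: fixed, value: 0.001}
    ai3_to_bb1: {kind: fixed, value: 0.0001}
    ai3_to_ln_th: {kind: fixed, value: 0.00002}
    bb1_to_big_bb1: {kind: fixed, value: 2}
    bb2_to_big_bb1: {kind: fixed, value: 0.03}
    bb_seq_to_ln_th: {kind: fixed, value: 0.01}
    big_bb1_to_et2: {kind: fixed, value: 10}
    big_bb2_to_et2: {kind: fixed, value: 0.03}
    big_bb_seq_to_ln_th: {kind: fixed, value: 0.01}
    et2_to_oesophagus: {kind: fixed, value: 100}
    et_seq_to_ln_et: {kind: fixed, value: 0.001}
    et1_to_environment: {kind: fixed, value: 1}
  # Fast dissolution rate to blood (F-type absorption).
  s_p_per_d: {kind: fixed, value: 100.0}
  # Fraction of BB/bb deposit sequestered in the airway wall, ET2 analogue,
  # and the slow-cleared fraction of the non-sequestered BB/bb deposit.
  seq_fraction: {kind: fixed, value: 0.007}
  et2_seq_fraction: {kind: fixed, value: 0.0005}
  slow_fraction: {kind: fixed, value: 0.5}
  # Sub-split of the AI deposit across AI1/AI2/AI3.
  ai_split: [0.3, 0.6, 0.1]
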