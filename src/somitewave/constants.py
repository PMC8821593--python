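"""Default constants for zebrafish somitogenesis.

Every default used elsewhere in the package funnels through this registry,
so derived quantities (periods, rates, spacings) are always recomputed from
these primitives rather than hard-coded downstream.

Units are stated per constant.  The temperature laws are affine in degrees
Celsius: a rate r(T) = slope * (T - T_CRITICAL_C) vanishes at the critical
temperature and is undefined (unphysical) below it.
"""

#: Critical temperature (deg C): common x-intercept of every rate-vs-T line.
T_CRITICAL_C = 14.4

#: Segmentation-period law coefficient (h * deg C): tau_s = 5.32 / (T - Tc).
PERIOD_COEFF_H_C = 5.32

#: Clock-frequency slope a_s (somites / h / deg C): f_s = a_s * (T - Tc).
CLOCK_FREQ_SLOPE = 0.188

#: Temperature slope a of the per-hour deltaCt(fgf8) drift
#: (cycles / h / deg C): alpha(T) = a * (T - Tc).
DCT_SLOPE_PER_H_C = 0.022

#: Collapsed per-somite deltaCt slope a' (cycles / somite), shared by all
#: temperatures once time is expressed in somite stages.
DCT_SLOPE_PER_STAGE = 0.122

#: Intercept b (cycles) of the collapsed deltaCt-vs-stage line.
DCT_INTERCEPT = 3.955

#: Per-somite deltaCt slope of fgf8 measured at 27 deg C alone
#: (cycles / somite).
DCT_SLOPE_27C = 0.094

#: Fgf8 mRNA spatial decay length lambda (um).
DECAY_LENGTH_UM = 260.0

#: Tail elongation-rate slope beta_tail (um / h / deg C).
TAIL_RATE_SLOPE = 4.79

#: PSM shrinkage-rate slope magnitude beta_psm (um / h / deg C).  The PSM
#: length decreases, so the signed fitted slope is negative; the package
#: stores the magnitude (see KymographModel sign convention).
PSM_RATE_SLOPE = 5.08

#: PSM shrinkage rate at 27 deg C (um / h).
V_PSM_27C_UM_H = 58.0

#: Plausibility band (deg C) for measured incubation temperatures; values
#: outside trigger a warning, not an error.
TEMP_PLAUSIBLE_MIN_C = 14.4
TEMP_PLAUSIBLE_MAX_C = 40.0
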