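# Methods

## Model and assumptions

**Morphogen field.** The fgf8 mRNA concentration along the PSM is the
separable closed form u(x,t) = F₀·exp(−x/λ − t/τ), with x ≥ 0 the
distance from the tail end (posterior origin, increasing anteriorly,
μm).  No reaction–diffusion equation is solved: the field is taken as
given, which presumes transcription confined to the progenitor domain,
first-order decay in space (length λ) from transport/degradation, and a
source amplitude decaying exponentially in time (rate 1/τ).  The mean
concentration over the PSM then decays as exp(−t/τ) whether the spatial
integral is taken unbounded (the default) or over a finite PSM length —
only the prefactor differs — so temporal ratios are domain independent.

**Boundary placement.** The determination wavefront is the locus where
the spatial gradient of the Fgf8 signal crosses a threshold η_t.  The
protein is assumed a monotonic, time-independent transfer of the mRNA,
Fgf8 = G(u); only the scalar slope G′(u_t) at threshold enters the
closed forms, so `ThresholdRule` carries a single `transfer_slope`
(default 1, the identity).  Boundary n forms at clock tick
t_n = t0 + n·τ_s, at x_n = x₀ − λ·t_n/τ with
x₀ = λ·ln(G′F₀/(η_t·λ)).  The default time origin is t0 = 0 at boundary
0, recovering constant spacing τ_s·λ/τ; a nonzero t0 simply shifts the
whole series, and the closed form agrees with direct root-finding of the
threshold crossing for any t0 (verified in the tests to ≤ 1 nm over
random parameter draws).  A negative anchor (threshold never reached in
the domain) and a series leaving x ≥ 0 are flagged, never silent.

**Somite size conventions.** Two distinct "sizes" coexist and are
reported separately: the tail-frame boundary spacing |x_{n+1} − x_n| =
τ_s·λ/τ (≈ 24 μm at the default constants), and the lab-frame distance
travelled by the wavefront per clock period, (V_tail + V_PSM)·τ_s
(≈ 52.5 μm), which is what a kymograph shows.  The measured anatomical
somite (~50 μm) corresponds to the lab-frame quantity; the model's
boundary series lives in the tail frame.  Signs: the PSM length
*decreases*, so the package stores the shrinkage rate as a positive
magnitude `v_psm_shrink` and defines V_front = V_tail + v_psm_shrink;
with a signed (negative) PSM slope this is the familiar
V_front = V_tail − V_PSM.

**Temperature laws.** Every rate is affine in temperature and vanishes
at a common critical temperature: r(T) = slope·(T − T_c), T_c = 14.4 °C.
No critical exponent is fitted (it is 1 throughout) and no
Arrhenius/Q10 alternative is considered.  Temperatures are °C
everywhere; evaluating a law at T ≤ T_c raises rather than returning a
non-positive rate.  Characteristic times diverge as 1/(T − T_c); the
segmentation period uses the coefficient form τ_s = 5.32/(T − T_c) h.
Note a deliberate redundancy: the period coefficient 5.32 h·°C and the
clock-frequency slope a_s = 0.188 somites·h⁻¹·°C⁻¹ are independent
defaults whose product is 1.0002, not forced to exactly 1; consistency
chains in the tests use one or the other explicitly.

**Two decay-time conventions.** A positive δCt slope a maps to a decay
time either as τ = 1/a (treating one cycle per abscissa unit as the
inverse time constant) or as τ = 1/(ln2·a) (the e-folding time of the
concentration 2^(−δCt)).  Both are in circulation and differ by ln 2
(~11 vs ~15 somitic periods for a = 0.094); `decay_time_from_slope`
refuses to guess and makes the convention a mandatory argument
(`"reciprocal"` / `"log2"`).  The temperature coefficient of the decay
rate, by contrast, is unambiguous: 1/τ = ln2·a·(T − T_c).

## δCt pipeline

δCt = mean(Ct_GOI) − mean(Ct_ref) per sample, replicates averaged
arithmetically before differencing; the point sd combines the two
standard errors of the mean in quadrature.  A single-replicate gene
contributes a floor sd (default 0.2 cycles, the practical Ct
resolution) in place of an undefined sample sd.  Amplification
efficiency is assumed exactly 2 per cycle (plain δCt, no efficiency
correction) — a documented limitation, as is the absence of any outlier
rejection.  Stage values may be non-integer (when derived from time via
s = t/τ_s); fits treat stage as continuous.

**Weighting.**  Fits minimise χ² = Σ((y − ax − b)/σ)².  The linear
algebra is delegated to statsmodels WLS; parameter errors use the
unscaled inverse normal matrix (the χ² convention) when σ are supplied,
and conventional residual-variance-scaled OLS errors when no σ exist
(flagged `unit_weights`, with χ² then the plain residual sum of
squares).  Per-point σ estimated from triplicates carry ~4 degrees of
freedom, and raw 1/σ² weights from such estimates are badly behaved:
E[1/s²] diverges, so a lucky near-zero sample sd pins the line to one
point and collapses its reported error (measured consequence: 2-se
slope coverage 0.67 and a 45% false-rejection rate in the collapse test
at nominal 5%).  The default weight policy therefore pools the
replicate scatter across the points of a fit (root-mean-square sd,
floored at 0.2 cycles), which matches the homoskedastic technical noise
of Ct measurements; measured calibration with pooling is 0.94 coverage
and a 4.5% type-I rate.  `pool_sds=False` restores floored per-point
weights for genuinely heteroskedastic data.

**Collapse test.**  One line is fitted to all temperatures pooled on
the stage axis and one per temperature; the statistic is
F = ((χ²_pooled − χ²_sep)/(df_pooled − df_sep)) / (χ²_sep/df_sep)
against F(df_pooled − df_sep, df_sep).  Small F means the series are
consistent with a single stage-axis line.  With one temperature's slope
doubled (0.2-cycle noise, 9 points per series) the test rejects in
essentially 100% of runs.

**T_c fitting.**  Per observable, T_c is the x-intercept −b/a of a
weighted straight-line fit of rate on T, with its error by the delta
method from the (slope, intercept) covariance.  The shared-T_c mode
minimises total χ² over one T_c and per-observable slopes
(scipy least_squares, Levenberg–Marquardt; errors from (JᵀJ)⁻¹ of the
whitened Jacobian; df = n − (k+1)).  A non-positive fitted slope makes
the intercept meaningless and raises.

**Gene classification.**  A transcript is "time-varying" when
|slope|/se ≥ 2 (two-sided 2σ rule; the threshold is configurable, and
chosen here as the package's own criterion).  **Reference-gene
ranking** is a simplified BestKeeper-style score: sd of per-sample mean
Ct across samples (ascending) then mean pairwise Pearson correlation
(descending); it is not the full geometric-mean BestKeeper index.

## Synthetic data

The generators emulate the study design the analysis assumes: wild-type
pools at incubation temperatures (23, 26, 27, 29, 31 °C), fixed somite
stages 5–21, triplicate PCR measurements.  Ct noise is Gaussian on the
cycle scale (sd 0.3 cycles by default — chosen so that reduced χ²
values of the fits are near 1), equivalent to multiplicative log-normal
noise on concentration; embryo-to-embryo variation is not modelled
separately from replicate noise (samples are pooled embryos), and the
extra stage-heterogeneity of fixed-time sampling is not modelled.
Kymographs default to an initial PSM length of 500 μm, 0.1 h sampling
over 6 h and 5 μm measurement noise — representative of time-lapse
measurements at this magnification.  Rate tables apply fractional
Gaussian noise (5%) with the generating sd written to the `sd` column.
Every generator is a pure function of its config including the
mandatory seed; repeated calls are byte-identical.

What passing tests do and do not show: the recovery and calibration
results demonstrate that the estimators are unbiased and honestly
calibrated *under the generator's assumptions* (Gaussian cycle noise,
exact linearity in stage, exact critical laws).  Real data add plate
effects, efficiency deviations, stage mis-staging and biological
dispersion that the generator deliberately omits; the pipeline's
robustness to those is untested here.

## Problem sizes and numerical choices

Monte-Carlo checks use 200–500 seeded replicates of the default study —
sizes at which binomial error on a coverage or rejection rate is ~1–3
points, adequate for the bands asserted.  Bisection oracles run with
xtol = 1e-12 and the closed forms agree to ≤ 1e-6 μm.  Ties and
degenerate inputs: all-identical abscissae raise a singular-design
error; an all-zero sd column falls back to unit weights; zero slope
with zero se classifies as constant, nonzero slope with zero se as
time-varying.  Seeds are mandatory for every stochastic operation;
unseeded noisy calls raise.

## Known limitations

- The field is purely closed-form: no diffusion, growth-driven dilution
  or cell-level dynamics; the clock is abstracted to a period.
- The 2-se "coverage ≥ 95%" style of check is bounded above by the t
  distribution when the scale is estimated (P(|t₃₆| ≤ 2) ≈ 0.947), so
  nominal-95% assertions are only achievable with known noise.
- Single-plate view of qPCR: no calibrator correction, standard curves
  or melt QC; inputs are assumed already inter-comparable.
- The period coefficient (5.32) and the observed ~45 min clock period
  sometimes quoted at 27 °C disagree (the law gives ~25 min); the
  package follows the scaling law and leaves the discrepancy to the
  user's calibration.
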