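# somitewave

Quantitative tools for zebrafish somitogenesis: a closed-form Fgf8
morphogen field whose spatial gradient, thresholded at each tick of the
segmentation clock, places somite boundaries; critical-slowing-down
temperature laws under which every developmental rate scales as
(T − T<sub>c</sub>); and an RT-qPCR δCt pipeline that estimates the
underlying slopes and decay times from replicate Ct tables.  Seeded
synthetic-data generators emit every table the analysis consumes, so the
whole chain is testable end to end without external data.

Intended users: developmental and systems biologists analysing
somitogenesis kinetics (kymographs, qPCR time courses across incubation
temperatures) and modellers exploring clock-and-wavefront variants.

## The model

The fgf8 mRNA concentration along the presomitic mesoderm (PSM) is a
source–sink field decaying in space and time,

```
u(x, t) = F₀ exp(−x/λ − t/τ),
```

with x the distance from the tail end (μm), λ ≈ 260 μm the decay length
and τ the decay time.  A somite boundary n forms at clock tick
t = n·τ_s where the gradient of the Fgf8 signal G(u) falls to a
threshold η_t, giving

```
x_n = x₀ − n·τ_s·λ/τ,       x₀ = λ ln(G′F₀ / (η_t λ)),
```

so the PSM shrinks at V_PSM = λ/τ per unit time regardless of threshold
or amplitude.  Two structural consequences follow exactly: a spatially
uniform added Fgf8 source leaves every boundary unchanged (the gradient
is blind to it), and a persistent threshold change from tick n_p onward
alters exactly one somite size.

Temperature enters through critical slowing down: the segmentation
period obeys τ_s ≈ 5.32/(T − T_c) h, the clock frequency
f_s = a_s(T − T_c) with a_s = 0.188, the fgf8 decay rate
1/τ = ln2 · a(T − T_c) with a = 0.022, and tail growth / PSM shrinkage
rates β(T − T_c) with β = 4.79 and 5.08 μm h⁻¹ °C⁻¹ (T_c = 14.4 °C).
Because every rate carries the same (T − T_c) factor, somite size
(V_front · τ_s) is temperature independent, and δCt time courses taken
at different temperatures collapse onto a single line
δCt = a′·s + b when plotted against somite stage s = t/τ_s, with
a = a′·a_s.

On the measurement side, δCt = Ct_GOI − Ct_ref = log₂(⟨[ref]⟩/⟨[goi]⟩),
so a linear δCt drift is an exponential concentration decay; fits are
χ²-weighted least squares with errors from the inverse normal matrix,
and the multi-temperature collapse is tested with an F ratio between one
pooled line and per-temperature lines.

## Worked example

Generate the default synthetic study (5 temperatures × stages 5–21 ×
triplicates, 0.3-cycle Ct noise; kymographs and rate tables from the
critical laws), then run the fits:

```sh
somitewave synth --seed 7 --out-dir data
somitewave fit-dct   --input data/ct_table.csv   --out-dir fit
somitewave collapse  --input data/ct_table.csv   --out-dir coll
somitewave fit-scaling --input data/rate_table.csv --share-tc --out-dir scal
somitewave simulate-kymo --temperature 27 --seed 7 --out-dir kymo
```

which prints

```
wrote 510 Ct rows and 20 rate rows to data
fgf8: slope 0.1225 +/- 0.0053 cycles/somite, chi2 58 (df 83), time-varying
pooled slope 0.1225 +/- 0.0053 cycles/somite; F = 0.663, p = 0.722 (collapse holds)
shared Tc = 13.595 +/- 0.670 degC (chi2 7.82, df 15)
T=27 degC: v_tail 60.94 +/- 0.31, v_psm 63.95 +/- 0.31, v_front 124.89 um/h
```

Reading the numbers: the fitted δCt slope 0.1225 ± 0.0053 cycles/somite
recovers the generating a′ = 0.122 (each cycle is a factor two in
concentration, so fgf8 halves every ~8 somites); the collapse F test
does not reject a single line across all five temperatures (p = 0.72);
the joint rate fit places the common critical temperature at
13.6 ± 0.7 °C against a true 14.4 °C; and the 27 °C kymograph rates
(60.9 and 64.0 μm/h) match the laws 4.79·12.6 and 5.08·12.6.  Each
command also writes a JSON run report (`report.json`) from which its
numbers are reproducible.

The same operations are available as a library:

```python
import somitewave as sw

cfg = sw.SynthConfig(seed=7)
table = sw.gen_ct_table(cfg)
points = sw.delta_ct_table(table, goi="fgf8", reference="rpl13a")
fit = sw.fit_dct_vs_stage(points)           # slope ~ 0.122 cycles/somite
tau = sw.decay_time_from_slope(fit.slope, "reciprocal")  # somitic periods
```

## Layout

- `src/somitewave/constants.py` — the single registry of default constants.
- `src/somitewave/morphogen.py` — field, threshold positioning, perturbations, kymographs.
- `src/somitewave/scaling.py` — critical laws, conversions, (slope, T_c) fitting.
- `src/somitewave/qpcr.py` — δCt tables, weighted fits, collapse analysis, gene classing.
- `src/somitewave/synth.py` — seeded generators for Ct, kymograph and rate tables.
- `src/somitewave/io.py`, `cli.py` — delimited-text IO, YAML configs, CLI.
- `docs/methods.md` — model assumptions, numerical choices, limitations.
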