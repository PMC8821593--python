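"""Seeded synthetic-data generators for the somitogenesis pipelines.

The generators emit exactly the tabular structures the analysis consumes —
replicate Ct tables, kymograph traces, rate-vs-temperature tables — with
the statistical structure the model assumes:

- Ct noise is Gaussian on the cycle scale (log-normal multiplicative on
  concentration), which matches deltaCt being the natural measurement
  scale; the gene-of-interest mean deltaCt is linear in somite stage with
  the per-stage slope shared across temperatures.
- Kymograph rates follow the critical laws beta * (T - Tc).
- Rate tables follow r = a * (T - Tc) with fractional Gaussian noise.

Default parameter values mirror the measured zebrafish fits collected in
:mod:`somitewave.constants`; the default study design is 5 incubation
temperatures (23, 26, 27, 29, 31 degC), somite stages 5-21, triplicate
PCR measurements and 0.3 cycles of Ct noise.  Every generator is a pure
function of its config (seed included): repeated calls are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .morphogen import KymographModel, KymographTrace, simulate_kymograph
from .scaling import rate_at, CriticalLaw, stage_to_time, time_to_stage

__all__ = ["GeneSpec", "SynthConfig", "gen_ct_table", "gen_kymograph", "gen_rate_table"]


@dataclass(frozen=True)
class GeneSpec:
    """A gene of interest: deltaCt(stage) = slope_per_stage * s + intercept.

    A constant (non-varying) gene is simply ``slope_per_stage = 0``.
    """

    name: str
    slope_per_stage: float
    intercept: float


def _default_genes() -> tuple[GeneSpec, ...]:
    return (GeneSpec("fgf8", C.DCT_SLOPE_PER_STAGE, C.DCT_INTERCEPT),)


def _default_rate_laws() -> dict[str, float]:
    return {
        "dct_slope": C.DCT_SLOPE_PER_H_C,
        "clock_freq": C.CLOCK_FREQ_SLOPE,
        "tail_growth": C.TAIL_RATE_SLOPE,
        "psm_shrink": C.PSM_RATE_SLOPE,
    }


@dataclass(frozen=True)
class SynthConfig:
    """Study design and noise model for all three generators.

    ``seed`` is mandatory.  ``stages`` drives fixed-stage sampling (the
    default design); setting ``time_grid`` instead samples at fixed times
    and records the temperature-dependent fractional stage s = t/tau_s(T).
    """

    seed: int
    genes: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    reference_gene: str = "rpl13a"
    reference_ct: float = 16.0
    temperatures: tuple[float, ...] = (23.0, 26.0, 27.0, 29.0, 31.0)
    stages: tuple[float, ...] = tuple(float(s) for s in range(5, 22))
    time_grid: tuple[float, ...] | None = None
    replicates: int = 3
    ct_noise_sd: float = 0.3
    period_coeff: float = C.PERIOD_COEFF_H_C
    tc: float = C.T_CRITICAL_C
    # kymograph block
    tail_slope: float = C.TAIL_RATE_SLOPE
    psm_slope: float = C.PSM_RATE_SLOPE
    psm_length_0_um: float = 500.0
    kymo_duration_h: float = 6.0
    kymo_sampling_h: float = 0.1
    kymo_noise_sd_um: float = 5.0
    # rate-table block
    rate_laws: dict[str, float] = field(default_factory=_default_rate_laws)
    rate_noise_frac: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.ct_noise_sd < 0 or self.kymo_noise_sd_um < 0:
            raise ValueError("noise sds must be >= 0")
        if self.rate_noise_frac < 0:
            raise ValueError("fractional rate noise must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def gen_ct_table(config: SynthConfig) -> pd.DataFrame:
    """Generate a replicate Ct table for all genes and temperatures.

    Per replicate, the reference gene reads Ct = reference_ct + eps and a
    gene of interest Ct = reference_ct + slope * s + intercept + eps with
    independent eps ~ N(0, ct_noise_sd), so the per-sample mean deltaCt is
    slope * s + intercept up to noise.  With a ``time_grid`` the stage is
    s = t / tau_s(T); otherwise times are back-computed from the fixed
    stages.  Deterministic per seed.

    Returns the standard Ct schema:
    ``sample, gene, temperature_C, stage, time_h, replicate, ct``.
    """
    if not config.genes:
        raise ValueError("at least one gene of interest is required")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for T in config.temperatures:
        if config.time_grid is not None:
            times = np.asarray(config.time_grid, dtype=float)
            stages = time_to_stage(times, T, config.period_coeff, config.tc)
        else:
            stages = np.asarray(config.stages, dtype=float)
            times = stage_to_time(stages, T, config.period_coeff, config.tc)
        for s, t in zip(stages, times):
            sample = f"T{T:g}_s{s:g}"
            for gene_name, mean_ct in [
                (config.reference_gene, config.reference_ct)
            ] + [
                (g.name, config.reference_ct + g.slope_per_stage * s + g.intercept)
                for g in config.genes
            ]:
                for rep in range(1, config.replicates + 1):
                    noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "gene": gene_name,
                            "temperature_C": T,
                            "stage": float(s),
                            "time_h": float(t),
                            "replicate": rep,
                            "ct": mean_ct + noise,
                        }
                    )
    return pd.DataFrame(rows)


def gen_kymograph(config: SynthConfig, T: float) -> KymographTrace:
    """Simulate a kymograph at temperature T with critically scaled rates.

    v_tail = tail_slope * (T - Tc) and v_psm = psm_slope * (T - Tc) feed
    :func:`somitewave.morphogen.simulate_kymograph` together with the
    configured initial PSM length, duration, sampling and noise.
    """
    v_tail = rate_at(CriticalLaw(config.tail_slope, config.tc, "tail"), T)
    v_psm = rate_at(CriticalLaw(config.psm_slope, config.tc, "psm"), T)
    period = config.period_coeff / (T - config.tc)
    model = KymographModel(
        v_tail_um_h=v_tail,
        v_psm_shrink_um_h=v_psm,
        psm_length_0_um=config.psm_length_0_um,
        period_h=period,
    )
    return simulate_kymograph(
        model,
        duration_h=config.kymo_duration_h,
        sampling_h=config.kymo_sampling_h,
        noise_sd_um=config.kymo_noise_sd_um,
        seed=config.seed,
    )


def gen_rate_table(config: SynthConfig) -> pd.DataFrame:
    """Generate a rate-vs-temperature table for the configured laws.

    rate = slope * (T - Tc) * (1 + eps), eps ~ N(0, rate_noise_frac); the
    ``sd`` column is rate_noise_frac * true rate (the generating per-point
    sd, 0 when noise-free).  Columns: ``observable, temperature_C, rate, sd``.
    """
    if len(config.temperatures) < 2:
        raise ValueError("need at least two temperatures")
    rng = np.random.default_rng(config.seed)
    rows = []
    for label, slope in config.rate_laws.items():
        for T in config.temperatures:
            true = slope * (T - config.tc)
            noise = rng.normal(0.0, config.rate_noise_frac) if config.rate_noise_frac else 0.0
            rows.append(
                {
                    "observable": label,
                    "temperature_C": T,
                    "rate": true * (1.0 + noise),
                    "sd": config.rate_noise_frac * true,
                }
            )
    return pd.DataFrame(rows)
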