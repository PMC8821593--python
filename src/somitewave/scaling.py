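"""Critical slowing down of somitogenesis rates with temperature.

Near a critical temperature Tc every characteristic rate of zebrafish
somitogenesis — the segmentation-clock frequency, the tail growth and PSM
shrinkage rates, the fgf8 mRNA decay rate — is proportional to (T - Tc)
with Tc = 14.4 degC.  Equivalently every characteristic time diverges as
1/(T - Tc).  This module evaluates those laws, converts between per-hour
and per-somite quantities, and fits (slope, Tc) from rate-vs-temperature
tables by chi-square weighted least squares, either per observable or
jointly with a shared Tc.

Rate tables are pandas DataFrames with columns
``observable, temperature_C, rate, sd`` (``observable`` and ``sd`` optional;
see :func:`fit_critical_law`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import (
    CLOCK_FREQ_SLOPE,
    DCT_SLOPE_PER_H_C,
    PERIOD_COEFF_H_C,
    T_CRITICAL_C,
    TEMP_PLAUSIBLE_MAX_C,
    TEMP_PLAUSIBLE_MIN_C,
)

__all__ = [
    "CriticalLaw",
    "ScalingFit",
    "SharedTcFit",
    "rate_at",
    "segmentation_period",
    "clock_frequency",
    "fgf8_decay_rate",
    "time_to_stage",
    "stage_to_time",
    "stage_time_convert",
    "slope_convert",
    "fit_critical_law",
]

LN2 = float(np.log(2.0))


class BelowCriticalError(ValueError):
    """Temperature at or below the critical temperature: rates vanish."""


def _check_above_tc(T: float, tc: float) -> None:
    if not T > tc:
        raise BelowCriticalError(
            f"temperature {T} degC is at or below critical temperature {tc} degC; "
            "all rates vanish there and characteristic times diverge"
        )


@dataclass(frozen=True)
class CriticalLaw:
    """A rate law r(T) = slope_a * (T - critical_temp_Tc).

    Parameters
    ----------
    slope_a
        Rate units per degC (e.g. cycles/h/degC, somites/h/degC, um/h/degC).
    critical_temp_Tc
        Critical temperature in degC.
    label
        Name of the observable the law describes.
    """

    slope_a: float
    critical_temp_Tc: float = T_CRITICAL_C
    label: str = "rate"

    def __call__(self, T: float) -> float:
        return rate_at(self, T)


def rate_at(law: CriticalLaw, T: float) -> float:
    """Evaluate a critical law at temperature ``T`` (degC).

    Raises
    ------
    BelowCriticalError
        If ``T <= law.critical_temp_Tc``; the linear law would give a
        non-positive rate, which is unphysical here.
    """
    _check_above_tc(T, law.critical_temp_Tc)
    return law.slope_a * (T - law.critical_temp_Tc)


def segmentation_period(
    T: float, coeff: float = PERIOD_COEFF_H_C, tc: float = T_CRITICAL_C
) -> float:
    """Segmentation-clock period tau_s(T) = coeff / (T - Tc), in hours.

    Diverges as T approaches Tc from above.  Its reciprocal is the clock
    frequency f_s = (1/coeff) * (T - Tc).
    """
    _check_above_tc(T, tc)
    return coeff / (T - tc)


def clock_frequency(
    T: float, slope: float = CLOCK_FREQ_SLOPE, tc: float = T_CRITICAL_C
) -> float:
    """Clock frequency f_s(T) = slope * (T - Tc), in somites per hour."""
    return rate_at(CriticalLaw(slope, tc, "clock_frequency"), T)


def fgf8_decay_rate(
    T: float, a: float = DCT_SLOPE_PER_H_C, tc: float = T_CRITICAL_C
) -> float:
    """Fgf8 mRNA concentration decay rate 1/tau in 1/h.

    The measured per-hour drift of deltaCt is alpha(T) = a * (T - Tc) in
    cycles/h.  Because one deltaCt cycle is a factor of two in
    concentration, the e-folding decay rate of the concentration is
    1/tau = ln(2) * alpha(T), with coefficient ln(2)*a
    (~0.0152 1/h/degC at the default a = 0.022).
    """
    _check_above_tc(T, tc)
    return LN2 * a * (T - tc)


def time_to_stage(
    t: float, T: float, coeff: float = PERIOD_COEFF_H_C, tc: float = T_CRITICAL_C
):
    """Convert time since somitogenesis onset (h) to somite stage s = t / tau_s(T)."""
    return np.asarray(t, dtype=float) / segmentation_period(T, coeff, tc)


def stage_to_time(
    s: float, T: float, coeff: float = PERIOD_COEFF_H_C, tc: float = T_CRITICAL_C
):
    """Convert somite stage to time since onset (h): t = s * tau_s(T)."""
    return np.asarray(s, dtype=float) * segmentation_period(T, coeff, tc)


def stage_time_convert(
    value,
    T: float,
    direction: str,
    coeff: float = PERIOD_COEFF_H_C,
    tc: float = T_CRITICAL_C,
):
    """Convert between hours and somite stage at temperature ``T``.

    ``direction`` is ``"to_stage"`` (hours -> somites) or ``"to_time"``
    (somites -> hours).  Round trip is the identity.
    """
    if direction == "to_stage":
        return time_to_stage(value, T, coeff, tc)
    if direction == "to_time":
        return stage_to_time(value, T, coeff, tc)
    raise ValueError(f"direction must be 'to_stage' or 'to_time', got {direction!r}")


def slope_convert(per_stage: float, stages_per_h_per_C: float) -> float:
    """Combine a per-somite slope with the clock-frequency temperature slope.

    A quantity drifting by ``per_stage`` units per somite, when the clock
    runs at f_s = a_s * (T - Tc) somites per hour, drifts per hour at
    ``per_stage * a_s * (T - Tc)`` — i.e. its per-hour temperature slope is
    the product a = a' * a_s.
    """
    if not (per_stage > 0 and stages_per_h_per_C > 0):
        raise ValueError("both slopes must be strictly positive")
    return per_stage * stages_per_h_per_C


# ---------------------------------------------------------------------------
# Fitting (slope, Tc) from rate-vs-temperature tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingFit:
    """Result of fitting r = a * (T - Tc) to one observable's rates."""

    label: str
    slope_a: float
    slope_se: float
    tc: float
    tc_se: float
    chi2: float
    df: int
    unit_weights: bool = False


@dataclass(frozen=True)
class SharedTcFit:
    """Joint fit of several observables with one common Tc.

    ``slopes`` maps observable label to (slope, se).  ``chi2`` is the total
    chi-square at the optimum; ``df = n_points - (n_observables + 1)``.
    """

    tc: float
    tc_se: float
    slopes: dict[str, tuple[float, float]] = field(default_factory=dict)
    chi2: float = 0.0
    df: int = 0
    unit_weights: bool = False


def _validate_rate_table(obs: pd.DataFrame) -> pd.DataFrame:
    required = {"temperature_C", "rate"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    obs = obs.copy()
    if "observable" not in obs.columns:
        obs["observable"] = "rate"
    temps = obs["temperature_C"].to_numpy(dtype=float)
    if ((temps < TEMP_PLAUSIBLE_MIN_C) | (temps > TEMP_PLAUSIBLE_MAX_C)).any():
        warnings.warn(
            "temperatures outside the plausible band "
            f"[{TEMP_PLAUSIBLE_MIN_C}, {TEMP_PLAUSIBLE_MAX_C}] degC",
            stacklevel=3,
        )
    return obs


def _fit_single(T: np.ndarray, r: np.ndarray, sd, label: str) -> ScalingFit:
    # weighted straight-line fit of rate on T; Tc is the x-intercept -b/a
    from .qpcr import fit_weighted_line

    fit = fit_weighted_line(T, r, sd)
    a, b = fit.slope, fit.intercept
    if a <= 0:
        raise ValueError(
            f"fitted slope for {label!r} is non-positive; Tc is undefined"
        )
    tc = -b / a
    # delta method on Tc = -b/a with cov of (slope, intercept)
    grad = np.array([b / a**2, -1.0 / a])
    tc_var = float(grad @ fit.cov @ grad)
    return ScalingFit(
        label=label,
        slope_a=float(a),
        slope_se=float(fit.slope_se),
        tc=float(tc),
        tc_se=float(np.sqrt(max(tc_var, 0.0))),
        chi2=float(fit.chi2),
        df=int(fit.df),
        unit_weights=fit.unit_weights,
    )


def fit_critical_law(obs: pd.DataFrame, share_tc: bool = False):
    """Fit critical laws r = a * (T - Tc) from a rate table.

    Parameters
    ----------
    obs
        DataFrame with columns ``temperature_C``, ``rate`` and optionally
        ``sd`` (per-point standard deviation; if absent or non-positive,
        unit weights are used and chi2 is the residual sum of squares,
        flagged via ``unit_weights``) and ``observable`` (defaults to a
        single observable).
    share_tc
        If False (default), each observable is fitted independently and a
        dict mapping label to :class:`ScalingFit` is returned.  If True,
        one Tc is shared across observables: total chi-square is minimized
        over (Tc, slope per observable) and a :class:`SharedTcFit` is
        returned, with errors from the Jacobian at the optimum.

    Notes
    -----
    Requires >= 3 observations per observable and >= 2 distinct
    temperatures.  All-identical temperatures raise a singular-design
    error; a non-positive fitted slope raises because the x-intercept Tc
    is then undefined.
    """
    obs = _validate_rate_table(obs)
    have_sd = "sd" in obs.columns and np.all(obs["sd"].to_numpy(dtype=float) > 0)

    groups = {
        str(label): g for label, g in obs.groupby("observable", sort=False)
    }
    for label, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"observable {label!r} has fewer than 2 observations")
        if g["temperature_C"].nunique() < 2:
            raise ValueError(
                f"observable {label!r}: all temperatures identical (singular design)"
            )

    if not share_tc:
        out = {}
        for label, g in groups.items():
            T = g["temperature_C"].to_numpy(dtype=float)
            r = g["rate"].to_numpy(dtype=float)
            sd = g["sd"].to_numpy(dtype=float) if have_sd else None
            out[label] = _fit_single(T, r, sd, label)
        return out

    # shared-Tc joint fit: params = [Tc, a_1, ..., a_k]
    labels = list(groups)
    T_all = [groups[lb]["temperature_C"].to_numpy(dtype=float) for lb in labels]
    r_all = [groups[lb]["rate"].to_numpy(dtype=float) for lb in labels]
    if have_sd:
        sd_all = [groups[lb]["sd"].to_numpy(dtype=float) for lb in labels]
    else:
        sd_all = [np.ones(len(groups[lb])) for lb in labels]

    seps = {
        lb: _fit_single(T_all[i], r_all[i], sd_all[i] if have_sd else None, lb)
        for i, lb in enumerate(labels)
    }
    tc0 = float(np.mean([f.tc for f in seps.values()]))
    x0 = np.array([tc0] + [seps[lb].slope_a for lb in labels])

    def residuals(theta: np.ndarray) -> np.ndarray:
        tc = theta[0]
        parts = [
            (r_all[i] - theta[1 + i] * (T_all[i] - tc)) / sd_all[i]
            for i in range(len(labels))
        ]
        return np.concatenate(parts)

    res = optimize.least_squares(residuals, x0, method="lm")
    if not res.success:
        raise RuntimeError(f"shared-Tc fit did not converge: {res.message}")
    n = sum(len(t) for t in T_all)
    df = n - (len(labels) + 1)
    chi2 = float(res.fun @ res.fun)
    # covariance from the whitened Jacobian: (J^T J)^-1
    jtj = res.jac.T @ res.jac
    cov = np.linalg.inv(jtj)
    ses = np.sqrt(np.diag(cov))
    if any(res.x[1:] <= 0):
        raise ValueError("shared-Tc fit produced a non-positive slope")
    return SharedTcFit(
        tc=float(res.x[0]),
        tc_se=float(ses[0]),
        slopes={
            lb: (float(res.x[1 + i]), float(ses[1 + i]))
            for i, lb in enumerate(labels)
        },
        chi2=chi2,
        df=int(df),
        unit_weights=not have_sd,
    )
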