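"""Fgf8 morphogen field, gradient-threshold somite positioning, kymographs.

The fgf8 mRNA concentration along the presomitic mesoderm (PSM) is modelled
as a closed-form source-sink field

    u(x, t) = F0 * exp(-x/lambda - t/tau),

where x >= 0 is the distance from the tail end (posterior origin,
increasing anteriorly, in um), lambda is the spatial decay length and tau
the temporal decay time.  A somite boundary n forms at the clock tick
t_n = t0 + n*tau_s at the position x_n where the spatial gradient of the
Fgf8 signal falls to a threshold eta_t.  For a monotonic transfer function
Fgf8 = G(u) with slope G' at threshold this gives the closed forms

    x_n = x0 - lambda * t_n / tau,      x0 = lambda * ln(G' F0 / (eta_t lambda)),

so boundaries march anteriorly-to-posteriorly at constant spacing
tau_s * lambda / tau per somite: the PSM shrinks at a velocity set entirely
by the morphogen dynamics.  Because only the spatial gradient matters, a
spatially uniform added source leaves every boundary unchanged, and a
persistent threshold change from one clock tick onward alters exactly one
somite size.

The module also provides the kinematic kymograph picture: the tail
elongates at V_tail while the PSM shrinks at V_psm, so the wavefront moves
in the lab frame at V_front = V_tail + V_psm (storing the shrinkage as a
positive magnitude; with a signed PSM slope this is the usual
V_front = V_tail - V_PSM).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "MorphogenParams",
    "ThresholdRule",
    "ClockSchedule",
    "BoundarySeries",
    "KymographModel",
    "KymographTrace",
    "UniformSource",
    "ThresholdChange",
    "field_value",
    "mean_concentration",
    "gradient_magnitude",
    "anchor_position",
    "boundary_series",
    "boundary_series_general",
    "apply_perturbation",
    "simulate_kymograph",
    "estimate_velocities",
    "lab_frame_somite_size",
    "VelocityEstimates",
]


@dataclass(frozen=True)
class MorphogenParams:
    """Field triple (F0, lambda, tau) defining u(x,t) = F0 exp(-x/lambda - t/tau).

    amplitude_F0 is in arbitrary concentration units, decay_length_um in
    um, decay_time_h in hours; all strictly positive.
    """

    amplitude_F0: float
    decay_length_um: float
    decay_time_h: float

    def __post_init__(self):
        for name in ("amplitude_F0", "decay_length_um", "decay_time_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MorphogenParams":
        return cls(**d)


@dataclass(frozen=True)
class ThresholdRule:
    """Gradient threshold eta_t (concentration/um) with transfer slope G'.

    The wavefront sits where |dFgf8/dx| = eta_t.  For Fgf8 = G(u) with
    G monotonic, only the scalar slope G'(u_t) at threshold enters the
    closed forms; the default G is the identity (G' = 1).
    """

    eta_t: float
    transfer_slope: float = 1.0

    def __post_init__(self):
        if not self.eta_t > 0:
            raise ValueError("eta_t must be strictly positive")
        if self.transfer_slope < 0:
            raise ValueError("transfer_slope must be non-negative")


@dataclass(frozen=True)
class ClockSchedule:
    """Segmentation clock ticks: boundary n forms at t_n = t0 + n * period_h."""

    period_h: float
    n_somites: int
    t0: float = 0.0

    def __post_init__(self):
        if not self.period_h > 0:
            raise ValueError("period_h must be strictly positive")
        if self.n_somites < 1:
            raise ValueError("n_somites must be a positive integer")

    def times(self) -> np.ndarray:
        return self.t0 + self.period_h * np.arange(self.n_somites + 1)


@dataclass(frozen=True)
class BoundarySeries:
    """Somite boundary positions over clock ticks.

    ``index`` holds n = 0..N, ``times`` the formation times t_n (h),
    ``positions`` the boundary positions x_n (um from the tail end) and
    ``sizes`` the tail-frame somite sizes l_n = |x_n - x_(n-1)| for n >= 1
    (NaN at n = 0).  ``truncated`` flags a series cut short because x_n
    would have left the domain (x < 0).
    """

    index: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    sizes: np.ndarray
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.index, "t_h": self.times, "x_um": self.positions,
             "l_um": self.sizes}
        )


def _field_args(x, t):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x is a distance from the tail end and must be >= 0")
    return x, np.asarray(t, dtype=float)


def field_value(x, t, params: MorphogenParams):
    """u(x,t) = F0 exp(-x/lambda - t/tau); positive, decreasing in x and t."""
    x, t = _field_args(x, t)
    return params.amplitude_F0 * np.exp(
        -x / params.decay_length_um - t / params.decay_time_h
    )


def mean_concentration(t, params: MorphogenParams, psm_length: float | None = None):
    """Spatial integral of the field at time t (concentration * um).

    With an unbounded domain (default) this is F0 * lambda * exp(-t/tau);
    over a finite PSM of length L it is F0 * lambda * (1 - exp(-L/lambda))
    * exp(-t/tau).  Either way the temporal decay is exp(-t/tau), so
    ratios M(t1)/M(t2) do not depend on the domain.
    """
    lam = params.decay_length_um
    t = np.asarray(t, dtype=float)
    if psm_length is None:
        geom = lam
    else:
        if not psm_length > 0:
            raise ValueError("psm_length must be strictly positive")
        geom = lam * (1.0 - np.exp(-psm_length / lam))
    return params.amplitude_F0 * geom * np.exp(-t / params.decay_time_h)


def gradient_magnitude(x, t, params: MorphogenParams):
    """|du/dx| = u(x,t) / lambda for the exponential field."""
    return field_value(x, t, params) / params.decay_length_um


def anchor_position(params: MorphogenParams, rule: ThresholdRule) -> float:
    """Anchor x0 = lambda * ln(G' F0 / (eta_t lambda)), the boundary at t = 0.

    May be negative when the gradient never reaches the threshold inside
    the domain; the value is returned as-is with a warning.
    """
    if not rule.transfer_slope > 0:
        raise ValueError("transfer_slope must be strictly positive for an anchor")
    lam = params.decay_length_um
    x0 = lam * np.log(rule.transfer_slope * params.amplitude_F0 / (rule.eta_t * lam))
    if x0 < 0:
        warnings.warn(
            "anchor position is negative: the gradient threshold is never "
            "reached inside the domain (x >= 0)",
            stacklevel=2,
        )
    return float(x0)


def _series_from_positions(times: np.ndarray, positions: np.ndarray) -> BoundarySeries:
    n_all = np.arange(len(positions))
    keep = positions >= 0
    truncated = not keep.all()
    if truncated:
        # keep the leading run of in-domain boundaries
        first_bad = int(np.argmin(keep))
        n_all, times, positions = n_all[:first_bad], times[:first_bad], positions[:first_bad]
    sizes = np.full(len(positions), np.nan)
    if len(positions) > 1:
        sizes[1:] = np.abs(np.diff(positions))
    return BoundarySeries(
        index=n_all, times=times, positions=positions, sizes=sizes, truncated=truncated
    )


def boundary_series(
    params: MorphogenParams, rule: ThresholdRule, clock: ClockSchedule
) -> BoundarySeries:
    """Boundary positions x_n = x0 - lambda * t_n / tau at clock ticks t_n.

    With the default clock origin t0 = 0 this is the constant-spacing
    series x_n = x0 - n * tau_s * lambda / tau: the PSM shrinks by
    lambda/tau per unit time regardless of threshold or amplitude.  The
    series is truncated (and flagged) where x_n would go below 0.
    """
    x0 = anchor_position(params, rule)
    times = clock.times()
    positions = x0 - params.decay_length_um * times / params.decay_time_h
    return _series_from_positions(times, positions)


def boundary_series_general(
    decay_profile: Callable[[np.ndarray], np.ndarray],
    params: MorphogenParams,
    rule: ThresholdRule,
    clock: ClockSchedule,
) -> BoundarySeries:
    """Boundary series for a general temporal amplitude, u = F(t) exp(-x/lambda).

    ``decay_profile`` maps time (h) to the field amplitude F(t) (must be
    strictly positive at every clock tick).  The threshold crossing is at
    x_n = lambda * ln(G' F(t_n) / (eta_t lambda)); with
    F(t) = F0 exp(-t/tau) this reduces exactly to :func:`boundary_series`,
    while a constant F freezes the wavefront (the PSM does not shrink) and
    a slower-than-exponential decay yields shrinking somite spacing.
    """
    if not rule.transfer_slope > 0:
        raise ValueError("transfer_slope must be strictly positive")
    lam = params.decay_length_um
    times = clock.times()
    amps = np.asarray(decay_profile(times), dtype=float)
    if amps.shape != times.shape:
        amps = np.broadcast_to(amps, times.shape).astype(float)
    if np.any(amps <= 0):
        raise ValueError("decay_profile must be strictly positive at all clock ticks")
    positions = lam * np.log(rule.transfer_slope * amps / (rule.eta_t * lam))
    return _series_from_positions(times, positions)


@dataclass(frozen=True)
class UniformSource:
    """A spatially uniform additive Fgf8 source c(t).

    Adding a constant-in-x offset to the field leaves its spatial gradient
    — and therefore every boundary position — unchanged.
    """

    offset: Callable[[float], float]


@dataclass(frozen=True)
class ThresholdChange:
    """Persistent threshold scaling eta_t -> factor * eta_t from clock tick from_index on.

    Boundaries n >= from_index + 1 are computed with the new threshold and
    shift by -lambda * ln(factor); exactly one somite size (l at
    from_index + 1) differs from baseline.
    """

    factor: float
    from_index: int = 0

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError("threshold factor must be strictly positive")
        if self.from_index < 0:
            raise ValueError("from_index must be >= 0")


def apply_perturbation(
    params: MorphogenParams,
    rule: ThresholdRule,
    clock: ClockSchedule,
    perturbation: UniformSource | ThresholdChange,
) -> BoundarySeries:
    """Boundary series under a perturbation of the field or the threshold.

    A :class:`UniformSource` does not alter the spatial gradient, so the
    series equals the baseline exactly.  A :class:`ThresholdChange` with
    factor k shifts every boundary from tick from_index + 1 onward by
    -lambda * ln(k), changing a single somite size.
    """
    base = boundary_series(params, rule, clock)
    if isinstance(perturbation, UniformSource):
        # d/dx (u + c(t)) = du/dx: threshold crossings are unchanged
        return base
    if isinstance(perturbation, ThresholdChange):
        x0 = anchor_position(params, rule)
        times = clock.times()
        lam = params.decay_length_um
        positions = x0 - lam * times / params.decay_time_h
        shift = -lam * np.log(perturbation.factor)
        idx = np.arange(len(positions))
        positions = np.where(idx >= perturbation.from_index + 1, positions + shift, positions)
        return _series_from_positions(times, positions)
    raise TypeError(f"unknown perturbation type: {type(perturbation).__name__}")


# ---------------------------------------------------------------------------
# Kymograph kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KymographModel:
    """Linear kinematics of tail, PSM and wavefront.

    ``v_tail_um_h`` is the tail elongation rate and ``v_psm_shrink_um_h``
    the magnitude of the PSM shortening rate (both >= 0, um/h);
    ``psm_length_0_um`` the PSM length at t = 0; ``period_h`` the
    segmentation period, used for the lab-frame somite size.  In the lab
    frame the wavefront advances at v_tail + v_psm_shrink.
    """

    v_tail_um_h: float
    v_psm_shrink_um_h: float
    psm_length_0_um: float
    period_h: float

    def __post_init__(self):
        if self.v_tail_um_h < 0 or self.v_psm_shrink_um_h < 0:
            raise ValueError("rates are magnitudes and must be >= 0")
        if not self.psm_length_0_um > 0:
            raise ValueError("psm_length_0_um must be strictly positive")
        if not self.period_h > 0:
            raise ValueError("period_h must be strictly positive")

    @property
    def v_front_um_h(self) -> float:
        return self.v_tail_um_h + self.v_psm_shrink_um_h


@dataclass(frozen=True)
class KymographTrace:
    """Sampled (time, tail position, PSM length, wavefront position) trace.

    Noise-free, front = tail - psm at every sample.  ``truncated`` flags a
    simulation cut short because the PSM length would have gone negative.
    """

    times: np.ndarray
    tail_um: np.ndarray
    psm_um: np.ndarray
    front_um: np.ndarray
    sampling_h: float
    noise_sd_um: float = 0.0
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_h": self.times, "tail_um": self.tail_um,
             "psm_um": self.psm_um, "front_um": self.front_um}
        )


def simulate_kymograph(
    model: KymographModel,
    duration_h: float,
    sampling_h: float,
    noise_sd_um: float = 0.0,
    seed: int | None = None,
) -> KymographTrace:
    """Simulate a kymograph trace with optional Gaussian measurement noise.

    Noise-free kinematics: tail = v_tail * t, psm = L0 - v_psm * t,
    front = tail - psm.  Gaussian noise of sd ``noise_sd_um`` is added
    independently to each tail and psm sample (front keeps the identity
    front = tail - psm on the noisy columns).  A seed is mandatory
    whenever noise is requested; the trace is deterministic under a fixed
    seed.  Samples where the noise-free PSM length would be negative are
    dropped and the trace flagged truncated.
    """
    if not duration_h > 0 or not sampling_h > 0:
        raise ValueError("duration and sampling interval must be positive")
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be >= 0")
    if noise_sd_um > 0 and seed is None:
        raise ValueError("a seed is required for stochastic simulation")

    times = np.arange(0.0, duration_h + 0.5 * sampling_h, sampling_h)
    tail = model.v_tail_um_h * times
    psm = model.psm_length_0_um - model.v_psm_shrink_um_h * times
    keep = psm >= 0
    truncated = not keep.all()
    if truncated:
        first_bad = int(np.argmin(keep))
        times, tail, psm = times[:first_bad], tail[:first_bad], psm[:first_bad]
    if noise_sd_um > 0:
        rng = np.random.default_rng(seed)
        tail = tail + rng.normal(0.0, noise_sd_um, size=times.shape)
        psm = psm + rng.normal(0.0, noise_sd_um, size=times.shape)
    front = tail - psm
    return KymographTrace(
        times=times, tail_um=tail, psm_um=psm, front_um=front,
        sampling_h=sampling_h, noise_sd_um=noise_sd_um, truncated=truncated,
    )


@dataclass(frozen=True)
class VelocityEstimates:
    """Fitted rates (um/h) with standard errors; v_front = v_tail + v_psm_shrink."""

    v_tail: float
    v_tail_se: float
    v_psm_shrink: float
    v_psm_shrink_se: float
    v_front: float
    v_front_se: float


def estimate_velocities(trace: KymographTrace) -> VelocityEstimates:
    """Estimate tail, PSM-shrinkage and wavefront rates from a trace.

    Ordinary line fits (unit weights — the trace carries no per-sample
    sds) of the tail and PSM columns against time; the shrinkage rate is
    the negated PSM slope, and the wavefront rate is the sum of the two
    magnitudes with errors combined in quadrature.  Needs >= 3 samples.
    """
    from .qpcr import fit_weighted_line

    if len(trace) < 3:
        raise ValueError("need at least 3 samples to estimate velocities")
    ft = fit_weighted_line(trace.times, trace.tail_um)
    fp = fit_weighted_line(trace.times, trace.psm_um)
    v_tail, v_psm = ft.slope, -fp.slope
    se_front = float(np.hypot(ft.slope_se, fp.slope_se))
    return VelocityEstimates(
        v_tail=float(v_tail),
        v_tail_se=float(ft.slope_se),
        v_psm_shrink=float(v_psm),
        v_psm_shrink_se=float(fp.slope_se),
        v_front=float(v_tail + v_psm),
        v_front_se=se_front,
    )


def lab_frame_somite_size(model: KymographModel) -> float:
    """Distance travelled by the wavefront in one clock period (um).

    (v_tail + v_psm_shrink) * tau_s.  When both rates scale as
    beta * (T - Tc) and the period as coeff / (T - Tc), the temperature
    factors cancel and the somite size is temperature independent.
    """
    return model.v_front_um_h * model.period_h
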