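"""RT-qPCR deltaCt analysis for somitogenesis transcript dynamics.

The measured quantity is the threshold-cycle difference between a gene of
interest (GOI) and a reference gene, deltaCt = Ct_GOI - Ct_ref, averaged
over PCR replicates.  One deltaCt cycle corresponds to a two-fold
concentration ratio, so deltaCt = log2(<[ref]>/<[goi]>) and a linear drift
of deltaCt in time means an exponential decay of the GOI concentration.

This module turns replicate Ct tables into deltaCt series with propagated
uncertainties, fits chi-square weighted straight lines against time or
somite stage, pools series taken at different temperatures onto the
stage axis (where critical scaling predicts they collapse onto one line),
tests that collapse with an F statistic, classifies genes as time-varying
or constant, and scores candidate reference genes for stability.

Ct tables are pandas DataFrames with columns
``sample, gene, temperature_C, stage, time_h, replicate, ct``
(``stage`` or ``time_h`` may be NaN, not both).  deltaCt series are
DataFrames with columns ``sample, temperature_C, stage, time_h, delta_ct,
sd, n_replicates``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import PERIOD_COEFF_H_C, T_CRITICAL_C
from .scaling import LN2, time_to_stage

__all__ = [
    "LinearFitResult",
    "GeneClassification",
    "CollapseFit",
    "CollapseTest",
    "delta_ct_table",
    "relative_concentration",
    "fit_weighted_line",
    "fit_dct_vs_stage",
    "pooled_collapse_fit",
    "collapse_test",
    "classify_gene",
    "decay_time_from_slope",
    "reference_stability",
]

logger = logging.getLogger("somitewave")

#: Practical Ct resolution (cycles); weights in fits are floored at this sd.
DEFAULT_FLOOR_SD = 0.2


@dataclass(frozen=True)
class LinearFitResult:
    """Weighted straight-line fit y = slope * x + intercept.

    ``cov`` is the 2x2 covariance of (slope, intercept).  With per-point
    sds the errors come from the unscaled inverse normal matrix (the
    chi-square convention) and ``chi2`` is the weighted sum of squared
    residuals; with unit weights (``unit_weights=True``) the errors are
    scaled by the residual variance and ``chi2`` is the plain residual sum
    of squares.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    chi2: float
    df: int
    cov: np.ndarray
    unit_weights: bool = False

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_weighted_line(x, y, sd=None) -> LinearFitResult:
    """Chi-square weighted straight-line fit, minimizing sum(((y-ax-b)/sd)^2).

    Delegates the linear algebra to statsmodels WLS (OLS when ``sd`` is
    None).  Requires n >= 2 and at least two distinct x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: singular design")

    X = sm.add_constant(x)
    if sd is None:
        res = sm.OLS(y, X).fit()
        resid = y - res.fittedvalues
        chi2 = float(resid @ resid)
        if n > 2:
            cov_ci = np.asarray(res.cov_params())
        else:
            cov_ci = np.full((2, 2), np.nan)
        unit = True
    else:
        sd = np.asarray(sd, dtype=float)
        if sd.shape != x.shape:
            raise ValueError("sd must match x in length")
        if not np.all(np.isfinite(sd)) or np.any(sd <= 0):
            raise ValueError("per-point sds must be finite and strictly positive")
        res = sm.WLS(y, X, weights=1.0 / sd**2).fit()
        resid = (y - res.fittedvalues) / sd
        chi2 = float(resid @ resid)
        cov_ci = np.asarray(res.normalized_cov_params)
        unit = False

    # statsmodels orders parameters (intercept, slope); expose (slope, intercept)
    swap = np.array([[0, 1], [1, 0]])
    cov = swap @ cov_ci @ swap.T
    se = np.sqrt(np.diag(cov))
    return LinearFitResult(
        slope=float(res.params[1]),
        slope_se=float(se[0]),
        intercept=float(res.params[0]),
        intercept_se=float(se[1]),
        chi2=chi2,
        df=int(n - 2),
        cov=cov,
        unit_weights=unit,
    )


def delta_ct_table(
    records: pd.DataFrame,
    goi: str,
    reference: str,
    floor_sd_single: float = DEFAULT_FLOOR_SD,
) -> pd.DataFrame:
    """Per-sample deltaCt = mean(Ct_goi) - mean(Ct_ref) with propagated sd.

    Replicates are averaged per (sample, gene); the point sd is the
    standard errors of the two means combined in quadrature,
    sqrt(sd_goi^2/n_goi + sd_ref^2/n_ref).  A gene measured with a single
    replicate contributes ``floor_sd_single`` (default 0.2 cycles) instead
    of an undefined sample sd.  Samples missing either gene are dropped
    with a logged warning; no overlap at all is an error.  Points are
    ordered by stage (or time when stage is absent).
    """
    needed = {"sample", "gene", "ct"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")

    def _summ(gene: str) -> pd.DataFrame:
        sub = records[records["gene"] == gene]
        g = sub.groupby("sample")["ct"]
        out = g.agg(mean="mean", sd="std", n="count")
        se = out["sd"] / np.sqrt(out["n"])
        se = se.where(out["n"] > 1, float(floor_sd_single))
        out["se"] = se
        return out

    s_goi = _summ(goi)
    s_ref = _summ(reference)
    if s_goi.empty:
        raise ValueError(f"gene of interest {goi!r} not present in the table")
    if s_ref.empty:
        raise ValueError(f"reference gene {reference!r} not present in the table")

    common = s_goi.index.intersection(s_ref.index)
    dropped = s_goi.index.difference(s_ref.index)
    if len(dropped):
        logger.warning(
            "dropping %d sample(s) without reference-gene measurements: %s",
            len(dropped),
            list(dropped),
        )
    if len(common) == 0:
        raise ValueError("no sample has both the gene of interest and the reference")

    meta_cols = [c for c in ("temperature_C", "stage", "time_h") if c in records.columns]
    meta = (
        records[records["gene"] == goi]
        .drop_duplicates("sample")
        .set_index("sample")[meta_cols]
        if meta_cols
        else pd.DataFrame(index=s_goi.index)
    )

    out = pd.DataFrame(
        {
            "delta_ct": s_goi.loc[common, "mean"] - s_ref.loc[common, "mean"],
            "sd": np.sqrt(
                s_goi.loc[common, "se"] ** 2 + s_ref.loc[common, "se"] ** 2
            ),
            "n_replicates": s_goi.loc[common, "n"],
        }
    )
    out = meta.loc[common].join(out) if meta_cols else out
    out.index.name = "sample"
    out = out.reset_index()
    sort_key = "stage" if "stage" in out.columns and out["stage"].notna().any() else (
        "time_h" if "time_h" in out.columns else None
    )
    if sort_key is not None:
        out = out.sort_values(sort_key, kind="stable").reset_index(drop=True)
    return out


def relative_concentration(delta_ct):
    """Concentration of the gene of interest relative to the reference, 2^(-deltaCt)."""
    return 2.0 ** (-np.asarray(delta_ct, dtype=float))


def _effective_sd(points: pd.DataFrame, floor_sd: float, pool_sds: bool = True):
    """Fit weights from point sds; None (unit weights) if all sds are 0.

    Per-point sds estimated from a handful of replicates carry only a few
    degrees of freedom, so raw 1/sd^2 weights are unstable — a lucky
    near-zero sample sd pins the line to one point and collapses its
    reported error.  Technical Ct noise is homoskedastic to a good
    approximation, so by default the replicate scatter is pooled across
    points (root-mean-square sd), floored at the instrument's practical
    Ct resolution.  ``pool_sds=False`` keeps per-point sds (still floored)
    for genuinely heteroskedastic data.  An all-zero sd column means
    deterministic input: fall back to unit weights.
    """
    if "sd" not in points.columns:
        return None
    sd = points["sd"].to_numpy(dtype=float)
    if np.all(sd == 0):
        return None
    if pool_sds:
        return np.full_like(sd, max(float(np.sqrt(np.mean(sd**2))), floor_sd))
    return np.maximum(sd, floor_sd)


def fit_dct_vs_stage(
    points: pd.DataFrame,
    x: str = "stage",
    floor_sd: float = DEFAULT_FLOOR_SD,
    pool_sds: bool = True,
) -> LinearFitResult:
    """Weighted line fit of deltaCt against somite stage (or time).

    Requires >= 3 points spanning >= 2 distinct x values.  ``x`` selects
    the abscissa column (``"stage"`` or ``"time_h"``).
    """
    if x not in points.columns:
        raise ValueError(f"points table has no {x!r} column")
    if len(points) < 3:
        raise ValueError("need at least 3 deltaCt points")
    xs = points[x].to_numpy(dtype=float)
    if np.unique(xs).size < 2:
        raise ValueError(f"need at least two distinct {x} values")
    ys = points["delta_ct"].to_numpy(dtype=float)
    return fit_weighted_line(xs, ys, _effective_sd(points, floor_sd, pool_sds))


@dataclass(frozen=True)
class CollapseFit:
    """Pooled stage-axis fit across temperatures, with per-T residual chi2."""

    fit: LinearFitResult
    per_temperature_chi2: dict[float, float]
    n_points: int


def pooled_collapse_fit(
    series_by_temperature: Mapping[float, pd.DataFrame],
    coeff: float = PERIOD_COEFF_H_C,
    tc: float = T_CRITICAL_C,
    floor_sd: float = DEFAULT_FLOOR_SD,
    pool_sds: bool = True,
) -> CollapseFit:
    """Rescale time to somite stage per temperature, pool, and fit one line.

    Each series must carry a ``time_h`` column; it is converted to stage
    via s = t / tau_s(T) with tau_s(T) = coeff/(T - tc).  Under critical
    scaling, deltaCt data taken at different temperatures collapse onto a
    single line in stage, deltaCt = a' * s + b.  The per-temperature
    chi-square of the pooled line is reported alongside.
    """
    if len(series_by_temperature) < 2:
        raise ValueError("need series from at least two temperatures")
    frames = []
    for T, pts in series_by_temperature.items():
        if "time_h" not in pts.columns:
            raise ValueError(f"series at {T} degC lacks a time_h column")
        pts = pts.copy()
        pts["stage"] = time_to_stage(pts["time_h"].to_numpy(dtype=float), T, coeff, tc)
        pts["__T"] = T
        frames.append(pts)
    pooled = pd.concat(frames, ignore_index=True)
    fit = fit_dct_vs_stage(pooled, x="stage", floor_sd=floor_sd, pool_sds=pool_sds)

    per_t: dict[float, float] = {}
    for T, pts in pooled.groupby("__T"):
        resid = pts["delta_ct"].to_numpy(dtype=float) - fit.predict(
            pts["stage"].to_numpy(dtype=float)
        )
        sd = _effective_sd(pts, floor_sd, pool_sds)
        per_t[float(T)] = float(np.sum((resid / sd) ** 2 if sd is not None else resid**2))
    return CollapseFit(fit=fit, per_temperature_chi2=per_t, n_points=len(pooled))


@dataclass(frozen=True)
class CollapseTest:
    """F test of one pooled line vs separate per-temperature lines.

    A small F (large p) means the series from different temperatures are
    consistent with a single line on the stage axis — the collapse holds.
    """

    f_stat: float
    p_value: float
    chi2_pooled: float
    df_pooled: int
    chi2_separate: float
    df_separate: int
    pooled: LinearFitResult
    per_temperature: dict[float, LinearFitResult]


def collapse_test(
    series_by_temperature: Mapping[float, pd.DataFrame],
    x: str = "stage",
    floor_sd: float = DEFAULT_FLOOR_SD,
    pool_sds: bool = True,
) -> CollapseTest:
    """Test whether stage-axis deltaCt series from several temperatures collapse.

    Fits one pooled line and one line per temperature, then compares
    F = ((chi2_pooled - chi2_sep)/(df_pooled - df_sep)) / (chi2_sep/df_sep)
    against an F(df_pooled - df_sep, df_sep) null.  Requires >= 2
    temperatures with >= 3 points each.
    """
    if len(series_by_temperature) < 2:
        raise ValueError("collapse test needs at least two temperatures")
    per_fits: dict[float, LinearFitResult] = {}
    chi2_sep = 0.0
    frames = []
    for T, pts in series_by_temperature.items():
        if len(pts) < 3:
            raise ValueError(f"series at {T} degC has fewer than 3 points")
        fit = fit_dct_vs_stage(pts, x=x, floor_sd=floor_sd, pool_sds=pool_sds)
        per_fits[float(T)] = fit
        chi2_sep += fit.chi2
        frames.append(pts)
    pooled_pts = pd.concat(frames, ignore_index=True)
    pooled = fit_dct_vs_stage(pooled_pts, x=x, floor_sd=floor_sd, pool_sds=pool_sds)

    df_pooled = pooled.df
    df_sep = sum(f.df for f in per_fits.values())
    d1 = df_pooled - df_sep
    if d1 <= 0 or df_sep <= 0:
        raise ValueError("not enough points for the collapse F test")
    if chi2_sep == 0:
        raise ValueError("separate fits are exact; F statistic undefined")
    f_stat = ((pooled.chi2 - chi2_sep) / d1) / (chi2_sep / df_sep)
    p = float(stats.f.sf(f_stat, d1, df_sep))
    return CollapseTest(
        f_stat=float(f_stat),
        p_value=p,
        chi2_pooled=float(pooled.chi2),
        df_pooled=int(df_pooled),
        chi2_separate=float(chi2_sep),
        df_separate=int(df_sep),
        pooled=pooled,
        per_temperature=per_fits,
    )


@dataclass(frozen=True)
class GeneClassification:
    gene: str
    label: str  # "time-varying" | "constant"
    z_score: float


def classify_gene(
    fit: LinearFitResult, gene: str = "", z_threshold: float = 2.0
) -> GeneClassification:
    """Classify a transcript as time-varying or constant from its slope z-score.

    z = |slope| / se; the gene is time-varying when z >= z_threshold
    (default 2, a two-sided two-sigma rule).  A zero se counts as
    time-varying for a non-zero slope and constant otherwise.
    """
    if fit.slope_se == 0:
        z = np.inf if fit.slope != 0 else 0.0
    else:
        z = abs(fit.slope) / fit.slope_se
    label = "time-varying" if z >= z_threshold else "constant"
    return GeneClassification(gene=gene, label=label, z_score=float(z))


def decay_time_from_slope(slope: float, convention: str) -> float:
    """Concentration decay time from a positive deltaCt slope.

    Two conventions are in circulation and differ by ln 2; the caller must
    pick one explicitly:

    - ``"reciprocal"``: tau = 1/slope — treats the deltaCt slope directly
      as the inverse time constant (halving time per cycle reading).
    - ``"log2"``: tau = 1/(ln2 * slope) — the e-folding time of the
      concentration 2^(-deltaCt), which decays at rate ln2 * slope.

    The returned time is in the units of the slope's abscissa (somitic
    periods for a per-stage slope, hours for a per-hour slope).
    """
    if slope <= 0:
        raise ValueError("slope must be strictly positive")
    if convention == "reciprocal":
        return 1.0 / slope
    if convention == "log2":
        return 1.0 / (LN2 * slope)
    raise ValueError("convention must be 'reciprocal' or 'log2'")


def reference_stability(
    records: pd.DataFrame, candidates: list[str]
) -> pd.DataFrame:
    """Rank candidate reference genes by stability across samples.

    A simplified BestKeeper-style score: for each candidate, the standard
    deviation of its per-sample mean Ct across samples (primary, ascending
    — the most stable gene varies least) and the mean pairwise Pearson
    correlation with the other candidates (secondary, descending — good
    references co-vary as overall input material varies).  This is not the
    full BestKeeper geometric-mean index.

    Candidates missing in more than half the samples are excluded with a
    logged warning.  Returns a DataFrame with columns
    ``gene, ct_sd, mean_pairwise_r, rank`` sorted by rank.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate reference genes")
    sub = records[records["gene"].isin(candidates)]
    wide = sub.pivot_table(index="sample", columns="gene", values="ct", aggfunc="mean")
    keep = []
    for g in candidates:
        if g not in wide.columns or wide[g].notna().mean() <= 0.5:
            logger.warning("candidate %r missing in >50%% of samples; excluded", g)
            continue
        keep.append(g)
    if len(keep) < 2:
        raise ValueError("fewer than two candidates with sufficient coverage")
    wide = wide[keep]
    if len(wide) < 3:
        raise ValueError("need at least three samples per candidate")

    sds = wide.std(ddof=1)
    corr = wide.corr(method="pearson")
    mean_r = (corr.sum(axis=0) - 1.0) / (len(keep) - 1)
    out = pd.DataFrame(
        {"gene": keep, "ct_sd": sds[keep].to_numpy(), "mean_pairwise_r": mean_r[keep].to_numpy()}
    )
    out = out.sort_values(
        ["ct_sd", "mean_pairwise_r"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
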