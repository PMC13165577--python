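"""Time-series rheology: calibrated flow rates, viscosity, shear and AI.

Turns the per-trigger channel observables (velocities Umc/Uac, intensities
Imc/Iac, interface alpha_b) into calibrated flow rates, the coflow-model
viscosity and shear-rate series, the continuous RBC aggregation index
AI = (Imc - Iac)/Imc, the conventional stopped-flow AI, and the summary
statistics used to compare runs (plateau velocity, AI_max, COV, normalized
difference, linear fits).

Missing-value policy: any trigger with an invalid interface, failed PIV or
undefined AI yields NaN in the outputs; gaps are propagated, never
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chip_model
from .chip_model import (
    ChipGeometry,
    CorrectionFactorModel,
    DEFAULT_CF,
    DegenerateFlowError,
    DomainError,
)

TIMESERIES_COLUMNS = ["t", "Umc", "Uac", "n_valid_mc", "n_valid_ac",
                      "Imc", "Iac", "wb", "alpha_b"]


class NoPlateauError(ValueError):
    """No contiguous low-variation run qualifies as a velocity plateau."""


@dataclass
class RheologySummary:
    plateau_umc_mm_s: float
    ai_max: float
    cov_wb_pct: float
    n_triggers: int
    n_valid_mu: int


@dataclass
class StasisResult:
    """Conventional stopped-flow aggregation measurement."""

    t_stop_s: float
    duration_s: float
    ai_conv: float


def plateau_velocity(series, window_frac: float = 0.1,
                     cv_threshold: float = 0.05,
                     min_run_frac: float = 0.1) -> float:
    """Steady plateau value <Umc> of a velocity time series.

    The series is scanned with a centred rolling window (``window_frac`` of
    its length); samples whose local coefficient of variation is below
    ``cv_threshold`` qualify, and the mean over the longest contiguous
    qualifying run (earliest on ties, covering at least ``min_run_frac`` of
    the samples) is returned.
    """
    u = pd.Series(np.asarray(series, dtype=float))
    n = int(u.notna().sum())
    if n < 20:
        raise ValueError("plateau selection needs >= 20 valid samples")
    win = max(3, int(round(window_frac * len(u))))
    roll = u.rolling(win, center=True, min_periods=max(2, win // 2))
    mean = roll.mean()
    sd = roll.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.inf)
    ok = np.asarray((cv < cv_threshold) & u.notna())

    best_start, best_len = -1, 0
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_len < max(1, int(np.ceil(min_run_frac * len(u)))):
        raise NoPlateauError(
            "no contiguous low-CV run long enough for a plateau; "
            "select the averaging window manually")
    return float(u.iloc[best_start:best_start + best_len].mean())


def calibrate_flow_rates(u_mc, u_ac, u_mc_plateau: float,
                         q_b: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale velocities to flow rates: Q = U / <Umc> * Qb.

    Any multiplicative velocimetry bias common to Umc and the plateau
    cancels by construction.
    """
    if not u_mc_plateau > 0:
        raise ValueError("plateau velocity must be > 0")
    if not q_b > 0:
        raise ValueError("Qb must be > 0")
    u_mc = np.asarray(u_mc, dtype=float)
    u_ac = np.asarray(u_ac, dtype=float)
    return u_mc / u_mc_plateau * q_b, u_ac / u_mc_plateau * q_b


def aggregation_index(i_mc, i_ac):
    """Continuous RBC aggregation index AI = (Imc - Iac) / Imc, per trigger.

    Undefined (NaN, with a warning) where Imc <= 0.
    """
    i_mc = np.asarray(i_mc, dtype=float)
    i_ac = np.asarray(i_ac, dtype=float)
    scalar = i_mc.ndim == 0
    i_mc, i_ac = np.atleast_1d(i_mc), np.atleast_1d(i_ac)
    bad = ~(i_mc > 0)
    if bad.any():
        warnings.warn(f"AI undefined at {int(bad.sum())} trigger(s) with "
                      "Imc <= 0", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(bad, np.nan, (i_mc - i_ac) / i_mc)
    return float(ai[0]) if scalar else ai


def viscosity_series(alpha_b, q_mc, q_ac, q_r: float, mu_r: float,
                     geometry: ChipGeometry | None = None,
                     cf_model: CorrectionFactorModel = DEFAULT_CF,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trigger blood viscosity and viscosity-channel shear rate.

    Applies the coflow formula with the calibrated blood stream Qmc - Qac;
    triggers with an interface outside the correction-factor domain or a
    non-positive blood stream yield NaN.
    """
    geometry = geometry or ChipGeometry()
    alpha_b = np.asarray(alpha_b, dtype=float)
    q_mc = np.asarray(q_mc, dtype=float)
    q_ac = np.asarray(q_ac, dtype=float)
    mu = np.full(alpha_b.shape, np.nan)
    shear = np.full(alpha_b.shape, np.nan)
    for i in range(alpha_b.size):
        a, qm, qa = alpha_b.flat[i], q_mc.flat[i], q_ac.flat[i]
        if not (np.isfinite(a) and np.isfinite(qm) and np.isfinite(qa)):
            continue
        try:
            mu.flat[i] = chip_model.blood_viscosity(a, q_r, qm, qa, mu_r,
                                                    cf_model)
            shear.flat[i] = chip_model.shear_rate_viscosity_channel(
                qm, qa, a, geometry.width_mm, geometry.depth_mm)
        except (DomainError, DegenerateFlowError):
            continue
    return mu, shear


def stasis_ai(t, i_trace, t_stop: float, duration: float = 120.0) -> StasisResult:
    """Conventional stopped-flow aggregation index.

    AI_conv = (I(t_stop) - I(t_stop + duration)) / I(t_stop), where
    I(t_stop) is the mean of the first five samples after the stop and the
    endpoint is the sample nearest t_stop + duration.
    """
    t = np.asarray(t, dtype=float)
    i_trace = np.asarray(i_trace, dtype=float)
    after = t >= t_stop
    if after.sum() < 5 or t[after].max() < t_stop + duration - 1e-9:
        raise ValueError(
            f"trace must cover [{t_stop}, {t_stop + duration}] s after the stop")
    t_a, i_a = t[after], i_trace[after]
    order = np.argsort(t_a)
    t_a, i_a = t_a[order], i_a[order]
    i_start = float(i_a[:5].mean())
    i_end = float(i_a[np.argmin(np.abs(t_a - (t_stop + duration)))])
    if i_start <= 0:
        raise ValueError("non-positive intensity at flow stop")
    return StasisResult(t_stop_s=t_stop, duration_s=duration,
                        ai_conv=(i_start - i_end) / i_start)


def ai_max(ai_series, smooth_window: int = 11) -> float:
    """Representative AI: maximum of the moving-average-smoothed series.

    The window is odd and edge-truncated; ``smooth_window=1`` reduces to the
    plain maximum.  Raises if every value is missing.
    """
    ai = pd.Series(np.asarray(ai_series, dtype=float))
    if ai.notna().sum() == 0:
        raise ValueError("no valid AI values")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    smoothed = ai.rolling(smooth_window, center=True, min_periods=1).mean()
    return float(smoothed.max())


def normalized_difference(measured: float, expected: float) -> float:
    """ND = |measured - expected| / |expected| * 100, in percent."""
    if expected == 0:
        raise ValueError("expected value must be nonzero")
    return abs(measured - expected) / abs(expected) * 100.0


def coefficient_of_variation(series) -> float:
    """Sample COV = SD / mean * 100, in percent."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("COV needs at least two samples")
    mean = x.mean()
    if mean == 0:
        raise ValueError("COV undefined for zero mean")
    return float(x.std(ddof=1) / abs(mean) * 100.0)


def linear_fit(x, y, through_origin: bool = False
               ) -> tuple[float, float, float]:
    """Ordinary least squares y ~ x, returning (slope, intercept, R^2).

    With ``through_origin`` the intercept is constrained to zero.  R^2 uses
    the 1 - SSres/SStot convention about the mean of y; a constant y
    (SStot = 0) yields R^2 = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("linear fit needs >= 2 points")
    if through_origin:
        sxx = float(x @ x)
        if sxx == 0:
            raise ValueError("cannot fit through origin with all-zero x")
        slope = float(x @ y) / sxx
        intercept = 0.0
    else:
        if np.ptp(x) == 0:
            raise ValueError("zero x-variance: free fit is degenerate")
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        warnings.warn("constant y: R^2 reported as 0 by convention",
                      RuntimeWarning, stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def compute_rheology(timeseries: pd.DataFrame, q_b: float, q_r: float,
                     mu_r: float, geometry: ChipGeometry | None = None,
                     cf_model: CorrectionFactorModel = DEFAULT_CF,
                     plateau_window_frac: float = 0.1,
                     plateau_cv_threshold: float = 0.05,
                     ai_smooth_window: int = 11,
                     ) -> tuple[pd.DataFrame, RheologySummary]:
    """Full conversion of a channel time series into a rheology table.

    ``timeseries`` must carry the columns t, Umc, Uac, Imc, Iac, alpha_b
    (wb optional).  Returns the per-trigger rheology table and a summary.
    """
    geometry = geometry or ChipGeometry()
    plateau = plateau_velocity(timeseries["Umc"],
                               window_frac=plateau_window_frac,
                               cv_threshold=plateau_cv_threshold)
    q_mc, q_ac = calibrate_flow_rates(timeseries["Umc"], timeseries["Uac"],
                                      plateau, q_b)
    ai = aggregation_index(timeseries["Imc"], timeseries["Iac"])
    mu, shear = viscosity_series(timeseries["alpha_b"], q_mc, q_ac,
                                 q_r, mu_r, geometry, cf_model)
    result = pd.DataFrame({
        "t": timeseries["t"].to_numpy(dtype=float),
        "Qmc_mLh": q_mc, "Qac_mLh": q_ac, "Qvc_mLh": q_b - q_ac,
        "mu_b_cP": mu, "shear_s1": shear, "AI": ai})
    cov_wb = (coefficient_of_variation(timeseries["wb"])
              if "wb" in timeseries and
              np.isfinite(timeseries["wb"]).sum() >= 2 else float("nan"))
    summary = RheologySummary(
        plateau_umc_mm_s=plateau,
        ai_max=ai_max(ai, ai_smooth_window),
        cov_wb_pct=cov_wb,
        n_triggers=len(result),
        n_valid_mu=int(np.isfinite(mu).sum()))
    return result, summary
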