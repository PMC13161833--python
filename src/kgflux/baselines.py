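"""Reference nighttime and daytime flux-partitioning methods.

Deliberately simplified single-pass implementations of the two classical
approaches used as comparators: a nighttime method that fits a Lloyd-Taylor
temperature response to nocturnal NEE in moving windows and extrapolates it
through the day, and a daytime method that fits a rectangular-hyperbola
light-response curve with a VPD-limited plateau and reads respiration off
its intercept. Neither clips negative GPP, and both satisfy
NEE = RECO - GPP identically on every partitioned row.

No u*-filtering, uncertainty ensembles or gap-filling — these are the
governing-equation versions, not re-implementations of the operational
processing chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import LT_T0, LT_TREF, lloyd_taylor

__all__ = [
    "NTParams", "DTParams", "FitError",
    "fit_nighttime", "partition_nighttime",
    "fit_daytime", "partition_daytime",
]

log = logging.getLogger(__name__)

NIGHT_PPFD_THRESHOLD = 5.0  # μmol m-2 s-1; low-light criterion for baseline fits


class FitError(RuntimeError):
    """No window anywhere produced a valid parameter fit."""


@dataclass
class NTParams:
    """Lloyd-Taylor parameters for one moving window (nighttime method)."""

    center: pd.Timestamp
    rref: float   # μmol CO2 m-2 s-1 at the reference temperature
    e0: float     # temperature sensitivity, K


@dataclass
class DTParams:
    """Light-response parameters for one moving window (daytime method)."""

    center: pd.Timestamp
    alpha: float    # initial slope, μmol CO2 per μmol photons
    beta: float     # plateau GPP at the VPD threshold, μmol CO2 m-2 s-1
    k_vpd: float    # exponential plateau reduction above the threshold, kPa-1
    rd: float       # intercept respiration at reference temperature
    e0: float       # shared temperature sensitivity, K


def _window_centers(index: pd.DatetimeIndex, window_days: int, step_days: int
                    ) -> list[pd.Timestamp]:
    start, end = index[0].normalize(), index[-1]
    centers = []
    c = start + pd.Timedelta(days=window_days / 2)
    while c - pd.Timedelta(days=window_days / 2) <= end:
        centers.append(c)
        c += pd.Timedelta(days=step_days)
    return centers


def fit_nighttime(table: pd.DataFrame, window_days: int = 14, step_days: int = 7,
                  min_samples: int = 20, tref: float = LT_TREF, t0: float = LT_T0,
                  e0_max: float = 450.0) -> list[NTParams]:
    """Fit R(T) = Rref exp(E0 (1/(Tref-T0) - 1/(T-T0))) to nocturnal NEE.

    Night is PPFD < 5 μmol m-2 s-1. Windows failing the sample or
    convergence checks are skipped; callers interpolate across the valid
    windows. Raises :class:`FitError` when no window fits.
    """
    is_night = table["PPFD"].to_numpy() < NIGHT_PPFD_THRESHOLD
    params: list[NTParams] = []
    half = pd.Timedelta(days=window_days / 2)
    for center in _window_centers(table.index, window_days, step_days):
        sel = is_night & (table.index >= center - half) & (table.index < center + half)
        ta = table.loc[sel, "TA"].to_numpy()
        nee = table.loc[sel, "NEE"].to_numpy()
        ok = np.isfinite(ta) & np.isfinite(nee)
        ta, nee = ta[ok], nee[ok]
        if len(nee) < min_samples:
            continue

        def model(t, rref, e0):
            return lloyd_taylor(t, rref, e0, tref=tref, t0=t0)

        try:
            p0 = (max(float(np.mean(nee)), 0.1), 100.0)
            popt, _ = curve_fit(model, ta, nee, p0=p0,
                                bounds=([0.0, 0.0], [np.inf, e0_max]), maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        params.append(NTParams(center, float(popt[0]), float(popt[1])))
    if not params:
        raise FitError("nighttime fit failed in every window")
    return params


def _interp_series(index: pd.DatetimeIndex, centers: list[pd.Timestamp],
                   values: list[float]) -> np.ndarray:
    t = index.view("int64").astype(float)
    tc = np.array([c.value for c in centers], dtype=float)
    return np.interp(t, tc, np.asarray(values, dtype=float))


def partition_nighttime(table: pd.DataFrame, params: list[NTParams],
                        tref: float = LT_TREF, t0: float = LT_T0) -> pd.DataFrame:
    """Extrapolate the nocturnal temperature response and split NEE.

    RECO_NT = R(T) at every half-hour with window parameters interpolated in
    time; GPP_NT = RECO_NT - NEE (negative values are kept, a documented
    contrast with the constrained model).
    """
    rref = _interp_series(table.index, [p.center for p in params], [p.rref for p in params])
    e0 = _interp_series(table.index, [p.center for p in params], [p.e0 for p in params])
    ta = table["TA"].to_numpy()
    reco = lloyd_taylor(ta, rref, e0, tref=tref, t0=t0)
    out = table.copy()
    out["RECO_NT"] = reco
    out["GPP_NT"] = reco - out["NEE"].to_numpy()
    return out


def light_response_nee(ppfd: np.ndarray, vpd: np.ndarray, ta: np.ndarray,
                       alpha: float, beta: float, k_vpd: float, rd: float,
                       e0: float = 0.0, vpd_threshold: float = 1.0) -> np.ndarray:
    """Rectangular-hyperbola NEE model with VPD-limited plateau.

    NEE = Rd * f(TA) - alpha * beta_eff * PPFD / (alpha * PPFD + beta_eff),
    beta_eff = beta * exp(-k_vpd * max(VPD - threshold, 0)). With e0 = 0 the
    respiration intercept is temperature-independent.
    """
    beta_eff = beta * np.exp(-k_vpd * np.maximum(vpd - vpd_threshold, 0.0))
    denom = alpha * ppfd + beta_eff
    gpp = np.where(denom > 0, alpha * beta_eff * ppfd / np.where(denom > 0, denom, 1.0), 0.0)
    return rd * lloyd_taylor(ta, 1.0, e0) - gpp


def fit_daytime(table: pd.DataFrame, window_days: int = 14, step_days: int = 7,
                min_samples: int = 20, vpd_threshold: float = 1.0,
                e0_shared: float | None = None) -> list[DTParams]:
    """Fit the light-response model to daytime NEE in moving windows.

    The shared temperature sensitivity of the respiration intercept defaults
    to the median E0 of a nighttime fit on the same table (0 if that fails);
    the VPD-limitation rate is fixed at zero in windows that never exceed
    the VPD threshold, where it is unidentifiable.
    """
    if e0_shared is None:
        try:
            e0_shared = float(np.median([p.e0 for p in fit_nighttime(
                table, window_days, step_days, min_samples)]))
        except FitError:
            e0_shared = 0.0
    is_day = table["PPFD"].to_numpy() >= NIGHT_PPFD_THRESHOLD
    params: list[DTParams] = []
    half = pd.Timedelta(days=window_days / 2)
    for center in _window_centers(table.index, window_days, step_days):
        sel = is_day & (table.index >= center - half) & (table.index < center + half)
        sub = table.loc[sel, ["PPFD", "VPD", "TA", "NEE"]].dropna()
        if len(sub) < min_samples:
            continue
        ppfd = sub["PPFD"].to_numpy()
        vpd = sub["VPD"].to_numpy()
        ta = sub["TA"].to_numpy()
        nee = sub["NEE"].to_numpy()
        fit_k = bool((vpd > vpd_threshold).sum() >= 5)
        beta0 = max(float(-np.percentile(nee, 5)), 1.0)

        try:
            if fit_k:
                def model(x, alpha, beta, k_vpd, rd):
                    p, v, t = x
                    return light_response_nee(p, v, t, alpha, beta, k_vpd, rd,
                                              e0_shared, vpd_threshold)
                popt, _ = curve_fit(model, (ppfd, vpd, ta), nee,
                                    p0=(0.03, beta0, 0.2, 1.0),
                                    bounds=([0, 0, 0, 0], [1.0, 200.0, 5.0, 50.0]),
                                    maxfev=20000)
                alpha, beta, k_vpd, rd = popt
            else:
                def model(x, alpha, beta, rd):
                    p, v, t = x
                    return light_response_nee(p, v, t, alpha, beta, 0.0, rd,
                                              e0_shared, vpd_threshold)
                popt, _ = curve_fit(model, (ppfd, vpd, ta), nee,
                                    p0=(0.03, beta0, 1.0),
                                    bounds=([0, 0, 0], [1.0, 200.0, 50.0]),
                                    maxfev=20000)
                alpha, beta, rd = popt
                k_vpd = 0.0
        except (RuntimeError, ValueError):
            continue
        params.append(DTParams(center, float(alpha), float(beta), float(k_vpd),
                               float(rd), e0_shared))
    if not params:
        raise FitError("daytime fit failed in every window")
    return params


def partition_daytime(table: pd.DataFrame, params: list[DTParams]) -> pd.DataFrame:
    """Split NEE using the fitted light-response intercept respiration.

    RECO_DT = Rd(T) from interpolated window parameters;
    GPP_DT = RECO_DT - NEE.
    """
    centers = [p.center for p in params]
    rd = _interp_series(table.index, centers, [p.rd for p in params])
    e0 = params[0].e0
    ta = table["TA"].to_numpy()
    reco = rd * lloyd_taylor(ta, 1.0, e0)
    out = table.copy()
    out["RECO_DT"] = reco
    out["GPP_DT"] = reco - out["NEE"].to_numpy()
    return out
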