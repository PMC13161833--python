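"""Synthetic half-hourly ecosystem with known latent carbon and water fluxes.

Generates the full predictor set a flux tower provides (NEE, energy and
radiation terms, meteorology, and high-frequency-partitioned canopy/surface
components) from simple, documented process forms, while retaining the latent
decomposition (GPP, the three respiration components, stomatal conductance,
transpiration and evaporation) as ground truth for recovery experiments.

The functional forms here are deliberately conventional stand-ins — a
rectangular-hyperbola light response with temperature and soil-moisture
modifiers, Medlyn-form stomatal conductance, Lloyd-Taylor respiration, and an
exponential light suppression of above-ground autotrophic respiration — chosen
so that every downstream inference step can be tested against exact truth.
They are not a calibrated ecosystem model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SiteConfig", "TrueFluxes", "generate_met", "simulate_fluxes", "write_site"]

SIGMA_SB = 5.670374e-8  # W m-2 K-4
LT_T0 = -46.02  # Lloyd-Taylor reference offset, deg C
LT_TREF = 15.0  # Lloyd-Taylor reference temperature, deg C
LAMBDA_MOL = 44.0e-3  # latent heat of vaporisation per mmol H2O, W s mmol-1


@dataclass
class SiteConfig:
    """Parameters of one synthetic site-year.

    Rates are in μmol CO2 m-2 s-1, conductances in mol m-2 s-1, light in
    μmol photons m-2 s-1, VPD in kPa.
    """

    latitude_deg: float = 43.0
    n_days: int = 365
    start_doy: int = 1
    amax: float = 25.0              # light-saturated gross assimilation
    k_light: float = 400.0          # half-saturation PPFD
    g1: float = 3.0                 # Medlyn slope, kPa^0.5
    g0: float = 0.01                # residual conductance, mol m-2 s-1
    ra0_above: float = 1.2          # base above-ground autotrophic respiration
    ra0_below: float = 0.6          # base below-ground autotrophic respiration
    rh0: float = 0.8                # base heterotrophic respiration
    e0_resp: float = 185.0          # Lloyd-Taylor activation energy, K
    kok_max_suppression: float = 0.15
    kok_ppfd_scale: float = 100.0
    noise_sd_nee: float = 0.5
    noise_sd_partition: float = 0.3
    heteroscedastic_noise: bool = False  # SD grows with |flux| when enabled
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.latitude_deg) > 90.0:
            raise ValueError(f"invalid latitude {self.latitude_deg}")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.kok_max_suppression <= 1.0:
            raise ValueError("kok_max_suppression must be in [0, 1]")
        for name in ("amax", "k_light", "g1", "g0", "ra0_above", "ra0_below",
                     "rh0", "e0_resp", "kok_ppfd_scale", "noise_sd_nee",
                     "noise_sd_partition"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")


@dataclass
class TrueFluxes:
    """Latent decomposition kept by the simulator for recovery tests."""

    gpp: np.ndarray           # μmol CO2 m-2 s-1
    ra_above: np.ndarray
    ra_below: np.ndarray
    rh: np.ndarray
    gs: np.ndarray            # mol m-2 s-1
    transpiration: np.ndarray  # mmol H2O m-2 s-1
    evaporation: np.ndarray    # mmol H2O m-2 s-1

    @property
    def reco(self) -> np.ndarray:
        return self.ra_above + self.ra_below + self.rh

    def to_frame(self, index: pd.DatetimeIndex) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "GPP_true": self.gpp,
                "Ra_above_true": self.ra_above,
                "Ra_below_true": self.ra_below,
                "Rh_true": self.rh,
                "RECO_true": self.reco,
                "gs_true": self.gs,
                "T_true": self.transpiration,
                "E_true": self.evaporation,
            },
            index=index,
        )


def saturation_vapour_pressure(ta_c: np.ndarray) -> np.ndarray:
    """Tetens form, kPa."""
    return 0.6108 * np.exp(17.27 * ta_c / (ta_c + 237.3))


def lloyd_taylor(ta_c: np.ndarray, rref: float, e0: float,
                 tref: float = LT_TREF, t0: float = LT_T0) -> np.ndarray:
    """Respiration R(T) = Rref * exp(E0 * (1/(Tref-T0) - 1/(T-T0)))."""
    ta_c = np.maximum(ta_c, t0 + 1.0)  # keep the denominator positive
    return rref * np.exp(e0 * (1.0 / (tref - t0) - 1.0 / (ta_c - t0)))


def _potential_ppfd(lat_deg: float, doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
    """Clear-sky PPFD from solar geometry; zero below the horizon."""
    lat = np.deg2rad(lat_deg)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return 2200.0 * np.maximum(cos_z, 0.0)


def generate_met(config: SiteConfig) -> pd.DataFrame:
    """Half-hourly meteorological drivers for one synthetic site record.

    PPFD follows solar geometry with multiplicative daily cloudiness and is
    exactly zero at night; VPD derives from TA and RH through the saturation
    vapour pressure; soil moisture follows stochastic recharge events with
    exponential drydown.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days * 48
    start = pd.Timestamp("2021-01-01") + pd.Timedelta(days=config.start_doy - 1)
    index = pd.date_range(start, periods=n, freq="30min")
    doy = ((config.start_doy - 1 + np.arange(n) // 48) % 365) + 1.0
    hour = (np.arange(n) % 48) / 2.0

    # --- radiation / light ---
    ppfd_pot = _potential_ppfd(config.latitude_deg, doy, hour)
    daily_cloud = np.clip(0.85 + 0.35 * rng.standard_normal(config.n_days), 0.25, 1.0)
    cloud = np.repeat(daily_cloud, 48) * np.clip(
        1.0 + 0.08 * rng.standard_normal(n), 0.6, 1.3
    )
    ppfd = ppfd_pot * cloud
    ppfd[ppfd_pot <= 0.0] = 0.0

    # --- temperature: seasonal + diurnal cycle + slow noise ---
    t_season = 12.0 + 10.0 * np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    t_diurnal = 5.5 * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
    ar = np.zeros(n)
    eps = 0.35 * rng.standard_normal(n)
    for i in range(1, n):
        ar[i] = 0.95 * ar[i - 1] + eps[i]
    ta = t_season + t_diurnal + ar

    # --- humidity / VPD ---
    rh = np.clip(82.0 - 2.2 * t_diurnal - 4.0 * rng.standard_normal(config.n_days).repeat(48)
                 + 2.0 * rng.standard_normal(n), 25.0, 100.0)
    vpd = saturation_vapour_pressure(ta) * (1.0 - rh / 100.0)
    vpd = np.maximum(vpd, 0.0)

    # --- soil moisture: Poisson recharge, exponential drydown ---
    sm = np.empty(n)
    sm[0] = 0.28
    rain = rng.random(n) < (0.08 / 48.0 * 6.0)  # a few events per fortnight
    recharge = rng.uniform(0.02, 0.10, size=n)
    for i in range(1, n):
        sm[i] = sm[i - 1] * (1.0 - 1.0 / (18.0 * 48.0))
        if rain[i]:
            sm[i] += recharge[i]
    sm = np.clip(sm, 0.03, 0.45)

    ws = np.clip(3.0 + 1.2 * rng.standard_normal(n), 0.2, None)
    sw_in = ppfd / 2.1  # μmol photons -> W m-2, canonical conversion
    sw_out = 0.15 * sw_in
    lw_in = 0.80 * SIGMA_SB * (ta + 273.15) ** 4
    lw_out = 0.97 * SIGMA_SB * (ta + 273.15) ** 4
    night = (ppfd <= 0.0).astype(float)
    co2 = 415.0 + 12.0 * night + 1.5 * rng.standard_normal(n)
    tsonic = ta + 0.2 * rng.standard_normal(n)

    return pd.DataFrame(
        {
            "PPFD": ppfd,
            "TA": ta,
            "VPD": vpd,
            "SM": sm,
            "RH": rh,
            "WS": ws,
            "SW_IN": sw_in,
            "SW_OUT": sw_out,
            "LW_IN": lw_in,
            "LW_OUT": lw_out,
            "CO2": co2,
            "Tsonic": tsonic,
        },
        index=index,
    )


def kok_factor(ppfd: np.ndarray, max_suppression: float, ppfd_scale: float) -> np.ndarray:
    """Light suppression multiplier for above-ground autotrophic respiration.

    Equals 1 in darkness and saturates at (1 - max_suppression) at high light.
    """
    return 1.0 - max_suppression * (1.0 - np.exp(-ppfd / ppfd_scale))


def simulate_fluxes(drivers: pd.DataFrame, config: SiteConfig
                    ) -> tuple[pd.DataFrame, TrueFluxes]:
    """Couple carbon and water fluxes to the drivers and emit the tower table.

    Returns the observable table (with noise) and the latent truth. The NEE
    column equals RECO_true - GPP_true plus Gaussian noise; the partitioned
    canopy/surface columns carry their own (independent) noise.
    """
    if drivers.isna().any().any():
        raise ValueError("drivers contain missing values")
    rng = np.random.default_rng(config.seed + 1)
    ppfd = drivers["PPFD"].to_numpy()
    ta = drivers["TA"].to_numpy()
    vpd = drivers["VPD"].to_numpy()
    sm = drivers["SM"].to_numpy()
    co2 = drivers["CO2"].to_numpy()

    # gross assimilation: light response * temperature optimum * moisture
    f_t = np.exp(-((ta - 25.0) ** 2) / (2.0 * 10.0**2))
    f_sm = sm / (sm + 0.08)
    gpp = config.amax * ppfd / (ppfd + config.k_light) * f_t * f_sm

    # Medlyn-form stomatal conductance and water fluxes
    vpd_safe = np.maximum(vpd, 1e-6)
    gs = config.g0 + 1.6 * (1.0 + config.g1 / np.sqrt(vpd_safe)) * gpp / co2
    transp = 1000.0 * gs * vpd / 101.325  # mmol H2O m-2 s-1
    evap = 0.012 * np.maximum(drivers["SW_IN"].to_numpy(), 0.0) * (sm / 0.3)

    # respiration components; soil proxy = trailing 24 h mean air temperature
    t_soil = pd.Series(ta, index=drivers.index).rolling(48, min_periods=1).mean().to_numpy()
    kok = kok_factor(ppfd, config.kok_max_suppression, config.kok_ppfd_scale)
    ra_above = lloyd_taylor(ta, config.ra0_above, config.e0_resp) * kok
    ra_below = lloyd_taylor(t_soil, config.ra0_below, config.e0_resp)
    rh_flux = lloyd_taylor(t_soil, config.rh0, config.e0_resp)
    truth = TrueFluxes(gpp, ra_above, ra_below, rh_flux, gs, transp, evap)

    nee_clean = truth.reco - gpp
    scale = (1.0 + 0.1 * np.abs(nee_clean)) if config.heteroscedastic_noise else 1.0
    eps_nee = config.noise_sd_nee * scale * rng.standard_normal(len(ppfd))
    eps_p = config.noise_sd_partition * rng.standard_normal(len(ppfd))
    eps_r = config.noise_sd_partition * rng.standard_normal(len(ppfd))

    nee = nee_clean + eps_nee
    et = transp + evap
    le = et * LAMBDA_MOL * 1000.0  # W m-2
    h = 0.45 * drivers["SW_IN"].to_numpy() - 0.3 * le + 5.0 * rng.standard_normal(len(ppfd))

    table = drivers.copy()
    table["NEE"] = nee
    table["ET"] = et
    table["LE"] = le
    table["H"] = h
    table["T_cea"] = np.maximum(transp + 0.02 * rng.standard_normal(len(ppfd)), 0.0)
    table["E_cea"] = np.maximum(evap + 0.02 * rng.standard_normal(len(ppfd)), 0.0)
    table["P_cea"] = gpp - ra_above + eps_p
    table["R_cea"] = ra_below + rh_flux + eps_r
    table["NEE_mean"] = _three_night_mean_nee(table)
    return table, truth


def _three_night_mean_nee(table: pd.DataFrame) -> np.ndarray:
    """Mean nocturnal NEE over the observation night and the two adjacent nights.

    A 'night' is the dark period spanning midnight, indexed by the date the
    timestamp falls on after a 12 h shift.
    """
    is_night = table["PPFD"].to_numpy() <= 0.001
    night_id = (table.index + pd.Timedelta(hours=12)).normalize()
    nee = pd.Series(table["NEE"].to_numpy(), index=night_id)
    nightly = nee[is_night].groupby(level=0).mean()
    # window of three consecutive nights, centred
    smoothed = nightly.rolling(3, center=True, min_periods=1).mean()
    return smoothed.reindex(night_id).to_numpy()


def write_site(path: str | Path, config: SiteConfig) -> tuple[Path, Path]:
    """Generate one site record and write the flux and truth CSVs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    drivers = generate_met(config)
    table, truth = simulate_fluxes(drivers, config)
    out = table.copy()
    out.insert(0, "TIMESTAMP_START", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)
    truth_path = path.with_name(path.stem + "_truth.csv")
    tf = truth.to_frame(table.index)
    tf.insert(0, "TIMESTAMP_START", table.index.strftime("%Y-%m-%dT%H:%M:%S"))
    tf.to_csv(truth_path, index=False)
    return path, truth_path
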