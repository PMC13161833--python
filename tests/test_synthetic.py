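"""Generator contracts: solar geometry, mass balance, Kok suppression, determinism."""

import numpy as np
import pandas as pd
import pytest

import kgflux as kg
from kgflux.synthetic import kok_factor, lloyd_taylor, saturation_vapour_pressure


@pytest.fixture(scope="module")
def noiseless():
    cfg = kg.SiteConfig(n_days=60, start_doy=120, noise_sd_nee=0.0,
                        noise_sd_partition=0.0, seed=2)
    drivers = kg.generate_met(cfg)
    table, truth = kg.simulate_fluxes(drivers, cfg)
    return cfg, table, truth


def test_ppfd_zero_at_night(small_site):
    _, table, _ = small_site
    midnight = table.index.hour == 0
    assert (table.loc[midnight, "PPFD"] == 0).all()
    # and strictly positive at local noon in summer
    noon = (table.index.hour == 12) & (table.index.minute == 0)
    assert (table.loc[noon, "PPFD"] > 0).all()


def test_vpd_zero_at_saturation():
    assert saturation_vapour_pressure(np.array([20.0]))[0] == pytest.approx(2.34, abs=0.02)
    # RH = 100% => VPD = 0 regardless of temperature
    for ta in (0.0, 15.0, 35.0):
        vpd = saturation_vapour_pressure(np.array([ta])) * (1 - 100.0 / 100.0)
        assert vpd[0] == 0.0


def test_same_seed_identical_different_seed_not():
    cfg = kg.SiteConfig(n_days=7, seed=9)
    t1, _ = kg.simulate_fluxes(kg.generate_met(cfg), cfg)
    t2, _ = kg.simulate_fluxes(kg.generate_met(cfg), cfg)
    pd.testing.assert_frame_equal(t1, t2)
    cfg3 = kg.SiteConfig(n_days=7, seed=10)
    t3, _ = kg.simulate_fluxes(kg.generate_met(cfg3), cfg3)
    assert np.abs(t1["NEE"].to_numpy() - t3["NEE"].to_numpy()).max() > 0.1


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        kg.SiteConfig(latitude_deg=95.0)
    with pytest.raises(ValueError):
        kg.SiteConfig(n_days=0)
    with pytest.raises(ValueError):
        kg.SiteConfig(amax=-1.0)
    with pytest.raises(ValueError):
        kg.SiteConfig(kok_max_suppression=1.5)


def test_truth_nonnegative_and_dark_gpp_zero(small_site):
    _, table, truth = small_site
    for arr in (truth.gpp, truth.ra_above, truth.ra_below, truth.rh,
                truth.gs, truth.transpiration, truth.evaporation):
        assert (arr >= 0).all()
    dark = table["PPFD"].to_numpy() == 0.0
    assert (truth.gpp[dark] == 0).all()
    # no light suppression in darkness
    np.testing.assert_allclose(kok_factor(np.zeros(3), 0.2, 100.0), 1.0)


def test_noiseless_identities(noiseless):
    _, table, truth = noiseless
    np.testing.assert_allclose(table["NEE"].to_numpy(), truth.reco - truth.gpp,
                               atol=1e-12)
    np.testing.assert_allclose(table["P_cea"].to_numpy(), truth.gpp - truth.ra_above,
                               atol=1e-12)
    np.testing.assert_allclose(table["R_cea"].to_numpy(), truth.ra_below + truth.rh,
                               atol=1e-12)
    np.testing.assert_allclose(table["ET"].to_numpy(),
                               truth.transpiration + truth.evaporation, atol=1e-12)


def test_mass_balance_of_noisy_components(small_site):
    cfg, table, truth = small_site
    # subtracting the truth leaves only the injected observation noise
    p_noise = table["P_cea"].to_numpy() - (truth.gpp - truth.ra_above)
    r_noise = table["R_cea"].to_numpy() - (truth.ra_below + truth.rh)
    assert np.abs(p_noise).max() < 6 * cfg.noise_sd_partition
    assert np.abs(r_noise).max() < 6 * cfg.noise_sd_partition


def test_gpp_monotone_in_ppfd_and_kok_monotone():
    ppfd = np.linspace(0, 2000, 200)
    gpp = 25.0 * ppfd / (ppfd + 400.0)
    assert (np.diff(gpp) >= 0).all()
    kok = kok_factor(ppfd, 0.15, 100.0)
    assert (np.diff(kok) <= 0).all()
    assert kok[0] == 1.0 and kok[-1] > 0.85 - 1e-9


def test_kok_suppression_magnitude_in_literature_range(noiseless):
    """Daytime above-ground respiration sits 10-20% below darkness at equal TA."""
    cfg, table, truth = noiseless
    ppfd = table["PPFD"].to_numpy()
    ta = table["TA"].to_numpy()
    # factor out the temperature response analytically, then compare strata
    base = lloyd_taylor(ta, cfg.ra0_above, cfg.e0_resp)
    ratio = truth.ra_above / base
    dark = ratio[ppfd == 0.0].mean()
    lit = ratio[(ppfd >= 200) & (ppfd <= 600)].mean()
    suppression = 1.0 - lit / dark
    assert 0.10 <= suppression <= 0.20


def test_heteroscedastic_noise_option():
    base = dict(n_days=40, start_doy=150, seed=3)
    homo = kg.SiteConfig(**base)
    hetero = kg.SiteConfig(heteroscedastic_noise=True, **base)
    t_homo, truth = kg.simulate_fluxes(kg.generate_met(homo), homo)
    t_het, _ = kg.simulate_fluxes(kg.generate_met(hetero), hetero)
    resid_homo = np.abs(t_homo["NEE"].to_numpy() - (truth.reco - truth.gpp))
    resid_het = np.abs(t_het["NEE"].to_numpy() - (truth.reco - truth.gpp))
    big = np.abs(truth.reco - truth.gpp) > 5.0
    # at large fluxes the heteroscedastic residuals are systematically larger
    assert resid_het[big].mean() > resid_homo[big].mean()


def test_write_site_round_trip(tmp_path):
    cfg = kg.SiteConfig(n_days=3, seed=4)
    flux_path, truth_path = kg.write_site(tmp_path / "site.csv", cfg)
    table = kg.read_flux_csv(flux_path)
    assert len(table) == 3 * 48
    assert set(kg.REQUIRED_COLUMNS) <= set(table.columns)
    truth = pd.read_csv(truth_path)
    assert len(truth) == len(table)
    assert "GPP_true" in truth.columns
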