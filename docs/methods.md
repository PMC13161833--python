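# Methods

`kgflux` partitions half-hourly eddy-covariance net ecosystem exchange (NEE)
into gross primary productivity (GPP) and ecosystem respiration (RECO) with a
multi-head neural network trained under hard mass-balance constraints and soft
ecophysiological losses. This note records the model, the synthetic ecosystem
used to test it, the numerical choices, and what the tests do and do not show.

## The partitioning model

NEE is the only carbon flux a tower measures; the decomposition
`NEE = RECO − GPP` is underdetermined without further structure. The network
treats GPP, the three respiration components (above-ground autotrophic
R_a,above, below-ground autotrophic R_a,below, heterotrophic R_h), canopy
stomatal conductance g_s and a per-timestep water-use-efficiency prior
WUE_hat as latent states, each predicted by an independent head branch on a
shared three-layer dense encoder (width 128, tanh, dropout 0.1 after each
hidden layer). Every head ends in a softplus, so non-negativity of all
components is architectural, not penalised. A forward output layer derives

    RECO      = R_a,above + R_a,below + R_h
    NEE_pred  = RECO − GPP
    P_canopy  = GPP − R_a,above        (net canopy CO2 flux)
    R_surface = R_a,below + R_h        (net surface CO2 flux)

so carbon closure holds to machine precision for any parameter values. Three
global coefficients — kMed (stomatal-optimality proportionality), betaT
(temperature scaling) and kT (conductance-to-transpiration scaling) — are
learnable scalars passed through a softplus, initialised at 1.0, 0.01 and 1.0.
g_s carries arbitrary model units; the physical scaling is absorbed by kMed
and kT because no conductance observations exist to pin units. Each timestep
is processed independently; no temporal recurrence.

## Loss terms

The training objective is a weighted sum `L = Σ_j w_j L_j` over:

| term   | form | role |
|--------|------|------|
| nee    | mean squared `NEE_obs − NEE_pred` | carbon-closure anchor |
| medlyn | mean abs. `GPP − kMed·g_s·PPFD/√VPD·(1 + betaT·TA)` on daytime rows | stomatal-optimality coupling |
| wue    | mean abs. `GPP/T_cea − WUE_hat` on daytime rows with T_cea > 0.05 mmol m⁻² s⁻¹ | water-use-efficiency prior |
| gs_t   | mean abs. `kT·g_s·VPD − T_cea` | conductance–transpiration link |
| night  | mean of `(1 − m)·GPP`, mask m = 1 iff PPFD > 0.001 μmol m⁻² s⁻¹ | zero GPP in darkness |
| pcea   | mean abs. `(GPP − R_a,above) − P_cea` | guidance toward partitioned canopy flux |
| rcea   | mean abs. `(R_a,below + R_h) − R_cea` | guidance toward partitioned surface flux |
| base   | mean of `ReLU(base_reco − RECO)` | one-sided nocturnal lower bound on RECO |

Two renderings of the stomatal-optimality target are plausible
(`PPFD/√VPD`, matching the `1 + g1/√D` VPD dependence of the unified
optimality model, or `PPFD/VPD`); both are implemented, the square-root form
is the default, and the choice is a config switch rather than a hidden
commitment. Likewise the deviation norm for the coupling terms defaults to
mean absolute deviation (robust to the heavy tails of ratio and partitioned
quantities) with a squared-error variant selectable. The closure term is
always squared.

`base_reco` is the mean nocturnal NEE over the observation night and the two
adjacent nights (a trailing/previous-night window is selectable), clipped at
zero; the one-sided ReLU means predictions above the baseline are never
penalised, so it acts purely as a guard against low-amplitude degenerate
solutions.

**Weights.** Defaults are w_nee = 1.0, w_medlyn = 0.3, w_night = 1.0,
w_pcea = w_rcea = 0.5, w_wue = 0.05, w_gs_t = 0.1, w_base = 0.1, selected
empirically on synthetic data. The partitioned-flux guidance terms carry
more weight than the remaining soft couplings because the canopy/surface
observations are the only direct constraints on how respiration splits into
components: with weaker guidance (0.1) the closure and GPP recovery are
unchanged but the observation noise that closure forces somewhere leaks into
RECO, degrading component recovery on held-out data. 0.5 keeps validation
NEE R² ≈ 0.998 while lifting held-out RECO correlation from ~0.80 to ~0.87.

**Training.** Adam, learning rate 1e-3, batch 256, up to 150 epochs with
early stopping (patience 25) on the validation total; the checkpoint with the
best validation total is returned. Data are split into contiguous 5-day
blocks assigned at random (seeded) to train/validation — no half-hour of a
day leaks across the split — and normalization statistics come from the
training split only. Rows with any missing model input are excluded and
counted. Training aborts with the offending term named if any loss goes
non-finite.

**Constraint importance.** For each weighted term, the L2 norm of its
gradient with respect to the whole parameter vector is computed in isolation
per batch, averaged, and normalized to percentages. Computed on the final
epoch's batches by default (all epochs selectable) because full tracking
triples the backward cost.

**Ablations.** Removing a constraint means zeroing its weight and retraining
from the same seed and epoch budget, never fine-tuning; all runs are scored
on the same validation split.

**Uncertainty.** Monte Carlo dropout: stochastic forward passes with the
training dropout rate active at inference, summarized as empirical 5th/50th/
95th percentiles per timestep. The sampler is seeded, so envelopes are
reproducible. MC dropout is known to be approximately, not exactly,
calibrated; the empirical coverage of the nominal-90% interval is reported
by the evaluation module rather than asserted.

## Synthetic ecosystem

Field studies of this method run on tower networks; this package ships a
generator so every claim is testable against known latent truth without
external data. It emulates the full predictor table (NEE, ET, LE, H, PPFD,
TA, VPD, SM, RH, WS, sonic temperature, four radiation streams, CO2,
three-night mean nocturnal NEE, and the high-frequency-partitioned
components T_cea, E_cea, P_cea, R_cea) at half-hourly resolution.

Functional forms are deliberately conventional stand-ins, chosen once:

- **Light:** clear-sky PPFD from solar geometry (declination + hour angle)
  times daily cloudiness (clipped Gaussian, AR within day), exactly zero
  below the horizon.
- **GPP:** rectangular hyperbola in PPFD (Amax = 25 μmol m⁻² s⁻¹,
  half-saturation 400 μmol m⁻² s⁻¹) × Gaussian temperature optimum
  (25 °C, σ = 10 °C) × saturating soil-moisture modifier.
- **Conductance/water:** Medlyn form
  g_s = g0 + 1.6(1 + g1/√VPD)·GPP/CO2 with g1 = 3 kPa^0.5; transpiration
  T = 1000·g_s·VPD/101.325 mmol m⁻² s⁻¹; evaporation scales with shortwave
  and soil moisture.
- **Respiration:** Lloyd-Taylor R(T) = R_ref·exp(E0(1/(Tref−T0) − 1/(T−T0)))
  with Tref = 15 °C, T0 = −46.02 °C, E0 = 185 K; above-ground autotrophic on
  air temperature, below-ground and heterotrophic on a soil proxy (trailing
  24 h mean of air temperature — no soil column is simulated).
- **Light suppression (Kok effect):** R_a,above is multiplied by
  1 − s_max(1 − e^(−PPFD/100)) with s_max = 0.15, applied to the
  above-ground autotrophic component only. At moderate light (200–600
  μmol m⁻² s⁻¹) this suppresses about 14% of R_a,above, inside the 10%–20%
  range leaf and canopy studies report.
- **Noise:** additive Gaussian, sd 0.5 μmol m⁻² s⁻¹ on NEE and 0.3 on the
  partitioned canopy/surface fluxes (independent), roughly matching the
  half-hourly random flux error of well-behaved towers. A heteroscedastic
  option exists but is off by default.

What the generator does **not** emulate: radiative transfer, phenology and
leaf-area dynamics, u*/advection artefacts and storage fluxes, gap
structure, C4/CAM physiology, drought legacy. Passing recovery tests on this
world therefore shows the inference machinery is correct and the constraint
set is sufficient to de-alias GPP from RECO under realistic noise — it does
not certify accuracy on real towers, where the latent truth is unobservable
and the forcing is richer.

## Classical baselines

The comparison methods are single-pass, governing-equation implementations:

- **Nighttime (NT):** Lloyd-Taylor fit to nocturnal NEE (PPFD < 5
  μmol m⁻² s⁻¹) in 14-day windows stepped by 7 days (minimum 20 samples,
  E0 bounded to [0, 450] K), parameters linearly interpolated between window
  centres, extrapolated through the day; GPP_NT = RECO_NT − NEE, negative
  values kept.
- **Daytime (DT):** rectangular-hyperbola light response
  NEE = Rd·f(TA) − αβ'P/(αP + β') per window, with the plateau β reduced
  exponentially above a 1 kPa VPD threshold (the reduction rate is fixed at
  zero in windows that never exceed the threshold, where it is
  unidentifiable) and the intercept temperature sensitivity shared from the
  NT fit; RECO_DT = Rd(T), GPP_DT = RECO_DT − NEE.

No u*-uncertainty ensembles, short-window E0 pre-estimation cascades, or
gap-filling: the operational processing chains add machinery that is
irrelevant to the structural comparison made here, and real-data comparisons
with those chains are therefore qualitative.

## Numerical and engineering choices

- The network, Adam, dropout and per-term gradient tracking run on a small
  reverse-mode automatic-differentiation engine over numpy arrays written
  for this package (`kgflux.autodiff`) and verified against central finite
  differences. Pure numpy keeps runs bit-reproducible for a fixed seed on
  one CPU.
- VPD is floored at 1e-6 kPa inside the √VPD of the stomatal target;
  the WUE ratio is only evaluated where T_cea > 0.05 mmol m⁻² s⁻¹.
- Empty-mask losses (no valid rows) return 0 with a warning rather than NaN.
- Timestamps mark period start, local standard time; "hour of day" for
  composites is hour + minute/60; dawn/dusk windows are half-open
  [4, 9) and [16, 21).
- PPFD-binned difference tables keep an overflow bin so counts always
  partition the sample.
- R² is the squared Pearson correlation by default (regression-style
  reporting); the coefficient of determination about the 1:1 line is also
  computed.

## Problem sizes

The shipped experiments train on one synthetic site-year (17,520
half-hours, ~80/20 block split). The ablation suite retrains nine models at
a reduced 20-epoch budget, which is enough for the ranking of constraint
importance to stabilise even though individual R² values are below their
fully-trained counterparts.

## Known limitations

- The low-light respiration comparison against the NT baseline mixes two
  mechanisms. Measured against the generator's truth, the NT overestimate
  actually grows with light (suppression saturates, and the nocturnal
  regression's warm-hour extrapolation error grows with temperature); the
  model-minus-NT divergence is nonetheless deepest in the 0–200
  μmol m⁻² s⁻¹ bin because the trained model also infers slightly lower
  GPP — and, through closure, lower RECO — in the low-light transition
  periods. The direction of the comparison is robust; its attribution to
  light suppression alone is not.
- Coefficients kMed, betaT, kT are global; real networks of sites would
  need per-site or per-biome calibration.
- MC-dropout intervals are a pragmatic uncertainty proxy, not a posterior.
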