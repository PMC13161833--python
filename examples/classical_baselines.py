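"""Classical nighttime/daytime partitioning and the low-light respiration bias.

Fits the Lloyd-Taylor nocturnal-regression (NT) and light-response-intercept
(DT) methods to a Kok-suppressed synthetic record, then shows the bias the
constrained model is designed to avoid: the NT extrapolation overestimates
daytime respiration exactly where light suppression operates.
"""

import numpy as np

import kgflux as kg

site = kg.SiteConfig(n_days=120, start_doy=120, kok_max_suppression=0.15, seed=4)
table, truth = kg.simulate_fluxes(kg.generate_met(site), site)

nt = kg.partition_nighttime(table, kg.fit_nighttime(table))
dt = kg.partition_daytime(table, kg.fit_daytime(table))

day = table["PPFD"].to_numpy() > 5
gpp_nt = nt["GPP_NT"].to_numpy()
print(f"NT daytime GPP vs truth: bias {np.mean(gpp_nt[day] - truth.gpp[day]):+.2f} "
      "umol m-2 s-1")
print(f"NT produces negative GPP in {100 * np.mean(gpp_nt[day] < 0):.1f}% of daytime rows"
      " (no clipping, by construction)")

# RECO bias by light level: the nocturnal regression cannot see suppression
bias = kg.ppfd_binned_difference(nt["RECO_NT"].to_numpy()[day], truth.reco[day],
                                 table["PPFD"].to_numpy()[day],
                                 edges=(0, 200, 400, 600))
for label, mean, n in zip(bias.labels(), bias.mean_diff, bias.count):
    if n:
        print(f"  RECO_NT - RECO_true at PPFD {label:>12}: {mean:+.2f} (n={n})")
print("The nocturnal regression overestimates daytime respiration at every")
print("light level: it cannot see the light suppression of above-ground")
print("respiration, and its warm-hour extrapolation error grows with light.")

m_dt = kg.compare(truth.gpp[day], dt["GPP_DT"].to_numpy()[day])
print(f"DT daytime GPP vs truth: R2={m_dt.r2:.2f} bias {m_dt.mean_bias:+.2f}")
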