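"""Metrics and diagnostic analyses for partitioned-flux comparisons.

Pure functions: paired regression metrics, half-hourly diurnal composites,
PPFD-binned method differences, the low-light (Kok-region) respiration
analysis with dawn/dusk windows, and empirical coverage of Monte Carlo
dropout uncertainty envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import UncertaintyEnvelope

__all__ = [
    "MetricSet", "BinnedBias",
    "compare", "diurnal_composite", "ppfd_binned_difference",
    "kok_window_analysis", "uncertainty_calibration",
    "DEFAULT_PPFD_EDGES", "KOK_REGIME_EDGES",
]

#: Default PPFD bin edges for binned-bias analyses, μmol m-2 s-1.
DEFAULT_PPFD_EDGES = (0.0, 150.0, 300.0, 450.0, 600.0, 750.0, 1000.0, 1500.0, 2000.0)

#: Light regimes of the low-light respiration analysis: pure suppression zone,
#: two transition zones, and light-saturated.
KOK_REGIME_EDGES = (0.0, 20.0, 50.0, 160.0)

DAWN_WINDOW = (4.0, 9.0)    # local standard time, [start, end)
DUSK_WINDOW = (16.0, 21.0)


@dataclass
class MetricSet:
    """Paired-series statistics: candidate regressed on reference."""

    r2: float          # squared Pearson correlation
    rmse: float
    mean_bias: float   # mean(candidate - reference)
    slope: float
    intercept: float
    r2_1to1: float     # coefficient of determination about the 1:1 line
    n: int


def compare(reference: np.ndarray, candidate: np.ndarray) -> MetricSet:
    """Standard agreement metrics on aligned, finite pairs."""
    reference = np.asarray(reference, dtype=float).ravel()
    candidate = np.asarray(candidate, dtype=float).ravel()
    ok = np.isfinite(reference) & np.isfinite(candidate)
    x, y = reference[ok], candidate[ok]
    if len(x) < 3:
        raise ValueError(f"compare() needs >= 3 paired samples, got {len(x)}")
    r = sps.pearsonr(x, y).statistic
    fit = sps.linregress(x, y)
    resid = y - x
    sst = float(np.sum((x - x.mean()) ** 2))
    r2_11 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    return MetricSet(
        r2=float(r**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mean_bias=float(np.mean(resid)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2_1to1=r2_11,
        n=int(len(x)),
    )


def diurnal_composite(series: np.ndarray, timestamps: pd.DatetimeIndex,
                      percentiles: tuple[float, float] = (5.0, 95.0)) -> pd.DataFrame:
    """Composite by half-hour of local day: mean and a percentile band.

    Returns a 48-row frame indexed by decimal hour; slots without samples
    carry NaN.
    """
    series = np.asarray(series, dtype=float)
    slot = timestamps.hour * 2 + timestamps.minute // 30
    df = pd.DataFrame({"slot": slot, "value": series}).dropna()
    lo, hi = percentiles
    grouped = df.groupby("slot")["value"]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "p_lo": grouped.quantile(lo / 100.0),
            "p_hi": grouped.quantile(hi / 100.0),
            "count": grouped.size(),
        }
    ).reindex(range(48))
    out["count"] = out["count"].fillna(0).astype(int)
    out.index = out.index / 2.0
    out.index.name = "hour"
    return out


@dataclass
class BinnedBias:
    """Mean paired difference (a - b) per PPFD bin, plus counts and SDs."""

    edges: tuple[float, ...]   # strictly increasing; final bin is overflow
    mean_diff: np.ndarray
    sd_diff: np.ndarray
    count: np.ndarray

    def labels(self) -> list[str]:
        labels = [f"[{a:g}, {b:g})" for a, b in zip(self.edges[:-1], self.edges[1:])]
        labels.append(f">= {self.edges[-1]:g}")
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.labels(), "mean_diff": self.mean_diff,
                             "sd_diff": self.sd_diff, "count": self.count})


def ppfd_binned_difference(series_a: np.ndarray, series_b: np.ndarray,
                           ppfd: np.ndarray,
                           edges: tuple[float, ...] = DEFAULT_PPFD_EDGES) -> BinnedBias:
    """Per-bin mean of (a - b) over PPFD; rows above the top edge overflow."""
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    p = np.asarray(ppfd, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(p) & (p >= edges[0])
    diff = a[ok] - b[ok]
    # bins: [e0,e1), ..., [e_{k-1}, e_k), then overflow [e_k, inf)
    which = np.digitize(p[ok], edges[1:])
    n_bins = len(edges)  # len(edges)-1 interior + 1 overflow
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        d = diff[which == i]
        count[i] = len(d)
        if len(d):
            mean[i] = d.mean()
            sd[i] = d.std(ddof=0)
    return BinnedBias(edges, mean, sd, count)


def _regime_label(ppfd: np.ndarray) -> np.ndarray:
    """Assign daytime rows to the low-light regimes; NaN-safe, night excluded."""
    labels = np.array(["night"] * len(ppfd), dtype=object)
    day = ppfd > 0.001
    e = KOK_REGIME_EDGES
    labels[day & (ppfd <= e[1])] = f"({e[0]:g}, {e[1]:g}]"
    labels[day & (ppfd > e[1]) & (ppfd <= e[2])] = f"({e[1]:g}, {e[2]:g}]"
    labels[day & (ppfd > e[2]) & (ppfd <= e[3])] = f"({e[2]:g}, {e[3]:g}]"
    labels[day & (ppfd > e[3])] = f"> {e[3]:g}"
    return labels


def kok_window_analysis(predictions: pd.DataFrame, table: pd.DataFrame
                        ) -> dict[str, pd.DataFrame]:
    """Low-light respiration regimes and dawn/dusk suppression tables.

    `predictions` must provide RECO and Ra_above columns aligned with
    `table` (which provides PPFD and timestamps). Returns per-regime RECO
    summaries over all daytime rows and, for the dawn (4:00-9:00) and dusk
    (16:00-21:00) windows, mean above-ground autotrophic respiration in
    low-light PPFD bins.
    """
    ppfd = table["PPFD"].to_numpy(dtype=float)
    regimes = _regime_label(ppfd)
    base = pd.DataFrame({
        "regime": regimes,
        "ppfd": ppfd,
        "reco": np.asarray(predictions["RECO"], dtype=float),
        "ra_above": np.asarray(predictions["Ra_above"], dtype=float),
    }, index=table.index)
    day = base[base["regime"] != "night"]
    regime_summary = day.groupby("regime", sort=False).agg(
        mean_reco=("reco", "mean"), mean_ra_above=("ra_above", "mean"),
        count=("reco", "size"))

    hour = table.index.hour + table.index.minute / 60.0
    out: dict[str, pd.DataFrame] = {"regimes": regime_summary}
    bins = (0.0, 20.0, 50.0, 160.0, 600.0)
    for name, (start, end) in (("dawn", DAWN_WINDOW), ("dusk", DUSK_WINDOW)):
        w = day[(hour[base["regime"] != "night"] >= start)
                & (hour[base["regime"] != "night"] < end)]
        which = np.digitize(w["ppfd"].to_numpy(), bins[1:])
        rows = []
        for i, (a, b) in enumerate(zip(bins[:-1], bins[1:])):
            sel = w[which == i]
            rows.append({"ppfd_bin": f"[{a:g}, {b:g})",
                         "mean_ra_above": sel["ra_above"].mean() if len(sel) else np.nan,
                         "count": len(sel)})
        out[name] = pd.DataFrame(rows)
    return out


def uncertainty_calibration(envelope: UncertaintyEnvelope, gpp_truth: np.ndarray,
                            reco_truth: np.ndarray) -> dict[str, float]:
    """Empirical coverage of the nominal-90% MC-dropout intervals."""
    gpp_truth = np.asarray(gpp_truth, dtype=float).ravel()
    reco_truth = np.asarray(reco_truth, dtype=float).ravel()
    gpp_in = (gpp_truth >= envelope.gpp_p05) & (gpp_truth <= envelope.gpp_p95)
    reco_in = (reco_truth >= envelope.reco_p05) & (reco_truth <= envelope.reco_p95)
    return {"gpp_coverage": float(gpp_in.mean()),
            "reco_coverage": float(reco_in.mean()),
            "nominal": 0.90}
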