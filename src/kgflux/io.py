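"""Reading, validation and preparation of half-hourly flux-tower tables.

Columns follow AmeriFlux/FLUXNET naming. Two derived columns feed the
physics losses: the daylight mask ``m`` (1 iff PPFD > 0.001 μmol m-2 s-1)
and ``base_reco``, the clipped mean nocturnal NEE over a window of nights
that acts as a soft lower bound on predicted ecosystem respiration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "REQUIRED_COLUMNS",
    "MODEL_INPUTS",
    "NormalizationStats",
    "read_flux_csv",
    "derive_night_mask",
    "derive_base_reco",
    "split_and_normalize",
]

log = logging.getLogger(__name__)

#: Variables every flux table must provide (besides TIMESTAMP_START).
REQUIRED_COLUMNS = (
    "NEE", "ET", "LE", "H", "PPFD", "TA", "VPD", "SM", "RH", "WS", "Tsonic",
    "SW_IN", "SW_OUT", "LW_IN", "LW_OUT", "CO2", "NEE_mean",
    "T_cea", "E_cea", "P_cea", "R_cea",
)

#: Default feature set fed to the network (all of the predictor table).
MODEL_INPUTS = tuple(REQUIRED_COLUMNS)

PPFD_DAY_THRESHOLD = 0.001  # μmol m-2 s-1; strictly above counts as daytime


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _parse_timestamps(raw: pd.Series) -> pd.DatetimeIndex:
    """Accept ISO-8601 or AmeriFlux YYYYMMDDHHMM period-start stamps."""
    s = raw.astype(str).str.strip()
    if s.str.fullmatch(r"\d{12}").all():
        ts = pd.to_datetime(s, format="%Y%m%d%H%M")
    else:
        ts = pd.to_datetime(s, format="ISO8601")
    return pd.DatetimeIndex(ts)


def read_flux_csv(path: str | Path, required: tuple[str, ...] = REQUIRED_COLUMNS
                  ) -> pd.DataFrame:
    """Read a half-hourly flux CSV into a typed, timestamp-indexed table.

    Unparseable numeric entries become NaN (never zero). Raises
    :class:`SchemaError` naming every missing required column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "TIMESTAMP_START" not in df.columns:
        raise SchemaError("missing required column: TIMESTAMP_START")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError("missing required column(s): " + ", ".join(missing))
    index = _parse_timestamps(df.pop("TIMESTAMP_START"))
    out = df.apply(pd.to_numeric, errors="coerce")
    out.index = index
    if len(out) > 1:
        deltas = np.unique(np.diff(index.values))
        if not (np.diff(index.values) > np.timedelta64(0, "s")).all():
            raise ValueError("timestamps must be strictly increasing")
        if not (deltas == np.timedelta64(30, "m")).all():
            log.warning("non-half-hourly spacing detected in %s", path.name)
    return out


def derive_night_mask(table: pd.DataFrame) -> pd.DataFrame:
    """Add the daylight mask column ``m``: 1 iff PPFD > 0.001 μmol m-2 s-1."""
    if "PPFD" not in table.columns:
        raise SchemaError("missing required column(s): PPFD")
    out = table.copy()
    out["m"] = (out["PPFD"] > PPFD_DAY_THRESHOLD).astype(int)
    return out


def derive_base_reco(table: pd.DataFrame, window_nights: int = 3,
                     mode: str = "centered") -> pd.DataFrame:
    """Add ``base_reco``: windowed mean nocturnal NEE, clipped at zero.

    The default covers the observation night and the two adjacent nights
    (``window_nights=3``, centered). ``mode="previous"`` uses the mean of
    the previous night only. Rows whose window contains no nocturnal
    samples get NaN.
    """
    if "m" not in table.columns:
        table = derive_night_mask(table)
    out = table.copy()
    night_id = (out.index + pd.Timedelta(hours=12)).normalize()
    nee_night = pd.Series(out["NEE"].to_numpy(), index=night_id)[out["m"].to_numpy() == 0]
    nightly = nee_night.groupby(level=0).mean()
    if mode == "centered":
        smoothed = nightly.rolling(window_nights, center=True, min_periods=1).mean()
    elif mode == "previous":
        smoothed = nightly.shift(1, freq="D")
    else:
        raise ValueError(f"unknown base_reco mode {mode!r}")
    base = smoothed.reindex(night_id).to_numpy()
    out["base_reco"] = np.clip(base, 0.0, None)
    return out


@dataclass
class NormalizationStats:
    """Per-variable location/scale computed on the training split only."""

    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, table: pd.DataFrame, columns: tuple[str, ...]) -> "NormalizationStats":
        stats = cls()
        for c in columns:
            mu = float(table[c].mean())
            sd = float(table[c].std(ddof=0))
            if not np.isfinite(sd) or sd <= 0.0:
                sd = 1.0
            stats.mean[c] = mu
            stats.std[c] = sd
        return stats

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.mean:
            out[c] = (out[c] - self.mean[c]) / self.std[c]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.mean:
            out[c] = out[c] * self.std[c] + self.mean[c]
        return out

    def matrix(self, table: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
        """Normalized feature matrix (rows x variables) for the model."""
        cols = [(table[c].to_numpy() - self.mean[c]) / self.std[c] for c in columns]
        return np.column_stack(cols)


def split_and_normalize(table: pd.DataFrame, train_fraction: float = 0.8,
                        block_days: int = 5, seed: int = 0,
                        columns: tuple[str, ...] = MODEL_INPUTS,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationStats]:
    """Split by contiguous whole-day blocks and fit normalization on train only.

    Blocks of `block_days` consecutive calendar days are assigned at random
    (seeded) to the training split until `train_fraction` of blocks is
    reached, so no half-hour of a day leaks across the split. Returns the
    (unnormalized) train and validation tables plus the stats; use
    ``NormalizationStats.matrix`` to build model inputs.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    days = table.index.normalize()
    unique_days = days.unique()
    n_blocks = int(np.ceil(len(unique_days) / block_days))
    if n_blocks < 2:
        raise ValueError("record too short to split into day blocks; reduce block_days")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_blocks)
    n_train = max(1, int(round(train_fraction * n_blocks)))
    if n_train >= n_blocks:
        n_train = n_blocks - 1
    train_blocks = set(order[:n_train])
    block_of_day = {d: i // block_days for i, d in enumerate(unique_days)}
    in_train = days.map(lambda d: block_of_day[d] in train_blocks).to_numpy()
    train, val = table[in_train], table[~in_train]
    n_bad = int(train[list(columns)].isna().any(axis=1).sum())
    if n_bad:
        log.info("training split: %d rows with missing model inputs will be excluded", n_bad)
    stats = NormalizationStats.fit(train.dropna(subset=list(columns)), columns)
    return train, val, stats


def drop_incomplete_rows(table: pd.DataFrame, columns: tuple[str, ...] = MODEL_INPUTS
                         ) -> pd.DataFrame:
    """Remove rows with any missing required model input, logging the count."""
    keep = ~table[list(columns)].isna().any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("excluded %d rows with missing model inputs", n_drop)
    return table[keep]
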