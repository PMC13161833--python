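"""Self-supervised training loop, constraint-importance tracking and ablations.

Training minimises the weighted physics objective with Adam on shuffled
mini-batches, keeps the checkpoint with the best validation total, and can
track the L2 gradient norm of each weighted loss term across batches to
express each constraint's relative influence as a percentage. The ablation
harness retrains from the same seed with one term's weight forced to zero
and scores every run on the same validation split.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .io import NormalizationStats, derive_base_reco, derive_night_mask, drop_incomplete_rows
from .losses import (LossBreakdown, LossOptions, LossWeights, TERM_NAMES,
                     compute_terms, evaluate_losses, weighted_total)
from .model import KGMLModel, ModelConfig

__all__ = [
    "TrainConfig", "TrainingLog", "ConstraintImportance", "Adam",
    "prepare_arrays", "train", "track_gradient_shares", "run_ablation_suite",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 25
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    options: LossOptions = field(default_factory=LossOptions)
    ablate: tuple[str, ...] = ()
    track_gradients: str = "final"  # "final", "all" or "none"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for t in self.ablate:
            if t not in TERM_NAMES:
                raise KeyError(f"unknown loss term {t!r}; known: {TERM_NAMES}")
        if self.track_gradients not in ("final", "all", "none"):
            raise ValueError("track_gradients must be 'final', 'all' or 'none'")

    def effective_weights(self) -> LossWeights:
        return self.weights.ablate(*self.ablate) if self.ablate else self.weights


@dataclass
class ConstraintImportance:
    """Normalized per-term gradient contribution, percent, sorted descending."""

    shares: dict[str, float]

    def __post_init__(self) -> None:
        self.shares = dict(sorted(self.shares.items(), key=lambda kv: -kv[1]))

    def total(self) -> float:
        return float(sum(self.shares.values()))


@dataclass
class TrainingLog:
    train_history: list[LossBreakdown] = field(default_factory=list)
    val_history: list[LossBreakdown] = field(default_factory=list)
    best_epoch: int = -1
    n_excluded_rows: int = 0
    gradient_shares: ConstraintImportance | None = None
    per_epoch_shares: list[ConstraintImportance] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (tr, va) in enumerate(zip(self.train_history, self.val_history)):
            row = {"epoch": i}
            row.update({f"train_{k}": v for k, v in tr.as_row().items()})
            row.update({f"val_{k}": v for k, v in va.as_row().items()})
            rows.append(row)
        return pd.DataFrame(rows)


class Adam:
    """Adaptive-moment estimation over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def prepare_arrays(table: pd.DataFrame, stats: NormalizationStats,
                   input_variables: tuple[str, ...]
                   ) -> tuple[np.ndarray, dict[str, np.ndarray], int]:
    """Build the normalized feature matrix and the observation batch.

    Derives the night mask and baseline-RECO columns if absent, drops rows
    with missing model inputs (count returned), and returns observations as
    column vectors in physical units.
    """
    if "m" not in table.columns:
        table = derive_night_mask(table)
    if "base_reco" not in table.columns:
        table = derive_base_reco(table)
    n_before = len(table)
    table = drop_incomplete_rows(table, input_variables)
    n_excluded = n_before - len(table)
    x = stats.matrix(table, input_variables)

    def col(name: str) -> np.ndarray:
        return table[name].to_numpy(dtype=float).reshape(-1, 1)

    obs = {
        "nee": col("NEE"), "t_cea": col("T_cea"), "p_cea": col("P_cea"),
        "r_cea": col("R_cea"), "ppfd": col("PPFD"), "vpd": col("VPD"),
        "ta": col("TA"), "m": col("m"), "base_reco": col("base_reco"),
    }
    return x, obs, n_excluded


def _slice_obs(obs: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in obs.items()}


def _eval_full(model: KGMLModel, x: np.ndarray, obs: dict, weights: LossWeights,
               options: LossOptions) -> LossBreakdown:
    outputs = model.forward_tensors(x)
    _, breakdown = evaluate_losses(outputs, obs, weights, options)
    return breakdown


def train(model: KGMLModel, train_table: pd.DataFrame, val_table: pd.DataFrame,
          stats: NormalizationStats, config: TrainConfig
          ) -> tuple[KGMLModel, TrainingLog]:
    """Train in place and return the model restored to its best-validation state."""
    weights = config.effective_weights()
    x_tr, obs_tr, n_excl = prepare_arrays(train_table, stats, model.config.input_variables)
    x_va, obs_va, _ = prepare_arrays(val_table, stats, model.config.input_variables)
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    logbook = TrainingLog(n_excluded_rows=n_excl)

    n = len(x_tr)
    best_val = np.inf
    best_state = None
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            outputs = model.forward_tensors(x_tr[idx], dropout_rng=drop_rng)
            total, _ = evaluate_losses(outputs, _slice_obs(obs_tr, idx),
                                       weights, config.options)
            if not isinstance(total, Tensor):  # all terms empty-masked
                continue
            model.zero_grad()
            total.backward()
            opt.step()
        logbook.train_history.append(_eval_full(model, x_tr, obs_tr, weights, config.options))
        val_bd = _eval_full(model, x_va, obs_va, weights, config.options)
        logbook.val_history.append(val_bd)
        if config.track_gradients == "all":
            batches = _make_batches(x_tr, obs_tr, config.batch_size, rng)
            logbook.per_epoch_shares.append(
                track_gradient_shares(model, batches, weights, config.options))
        if val_bd.total < best_val - 1e-12:
            best_val = val_bd.total
            best_state = {k: p.data.copy() for k, p in model.params.items()}
            logbook.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                log.info("early stop at epoch %d (best %d)", epoch, logbook.best_epoch)
                break

    if config.track_gradients == "all" and logbook.per_epoch_shares:
        acc = {t: float(np.mean([s.shares[t] for s in logbook.per_epoch_shares]))
               for t in TERM_NAMES}
        total = sum(acc.values())
        logbook.gradient_shares = ConstraintImportance(
            {t: (100.0 * v / total if total else 0.0) for t, v in acc.items()})
    elif config.track_gradients == "final":
        batches = _make_batches(x_tr, obs_tr, config.batch_size, rng)
        logbook.gradient_shares = track_gradient_shares(
            model, batches, weights, config.options)
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, logbook


def _make_batches(x: np.ndarray, obs: dict, batch_size: int,
                  rng: np.random.Generator) -> list[tuple[np.ndarray, dict]]:
    order = rng.permutation(len(x))
    return [
        (x[order[s:s + batch_size]], _slice_obs(obs, order[s:s + batch_size]))
        for s in range(0, len(x), batch_size)
    ]


def track_gradient_shares(model: KGMLModel, batches: list[tuple[np.ndarray, dict]],
                          weights: LossWeights, options: LossOptions | None = None
                          ) -> ConstraintImportance:
    """Backpropagate each weighted term alone and normalize its mean L2 norm.

    For every batch and term j, the gradient of w_j * L_j with respect to all
    model parameters is computed in isolation; the L2 norm over the whole
    parameter vector is averaged across batches and expressed as a share of
    the sum over terms, in percent.
    """
    if not batches:
        raise ValueError("track_gradient_shares needs at least one batch")
    w = weights.as_dict()
    norms = {t: 0.0 for t in TERM_NAMES}
    for x, obs in batches:
        outputs = model.forward_tensors(x)
        terms = compute_terms(outputs, obs, options)
        for name in TERM_NAMES:
            term = terms[name]
            weighted = term * w[name] if isinstance(term, Tensor) else None
            if weighted is None or not weighted.requires_grad:
                continue
            model.zero_grad()
            weighted.backward()
            grads = [p.grad.ravel() for p in model.parameters() if p.grad is not None]
            if grads:
                norms[name] += float(np.linalg.norm(np.concatenate(grads)))
    mean_norms = {t: v / len(batches) for t, v in norms.items()}
    total = sum(mean_norms.values())
    if total == 0.0:
        return ConstraintImportance({t: 0.0 for t in TERM_NAMES})
    return ConstraintImportance({t: 100.0 * v / total for t, v in mean_norms.items()})


def run_ablation_suite(model_config: ModelConfig, train_table: pd.DataFrame,
                       val_table: pd.DataFrame, stats: NormalizationStats,
                       train_config: TrainConfig,
                       terms: tuple[str, ...] = TERM_NAMES) -> pd.DataFrame:
    """Retrain once per ablated term (weight -> 0) plus the full model.

    Every run starts from the same seed and configuration and is scored on
    the same validation split; returns one row per run with NEE R^2 and RMSE.
    """
    from .evaluation import compare  # local import to avoid a cycle

    runs: list[tuple[str, tuple[str, ...]]] = [("full", ())]
    runs += [(f"no_{t}", (t,)) for t in terms]
    x_va, obs_va, _ = prepare_arrays(val_table, stats, model_config.input_variables)
    records = []
    for label, ablate in runs:
        cfg = copy.deepcopy(train_config)
        cfg.ablate = ablate
        cfg.track_gradients = "none"
        model = KGMLModel(copy.deepcopy(model_config))
        model, _ = train(model, train_table, val_table, stats, cfg)
        pred = model.predict(x_va)
        m = compare(obs_va["nee"].ravel(), pred.nee_pred)
        records.append({"ablation": label, "nee_r2": m.r2, "nee_rmse": m.rmse})
        log.info("ablation %-12s NEE R2=%.4f RMSE=%.3f", label, m.r2, m.rmse)
    return pd.DataFrame(records)
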