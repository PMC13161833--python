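"""Multi-head network that partitions NEE under hard mass-balance constraints.

A shared dense encoder maps the normalized predictor vector to a latent
representation; six independent head branches predict stomatal conductance,
GPP, the three respiration components (above/below-ground autotrophic,
heterotrophic) and a per-timestep water-use-efficiency prior, each forced
non-negative by a softplus output. Three global learnable coefficients
(kMed, betaT, kT) calibrate the stomatal-optimality and conductance-
transpiration couplings. A forward output layer assembles the derived
fluxes so that carbon closure holds architecturally:

    RECO = Ra_above + Ra_below + Rh
    NEE_pred = RECO - GPP
    P_canopy = GPP - Ra_above,  R_surface = Ra_below + Rh

Predictive uncertainty comes from Monte Carlo dropout: stochastic forward
passes with dropout active at inference, summarized as empirical
5th/50th/95th percentiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import MODEL_INPUTS, NormalizationStats

__all__ = ["ModelConfig", "PredictionBundle", "UncertaintyEnvelope", "KGMLModel"]

log = logging.getLogger(__name__)

_ACTIVATIONS = {"tanh": ad.tanh, "softplus": ad.softplus, "sigmoid": ad.sigmoid}

HEAD_NAMES = ("gs", "gpp", "ra_above", "ra_below", "rh", "wue")


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


@dataclass
class ModelConfig:
    input_variables: tuple[str, ...] = MODEL_INPUTS
    encoder_layers: int = 3
    encoder_width: int = 128
    head_width: int = 64
    dropout_rate: float = 0.1
    activation: str = "tanh"
    mc_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_layers < 1:
            raise ValueError("encoder_layers must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        self.input_variables = tuple(self.input_variables)


@dataclass
class PredictionBundle:
    """Per-timestep head outputs and forward-derived fluxes (numpy, 1-D)."""

    gs: np.ndarray
    gpp: np.ndarray
    ra_above: np.ndarray
    ra_below: np.ndarray
    rh: np.ndarray
    wue_hat: np.ndarray
    reco: np.ndarray
    nee_pred: np.ndarray
    pcea_pred: np.ndarray
    rcea_pred: np.ndarray

    def to_dict(self) -> dict[str, np.ndarray]:
        return asdict(self)


@dataclass
class UncertaintyEnvelope:
    """MC-dropout percentile envelopes for GPP and RECO."""

    gpp_p05: np.ndarray
    gpp_p50: np.ndarray
    gpp_p95: np.ndarray
    reco_p05: np.ndarray
    reco_p50: np.ndarray
    reco_p95: np.ndarray

    @property
    def gpp_half_width(self) -> np.ndarray:
        return (self.gpp_p95 - self.gpp_p05) / 2.0

    @property
    def reco_half_width(self) -> np.ndarray:
        return (self.reco_p95 - self.reco_p05) / 2.0


class KGMLModel:
    """Shared encoder + six softplus-constrained heads + forward output layer."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        n_in = len(config.input_variables)
        w = config.encoder_width
        dims = [n_in] + [w] * config.encoder_layers
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self._add_layer(f"enc{i}", a, b, rng)
        for head in HEAD_NAMES:
            self._add_layer(f"{head}_h", w, config.head_width, rng)
            self._add_layer(f"{head}_out", config.head_width, 1, rng)
            # bias the softplus outputs to start near ~1 flux unit
            self.params[f"{head}_out_b"].data[:] = 0.5
        for name, init in (("kmed", 1.0), ("betat", 0.01), ("kt", 1.0)):
            self.params[f"raw_{name}"] = Tensor(_inv_softplus(init), requires_grad=True)

    def _add_layer(self, name: str, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.params[f"{name}_W"] = Tensor(scale * rng.standard_normal((n_in, n_out)),
                                          requires_grad=True)
        self.params[f"{name}_b"] = Tensor(np.zeros(n_out), requires_grad=True)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def coefficients(self) -> dict[str, Tensor]:
        """Positive global coefficients kMed, betaT, kT (softplus transform)."""
        return {name: ad.softplus(self.params[f"raw_{name}"])
                for name in ("kmed", "betat", "kt")}

    # -- forward passes -------------------------------------------------------
    def forward_tensors(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None
                        ) -> dict[str, Tensor]:
        """Differentiable forward pass; dropout active iff a generator is given."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != len(self.config.input_variables):
            raise ValueError(
                f"feature dimension mismatch: expected {len(self.config.input_variables)}"
                f" columns, got shape {x.shape}"
            )
        act = _ACTIVATIONS[self.config.activation]
        h = Tensor(x)
        for i in range(self.config.encoder_layers):
            h = act(h @ self.params[f"enc{i}_W"] + self.params[f"enc{i}_b"])
            if dropout_rng is not None and self.config.dropout_rate > 0.0:
                h = ad.dropout(h, self.config.dropout_rate, dropout_rng)
        heads: dict[str, Tensor] = {}
        for name in HEAD_NAMES:
            z = act(h @ self.params[f"{name}_h_W"] + self.params[f"{name}_h_b"])
            heads[name] = ad.softplus(z @ self.params[f"{name}_out_W"]
                                      + self.params[f"{name}_out_b"])
        reco = heads["ra_above"] + heads["ra_below"] + heads["rh"]
        out = {
            "gs": heads["gs"],
            "gpp": heads["gpp"],
            "ra_above": heads["ra_above"],
            "ra_below": heads["ra_below"],
            "rh": heads["rh"],
            "wue_hat": heads["wue"],
            "reco": reco,
            "nee_pred": reco - heads["gpp"],
            "pcea_pred": heads["gpp"] - heads["ra_above"],
            "rcea_pred": heads["ra_below"] + heads["rh"],
        }
        out.update(self.coefficients())
        return out

    def predict(self, x: np.ndarray) -> PredictionBundle:
        """Deterministic forward pass (dropout off) returning numpy arrays."""
        t = self.forward_tensors(x)
        return PredictionBundle(**{k: t[k].data.ravel() for k in (
            "gs", "gpp", "ra_above", "ra_below", "rh", "wue_hat",
            "reco", "nee_pred", "pcea_pred", "rcea_pred")})

    def predict_with_uncertainty(self, x: np.ndarray, mc_samples: int | None = None,
                                 seed: int = 0) -> UncertaintyEnvelope:
        """MC-dropout envelope: empirical 5/50/95 percentiles over samples."""
        k = self.config.mc_samples if mc_samples is None else mc_samples
        if k < 1:
            raise ValueError("mc_samples must be >= 1")
        if k == 1:
            log.warning("mc_samples=1 gives a degenerate (zero-width) envelope")
        rng = np.random.default_rng(seed)
        gpp = np.empty((k, len(x)))
        reco = np.empty((k, len(x)))
        for i in range(k):
            t = self.forward_tensors(x, dropout_rng=rng)
            gpp[i] = t["gpp"].data.ravel()
            reco[i] = t["reco"].data.ravel()
        q = np.percentile(gpp, [5, 50, 95], axis=0)
        r = np.percentile(reco, [5, 50, 95], axis=0)
        return UncertaintyEnvelope(q[0], q[1], q[2], r[0], r[1], r[2])

    # -- persistence ----------------------------------------------------------
    def save(self, path, stats: NormalizationStats | None = None) -> None:
        meta = {"version": 1, "config": asdict(self.config)}
        if stats is not None:
            meta["stats"] = {"mean": stats.mean, "std": stats.std}
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> tuple["KGMLModel", NormalizationStats | None]:
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            cfg = meta["config"]
            cfg["input_variables"] = tuple(cfg["input_variables"])
            model = cls(ModelConfig(**cfg))
            for k in model.params:
                model.params[k].data = np.asarray(f[k], dtype=np.float64)
        stats = None
        if "stats" in meta:
            stats = NormalizationStats(mean=meta["stats"]["mean"], std=meta["stats"]["std"])
        return model, stats
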