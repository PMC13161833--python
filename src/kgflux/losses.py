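"""Physics- and ecology-informed loss terms and their weighted combination.

Each term is a pure function of predicted quantities and an observation
batch, returning a non-negative scalar. Functions accept either plain numpy
arrays (for testing and diagnostics) or autodiff tensors (for training);
observed drivers and masks are always numpy.

Terms:
  - ``loss_nee``            squared-error carbon-closure term (NEE vs predicted)
  - ``loss_medlyn``         stomatal-optimality coupling of GPP to gs, light, VPD, TA
  - ``loss_wue``            water-use-efficiency prior on GPP / canopy transpiration
  - ``loss_gs_t``           conductance-transpiration link  kT * gs * VPD ~ T
  - ``loss_night``          penalty on any GPP in darkness
  - ``loss_pcea``/``loss_rcea``  guidance toward partitioned canopy/surface fluxes
  - ``loss_reco_baseline``  one-sided lower bound: predicted RECO should not fall
                            below the nocturnal-NEE baseline (ReLU penalty)

The deviation norm for the soft coupling terms defaults to mean absolute
deviation, with a squared-error variant selectable; the closure term is
always squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossWeights", "LossBreakdown", "LossOptions",
    "loss_wue", "loss_medlyn", "loss_gs_t", "loss_night", "loss_nee",
    "loss_pcea", "loss_rcea", "loss_reco_baseline",
    "combine", "weighted_total", "compute_terms", "evaluate_losses", "TERM_NAMES",
]

log = logging.getLogger(__name__)

TERM_NAMES = ("nee", "medlyn", "wue", "gs_t", "night", "pcea", "rcea", "base")

VPD_FLOOR = 1e-6  # kPa, avoids the sqrt/division blow-up at saturation


# -- numpy/tensor dispatch helpers --------------------------------------------
def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def _abs(x):
    return ad.absolute(x) if _is_t(x) else np.abs(x)


def _relu(x):
    return ad.relu(x) if _is_t(x) else np.maximum(x, 0.0)


def _mean(x):
    return ad.mean(x) if _is_t(x) else float(np.mean(x))


def _masked_mean(values, mask: np.ndarray):
    """Mean of `values` over rows where numpy `mask` is 1; 0 if mask empty."""
    count = float(mask.sum())
    if count == 0.0:
        return 0.0
    if _is_t(values):
        return ad.sum_(values * mask) / count
    return float(np.sum(values * mask) / count)


def _deviation(x, norm: str):
    if norm == "mad":
        return _abs(x)
    if norm == "mse":
        return x * x
    raise ValueError(f"unknown deviation norm {norm!r}")


# -- individual terms ---------------------------------------------------------
def loss_wue(gpp, t_cea: np.ndarray, wue_hat, valid_mask: np.ndarray | None = None,
             t_threshold: float = 0.05, norm: str = "mad"):
    """Deviation of GPP / T_canopy from the learned WUE prior.

    Rows with canopy transpiration at or below `t_threshold` (mmol m-2 s-1)
    are excluded because the ratio degenerates as T -> 0.
    """
    t_cea = np.asarray(t_cea, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(t_cea) & (t_cea > t_threshold)
    valid = valid_mask.astype(float)
    if valid.sum() == 0:
        log.warning("loss_wue: no valid rows (all T below threshold)")
        return 0.0
    t_safe = np.where(valid > 0, t_cea, 1.0)
    return _masked_mean(_deviation(gpp / t_safe - wue_hat, norm), valid)


def medlyn_target(gs, ppfd: np.ndarray, vpd: np.ndarray, ta: np.ndarray,
                  kmed, betat, form: str = "sqrt_vpd"):
    """Stomatal-optimality GPP target  kMed * gs * PPFD / f(VPD) * (1 + betaT*TA)."""
    vpd_safe = np.maximum(np.asarray(vpd, dtype=float), VPD_FLOOR)
    if form == "sqrt_vpd":
        light = ppfd / np.sqrt(vpd_safe)
    elif form == "vpd":
        light = ppfd / vpd_safe
    else:
        raise ValueError(f"unknown medlyn form {form!r}")
    return kmed * gs * light * (betat * ta + 1.0)


def loss_medlyn(gpp, gs, ppfd: np.ndarray, vpd: np.ndarray, ta: np.ndarray,
                kmed, betat, day_mask: np.ndarray | None = None,
                form: str = "sqrt_vpd", norm: str = "mad"):
    """Deviation of predicted GPP from the stomatal-optimality target."""
    target = medlyn_target(gs, ppfd, vpd, ta, kmed, betat, form)
    dev = _deviation(gpp - target, norm)
    if day_mask is None:
        return _mean(dev)
    return _masked_mean(dev, day_mask.astype(float))


def loss_gs_t(gs, vpd: np.ndarray, t_cea: np.ndarray, kt, norm: str = "mad"):
    """Deviation of kT * gs * VPD from observed canopy transpiration."""
    return _mean(_deviation(kt * gs * np.asarray(vpd, dtype=float)
                            - np.asarray(t_cea, dtype=float), norm))


def loss_night(gpp, m: np.ndarray):
    """Mean nocturnal GPP: (1/N) sum (1 - m_i) GPP_i, non-negative since GPP >= 0."""
    return _mean(gpp * (1.0 - np.asarray(m, dtype=float)))


def loss_nee(nee_obs: np.ndarray, nee_pred):
    """Mean squared error of the carbon-closure prediction."""
    d = nee_pred - np.asarray(nee_obs, dtype=float)
    return _mean(d * d)


def _guidance(pred, obs: np.ndarray, name: str, norm: str):
    obs = np.asarray(obs, dtype=float)
    valid = np.isfinite(obs).astype(float)
    if valid.sum() == 0:
        log.warning("loss_%s: no valid observations", name)
        return 0.0
    obs_safe = np.where(valid > 0, obs, 0.0)
    return _masked_mean(_deviation(pred - obs_safe, norm), valid)


def loss_pcea(pcea_pred, pcea_obs: np.ndarray, norm: str = "mad"):
    """Guidance of GPP - Ra_above toward the partitioned canopy CO2 flux."""
    return _guidance(pcea_pred, pcea_obs, "pcea", norm)


def loss_rcea(rcea_pred, rcea_obs: np.ndarray, norm: str = "mad"):
    """Guidance of Ra_below + Rh toward the partitioned surface CO2 flux."""
    return _guidance(rcea_pred, rcea_obs, "rcea", norm)


def loss_reco_baseline(reco_pred, base_reco: np.ndarray):
    """One-sided penalty ReLU(base - RECO_pred): a soft lower bound on RECO."""
    base = np.asarray(base_reco, dtype=float)
    valid = np.isfinite(base).astype(float)
    if valid.sum() == 0:
        log.warning("loss_reco_baseline: no rows with a defined baseline")
        return 0.0
    base_safe = np.where(valid > 0, base, -1.0)
    return _masked_mean(_relu(base_safe - reco_pred), valid)


# -- combination --------------------------------------------------------------
@dataclass
class LossWeights:
    """Static weights w_j of the composite objective (all >= 0, one > 0)."""

    nee: float = 1.0
    medlyn: float = 0.3
    night: float = 1.0
    pcea: float = 0.5
    rcea: float = 0.5
    wue: float = 0.05
    gs_t: float = 0.1
    base: float = 0.1

    def __post_init__(self) -> None:
        vals = self.as_dict()
        if any(v < 0 for v in vals.values()):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals.values()):
            raise ValueError("at least one loss weight must be positive")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in TERM_NAMES}

    def ablate(self, *terms: str) -> "LossWeights":
        d = self.as_dict()
        for t in terms:
            if t not in d:
                raise KeyError(f"unknown loss term {t!r}; known: {TERM_NAMES}")
            d[t] = 0.0
        return LossWeights(**d)


@dataclass
class LossBreakdown:
    """Per-term loss values and their weighted total."""

    terms: dict[str, float]
    total: float

    def as_row(self) -> dict[str, float]:
        return {**{f"L_{k}": v for k, v in self.terms.items()}, "total": self.total}


@dataclass
class LossOptions:
    """Norm and form switches for the soft terms."""

    norm: str = "mad"            # "mad" or "mse" for the coupling terms
    medlyn_form: str = "sqrt_vpd"  # "sqrt_vpd" or "vpd"
    medlyn_day_only: bool = True
    wue_t_threshold: float = 0.05  # mmol m-2 s-1


def weighted_total(terms: dict, weights: LossWeights):
    """Sum_j w_j L_j; preserves tensor type when any term is a tensor."""
    w = weights.as_dict()
    total = None
    for name in TERM_NAMES:
        term = terms[name]
        value = term.data if _is_t(term) else term
        if not np.all(np.isfinite(value)):
            raise FloatingPointError(f"non-finite loss term: {name}")
        contrib = term * w[name]
        total = contrib if total is None else total + contrib
    return total


def combine(terms: dict, weights: LossWeights) -> LossBreakdown:
    """Collapse term values into a :class:`LossBreakdown` for logging."""
    total = weighted_total(terms, weights)
    total_f = total.item() if _is_t(total) else float(total)
    floats = {k: (v.item() if _is_t(v) else float(v)) for k, v in terms.items()}
    return LossBreakdown(terms=floats, total=total_f)


def compute_terms(outputs: dict, obs: dict[str, np.ndarray],
                  options: LossOptions | None = None) -> dict:
    """Every loss term from a forward-output dict and an observation batch.

    `outputs` holds tensors (or arrays) keyed as produced by
    :meth:`KGMLModel.forward_tensors`; `obs` holds numpy column vectors for
    nee, t_cea, p_cea, r_cea, ppfd, vpd, ta, m and base_reco.
    """
    opt = options or LossOptions()
    day = obs["m"].astype(float)
    terms = {
        "nee": loss_nee(obs["nee"], outputs["nee_pred"]),
        "medlyn": loss_medlyn(
            outputs["gpp"], outputs["gs"], obs["ppfd"], obs["vpd"], obs["ta"],
            outputs["kmed"], outputs["betat"],
            day_mask=day if opt.medlyn_day_only else None,
            form=opt.medlyn_form, norm=opt.norm),
        "wue": loss_wue(outputs["gpp"], obs["t_cea"], outputs["wue_hat"],
                        valid_mask=(day > 0) & (obs["t_cea"] > opt.wue_t_threshold),
                        norm=opt.norm),
        "gs_t": loss_gs_t(outputs["gs"], obs["vpd"], obs["t_cea"],
                          outputs["kt"], norm=opt.norm),
        "night": loss_night(outputs["gpp"], obs["m"]),
        "pcea": loss_pcea(outputs["pcea_pred"], obs["p_cea"], norm=opt.norm),
        "rcea": loss_rcea(outputs["rcea_pred"], obs["r_cea"], norm=opt.norm),
        "base": loss_reco_baseline(outputs["reco"], obs["base_reco"]),
    }
    return terms


def evaluate_losses(outputs: dict, obs: dict[str, np.ndarray],
                    weights: LossWeights, options: LossOptions | None = None
                    ) -> tuple[object, LossBreakdown]:
    """Weighted total (tensor when training) plus the per-term breakdown."""
    terms = compute_terms(outputs, obs, options)
    total = weighted_total(terms, weights)
    total_f = total.item() if _is_t(total) else float(total)
    floats = {k: (v.item() if _is_t(v) else float(v)) for k, v in terms.items()}
    return total, LossBreakdown(terms=floats, total=total_f)
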