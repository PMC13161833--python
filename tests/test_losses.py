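"""Worked arithmetic examples, elementwise oracles, and invariants of the loss terms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kgflux as kg
from kgflux import losses as L
from kgflux.autodiff import Tensor


# -- worked examples ----------------------------------------------------------
def test_wue_exact_ratio_and_hand_value():
    assert L.loss_wue(np.array([4.0]), np.array([2.0]), np.array([2.0])) == 0.0
    assert L.loss_wue(np.array([4.0]), np.array([2.0]), np.array([3.0])) == pytest.approx(1.0)


def test_wue_empty_mask_returns_zero_with_warning(caplog):
    with caplog.at_level("WARNING"):
        out = L.loss_wue(np.array([4.0]), np.array([0.0]), np.array([3.0]))
    assert out == 0.0
    assert "no valid rows" in caplog.text


def test_gs_t_hand_values():
    assert L.loss_gs_t(np.array([2.0]), np.array([1.0]), np.array([2.0]), 1.0) == 0.0
    assert L.loss_gs_t(np.array([2.0]), np.array([1.0]), np.array([5.0]), 1.0) == pytest.approx(3.0)
    # closed stomata at night: gs ~ 0, T ~ 0 => vanishing loss
    assert L.loss_gs_t(np.zeros(4), np.ones(4), np.zeros(4), 1.0) == 0.0


def test_night_hand_value_and_limits():
    assert L.loss_night(np.array([2.0, 3.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
    assert L.loss_night(np.array([2.0, 3.0]), np.ones(2)) == 0.0
    assert L.loss_night(np.zeros(5), np.zeros(5)) == 0.0


def test_nee_mse_and_permutation_invariance():
    assert L.loss_nee(np.array([1.0]), np.array([3.0])) == pytest.approx(4.0)
    rng = np.random.default_rng(0)
    obs, pred = rng.standard_normal(20), rng.standard_normal(20)
    perm = rng.permutation(20)
    assert L.loss_nee(obs, pred) == pytest.approx(L.loss_nee(obs[perm], pred[perm]))
    assert L.loss_nee(obs, obs) == 0.0


def test_cea_guidance_hand_values_and_missing(caplog):
    assert L.loss_pcea(np.array([1.0, 3.0]), np.array([2.0, 2.0])) == pytest.approx(1.0)
    assert L.loss_rcea(np.array([2.0]), np.array([2.0])) == 0.0
    with caplog.at_level("WARNING"):
        assert L.loss_pcea(np.array([1.0]), np.array([np.nan])) == 0.0
    assert "no valid observations" in caplog.text


def test_reco_baseline_one_sided():
    assert L.loss_reco_baseline(np.array([3.0]), np.array([2.0])) == 0.0
    assert L.loss_reco_baseline(np.array([1.0]), np.array([2.0])) == pytest.approx(1.0)
    assert L.loss_reco_baseline(np.array([2.0]), np.array([2.0])) == 0.0


def test_medlyn_target_collapse_and_exact_match():
    gpp = np.array([5.0, 2.0])
    gs = np.array([0.2, 0.1])
    ppfd = np.array([800.0, 300.0])
    vpd = np.array([1.2, 0.8])
    ta = np.array([20.0, 15.0])
    target = L.medlyn_target(gs, ppfd, vpd, ta, kmed=0.02, betat=0.01)
    assert L.loss_medlyn(target, gs, ppfd, vpd, ta, 0.02, 0.01) == pytest.approx(0.0)
    # kMed = 0 collapses the target to zero => loss is mean daytime GPP
    day = np.ones(2)
    assert L.loss_medlyn(gpp, gs, ppfd, vpd, ta, 0.0, 0.01, day_mask=day) == pytest.approx(gpp.mean())


def test_medlyn_form_variants_differ_by_sqrt_vpd():
    gs = np.array([0.2, 0.1])
    ppfd = np.array([800.0, 300.0])
    vpd = np.array([1.44, 0.64])
    ta = np.array([20.0, 15.0])
    t_sqrt = L.medlyn_target(gs, ppfd, vpd, ta, 0.02, 0.01, form="sqrt_vpd")
    t_lin = L.medlyn_target(gs, ppfd, vpd, ta, 0.02, 0.01, form="vpd")
    np.testing.assert_allclose(t_lin * np.sqrt(vpd), t_sqrt, rtol=1e-12)
    with pytest.raises(ValueError):
        L.medlyn_target(gs, ppfd, vpd, ta, 0.02, 0.01, form="cubic")


# -- elementwise oracles ------------------------------------------------------
def brute_force_terms(outputs, obs, opt):
    """Independent per-row python-loop evaluation of every term."""
    n = len(obs["nee"])
    acc = {k: [] for k in L.TERM_NAMES}
    for i in range(n):
        gpp, gs = outputs["gpp"][i, 0], outputs["gs"][i, 0]
        wue, reco = outputs["wue_hat"][i, 0], outputs["reco"][i, 0]
        m = obs["m"][i, 0]
        acc["nee"].append((obs["nee"][i, 0] - outputs["nee_pred"][i, 0]) ** 2)
        vpd_s = max(obs["vpd"][i, 0], 1e-6)
        tgt = (outputs["kmed"] * gs * obs["ppfd"][i, 0] / np.sqrt(vpd_s)
               * (1 + outputs["betat"] * obs["ta"][i, 0]))
        if m > 0:
            acc["medlyn"].append(abs(gpp - tgt))
        if m > 0 and obs["t_cea"][i, 0] > opt.wue_t_threshold:
            acc["wue"].append(abs(gpp / obs["t_cea"][i, 0] - wue))
        acc["gs_t"].append(abs(outputs["kt"] * gs * obs["vpd"][i, 0] - obs["t_cea"][i, 0]))
        acc["night"].append((1 - m) * gpp)
        if np.isfinite(obs["p_cea"][i, 0]):
            acc["pcea"].append(abs(outputs["pcea_pred"][i, 0] - obs["p_cea"][i, 0]))
        if np.isfinite(obs["r_cea"][i, 0]):
            acc["rcea"].append(abs(outputs["rcea_pred"][i, 0] - obs["r_cea"][i, 0]))
        if np.isfinite(obs["base_reco"][i, 0]):
            acc["base"].append(max(obs["base_reco"][i, 0] - reco, 0.0))
    return {k: (float(np.mean(v)) if v else 0.0) for k, v in acc.items()}


def _random_batch(seed, n=64):
    rng = np.random.default_rng(seed)
    col = lambda lo, hi: rng.uniform(lo, hi, (n, 1))
    outputs = {
        "gpp": col(0, 20), "gs": col(0, 0.4), "ra_above": col(0, 2),
        "ra_below": col(0, 1), "rh": col(0, 1), "wue_hat": col(0, 10),
        "kmed": 0.05, "betat": 0.01, "kt": 9.0,
    }
    outputs["reco"] = outputs["ra_above"] + outputs["ra_below"] + outputs["rh"]
    outputs["nee_pred"] = outputs["reco"] - outputs["gpp"]
    outputs["pcea_pred"] = outputs["gpp"] - outputs["ra_above"]
    outputs["rcea_pred"] = outputs["ra_below"] + outputs["rh"]
    obs = {
        "nee": col(-20, 10), "t_cea": col(0, 5), "p_cea": col(-2, 18),
        "r_cea": col(0, 2), "ppfd": col(0, 1800), "vpd": col(0, 3),
        "ta": col(-5, 35), "m": (col(0, 1) > 0.4).astype(float),
        "base_reco": col(0, 4),
    }
    obs["p_cea"][::17] = np.nan
    obs["base_reco"][::11] = np.nan
    return outputs, obs


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_vectorized_terms_match_brute_force(seed):
    opt = L.LossOptions()
    outputs, obs = _random_batch(seed)
    vec = L.compute_terms(outputs, obs, opt)
    ref = brute_force_terms(outputs, obs, opt)
    for name in L.TERM_NAMES:
        assert vec[name] == pytest.approx(ref[name], abs=1e-10), name


@pytest.mark.parametrize("seed", [4, 5])
def test_weighted_total_matches_elementwise_sum(seed):
    rng = np.random.default_rng(seed)
    terms = {k: float(rng.uniform(0, 5)) for k in L.TERM_NAMES}
    w = {k: float(rng.uniform(0, 2)) for k in L.TERM_NAMES}
    weights = kg.LossWeights(**w)
    expected = 0.0
    for k in L.TERM_NAMES:
        expected += w[k] * terms[k]
    bd = L.combine(terms, weights)
    assert bd.total == pytest.approx(expected, abs=1e-12)
    # doubling every weight doubles the total
    doubled = kg.LossWeights(**{k: 2 * v for k, v in w.items()})
    assert L.combine(terms, doubled).total == pytest.approx(2 * expected, rel=1e-12)


def test_single_weight_selects_single_term():
    terms = {k: float(i + 1) for i, k in enumerate(L.TERM_NAMES)}
    weights = kg.LossWeights(**{k: (1.0 if k == "nee" else 0.0) for k in L.TERM_NAMES})
    assert L.combine(terms, weights).total == terms["nee"]


def test_nonfinite_term_is_named():
    terms = {k: 1.0 for k in L.TERM_NAMES}
    terms["medlyn"] = float("nan")
    with pytest.raises(FloatingPointError, match="medlyn"):
        L.combine(terms, kg.LossWeights())


def test_weights_validation():
    with pytest.raises(ValueError):
        kg.LossWeights(nee=-0.1)
    with pytest.raises(ValueError):
        kg.LossWeights(**{k: 0.0 for k in L.TERM_NAMES})
    with pytest.raises(KeyError):
        kg.LossWeights().ablate("gravity")


# -- property tests -----------------------------------------------------------
@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_all_terms_nonnegative(seed):
    outputs, obs = _random_batch(seed, n=16)
    terms = L.compute_terms(outputs, obs)
    for name, val in terms.items():
        assert val >= 0.0, name


@settings(max_examples=30, deadline=None)
@given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
def test_baseline_monotone_one_sided(base, delta):
    """Raising predicted RECO above the baseline never increases the penalty."""
    lo = L.loss_reco_baseline(np.array([base - 0.5]), np.array([base]))
    hi = L.loss_reco_baseline(np.array([base - 0.5 + delta]), np.array([base]))
    assert hi <= lo + 1e-12
    assert L.loss_reco_baseline(np.array([base + delta]), np.array([base])) == 0.0


def test_every_term_reaches_some_head_gradient(tiny_model, random_features):
    """No silently dead constraints: each term backpropagates into the network."""
    rng = np.random.default_rng(0)
    n = len(random_features)
    col = lambda lo, hi: rng.uniform(lo, hi, (n, 1))
    obs = {
        "nee": col(-10, 5), "t_cea": col(0.1, 4), "p_cea": col(-1, 10),
        "r_cea": col(0, 2), "ppfd": col(10, 1500), "vpd": col(0.2, 2.5),
        "ta": col(5, 30), "m": np.ones((n, 1)), "base_reco": col(0.5, 3),
    }
    obs["m"][:5] = 0.0  # a few night rows so the night term is active
    outputs = tiny_model.forward_tensors(random_features)
    terms = L.compute_terms(outputs, obs)
    for name in L.TERM_NAMES:
        term = terms[name]
        assert isinstance(term, Tensor), name
        tiny_model.zero_grad()
        term.backward()
        norm = sum(float(np.abs(p.grad).sum()) for p in tiny_model.parameters()
                   if p.grad is not None)
        assert norm > 0.0, f"term {name} has zero gradient"
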