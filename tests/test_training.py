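"""Training-loop contracts at small scale: descent, reproducibility, tracking."""

import numpy as np
import pytest

import kgflux as kg
from kgflux.losses import TERM_NAMES
from kgflux.training import _make_batches, prepare_arrays, track_gradient_shares


SMALL_MODEL = dict(encoder_width=24, head_width=12)


@pytest.fixture(scope="module")
def splits(small_site):
    _, table, _ = small_site
    tr, va, stats = kg.split_and_normalize(table, block_days=2, seed=1)
    return tr, va, stats


def test_one_epoch_smoke(splits):
    tr, va, stats = splits
    model = kg.KGMLModel(kg.ModelConfig(seed=0, **SMALL_MODEL))
    model, logbook = kg.train(model, tr.iloc[:96], va.iloc[:96], stats,
                              kg.TrainConfig(epochs=1, seed=0, track_gradients="none"))
    assert len(logbook.train_history) == 1
    assert len(logbook.val_history) == 1
    assert np.isfinite(logbook.val_history[0].total)


def test_nee_only_training_descends(splits):
    tr, va, stats = splits
    weights = kg.LossWeights(**{k: (1.0 if k == "nee" else 0.0) for k in TERM_NAMES})
    model = kg.KGMLModel(kg.ModelConfig(seed=0, **SMALL_MODEL))
    cfg = kg.TrainConfig(epochs=10, seed=0, weights=weights, track_gradients="none")
    model, logbook = kg.train(model, tr, va, stats, cfg)
    assert logbook.val_history[-1].terms["nee"] < logbook.val_history[0].terms["nee"]
    assert logbook.train_history[logbook.best_epoch].total < logbook.train_history[0].total


def test_fixed_seed_reproduces_trajectory(splits):
    tr, va, stats = splits
    losses = []
    for _ in range(2):
        model = kg.KGMLModel(kg.ModelConfig(seed=3, **SMALL_MODEL))
        _, logbook = kg.train(model, tr, va, stats,
                              kg.TrainConfig(epochs=3, seed=3, track_gradients="none"))
        losses.append([b.total for b in logbook.val_history])
    assert losses[0] == losses[1]


def test_train_config_validation():
    with pytest.raises(ValueError):
        kg.TrainConfig(epochs=0)
    with pytest.raises(KeyError):
        kg.TrainConfig(ablate=("not_a_term",))
    with pytest.raises(ValueError):
        kg.TrainConfig(track_gradients="sometimes")


def test_all_epoch_gradient_tracking(splits):
    tr, va, stats = splits
    model = kg.KGMLModel(kg.ModelConfig(seed=0, **SMALL_MODEL))
    cfg = kg.TrainConfig(epochs=2, seed=0, track_gradients="all")
    model, logbook = kg.train(model, tr.iloc[:192], va.iloc[:96], stats, cfg)
    assert len(logbook.per_epoch_shares) == 2
    assert logbook.gradient_shares is not None
    assert logbook.gradient_shares.total() == pytest.approx(100.0, abs=1e-6)


def test_ablated_term_excluded_from_total(splits):
    tr, _, stats = splits
    x, obs, _ = prepare_arrays(tr, stats, kg.ModelConfig().input_variables)
    model = kg.KGMLModel(kg.ModelConfig(seed=0, **SMALL_MODEL))
    outputs = model.forward_tensors(x[:64])
    from kgflux.losses import compute_terms, combine
    terms = compute_terms(outputs, {k: v[:64] for k, v in obs.items()})
    full = combine(terms, kg.LossWeights())
    no_night = combine(terms, kg.LossWeights().ablate("night"))
    w = kg.LossWeights().as_dict()
    assert full.total - no_night.total == pytest.approx(
        w["night"] * full.terms["night"], rel=1e-10)


def test_gradient_shares_sum_and_single_term(splits):
    tr, _, stats = splits
    model = kg.KGMLModel(kg.ModelConfig(seed=1, **SMALL_MODEL))
    x, obs, _ = prepare_arrays(tr, stats, model.config.input_variables)
    batches = _make_batches(x[:256], {k: v[:256] for k, v in obs.items()},
                            128, np.random.default_rng(0))
    only_nee = kg.LossWeights(**{k: (1.0 if k == "nee" else 0.0) for k in TERM_NAMES})
    shares = track_gradient_shares(model, batches, only_nee)
    assert shares.shares["nee"] == pytest.approx(100.0)
    assert shares.total() == pytest.approx(100.0, abs=1e-6)
    default = track_gradient_shares(model, batches, kg.LossWeights())
    assert default.total() == pytest.approx(100.0, abs=1e-6)
    assert all(v >= 0 for v in default.shares.values())


def test_gradient_shares_match_brute_force_accumulation(splits):
    """Whole-parameter-vector norms equal a per-parameter python accumulation."""
    from kgflux.losses import compute_terms
    from kgflux.autodiff import Tensor

    tr, _, stats = splits
    model = kg.KGMLModel(kg.ModelConfig(seed=2, **SMALL_MODEL))
    x, obs, _ = prepare_arrays(tr, stats, model.config.input_variables)
    batch = (x[:128], {k: v[:128] for k, v in obs.items()})
    weights = kg.LossWeights()
    shares = track_gradient_shares(model, [batch], weights)

    w = weights.as_dict()
    norms = {}
    for name in TERM_NAMES:
        outputs = model.forward_tensors(batch[0])
        term = compute_terms(outputs, batch[1])[name]
        if not isinstance(term, Tensor):
            norms[name] = 0.0
            continue
        model.zero_grad()
        (term * w[name]).backward()
        acc = 0.0
        for p in model.parameters():
            if p.grad is not None:
                for g in p.grad.ravel():
                    acc += float(g) * float(g)
        norms[name] = float(np.sqrt(acc))
    total = sum(norms.values())
    for name in TERM_NAMES:
        assert shares.shares[name] == pytest.approx(100.0 * norms[name] / total, abs=1e-8)


def test_ablation_suite_rows_and_unknown_term(splits):
    tr, va, stats = splits
    cfg = kg.TrainConfig(epochs=2, seed=0, track_gradients="none")
    out = kg.run_ablation_suite(kg.ModelConfig(seed=0, **SMALL_MODEL),
                                tr, va, stats, cfg, terms=("night",))
    assert list(out["ablation"]) == ["full", "no_night"]
    assert np.isfinite(out["nee_r2"]).all()
    with pytest.raises(KeyError):
        kg.run_ablation_suite(kg.ModelConfig(seed=0, **SMALL_MODEL),
                              tr, va, stats, cfg, terms=("bogus",))
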