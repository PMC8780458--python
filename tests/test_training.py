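"""Loss/optimizer arithmetic, training regimes, freezing, determinism."""

import numpy as np
import pytest

from imfcnet import nn
from imfcnet.data import AugmentationPolicy, FoldSplit, make_splits
from imfcnet.ensemble import JMLP, JMLPSpec, EnsembleNet
from imfcnet.nn import functional as F
from imfcnet.training import (OptimizerConfig, SGD, cross_entropy,
                              cross_validate, evaluate_subnet, sgd_step,
                              split_decay_params, state_checksum,
                              train_end_to_end, train_sequential,
                              train_subnet)
from tests.conftest import build_tiny_ifc, build_tiny_mfc

POLICY_NONE = AugmentationPolicy(mode="none")


def tiny_cfg(seed=0, **kw):
    kw.setdefault("epochs_jmlp", 2)
    return OptimizerConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# closed-form arithmetic
# ---------------------------------------------------------------------------

def test_cross_entropy_closed_forms():
    assert cross_entropy([1.0, 0.0, 0.0, 0.0], 0) == 0.0
    assert cross_entropy([0.25] * 4, 2) == pytest.approx(np.log(4))
    assert cross_entropy([0.5, 0.3, 0.1, 0.1], 1) == pytest.approx(
        -np.log(0.3))


def test_cross_entropy_clamps_zero_probability():
    with pytest.warns(UserWarning, match="clamped"):
        loss = cross_entropy([0.0, 1.0, 0.0, 0.0], 0)
    assert loss == pytest.approx(-np.log(1e-12))


def test_sgd_step_plain_update():
    cfg = OptimizerConfig(lr=0.001, momentum=0.0, weight_decay=0.0)
    theta, buf = sgd_step(np.array(1.0), np.array(2.0), cfg)
    assert theta == pytest.approx(0.998)
    theta, _ = sgd_step(theta, np.array(0.0), cfg, buf * 0)
    assert theta == pytest.approx(0.998)  # zero gradient leaves theta


def test_sgd_momentum_two_step_displacement():
    # constant gradient g, momentum 0.9: displacement lr*g*(1 + 1.9)
    cfg = OptimizerConfig(lr=0.001, momentum=0.9, weight_decay=0.0)
    g = np.array(3.0)
    theta, buf = sgd_step(np.array(5.0), g, cfg)
    theta, _ = sgd_step(theta, g, cfg, buf)
    assert 5.0 - theta == pytest.approx(0.001 * 3.0 * (1 + 1.9))


def test_sgd_class_matches_functional_variant():
    p = nn.Parameter(np.array([2.0], np.float32))
    opt = SGD([p], lr=0.01, momentum=0.9, weight_decay=0.1)
    expected, buf = np.array([2.0]), None
    for _ in range(3):
        p.grad = np.array([1.0], np.float32)
        opt.step()
        expected, buf = sgd_step(
            expected, np.array([1.0]),
            OptimizerConfig(lr=0.01, momentum=0.9, weight_decay=0.1), buf)
    assert p.data == pytest.approx(expected, rel=1e-5)


def test_split_decay_excludes_batch_norm():
    mod = nn.Sequential(nn.Conv2d(3, 4, 3), nn.BatchNorm2d(4),
                        nn.Linear(4, 2))
    decay, no_decay = split_decay_params(mod)
    assert len(no_decay) == 2  # BN scale + shift
    assert len(decay) == 4     # conv w/b + linear w/b


def test_optimizer_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(lr=0.0)
    with pytest.raises(ValueError):
        OptimizerConfig(epochs_jmlp=0)


# ---------------------------------------------------------------------------
# training regimes on reduced-scale networks
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def overfit_fold(synth_index):
    # 12 images (3 per class), trained on all of them
    ids = [i for i, r in enumerate(synth_index.records)
           if int(r.subject_id.rsplit("_", 1)[1]) < 3]
    return FoldSplit(0, tuple(ids), (), ())


def test_loss_decreases_on_fixed_tiny_batch(synth_index, overfit_fold):
    sub = build_tiny_mfc(seed=4)
    state = train_subnet(sub, overfit_fold, synth_index, POLICY_NONE,
                         tiny_cfg(), epochs=6)
    hist = state["history"]
    assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]


def test_train_subnet_validates_preconditions(synth_index, overfit_fold):
    sub = build_tiny_mfc(seed=0)
    with pytest.raises(ValueError, match="epochs"):
        train_subnet(sub, overfit_fold, synth_index, POLICY_NONE, tiny_cfg(),
                     epochs=0)
    empty = FoldSplit(0, (), (), tuple(range(4)))
    with pytest.raises(ValueError, match="empty training set"):
        train_subnet(sub, empty, synth_index, POLICY_NONE, tiny_cfg(),
                     epochs=1)
    featonly = build_tiny_mfc(seed=0, with_head=False)
    with pytest.raises(ValueError, match="standalone head"):
        train_subnet(featonly, overfit_fold, synth_index, POLICY_NONE,
                     tiny_cfg(), epochs=1)


def test_train_subnet_seeded_determinism(synth_index, overfit_fold):
    losses = []
    for _ in range(2):
        sub = build_tiny_mfc(seed=6)
        state = train_subnet(sub, overfit_fold, synth_index, POLICY_NONE,
                             tiny_cfg(seed=11), epochs=2)
        losses.append(state["history"]["train_loss"].tolist())
    assert losses[0] == losses[1]


def test_sequential_training_freezes_subnets_bit_exactly(synth_index,
                                                         overfit_fold):
    ifc = build_tiny_ifc(seed=0)
    mfc = build_tiny_mfc(seed=1)
    cfg = tiny_cfg()
    train_subnet(ifc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    train_subnet(mfc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    sums = (state_checksum(ifc), state_checksum(mfc))
    jmlp = JMLP(JMLPSpec(seed=2))
    jmlp_before = state_checksum(jmlp)
    ens = train_sequential(ifc, mfc, jmlp, overfit_fold, synth_index,
                           POLICY_NONE, cfg)
    assert (state_checksum(ens.subnet_i), state_checksum(ens.subnet_m)) == sums
    assert state_checksum(ens.jmlp) != jmlp_before  # the JMLP did train


def test_sequential_rejects_fold_mismatch(synth_index, overfit_fold):
    ifc = build_tiny_ifc(seed=0)
    mfc = build_tiny_mfc(seed=1)
    cfg = tiny_cfg()
    train_subnet(ifc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    train_subnet(mfc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    other = FoldSplit(3, overfit_fold.train, (), ())
    with pytest.raises(ValueError, match="fold"):
        train_sequential(ifc, mfc, JMLP(JMLPSpec(seed=2)), other, synth_index,
                         POLICY_NONE, cfg)


def test_jmlp_is_the_only_trainable_part_during_fusion(synth_index,
                                                       overfit_fold):
    ifc = build_tiny_ifc(seed=0)
    mfc = build_tiny_mfc(seed=1)
    cfg = tiny_cfg()
    train_subnet(ifc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    train_subnet(mfc, overfit_fold, synth_index, POLICY_NONE, cfg, epochs=1)
    ens = train_sequential(ifc, mfc, JMLP(JMLPSpec(seed=2)), overfit_fold,
                           synth_index, POLICY_NONE, cfg)
    trainable = sum(p.size for p in ens.parameters() if p.requires_grad)
    assert trainable == 12_676


def test_end_to_end_updates_every_parameter(synth_index, overfit_fold):
    ifc = build_tiny_ifc(seed=0, with_head=False)
    mfc = build_tiny_mfc(seed=1, with_head=False)
    ens = EnsembleNet(ifc, mfc, JMLP(JMLPSpec(seed=2)))
    before = {name: p.data.copy() for name, p in ens.named_parameters()}
    train_end_to_end(ens, overfit_fold, synth_index, POLICY_NONE, tiny_cfg(),
                     epochs=1)
    changed = [name for name, p in ens.named_parameters()
               if not np.array_equal(before[name], p.data)]
    # every weight tensor moves (a bias deep in a dead ReLU may not)
    weight_names = [n for n, p in ens.named_parameters() if p.data.ndim > 1]
    assert set(weight_names) <= set(changed)


def test_gradient_reaches_both_branches(synth_index, overfit_fold, rng):
    ifc = build_tiny_ifc(seed=0, with_head=False)
    mfc = build_tiny_mfc(seed=1, with_head=False)
    ens = EnsembleNet(ifc, mfc, JMLP(JMLPSpec(seed=2)))
    ens.train()
    x_i = nn.Tensor(rng.standard_normal((2, 3, 96, 96)).astype(np.float32))
    x_m = nn.Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
    loss = F.cross_entropy_logits(ens(x_i, x_m), np.array([0, 1]))
    loss.backward()
    assert any(p.grad is not None and np.abs(p.grad).max() > 0
               for p in ens.subnet_i.parameters())
    assert any(p.grad is not None and np.abs(p.grad).max() > 0
               for p in ens.subnet_m.parameters())


def test_cross_validate_emits_paired_fold_metrics(synth_index):
    plan = make_splits(synth_index, k=2, fractions=(0.6, 0.2, 0.2), seed=1)
    builders = {
        "ifc": lambda s: build_tiny_ifc(seed=s, width=0.25),
        "mfc": lambda s: build_tiny_mfc(seed=s, width=0.25),
        "jmlp": lambda s: JMLP(JMLPSpec(seed=s)),
    }
    cfg = tiny_cfg(epochs_ifc=1, epochs_mfc=1)
    mfc_folds = cross_validate(builders, plan, synth_index, POLICY_NONE, cfg,
                               mode="mfc")
    seq_folds = cross_validate(builders, plan, synth_index, POLICY_NONE, cfg,
                               mode="sequential")
    assert len(mfc_folds) == len(seq_folds) == 2
    assert [f.fold_id for f in mfc_folds] == [f.fold_id for f in seq_folds]
    for f in mfc_folds + seq_folds:
        assert 0 <= f.acc <= 100
        assert f.cm.total == len(plan.folds[f.fold_id].test)


def test_evaluate_subnet_returns_label_strings(synth_index):
    sub = build_tiny_mfc(seed=8, width=0.25)
    records = synth_index.records[:6]
    y_true, y_pred = evaluate_subnet(sub, records)
    assert list(y_true) == [r.label for r in records]
    assert set(y_pred) <= set(sub.class_labels)
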