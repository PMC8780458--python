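"""Grad-CAM against analytic and occlusion oracles; overlay rendering."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from imfcnet import nn
from imfcnet.data import preprocess
from imfcnet.interpret import (CamRequest, TAP_REGISTRY, grad_cam,
                               grad_cam_at, overlay, upsample_bilinear)
from imfcnet.nn import functional as F
from tests.conftest import build_tiny_mfc


class ToyNet(nn.Module):
    """One conv -> global average pool -> linear head; input 8x8."""

    input_size = 8
    class_labels = ("a", "b", "c", "d")

    def __init__(self, rng):
        super().__init__()
        self.conv = nn.Conv2d(3, 2, 3, padding=1, bias=False, rng=rng)
        self.head = nn.Linear(2, 4, rng=rng)
        self.head.bias.data[...] = rng.standard_normal(4).astype(np.float32)

    def logits(self, x):
        return self.head(F.global_avg_pool(self.conv(x)))


def toy_cam_closed_form(net, image, class_index):
    """Analytic Grad-CAM for the toy: activations via an independent
    correlation implementation, channel weights W[c, k] / (H * W)."""
    x = preprocess(image, net.input_size)[0]
    acts = []
    for c_out in range(2):
        a = np.zeros((8, 8))
        for c_in in range(3):
            a += correlate2d(x[c_in], net.conv.weight.data[c_out, c_in],
                             mode="same")
        acts.append(a)
    weights = net.head.weight.data[:, class_index] / 64.0
    cam = np.maximum(weights[0] * acts[0] + weights[1] * acts[1], 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def test_grad_cam_matches_analytic_toy(rng):
    net = ToyNet(rng)
    image = rng.integers(0, 255, (8, 8), dtype=np.uint8)
    for k in range(4):
        cam = grad_cam_at(net, net.conv, image, k)
        expected = toy_cam_closed_form(net, image, k)
        assert cam.shape == (8, 8)
        assert np.allclose(cam, expected, atol=1e-4)


def test_grad_cam_ignores_regions_the_score_ignores(rng):
    """Zero-sum (edge-detecting) filters yield zero activation over constant
    regions; Grad-CAM there must vanish, matching an occlusion probe."""
    net = ToyNet(rng)
    w = rng.standard_normal((2, 3, 3, 3)).astype(np.float32)
    w -= w.mean(axis=(2, 3), keepdims=True)  # zero-sum per filter
    net.conv.weight.data[...] = w
    image = np.zeros((8, 8), np.uint8)
    image[2:6, 0:3] = 200   # structure only in the left block
    cam = grad_cam_at(net, net.conv, image, 0)
    # occlusion oracle: perturbing the constant right half leaves the score
    # unchanged, so the map there must be ~0
    def score(img):
        with nn.no_grad():
            return float(net.logits(nn.Tensor(
                preprocess(img, 8))).data[0, 0])

    poked = image.copy()
    poked[1:7, 6] = 50
    interior = image.copy()
    interior[3, 1] = 0
    assert abs(score(poked) - score(image)) < 1e-4 + abs(
        score(interior) - score(image))
    assert cam[:, 6:].max() <= 0.2
    assert cam.max() == pytest.approx(1.0)


def test_grad_cam_range_and_positive_logit_rescaling_invariance(synth_index):
    sub = build_tiny_mfc(seed=3, width=0.25)
    from imfcnet.data import load_image

    image = load_image(synth_index.records[0].path)
    req = CamRequest("mfc", "block_b_3", 1, image)
    cam = grad_cam(sub, req)
    assert cam.shape == (sub.input_size, sub.input_size)
    assert cam.min() >= 0.0 and cam.max() <= 1.0
    # scaling every logit by a positive constant leaves the map unchanged
    sub.head.weight.data *= 3.0
    sub.head.bias.data *= 3.0
    cam_scaled = grad_cam(sub, req)
    assert np.allclose(cam, cam_scaled, atol=1e-4)


def test_grad_cam_all_zero_map_stays_zero(rng):
    net = ToyNet(rng)
    net.head.weight.data[...] = 0.0  # gradient at conv output is zero
    image = rng.integers(0, 255, (8, 8), dtype=np.uint8)
    cam = grad_cam_at(net, net.conv, image, 0)
    assert np.array_equal(cam, np.zeros((8, 8), np.float32))


def test_unknown_tap_lists_valid_names(synth_index):
    sub = build_tiny_mfc(seed=0, width=0.25)
    from imfcnet.data import load_image

    image = load_image(synth_index.records[0].path)
    with pytest.raises(KeyError, match="block_b_1"):
        grad_cam(sub, CamRequest("mfc", "nonexistent", 0, image))


def test_registry_taps_resolve_on_both_subnets():
    from imfcnet.interpret import _target_module
    from tests.conftest import build_tiny_ifc

    ifc = build_tiny_ifc(seed=0, width=0.25)
    mfc = build_tiny_mfc(seed=0, width=0.25)
    for name in TAP_REGISTRY["ifc"]:
        assert isinstance(_target_module(ifc, "ifc", name), nn.Module)
    for name in TAP_REGISTRY["mfc"]:
        assert isinstance(_target_module(mfc, "mfc", name), nn.Module)


def test_overlay_alpha_extremes(rng):
    image = rng.integers(0, 255, (32, 32), dtype=np.uint8)
    heat = rng.uniform(0, 1, (32, 32))
    plain = overlay(image, heat, alpha=0.0)
    assert plain.shape == (32, 32, 3)
    assert np.abs(plain[..., 0].astype(int) - image.astype(int)).max() <= 1
    import matplotlib

    pure = overlay(image, heat, alpha=1.0)
    expected = (matplotlib.colormaps["jet"](heat)[..., :3] * 255).round()
    assert np.abs(pure.astype(int) - expected.astype(int)).max() <= 1


def test_overlay_resizes_heatmap_to_image():
    image = np.zeros((64, 64), np.uint8)
    heat = np.ones((8, 8))
    assert overlay(image, heat, alpha=0.5).shape == (64, 64, 3)


def test_upsample_bilinear_preserves_constants():
    arr = np.full((4, 4), 0.7, np.float32)
    up = upsample_bilinear(arr, 16)
    assert up.shape == (16, 16)
    assert np.allclose(up, 0.7, atol=1e-6)
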