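"""Grad-CAM heatmaps at named blocks of either subnet.

Channel weights are the spatial mean of the class-score (logit) gradient at
the target layer; the map is the ReLU of the weighted channel sum, upsampled
bilinearly to the input size and max-normalized to [0, 1] per image (an
all-zero map stays zero).  Tap points default to each block's final
activation and are declared in :data:`TAP_REGISTRY` so figure panels are
scriptable by block name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from . import nn
from .cp_heads import Subnet
from .data import preprocess

# block name -> attribute path inside subnet.backbone
TAP_REGISTRY: dict[str, dict[str, str]] = {
    # Inception branch: A = stem, B-E = the inception stages
    "ifc": {
        "block_a": "stem",
        "block_b": "mixed_5d",
        "block_c": "mixed_6e",
        "block_d": "mixed_7a",
        "block_e": "mixed_7c",
    },
    # MobileNet branch: bottleneck ("Block B") taps at stage boundaries plus
    # the final plain-convolution ("Block A") layer
    "mfc": {
        "block_b_1": "blocks.layer0",
        "block_b_2": "blocks.layer2",
        "block_b_3": "blocks.layer5",
        "block_b_4": "blocks.layer9",
        "block_b_5": "blocks.layer15",
        "block_a_last": "head_conv",
    },
}


@dataclass
class CamRequest:
    network: str           # 'ifc' | 'mfc' (registry key), or 'custom'
    layer: str             # tap name in the registry, or attribute path
    class_index: int
    image: np.ndarray      # 2-D grayscale (any size)


def _resolve_module(root: nn.Module, path: str) -> nn.Module:
    mod = root
    for part in path.split("."):
        if not hasattr(mod, part) or not isinstance(getattr(mod, part),
                                                    nn.Module):
            raise KeyError(path)
        mod = getattr(mod, part)
    return mod


def _target_module(subnet: Subnet, network: str, layer: str) -> nn.Module:
    registry = TAP_REGISTRY.get(network, {})
    path = registry.get(layer, layer)
    try:
        return _resolve_module(subnet.backbone, path)
    except KeyError:
        valid = sorted(registry) if registry else ["<attribute paths>"]
        raise KeyError(
            f"unknown tap layer {layer!r} for network {network!r}; "
            f"valid taps: {valid}") from None


def upsample_bilinear(arr: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(np.ascontiguousarray(arr, dtype=np.float32),
                          mode="F")
    return np.asarray(img.resize((size, size), Image.BILINEAR))


def grad_cam_at(subnet: Subnet, target: nn.Module, image: np.ndarray,
                class_index: int) -> np.ndarray:
    """Grad-CAM for ``class_index`` at ``target``; returns an input-sized
    float map in [0, 1]."""
    n_classes = subnet.head.out_features if subnet.head is not None else None
    if n_classes is not None and not (0 <= class_index < n_classes):
        raise ValueError(f"class index {class_index} out of range "
                         f"[0, {n_classes})")
    captured: list[nn.Tensor] = []
    remove = target.register_forward_hook(
        lambda _mod, out: captured.append(out))
    try:
        subnet.eval()
        x = nn.Tensor(preprocess(image, subnet.input_size))
        logits = subnet.logits(x)
    finally:
        remove()
    if not captured:
        raise RuntimeError("target layer did not fire during the forward pass")
    act = captured[-1]
    seed = np.zeros_like(logits.data)
    seed[0, class_index] = 1.0
    logits.backward(seed)
    if act.grad is None:
        raise RuntimeError("no gradient reached the target layer")
    weights = act.grad.mean(axis=(2, 3))[0]             # (C,)
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    cam = upsample_bilinear(cam, subnet.input_size)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam


def grad_cam(subnet: Subnet, req: CamRequest) -> np.ndarray:
    target = _target_module(subnet, req.network, req.layer)
    return grad_cam_at(subnet, target, req.image, req.class_index)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto a grayscale image -> RGB uint8."""
    import matplotlib

    image = np.asarray(image)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if heatmap.shape != image.shape:
        heatmap = upsample_bilinear(heatmap, image.shape[0])
    gray = (image.astype(np.float64) / 255.0)[..., None].repeat(3, axis=2)
    colors = matplotlib.colormaps[cmap](np.clip(heatmap, 0, 1))[..., :3]
    blend = (1.0 - alpha) * gray + alpha * colors
    return (np.clip(blend, 0, 1) * 255).round().astype(np.uint8)


def cam_panel(subnet: Subnet, network: str, images_by_class: dict[str, np.ndarray],
              blocks, out_path, alpha: float = 0.5) -> None:
    """One row per class, one column per block, saved as a PNG grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = list(images_by_class)
    fig, axes = plt.subplots(len(classes), len(blocks),
                             figsize=(2.2 * len(blocks), 2.2 * len(classes)),
                             squeeze=False)
    for r, cls in enumerate(classes):
        img = images_by_class[cls]
        cidx = subnet.class_labels.index(cls)
        for cc, block in enumerate(blocks):
            cam = grad_cam(subnet, CamRequest(network, block, cidx, img))
            small = np.asarray(Image.fromarray(img).resize(
                (subnet.input_size, subnet.input_size), Image.BILINEAR))
            axes[r][cc].imshow(overlay(small, cam, alpha))
            axes[r][cc].set_axis_off()
            if r == 0:
                axes[r][cc].set_title(block, fontsize=8)
        axes[r][0].set_ylabel(cls)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
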