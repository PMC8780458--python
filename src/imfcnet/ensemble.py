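"""Feature fusion: the joint multilayer perceptron (JMLP) and IMFC-Net.

The ensemble concatenates the two 64-dimensional subnet features f_I and
f_M into a 128-dimensional vector f_IM and classifies it with a small MLP:
FC-1 (64) -> FC-2 (64) -> FC-3 (n_classes) -> softmax.  ReLU is applied
after FC-1 and FC-2 by default (``activation=False`` gives the purely
linear stack); softmax follows FC-3 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cp_heads import CLASS_LABELS, Subnet
from .data import load_image, preprocess
from .nn import functional as F


@dataclass
class JMLPSpec:
    input_lengths: tuple[int, int] = (64, 64)
    hidden: tuple[int, int] = (64, 64)
    n_classes: int = 4
    activation: bool = True  # ReLU between FC layers
    class_labels: tuple[str, ...] = CLASS_LABELS
    seed: int = 0

    @property
    def concat_length(self) -> int:
        return sum(self.input_lengths)


class JMLP(nn.Module):
    """Fusion MLP over the concatenated subnet features."""

    def __init__(self, spec: JMLPSpec | None = None):
        super().__init__()
        self.spec = spec = spec or JMLPSpec()
        rng = np.random.default_rng(spec.seed)
        self.fc1 = nn.Linear(spec.concat_length, spec.hidden[0], rng=rng)
        self.fc2 = nn.Linear(spec.hidden[0], spec.hidden[1], rng=rng)
        self.fc3 = nn.Linear(spec.hidden[1], spec.n_classes, rng=rng)

    def forward(self, f_im):
        x = nn.as_tensor(f_im)
        if x.data.ndim == 1:
            x = F.reshape(x, (1, -1))
        x = self.fc1(x)
        if self.spec.activation:
            x = F.relu(x)
        x = self.fc2(x)
        if self.spec.activation:
            x = F.relu(x)
        return self.fc3(x)


def concat_features(f_i, f_m, spec: JMLPSpec | None = None):
    """Concatenate the two branch features, f_I first.

    Accepts 1-D vectors or (N, d) batches, numpy or Tensor; returns the same
    kind.  Lengths are validated against the spec (default 64 + 64 = 128).
    """
    spec = spec or JMLPSpec()
    li, lm = spec.input_lengths

    def _len(v):
        return v.shape[-1]

    if _len(f_i) != li or _len(f_m) != lm:
        raise ValueError(
            f"feature length mismatch: expected ({li}, {lm}), "
            f"got ({_len(f_i)}, {_len(f_m)})")
    if isinstance(f_i, nn.Tensor) or isinstance(f_m, nn.Tensor):
        return F.concat([nn.as_tensor(f_i), nn.as_tensor(f_m)], axis=-1 if
                        nn.as_tensor(f_i).data.ndim == 1 else 1)
    return np.concatenate([f_i, f_m], axis=-1)


def jmlp_forward(jmlp: JMLP, f_im) -> np.ndarray:
    """Class probabilities for a concatenated feature vector (or batch)."""
    with nn.no_grad():
        logits = jmlp(f_im).data
    probs = F.softmax(logits, axis=1)
    return probs[0] if np.ndim(f_im) == 1 else probs


class EnsembleNet(nn.Module):
    """IMFC-Net: two feature-mode subnets fused by a JMLP.

    One input image feeds both branches, resized independently to each
    branch's input size.  The forward contract is exactly
    ``jmlp(concat(subnet_i(x_i), subnet_m(x_m)))``.
    """

    def __init__(self, subnet_i: Subnet, subnet_m: Subnet,
                 jmlp: JMLP | None = None,
                 class_labels: tuple[str, ...] = CLASS_LABELS):
        super().__init__()
        self.subnet_i = subnet_i
        self.subnet_m = subnet_m
        self.jmlp = jmlp or JMLP(JMLPSpec(
            input_lengths=(subnet_i.feature_dim, subnet_m.feature_dim)))
        if self.jmlp.spec.input_lengths != (subnet_i.feature_dim,
                                            subnet_m.feature_dim):
            raise ValueError(
                f"JMLP input lengths {self.jmlp.spec.input_lengths} do not "
                f"match subnet feature dims "
                f"({subnet_i.feature_dim}, {subnet_m.feature_dim})")
        self.class_labels = class_labels

    def forward(self, x_i, x_m):
        f_i = self.subnet_i.features(x_i)
        f_m = self.subnet_m.features(x_m)
        return self.jmlp(concat_features(f_i, f_m, self.jmlp.spec))

    def probabilities(self, x_i, x_m) -> np.ndarray:
        with nn.no_grad():
            return F.softmax(self(x_i, x_m).data, axis=1)


def build_imfc_net(seed: int = 0, pretrained: bool = False,
                   width_mult: float = 1.0,
                   input_sizes: tuple[int | None, int | None] = (None, None),
                   activation: bool = True) -> EnsembleNet:
    """Default IMFC-Net: feature-path IFC-Net and MFC-Net plus a JMLP."""
    from .cp_heads import build_ifc_net, build_mfc_net

    sub_i = build_ifc_net(pretrained=pretrained, with_head=False, seed=seed,
                          width_mult=width_mult, input_size=input_sizes[0])
    sub_m = build_mfc_net(pretrained=pretrained, with_head=False,
                          seed=seed + 1, width_mult=width_mult,
                          input_size=input_sizes[1])
    jmlp = JMLP(JMLPSpec(input_lengths=(sub_i.feature_dim, sub_m.feature_dim),
                         activation=activation, seed=seed + 2))
    return EnsembleNet(sub_i, sub_m, jmlp)


def predict(ens: EnsembleNet, image) -> tuple[str, np.ndarray]:
    """Classify one image (path, or grayscale/RGB array).

    Returns ``(label, probabilities)``; the label is the argmax class and
    exact ties resolve to the lowest class index.
    """
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = load_image(image)
    image = np.asarray(image)
    if image.size == 0:
        raise IOError("empty image")
    x_i = preprocess(image, ens.subnet_i.input_size)
    x_m = preprocess(image, ens.subnet_m.input_size)
    probs = ens.probabilities(nn.Tensor(x_i), nn.Tensor(x_m))[0]
    return ens.class_labels[int(np.argmax(probs))], probs


def predict_csv(ens: EnsembleNet, paths, out_path) -> None:
    """Batch prediction to CSV: image id, label, four probabilities."""
    import pandas as pd

    rows = []
    for p in paths:
        label, probs = predict(ens, p)
        rows.append([str(p), label, *probs.tolist()])
    cols = ["image", "label"] + [f"p_{c}" for c in ens.class_labels]
    pd.DataFrame(rows, columns=cols).to_csv(out_path, index=False)
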