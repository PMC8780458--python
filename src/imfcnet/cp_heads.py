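"""The convolution-pooling (CP) head and the two retrofitted subnets.

A CP block replaces a backbone's global average pooling: a bank of
``n_filters`` convolution filters whose spatial extent equals the incoming
feature map (8x8 on Inception-V3's terminal map, 7x7 on MobileNet-V2's),
batch normalization, ReLU, then a fully connected layer to ``fc_nodes``
(default 64) with a terminal ReLU.  The motivation is to learn the spatial
pooling instead of averaging it away: implants of different manufacturers
differ in localized head/fin/hole patterns that a global mean blurs.

``build_ifc_net`` / ``build_mfc_net`` attach a CP block (and optionally a
4-class softmax head for standalone training) to the Inception-V3 and
MobileNet-V2 extractors respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbones import (BackboneSpec, ConfigurationError, build_backbone)
from .nn import functional as F

CLASS_LABELS = ("Cofield", "Depuy", "Tornier", "Zimmer")


@dataclass
class CPBlockSpec:
    """Configuration of a convolution-pooling block.

    ``kernel=None`` means "match the incoming map's spatial size" (the
    defining property of the block).  With ``padding_mode='valid'`` the
    convolution collapses the map to 1x1xn_filters before the FC layer;
    with ``'same'`` the map keeps its spatial size and the FC consumes
    spatial^2 * n_filters inputs.
    """

    n_filters: int = 50
    kernel: int | None = None
    padding_mode: str = "valid"
    fc_nodes: int = 64

    def __post_init__(self):
        if self.padding_mode not in ("valid", "same"):
            raise ConfigurationError(
                f"padding_mode must be 'valid' or 'same', got "
                f"{self.padding_mode!r}")


@dataclass
class SubnetSpec:
    """A backbone plus CP head, optionally with a standalone classifier."""

    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    cp: CPBlockSpec = field(default_factory=CPBlockSpec)
    n_classes: int = 4
    with_head: bool = True
    class_labels: tuple[str, ...] = CLASS_LABELS
    seed: int = 0


class CPBlock(nn.Module):
    """conv (full-extent kernel) -> BN -> ReLU -> flatten -> FC -> ReLU."""

    def __init__(self, spec: CPBlockSpec, incoming_shape: tuple[int, int, int],
                 rng: np.random.Generator | None = None):
        super().__init__()
        h, w, c = incoming_shape
        kernel = spec.kernel if spec.kernel is not None else h
        if kernel != h or h != w:
            raise ConfigurationError(
                f"CP kernel must equal the incoming square spatial size; "
                f"kernel {kernel}, incoming {h}x{w}")
        rng = rng or np.random.default_rng(0)
        padding = 0 if spec.padding_mode == "valid" else "same"
        self.conv = nn.Conv2d(c, spec.n_filters, kernel, 1, padding, rng=rng)
        self.bn = nn.BatchNorm2d(spec.n_filters)
        spatial_out = 1 if spec.padding_mode == "valid" else h
        self.fc_in = spec.n_filters * spatial_out * spatial_out
        self.fc = nn.Linear(self.fc_in, spec.fc_nodes, rng=rng)
        self.fc_nodes = spec.fc_nodes
        self.spec = spec

    def forward(self, x):
        y = F.relu(self.bn(self.conv(x)))
        return F.relu(self.fc(F.flatten(y)))


def build_cp_block(spec: CPBlockSpec, incoming_shape,
                   rng: np.random.Generator | None = None) -> CPBlock:
    return CPBlock(spec, tuple(incoming_shape), rng=rng)


class Subnet(nn.Module):
    """Backbone + CP head, exposing feature / logits / probability modes."""

    def __init__(self, spec: SubnetSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.backbone = build_backbone(spec.backbone)
        try:
            self.cp = CPBlock(spec.cp, spec.backbone.terminal_shape, rng=rng)
        except ConfigurationError as err:
            raise ConfigurationError(
                f"CP head incompatible with backbone "
                f"{spec.backbone.family}: {err}") from err
        self.head = (nn.Linear(spec.cp.fc_nodes, spec.n_classes, rng=rng)
                     if spec.with_head else None)
        self.class_labels = spec.class_labels
        self.feature_dim = spec.cp.fc_nodes
        self.input_size = spec.backbone.input_shape[0]

    def features(self, x):
        return self.cp(self.backbone(x))

    def logits(self, x):
        if self.head is None:
            raise ConfigurationError(
                "subnet was built without a standalone head "
                "(with_head=False); only feature mode is available")
        return self.head(self.features(x))

    def probabilities(self, x) -> np.ndarray:
        with nn.no_grad():
            return F.softmax(self.logits(x).data, axis=1)

    def forward(self, x, mode: str = "features"):
        if mode == "features":
            return self.features(x)
        if mode == "logits":
            return self.logits(x)
        if mode == "probs":
            return self.probabilities(x)
        raise ValueError(f"unknown mode {mode!r}")


class PooledSubnet(nn.Module):
    """Ablation build: global average pooling in place of the CP block."""

    def __init__(self, spec: SubnetSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.backbone = build_backbone(spec.backbone)
        self.pool = nn.GlobalAvgPool()
        channels = spec.backbone.terminal_shape[2]
        self.head = (nn.Linear(channels, spec.n_classes, rng=rng)
                     if spec.with_head else None)
        self.class_labels = spec.class_labels
        self.feature_dim = channels
        self.input_size = spec.backbone.input_shape[0]

    def features(self, x):
        return self.pool(self.backbone(x))

    def logits(self, x):
        return self.head(self.features(x))

    def probabilities(self, x) -> np.ndarray:
        with nn.no_grad():
            return F.softmax(self.logits(x).data, axis=1)

    def forward(self, x, mode: str = "features"):
        if mode == "features":
            return self.features(x)
        if mode == "logits":
            return self.logits(x)
        if mode == "probs":
            return self.probabilities(x)
        raise ValueError(f"unknown mode {mode!r}")


def build_subnet(spec: SubnetSpec) -> Subnet:
    return Subnet(spec)


def ablate_cp(spec: SubnetSpec) -> PooledSubnet:
    """The same subnet with the CP block replaced by global average pooling
    (the base-architecture configuration used in the CP-on/off ablation)."""
    return PooledSubnet(replace(spec, with_head=True))


def build_ifc_net(pretrained: bool = False, weights_path: str | None = None,
                  with_head: bool = True, seed: int = 0,
                  width_mult: float = 1.0, input_size: int | None = None,
                  cp: CPBlockSpec | None = None) -> Subnet:
    """Inception-V3 + CP head ("IFC-Net")."""
    spec = SubnetSpec(
        backbone=BackboneSpec(family="inception_v3", pretrained=pretrained,
                              weights_path=weights_path, seed=seed,
                              width_mult=width_mult, input_size=input_size),
        cp=cp or CPBlockSpec(), with_head=with_head, seed=seed + 1)
    return Subnet(spec)


def build_mfc_net(pretrained: bool = False, weights_path: str | None = None,
                  with_head: bool = True, seed: int = 0,
                  width_mult: float = 1.0, input_size: int | None = None,
                  cp: CPBlockSpec | None = None) -> Subnet:
    """MobileNet-V2 + CP head ("MFC-Net")."""
    spec = SubnetSpec(
        backbone=BackboneSpec(family="mobilenet_v2", pretrained=pretrained,
                              weights_path=weights_path, seed=seed,
                              width_mult=width_mult, input_size=input_size),
        cp=cp or CPBlockSpec(), with_head=with_head, seed=seed + 1)
    return Subnet(spec)


def export_features_csv(subnet: Subnet, images, ids, path) -> None:
    """One row per image: id followed by the subnet's feature vector."""
    import pandas as pd

    rows = []
    with nn.no_grad():
        for img, iid in zip(images, ids):
            f = subnet.features(nn.as_tensor(img)).data.ravel()
            rows.append([iid, *f.tolist()])
    cols = ["id"] + [f"f{i}" for i in range(len(rows[0]) - 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
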