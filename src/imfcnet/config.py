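"""Run configuration, seed fan-out, and artifact bookkeeping.

A :class:`RunConfig` is loadable from YAML (CLI flags override file values);
every run directory receives the resolved config plus the package version so
a deterministic rerun can be reproduced from the snapshot alone.  A single
root seed fans out to the split / initialization / shuffle / augmentation
seeds through ``numpy.random.SeedSequence`` and the derived seeds are logged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "crossval"            # train-subnet | train-sequential |
    #                                   train-end2end | crossval | evaluate |
    #                                   gradcam | synth
    dataset_root: str | None = None
    synthetic: bool = False
    synthetic_per_class: int | None = None   # None -> paper-scale counts
    image_size: int = 256
    augmentation: str = "ria"
    ria_angles: tuple[float, ...] = (45, 90, 135, 180, 225, 270, 315)
    rotation_range: float = 15.0
    translate_frac: float = 0.10
    k_folds: int = 10
    fractions: tuple[float, float, float] = (0.90, 0.02, 0.08)
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 10
    epochs_ifc: int = 13
    epochs_mfc: int = 13
    epochs_jmlp: int = 4
    epochs_end_to_end: int = 13
    width_mult: float = 1.0
    input_size_ifc: int | None = None
    input_size_mfc: int | None = None
    pretrained: bool = False
    seed: int = 0
    out_dir: str = "runs/run0"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError(
                f"fractions must sum to 1, got {self.fractions}")
        if self.augmentation not in ("ria", "online", "none"):
            raise ConfigError(
                f"augmentation must be ria|online|none, got "
                f"{self.augmentation!r}")
        if self.k_folds < 1:
            raise ConfigError("k_folds must be >= 1")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported config schema version {self.schema_version}")

    # -- seeds ---------------------------------------------------------------
    def derived_seeds(self) -> dict[str, int]:
        """Deterministic fan-out of the root seed (all below 2**31)."""
        ss = np.random.SeedSequence(self.seed)
        names = ("split", "init", "shuffle", "augment", "synth")
        state = ss.generate_state(len(names))
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("package_version", None)   # snapshot metadata
        raw.pop("derived_seeds", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for tup in ("fractions", "ria_angles"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def snapshot(self, out_dir=None) -> Path:
        """Write the resolved config (+ package version and derived seeds)."""
        from . import __version__

        out = Path(out_dir or self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["fractions"] = list(self.fractions)
        payload["ria_angles"] = list(self.ria_angles)
        payload["package_version"] = __version__
        payload["derived_seeds"] = self.derived_seeds()
        path = out / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    def optimizer_config(self):
        from .training import OptimizerConfig

        return OptimizerConfig(
            lr=self.lr, momentum=self.momentum,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            epochs_ifc=self.epochs_ifc, epochs_mfc=self.epochs_mfc,
            epochs_jmlp=self.epochs_jmlp,
            epochs_end_to_end=self.epochs_end_to_end,
            seed=self.derived_seeds()["shuffle"])

    def augmentation_policy(self):
        from .data import AugmentationPolicy

        return AugmentationPolicy(
            mode=self.augmentation, ria_angles=self.ria_angles,
            rotation_range=self.rotation_range,
            translate_frac=self.translate_frac)
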