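"""Dataset indexing, the ten-fold 90/2/8 split protocol, and augmentation.

Images live in a class-per-directory tree (PNG/JPEG/BMP).  Each record is
one subject: the implant radiographs are de-identified one-scan-per-patient,
so image-level and patient-level splits coincide.

Splits are stratified independent draws: each fold shuffles every class with
its own derived seed and allocates round-half-up ``8%`` to test and ``2%``
to validation (largest-remainder apportionment across classes so the global
sizes are exact — 597 records give 537/12/48), with training absorbing the
remainder.  Ten disjoint test blocks are impossible at 8% x 10, hence
independent draws rather than a partition.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read an image as 2-D grayscale uint8."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def to_rgb_float(image: np.ndarray) -> np.ndarray:
    """Grayscale (H, W) or RGB (H, W, 3) uint8 -> (3, H, W) float32 in [0,1].
    Single-channel input is replicated to the 3 channels the ImageNet
    topologies expect."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=0)
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = arr[..., :3].transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported image shape {arr.shape}")
    return arr.astype(np.float32) / 255.0


def resize(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2-D grayscale array to (size, size)."""
    img = Image.fromarray(np.asarray(image))
    return np.asarray(img.resize((size, size), Image.BILINEAR))


def preprocess(image: np.ndarray, size: int,
               mean: float = 0.5, std: float = 0.25) -> np.ndarray:
    """Resize + channel replication + standardization -> (1, 3, size, size)."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr.mean(axis=2).astype(arr.dtype)
    x = to_rgb_float(resize(arr, size))
    return ((x - mean) / std)[None]


# ---------------------------------------------------------------------------
# dataset index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Record:
    path: str
    label: str
    subject_id: str


@dataclass
class DatasetIndex:
    records: list[Record]
    classes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> dict[str, int]:
        c = {cls: 0 for cls in self.classes}
        for r in self.records:
            c[r.label] += 1
        return c

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def subset(self, ids) -> "DatasetIndex":
        return DatasetIndex([self.records[i] for i in ids], self.classes)


def load_dataset(root_dir) -> DatasetIndex:
    """Index a class-per-directory image tree.

    Record ordering is deterministic (classes and paths sorted).  Every image
    must decode; an empty class directory is an error.
    """
    root = Path(root_dir)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    records: list[Record] = []
    for d in class_dirs:
        paths = sorted(p for p in d.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not paths:
            raise ValueError(f"class directory {d.name!r} contains no images")
        for p in paths:
            try:
                with Image.open(p) as img:
                    img.verify()
            except Exception as err:
                raise ValueError(f"undecodable image: {p}") from err
            records.append(Record(str(p), d.name, p.stem))
    return DatasetIndex(records, tuple(d.name for d in class_dirs))


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]


@dataclass
class SplitPlan:
    folds: list[FoldSplit]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def to_json(self, path) -> None:
        import json

        payload = {
            "fractions": list(self.fractions), "seed": self.seed,
            "folds": [{"fold": f.fold, "train": list(f.train),
                       "val": list(f.val), "test": list(f.test)}
                      for f in self.folds],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        import json

        payload = json.loads(Path(path).read_text())
        folds = [FoldSplit(f["fold"], tuple(f["train"]), tuple(f["val"]),
                           tuple(f["test"])) for f in payload["folds"]]
        return cls(folds, tuple(payload["fractions"]), payload["seed"])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _apportion(class_sizes: dict[str, int], target: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``target`` records across classes,
    proportional to class size (stratification within one record per class)."""
    n = sum(class_sizes.values())
    ideal = {c: s * target / n for c, s in class_sizes.items()}
    alloc = {c: int(np.floor(v)) for c, v in ideal.items()}
    shortfall = target - sum(alloc.values())
    order = sorted(class_sizes, key=lambda c: (-(ideal[c] - alloc[c]), c))
    for c in order[:shortfall]:
        alloc[c] += 1
    return alloc


def make_splits(index: DatasetIndex, k: int = 10,
                fractions: tuple[float, float, float] = (0.90, 0.02, 0.08),
                seed: int = 0) -> SplitPlan:
    """``k`` independent seeded stratified train/val/test draws."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(index)
    labels = index.labels()
    class_ids = {c: np.flatnonzero(labels == c) for c in index.classes}
    sizes = {c: len(v) for c, v in class_ids.items()}
    if min(sizes.values()) < k:
        raise ValueError(
            f"every class needs at least k={k} records; counts: {sizes}")
    n_test = _round_half_up(fractions[2] * n)
    n_val = _round_half_up(fractions[1] * n)
    test_alloc = _apportion(sizes, n_test)
    val_alloc = _apportion(sizes, n_val)
    for c in index.classes:
        if test_alloc[c] + val_alloc[c] >= sizes[c]:
            raise ValueError(
                f"class {c!r} too small for stratified val/test at these "
                f"fractions")
    fold_seeds = np.random.SeedSequence(seed).spawn(k)
    folds = []
    for f, ss in enumerate(fold_seeds):
        rng = np.random.default_rng(ss)
        train, val, test = [], [], []
        for c in index.classes:
            ids = rng.permutation(class_ids[c])
            t, v = test_alloc[c], val_alloc[c]
            test.extend(ids[:t])
            val.extend(ids[t:t + v])
            train.extend(ids[t + v:])
        folds.append(FoldSplit(f, tuple(int(i) for i in sorted(train)),
                               tuple(int(i) for i in sorted(val)),
                               tuple(int(i) for i in sorted(test))))
    return SplitPlan(folds, tuple(fractions), seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPolicy:
    """``ria``: offline rotated copies of the training images at fixed
    angles; ``online``: per-iteration random rotation/translation;
    ``none``: identity.  Validation and test data are never augmented."""

    mode: str = "ria"
    ria_angles: tuple[float, ...] = (45, 90, 135, 180, 225, 270, 315)
    rotation_range: float = 15.0
    translate_frac: float = 0.10
    fill: int = 0

    def __post_init__(self):
        if self.mode not in ("ria", "online", "none"):
            raise ValueError(f"unknown augmentation mode {self.mode!r}")


def _rotate(img: Image.Image, angle: float, fill: int,
            translate=(0, 0)) -> Image.Image:
    angle = float(angle) % 360.0
    if angle == 0.0 and translate == (0, 0):
        return img.copy()
    return img.rotate(angle, resample=Image.BILINEAR, expand=False,
                      translate=translate, fillcolor=fill)


def apply_ria(index: DatasetIndex, angles, out_dir,
              overwrite: bool = False, fill: int = 0) -> DatasetIndex:
    """Write each training image plus one rotated copy per angle.

    Rotation is about the image center; exposed corners take the fill value
    (radiograph backgrounds are dark, so 0).  The returned index has
    ``(len(angles) + 1) * n`` records.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {out} is not empty (pass overwrite=True)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    records: list[Record] = []
    classes = index.classes
    for r in index.records:
        cls_dir = out / r.label
        cls_dir.mkdir(exist_ok=True)
        with Image.open(r.path) as img:
            img = img.convert("L")
            stem = Path(r.path).stem
            orig = cls_dir / f"{stem}_a000.png"
            img.save(orig)
            records.append(Record(str(orig), r.label, r.subject_id))
            for a in angles:
                rot = _rotate(img, a, fill)
                p = cls_dir / f"{stem}_a{int(round(a % 360)):03d}.png"
                rot.save(p)
                records.append(Record(str(p), r.label, r.subject_id))
    return DatasetIndex(records, classes)


def online_transform(image, rng: np.random.Generator,
                     policy: AugmentationPolicy):
    """Random in-plane rotation and translation of one training image.

    Rotation angle ~ U(-r, r) degrees; translation ~ U(-t, t) of the image
    size per axis.  Deterministic given the rng state.  Accepts and returns
    a 2-D uint8 array (or a PIL image).
    """
    was_array = isinstance(image, np.ndarray)
    img = Image.fromarray(image) if was_array else image
    angle = rng.uniform(-policy.rotation_range, policy.rotation_range)
    tx = rng.uniform(-policy.translate_frac, policy.translate_frac) * img.width
    ty = rng.uniform(-policy.translate_frac, policy.translate_frac) * img.height
    if policy.rotation_range == 0 and policy.translate_frac == 0:
        out = img.copy()
    else:
        out = img.rotate(angle, resample=Image.BILINEAR, expand=False,
                         translate=(tx, ty), fillcolor=policy.fill)
    return np.asarray(out) if was_array else out
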