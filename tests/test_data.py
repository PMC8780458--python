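"""Dataset indexing, the 90/2/8 split protocol, and augmentation."""

import numpy as np
import pytest
from PIL import Image

from imfcnet.data import (AugmentationPolicy, DatasetIndex, Record, apply_ria,
                          load_dataset, load_image, make_splits,
                          online_transform, preprocess)


def _dummy_index(counts: dict[str, int]) -> DatasetIndex:
    records = []
    for cls, n in counts.items():
        for i in range(n):
            records.append(Record(f"{cls}/{i}.png", cls, f"{cls}_{i}"))
    return DatasetIndex(records, tuple(sorted(counts)))


PAPER_COUNTS = {"Cofield": 83, "Depuy": 294, "Tornier": 71, "Zimmer": 149}


def test_load_dataset_counts_and_order(synth_dir, synth_index):
    assert len(synth_index) == 40
    assert synth_index.counts == {c: 10 for c in synth_index.classes}
    paths = [r.path for r in synth_index.records]
    assert paths == sorted(paths, key=lambda p: (p.rsplit("/", 2)[-2], p))


def test_load_dataset_empty_class_dir_errors(tmp_path):
    (tmp_path / "Cofield").mkdir()
    with pytest.raises(ValueError, match="Cofield"):
        load_dataset(tmp_path)


def test_load_dataset_undecodable_image_errors(tmp_path):
    d = tmp_path / "Depuy"
    d.mkdir()
    (d / "bad.png").write_bytes(b"not an image")
    with pytest.raises(ValueError, match="bad.png"):
        load_dataset(tmp_path)


def test_split_sizes_597_records():
    plan = make_splits(_dummy_index(PAPER_COUNTS), k=10, seed=0)
    for fold in plan.folds:
        assert (len(fold.train), len(fold.val), len(fold.test)) == (537, 12, 48)


def test_split_sizes_round_even_100():
    counts = {"a": 25, "b": 25, "c": 25, "d": 25}
    plan = make_splits(_dummy_index(counts), k=2, seed=1)
    assert (len(plan.folds[0].train), len(plan.folds[0].val),
            len(plan.folds[0].test)) == (90, 2, 8)


@pytest.mark.parametrize("seed", range(50))
def test_split_disjointness_and_stratification_over_seeds(seed):
    index = _dummy_index(PAPER_COUNTS)
    plan = make_splits(index, k=1, seed=seed)
    labels = index.labels()
    n = len(index)
    for fold in plan.folds:
        train, val, test = map(set, (fold.train, fold.val, fold.test))
        assert not (train & val or train & test or val & test)
        assert train | val | test == set(range(n))
        for split in (fold.train, fold.val, fold.test):
            split_labels = labels[list(split)]
            for cls, cnt in PAPER_COUNTS.items():
                share = np.mean(split_labels == cls)
                global_share = cnt / n
                assert abs(share - global_share) <= 1.0 / len(split) + 1e-12


def test_splits_deterministic_under_seed():
    index = _dummy_index(PAPER_COUNTS)
    assert make_splits(index, k=3, seed=42).folds == \
        make_splits(index, k=3, seed=42).folds
    assert make_splits(index, k=3, seed=42).folds != \
        make_splits(index, k=3, seed=43).folds


def test_split_requires_k_records_per_class():
    with pytest.raises(ValueError, match="at least k"):
        make_splits(_dummy_index({"a": 5, "b": 100, "c": 100, "d": 100}),
                    k=10)


def test_split_fractions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        make_splits(_dummy_index(PAPER_COUNTS), fractions=(0.9, 0.05, 0.08))


def test_split_plan_json_roundtrip(tmp_path):
    from imfcnet.data import SplitPlan

    plan = make_splits(_dummy_index(PAPER_COUNTS), k=2, seed=3)
    plan.to_json(tmp_path / "plan.json")
    loaded = SplitPlan.from_json(tmp_path / "plan.json")
    assert loaded.folds == plan.folds
    assert loaded.fractions == plan.fractions


def test_ria_cardinality_and_val_test_untouched(synth_index, tmp_path):
    plan = make_splits(synth_index, k=1, fractions=(0.6, 0.2, 0.2), seed=0)
    fold = plan.folds[0]
    train_index = synth_index.subset(fold.train)
    angles = (45, 90, 135, 180, 225, 270, 315)
    aug = apply_ria(train_index, angles, tmp_path / "ria")
    assert len(aug) == (len(angles) + 1) * len(train_index)
    aug_paths = {r.path for r in aug.records}
    untouched = {synth_index.records[i].path
                 for i in list(fold.val) + list(fold.test)}
    assert not aug_paths & untouched


def test_ria_angle_0_and_360_are_pixel_identical(synth_index, tmp_path):
    one = synth_index.subset([0])
    aug = apply_ria(one, [0, 360, 90], tmp_path / "ria0")
    arrays = {r.path: load_image(r.path) for r in aug.records}
    paths = sorted(arrays)
    base = load_image(one.records[0].path)
    a000 = [p for p in paths if p.endswith("_a000.png")]
    # the original copy, angle 0 and angle 360 all collapse to one file,
    # pixel-identical to the source
    assert np.array_equal(arrays[a000[0]], base)
    rotated = [p for p in paths if p.endswith("_a090.png")]
    assert not np.array_equal(arrays[rotated[0]], base)


def test_ria_refuses_nonempty_output_without_overwrite(synth_index, tmp_path):
    out = tmp_path / "ria_clash"
    apply_ria(synth_index.subset([0]), [90], out)
    with pytest.raises(FileExistsError):
        apply_ria(synth_index.subset([0]), [90], out)
    apply_ria(synth_index.subset([1]), [90], out, overwrite=True)


def test_online_transform_identity_and_determinism(synth_index):
    img = load_image(synth_index.records[0].path)
    identity = AugmentationPolicy(mode="online", rotation_range=0,
                                  translate_frac=0)
    out = online_transform(img, np.random.default_rng(0), identity)
    assert np.array_equal(out, img)
    policy = AugmentationPolicy(mode="online")
    rng = np.random.default_rng(7)
    a1 = online_transform(img, rng, policy)
    a2 = online_transform(img, rng, policy)
    assert a1.shape == img.shape
    assert not np.array_equal(a1, a2)  # fresh draw per call
    rng = np.random.default_rng(7)
    b1 = online_transform(img, rng, policy)
    b2 = online_transform(img, rng, policy)
    assert np.array_equal(a1, b1) and np.array_equal(a2, b2)


def test_augmentation_mode_validation():
    with pytest.raises(ValueError, match="unknown augmentation"):
        AugmentationPolicy(mode="offline")


def test_preprocess_replicates_grayscale_to_three_channels(synth_index):
    img = load_image(synth_index.records[0].path)
    x = preprocess(img, 64)
    assert x.shape == (1, 3, 64, 64)
    assert np.array_equal(x[0, 0], x[0, 1]) and np.array_equal(x[0, 1], x[0, 2])
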