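import numpy as np
import pytest
from scipy import ndimage

from nucseg.masks import make_auxiliary_masks
from nucseg.preprocess import make_variant
from nucseg.segmentation import (
    MergeParams,
    NotNormalizedError,
    StagePredictor,
    TrainConfig,
    classical_predictor,
    learning_rate_at,
    replicate_channels,
    segment,
    train_stage,
    watershed_merge,
)
from nucseg.synthetic import MagnificationPreset, generate_dataset


def two_disks(shape=(40, 64), r=10, gap=-2):
    """Two bright disks whose centres are 2r + gap apart (gap<0 = touching)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c1, c2 = (20, 20), (20, 20 + 2 * r + gap)
    img = np.zeros(shape)
    for cy, cx in (c1, c2):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 0.8
    return img


def test_replicate_channels_contract(rng):
    img = rng.random((12, 17))
    out = replicate_channels(img)
    assert out.shape == (12, 17, 3)
    for k in range(3):
        np.testing.assert_array_equal(out[..., k], img)
    with pytest.raises(ValueError):
        replicate_channels(out)


def test_learning_rate_halves_every_eight_epochs():
    cfg = TrainConfig()
    assert learning_rate_at(1, cfg) == 0.01
    assert learning_rate_at(8, cfg) == 0.01
    assert learning_rate_at(9, cfg) == 0.005
    assert learning_rate_at(17, cfg) == 0.0025


class TestClassicalPredictors:
    def test_bright_disk_recovered_as_foreground(self):
        img = two_disks(gap=30) + 0.01  # well separated
        fg = classical_predictor("foreground").predict(img)
        assert set(np.unique(fg)) <= {0.0, 1.0}
        # Otsu separates the bimodal histogram: disk pixels on, background off
        assert fg[20, 20] == 1.0 and fg[2, 2] == 0.0

    def test_constant_image_has_empty_foreground(self):
        assert not classical_predictor("foreground").predict(np.full((16, 16), 0.3)).any()

    def test_touching_disks_give_two_distance_maxima(self):
        img = two_disks(gap=-2)
        d = classical_predictor("distance").predict(img)
        assert d.max() == 1.0
        # two local maxima: one peak in each disk
        peaks = (d == 1.0)
        assert ndimage.label(peaks, structure=np.ones((3, 3)))[1] == 2

    def test_rejects_raw_integer_input(self):
        raw = np.full((8, 8), 4000, dtype=np.uint16)
        with pytest.raises(NotNormalizedError):
            classical_predictor("foreground").predict(raw)


class TestWatershedMerge:
    def test_single_disk_is_single_instance(self):
        img = two_disks(gap=30)
        img[:, 32:] = 0  # keep only the first disk
        fg = classical_predictor("foreground").predict(img + 0.01)
        d = classical_predictor("distance").predict(img + 0.01)
        labels = watershed_merge(fg, d)
        assert labels.max() == 1

    def test_touching_disks_split_along_equidistance_valley(self):
        img = two_disks(gap=-2)
        fg = classical_predictor("foreground").predict(img + 0.01)
        d = classical_predictor("distance").predict(img + 0.01)
        labels = watershed_merge(fg, d)
        assert labels.max() == 2
        # symmetric geometry: the split line is the perpendicular bisector
        # of the two centres (x = 29), so label identity flips across it
        ys, xs = np.where(labels > 0)
        left, right = labels[20, 21], labels[20, 37]
        assert left != right
        assert np.all(labels[ys[xs <= 27], xs[xs <= 27]] == left)
        assert np.all(labels[ys[xs >= 31], xs[xs >= 31]] == right)

    def test_empty_foreground_gives_empty_mask(self):
        z = np.zeros((16, 16))
        assert not watershed_merge(z, z).any()

    def test_small_components_removed(self):
        fg = np.zeros((16, 16))
        fg[2:4, 2:4] = 1.0  # 4 px < min_object_area
        d = fg.copy()
        assert not watershed_merge(fg, d, MergeParams(min_object_area=10)).any()
        assert watershed_merge(fg, d, MergeParams(min_object_area=4)).max() == 1

    def test_decreasing_h_never_decreases_seed_count(self):
        img = two_disks(gap=-2)
        d = classical_predictor("distance").predict(img + 0.01)
        fg = classical_predictor("foreground").predict(img + 0.01)
        counts = []
        for h in (0.5, 0.2, 0.1, 0.02):
            counts.append(int(watershed_merge(fg, d, MergeParams(h_maxima=h, min_object_area=1)).max()))
        assert counts == sorted(counts)

    def test_instances_partition_thresholded_foreground(self, easy_scene):
        norm = make_variant(easy_scene.image, "D4")
        fg = classical_predictor("foreground").predict(norm)
        labels = watershed_merge(fg, classical_predictor("distance").predict(norm))
        # every instance lies inside the foreground; instances are disjoint
        assert np.all(fg[labels > 0] == 1.0)
        for k in np.unique(labels)[1:]:
            assert ndimage.label(labels == k)[1] == 1  # connected


class TestTrainStage:
    def _pairs(self, n=4, seed=0):
        preset = MagnificationPreset("tiny", 5.0, (6.0, 10.0), touch_fraction=0.0, hotspot_rate=0.0)
        scenes = generate_dataset(preset, n, seed=seed, shape=(96, 96))
        return [(make_variant(s.image, "D4"), make_auxiliary_masks(s.labels)) for s in scenes]

    def test_smoke_single_epoch_records_loss(self):
        pred = train_stage(self._pairs(2), "foreground", TrainConfig(epochs=1, seed=0))
        assert isinstance(pred, StagePredictor)
        assert pred.provenance == "trained"
        assert len(pred.losses) == 1

    def test_training_loss_decreases(self):
        for stage in ("foreground", "distance"):
            pred = train_stage(self._pairs(6, seed=3), stage, TrainConfig(epochs=5, seed=3))
            assert pred.losses[-1] < pred.losses[0]

    def test_prediction_bounded_and_shaped(self):
        pairs = self._pairs(3, seed=1)
        pred = train_stage(pairs, "distance", TrainConfig(epochs=2, seed=1))
        out = pred.predict(pairs[0][0])
        assert out.shape == pairs[0][0].shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_refuses_unnormalized_training_images(self):
        img = np.full((32, 32), 9000, dtype=np.uint16)
        aux = make_auxiliary_masks(np.zeros((32, 32), dtype=int))
        with pytest.raises(NotNormalizedError):
            train_stage([(img, aux)], "foreground")

    def test_backends_are_interchangeable_in_segment(self):
        pairs = self._pairs(4, seed=5)
        cfg = TrainConfig(epochs=2, seed=5)
        trained_fg = train_stage(pairs, "foreground", cfg)
        trained_d = train_stage(pairs, "distance", cfg)
        img = pairs[0][0]
        for fg, d in [
            (classical_predictor("foreground"), classical_predictor("distance")),
            (trained_fg, trained_d),
            (classical_predictor("foreground"), trained_d),
        ]:
            labels = segment(img, fg, d)
            assert labels.shape == img.shape
            assert labels.dtype == np.uint16


def test_segment_is_deterministic(easy_scene, classical_pair):
    norm = make_variant(easy_scene.image, "D4")
    fg, d = classical_pair
    a, b = segment(norm, fg, d), segment(norm, fg, d)
    np.testing.assert_array_equal(a, b)


def test_segment_on_blank_image_returns_empty(classical_pair):
    fg, d = classical_pair
    labels = segment(np.zeros((64, 64)), fg, d)
    assert not labels.any()
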