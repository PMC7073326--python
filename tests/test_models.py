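import time

import numpy as np
import pytest

from colornet.features import FEATURE_LENGTH, HistogramFeature, extract_feature
from colornet.imgio import from_array
from colornet.models import (
    InvalidDatasetError,
    RankerModel,
    VerifierModel,
    score_partitions,
    train_ranker,
    train_verifier,
    verify_patch,
)
from colornet.proposals import Partition


def delta_histogram_dataset(n=300, seed=0):
    """Two linearly separable classes: all mass in bin 0 vs bin 255."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, FEATURE_LENGTH))
    y = np.zeros(n, dtype=int)
    for i in range(n):
        y[i] = i % 2
        bin_at = 255 if y[i] else 0
        for c in range(6):
            X[i, c * 256 + bin_at] = 1.0
        X[i] += rng.uniform(0, 1e-3, FEATURE_LENGTH)  # break exact ties
    return X, y


def toy_patch_dataset(n=200, seed=0):
    """Solid white vs solid black 125 x 125 patches."""
    rng = np.random.default_rng(seed)
    X = np.empty((n, 125, 125, 3), dtype=np.uint8)
    y = np.arange(n) % 2
    for i in range(n):
        base = 235 if y[i] else 15
        X[i] = np.clip(base + rng.integers(-10, 11, (125, 125, 3)), 0, 255)
    return X, y.astype(int)


class TestTrainRanker:
    def test_separable_toy_reaches_perfect_validation(self):
        model = train_ranker(delta_histogram_dataset(), hyper={"epochs": 8, "seed": 1})
        assert model.training_meta["val_accuracy"] == 1.0

    def test_permuted_labels_hover_at_chance(self):
        X, y = delta_histogram_dataset(n=600, seed=2)
        rng = np.random.default_rng(3)
        model = train_ranker((X, rng.permutation(y)), hyper={"epochs": 6, "seed": 1})
        assert 0.35 <= model.training_meta["val_accuracy"] <= 0.65

    def test_single_class_rejected(self):
        X, _ = delta_histogram_dataset(n=100)
        with pytest.raises(InvalidDatasetError):
            train_ranker((X, np.ones(100, dtype=int)), hyper={"epochs": 2})

    def test_fixed_seed_reproducible_bitwise(self):
        data = delta_histogram_dataset(n=200, seed=5)
        m1 = train_ranker(data, hyper={"epochs": 4, "seed": 9})
        m2 = train_ranker(data, hyper={"epochs": 4, "seed": 9})
        assert m1.training_meta == m2.training_meta
        probe = np.asarray(data[0][:10])
        assert np.array_equal(m1.predict_proba(probe), m2.predict_proba(probe))


@pytest.fixture(scope="module")
def toy_ranker():
    return train_ranker(delta_histogram_dataset(), hyper={"epochs": 6, "seed": 1})


class TestScorePartitions:
    def test_single_feature(self, toy_ranker):
        f = HistogramFeature(np.full(FEATURE_LENGTH, 1e-3), source_partition="p0")
        out = score_partitions([f], toy_ranker)
        assert len(out) == 1 and 0.0 <= out[0][1] <= 1.0

    def test_duplicates_tie_and_keep_order(self, toy_ranker):
        v = np.full(FEATURE_LENGTH, 1e-3)
        feats = [
            HistogramFeature(v.copy(), source_partition="a"),
            HistogramFeature(v.copy(), source_partition="b"),
        ]
        out = score_partitions(feats, toy_ranker)
        assert out[0][1] == out[1][1]
        assert [p for p, _ in out] == ["a", "b"]

    def test_sorted_descending_and_order_invariant(self, toy_ranker):
        rng = np.random.default_rng(4)
        feats = [
            HistogramFeature(rng.uniform(0, 0.01, FEATURE_LENGTH), source_partition=i)
            for i in range(20)
        ]
        out = score_partitions(feats, toy_ranker)
        probs = [p for _, p in out]
        assert probs == sorted(probs, reverse=True)
        shuffled = [feats[i] for i in rng.permutation(20)]
        out2 = score_partitions(shuffled, toy_ranker)
        assert sorted(p for _, p in out2) == sorted(probs)

    def test_wrong_feature_length_rejected(self, toy_ranker):
        with pytest.raises(ValueError):
            toy_ranker.predict_proba(np.zeros((2, 100)))

    def test_score_cost_independent_of_source_partition_size(self, toy_ranker):
        rng = np.random.default_rng(8)
        small_img = from_array(rng.integers(0, 256, (130, 130, 3), dtype=np.uint8))
        big_img = from_array(rng.integers(0, 256, (310, 310, 3), dtype=np.uint8))
        f_small = extract_feature(small_img, Partition(0, 0, 125, 125)).values[None]
        f_big = extract_feature(big_img, Partition(0, 0, 300, 300)).values[None]

        def median_time(feat):
            times = []
            for _ in range(7):
                t0 = time.perf_counter()
                toy_ranker.predict_proba(feat)
                times.append(time.perf_counter() - t0)
            return np.median(times)

        t_small, t_big = median_time(f_small), median_time(f_big)
        assert t_big / t_small < 1.5


@pytest.fixture(scope="module")
def toy_verifier():
    return train_verifier(toy_patch_dataset(), hyper={"epochs": 5, "seed": 2})


class TestVerifier:
    def test_separable_toy_reaches_perfect_validation(self, toy_verifier):
        assert toy_verifier.training_meta["val_accuracy"] == 1.0

    def test_permuted_labels_hover_at_chance(self):
        X, y = toy_patch_dataset(n=300, seed=7)
        rng = np.random.default_rng(8)
        model = train_verifier((X, rng.permutation(y)), hyper={"epochs": 3, "seed": 2})
        assert 0.3 <= model.training_meta["val_accuracy"] <= 0.7

    def test_deterministic_probability(self, toy_verifier):
        rng = np.random.default_rng(9)
        patch = rng.integers(0, 256, (125, 125, 3), dtype=np.uint8)
        assert verify_patch(patch, toy_verifier) == verify_patch(patch, toy_verifier)

    def test_wrong_shape_rejected(self, toy_verifier):
        with pytest.raises(ValueError):
            verify_patch(np.zeros((64, 64, 3), dtype=np.uint8), toy_verifier)

    def test_single_class_rejected(self):
        X, _ = toy_patch_dataset(n=100)
        with pytest.raises(InvalidDatasetError):
            train_verifier((X, np.zeros(100, dtype=int)), hyper={"epochs": 1})

    def test_fixed_seed_reproducible_bitwise(self):
        data = toy_patch_dataset(n=120, seed=3)
        m1 = train_verifier(data, hyper={"epochs": 2, "seed": 6})
        m2 = train_verifier(data, hyper={"epochs": 2, "seed": 6})
        assert m1.training_meta == m2.training_meta
        assert np.array_equal(m1.predict_proba(data[0][:4]), m2.predict_proba(data[0][:4]))


class TestModelContainers:
    def test_ranker_roundtrip(self, tmp_path):
        model = train_ranker(delta_histogram_dataset(n=100), hyper={"epochs": 2, "seed": 0})
        path = tmp_path / "ranker.npz"
        model.save(path)
        loaded = RankerModel.load(path)
        probe = np.random.default_rng(0).uniform(0, 0.01, (5, FEATURE_LENGTH))
        assert np.array_equal(model.predict_proba(probe), loaded.predict_proba(probe))
        assert loaded.training_meta == model.training_meta

    def test_verifier_roundtrip(self, tmp_path):
        model = train_verifier(toy_patch_dataset(n=60), hyper={"epochs": 1, "seed": 0})
        path = tmp_path / "verifier.npz"
        model.save(path)
        loaded = VerifierModel.load(path)
        X, _ = toy_patch_dataset(n=4, seed=1)
        assert np.array_equal(model.predict_proba(X), loaded.predict_proba(X))

    def test_kind_mismatch_refused(self, tmp_path):
        model = train_ranker(delta_histogram_dataset(n=100), hyper={"epochs": 1, "seed": 0})
        path = tmp_path / "ranker.npz"
        model.save(path)
        with pytest.raises(ValueError, match="expected 'verifier'"):
            VerifierModel.load(path)
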