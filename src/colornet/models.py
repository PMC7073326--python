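"""The two learners of the detection cascade.

* **RankerModel** — a multilayer perceptron over the 1536-element RGB+HSV
  histogram feature.  It is cheap enough to score every sliding-window
  partition, and is used only to *order* candidates from most to least
  likely to contain the chart.
* **VerifierModel** — a small convolutional classifier on raw RGB pixels
  that confirms or rejects the top-ranked partitions.  It sees spatial
  structure (the patch grid and frame) that the histogram cannot encode,
  which is what rescues cases like flowers or colorful logos that fool a
  pure color ranker.

The ranker is trained with scikit-learn's MLP implementation (weights are
extracted afterwards, so inference is a plain numpy forward pass); the
verifier is a compact numpy CNN (see ``_cnn``).  Training is reproducible:
every random source (splits, init, batching) derives from one seed.
Weights are stored in a single ``.npz`` container with an embedded JSON
header describing the architecture; loading refuses mismatched shapes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from ._cnn import SmallCNN, sigmoid
from .features import FEATURE_LENGTH

DEFAULT_HYPER = {"epochs": 10, "batch": 64, "lr": 1e-3, "seed": 0}

PATCH_SIZE = 125          # verifier contract: 125 x 125 x 3 uint8 patches
_VERIFIER_INPUT = 30      # internal working resolution of the conv stack


class InvalidDatasetError(ValueError):
    """Raised when a training set cannot support binary training."""


def _merge_hyper(hyper: dict | None) -> dict:
    out = dict(DEFAULT_HYPER)
    if hyper:
        out.update(hyper)
    return out


def _split_train_val(n: int, seed: int, frac: float = 0.1):
    rng = np.random.default_rng([int(seed), 97])
    order = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return order[n_val:], order[:n_val]


# ---------------------------------------------------------------------------
# ranker


@dataclass
class RankerModel:
    """MLP scoring histogram features; layers 1536 -> 512 -> 128 -> 1.

    Features enter through a Hellinger (element-wise square-root) mapping:
    histogram frequencies are spiky and the sqrt map both stabilizes their
    variance and turns Euclidean inner products into the Hellinger affinity,
    a standard choice for histogram features.
    """

    coefs: list
    intercepts: list
    hidden: tuple[int, ...] = (512, 128)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coefs[0].shape[0] != FEATURE_LENGTH:
            raise ValueError(f"ranker input width must be {FEATURE_LENGTH}")
        if self.coefs[-1].shape[1] != 1:
            raise ValueError("ranker must end in a single probability unit")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != FEATURE_LENGTH:
            raise ValueError(
                f"expected features of length {FEATURE_LENGTH}, got {x.shape[1]}"
            )
        x = np.sqrt(np.maximum(x, 0.0))  # Hellinger mapping
        for w, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            x = np.maximum(x @ w + b, 0.0)
        z = (x @ self.coefs[-1] + self.intercepts[-1])[:, 0]
        return sigmoid(z)

    def save(self, path) -> None:
        _save_container(path, kind="ranker",
                        arch={"hidden": list(self.hidden)},
                        meta=self.training_meta,
                        arrays=list(self.coefs) + list(self.intercepts))

    @classmethod
    def load(cls, path) -> "RankerModel":
        header, arrays = _load_container(path, expected_kind="ranker")
        n = len(arrays) // 2
        model = cls(coefs=arrays[:n], intercepts=arrays[n:],
                    hidden=tuple(header["arch"]["hidden"]),
                    training_meta=header["meta"])
        widths = [FEATURE_LENGTH, *model.hidden, 1]
        for w, (a, b) in zip(model.coefs, zip(widths[:-1], widths[1:])):
            if w.shape != (a, b):
                raise ValueError(
                    f"architecture mismatch: stored layer {w.shape}, expected {(a, b)}"
                )
        return model


def train_ranker(dataset, hyper: dict | None = None,
                 hidden: tuple[int, ...] = (512, 128)) -> RankerModel:
    """Fit the histogram ranker on ``(features (n, 1536), labels (n,))``.

    A seeded 90/10 shuffle provides the validation split whose accuracy is
    recorded in ``training_meta``.
    """
    hyper = _merge_hyper(hyper)
    X, y = dataset
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[1] != FEATURE_LENGTH:
        raise ValueError(f"features must be (n, {FEATURE_LENGTH})")
    if len(np.unique(y)) < 2:
        raise InvalidDatasetError("both classes must be present to train the ranker")
    tr, va = _split_train_val(len(X), hyper["seed"])
    if len(np.unique(y[tr])) < 2:
        raise InvalidDatasetError("both classes must be present in the training split")
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(hidden),
        activation="relu",
        solver="adam",
        batch_size=min(hyper["batch"], len(tr)),
        learning_rate_init=hyper["lr"],
        max_iter=hyper["epochs"],
        n_iter_no_change=max(hyper["epochs"], 10),
        random_state=int(hyper["seed"]) % (2**32),
        alpha=1e-4,
    )
    Xh = np.sqrt(np.maximum(X, 0.0))  # Hellinger mapping, mirrored in predict
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # max_iter is an epoch budget, not a tolerance
        clf.fit(Xh[tr], y[tr])
    model = RankerModel(
        coefs=[np.asarray(w) for w in clf.coefs_],
        intercepts=[np.asarray(b).ravel() for b in clf.intercepts_],
        hidden=tuple(hidden),
    )
    val_acc = float(np.mean((model.predict_proba(X[va]) >= 0.5) == (y[va] == 1)))
    model.training_meta = {
        "seed": int(hyper["seed"]),
        "epochs": int(hyper["epochs"]),
        "n_samples": int(len(tr)),
        "val_accuracy": val_acc,
    }
    return model


def score_partitions(features, model: RankerModel):
    """Score and rank partitions by chart probability, descending.

    *features* is a list of :class:`~colornet.features.HistogramFeature`
    (their ``source_partition`` travels along) or a bare (n, 1536) matrix
    paired with partitions via ``partitions=``-style tuples.  Ties keep the
    original (row-major) order, so the ranking is deterministic.
    """
    if len(features) == 0:
        raise ValueError("need at least one feature to score")
    if hasattr(features[0], "values"):
        matrix = np.stack([f.values for f in features])
        parts = [f.source_partition for f in features]
    else:
        matrix = np.asarray(features, dtype=np.float64)
        parts = list(range(len(features)))
    probs = model.predict_proba(matrix)
    order = np.argsort(-probs, kind="stable")
    return [(parts[i], float(probs[i])) for i in order]


# ---------------------------------------------------------------------------
# verifier


def _downsample_patches(patches: np.ndarray) -> np.ndarray:
    """(n, 125, 125, 3) uint8 -> (n, 30, 30, 3) float in [0, 1] by box averaging."""
    if patches.ndim == 3:
        patches = patches[None]
    if patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(
            f"verifier patches must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {patches.shape[1:]}"
        )
    crop = patches[:, 2:122, 2:122, :].astype(np.float64)
    n = crop.shape[0]
    down = crop.reshape(n, _VERIFIER_INPUT, 4, _VERIFIER_INPUT, 4, 3).mean(axis=(2, 4))
    return down / 255.0


@dataclass
class VerifierModel:
    """Convolutional background-vs-chart classifier on 125 x 125 x 3 patches.

    Non-square proposals are resized to 125 x 125 upstream; the conv stack
    itself runs at a reduced internal resolution for CPU speed.
    """

    net: SmallCNN
    input_size: tuple[int, int, int] = (PATCH_SIZE, PATCH_SIZE, 3)
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(_downsample_patches(np.asarray(patches)))

    def save(self, path) -> None:
        arch = {"input_hw": self.net.input_hw, "channels": list(self.net.channels),
                "dense": self.net.dense}
        _save_container(path, kind="verifier", arch=arch, meta=self.training_meta,
                        arrays=self.net.get_weights())

    @classmethod
    def load(cls, path) -> "VerifierModel":
        header, arrays = _load_container(path, expected_kind="verifier")
        arch = header["arch"]
        net = SmallCNN(input_hw=arch["input_hw"], channels=tuple(arch["channels"]),
                       dense=arch["dense"], seed=0)
        net.set_weights(arrays)  # raises on architecture mismatch
        return cls(net=net, training_meta=header["meta"])


def train_verifier(dataset, hyper: dict | None = None,
                   channels: tuple[int, ...] = (16, 32, 64),
                   dense: int = 64) -> VerifierModel:
    """Fit the patch verifier on ``(patches uint8 (n, 125, 125, 3), labels)``."""
    hyper = _merge_hyper(hyper)
    X, y = dataset
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise InvalidDatasetError("both classes must be present to train the verifier")
    Xd = _downsample_patches(X)
    tr, va = _split_train_val(len(Xd), hyper["seed"])
    if len(np.unique(y[tr])) < 2:
        raise InvalidDatasetError("both classes must be present in the training split")
    net = SmallCNN(input_hw=_VERIFIER_INPUT, channels=channels, dense=dense,
                   seed=int(hyper["seed"]))
    net.fit(Xd[tr], y[tr], epochs=hyper["epochs"], batch_size=hyper["batch"],
            lr=hyper["lr"], seed=int(hyper["seed"]) + 1)
    model = VerifierModel(net=net)
    val_acc = float(np.mean((net.predict_proba(Xd[va]) >= 0.5) == (y[va] == 1)))
    model.training_meta = {
        "seed": int(hyper["seed"]),
        "epochs": int(hyper["epochs"]),
        "n_samples": int(len(tr)),
        "val_accuracy": val_acc,
    }
    return model


def verify_patch(patch: np.ndarray, model: VerifierModel) -> float:
    """Probability that a single 125 x 125 x 3 patch is a chart."""
    patch = np.asarray(patch)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected a {PATCH_SIZE}x{PATCH_SIZE}x3 patch, got {patch.shape}")
    return float(model.predict_proba(patch[None])[0])


# ---------------------------------------------------------------------------
# weight container


def _save_container(path, kind: str, arch: dict, meta: dict, arrays) -> None:
    header = json.dumps({"kind": kind, "arch": arch, "meta": meta})
    payload = {f"arr_{i:03d}": a for i, a in enumerate(arrays)}
    np.savez(str(path), header=np.array(header), **payload)


def _load_container(path, expected_kind: str):
    with np.load(str(path), allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header["kind"] != expected_kind:
            raise ValueError(
                f"{path} holds a {header['kind']!r} model, expected {expected_kind!r}"
            )
        keys = sorted(k for k in data.files if k.startswith("arr_"))
        arrays = [np.array(data[k]) for k in keys]
    return header, arrays
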