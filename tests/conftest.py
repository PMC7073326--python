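import numpy as np
import pytest

from colornet.features import extract_features
from colornet.imgio import from_array
from colornet.models import train_ranker, train_verifier
from colornet.proposals import Partition
from colornet.synthdata import (
    AugmentationParams,
    SheetSpec,
    make_patch_dataset,
    render_sheet,
)


def patch_features(patches: np.ndarray) -> np.ndarray:
    """(n, 125, 125, 3) -> (n, 1536) histogram features."""
    window = [Partition(0, 0, 125, 125)]
    return np.stack([extract_features(from_array(p), window)[0] for p in patches])


@pytest.fixture(scope="session")
def small_models():
    """Quickly trained model pair for pipeline plumbing tests.

    Trained on a small patch set: good enough to find obvious charts, not
    meant to meet the benchmark accuracy bar (the acceptance suite trains
    the full-size models).
    """
    X, y = make_patch_dataset(2000, seed=4242)
    ranker = train_ranker((patch_features(X), y), hyper={"epochs": 8, "seed": 0})
    Xv, yv = make_patch_dataset(2400, seed=4243)
    verifier = train_verifier((Xv, yv), hyper={"epochs": 8, "seed": 0})
    return ranker, verifier


@pytest.fixture()
def plain_sheet():
    """One deterministic unaugmented sheet with a chart at a known position."""
    spec = SheetSpec(
        size=(1250, 1875),
        crc_position=(400, 700),
        skew_prob=0.0,
        occlusion_prob=0.0,
        augmentation=None,
        seed=1234,
    )
    img, gt = render_sheet(spec)
    return img, gt


@pytest.fixture()
def mild_augmentation():
    return AugmentationParams(darken=0.85, desaturate=0.2, wb_shift=(1.1, 1.0, 0.9))
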