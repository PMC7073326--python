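"""End-to-end convenience routines: default training and study trials.

These wrap the module-level pieces into the standard experiment recipe:
train both learners on generated patches, evaluate on a held-out generated
benchmark, and run the two post-processing parameter studies (white-balance
recovery, orientation round trip).  The CLI, the acceptance script and the
test suite all go through these entry points so they measure the same thing.
"""

from __future__ import annotations

import numpy as np

from .detector import DetectorConfig, detect, precision_crop
from .features import extract_features
from .imgio import from_array, standardize
from .models import train_ranker, train_verifier
from .postprocess import apply_gains, compute_gains, orient
from .proposals import Partition
from .synthdata import (
    AugmentationParams,
    SheetSpec,
    make_patch_dataset,
    render_sheet,
    _random_template,
)

# default training recipe: enough samples/epochs for the synthetic task
# while keeping a full train+evaluate cycle in the tens of minutes on 1 CPU
N_RANKER_PATCHES = 10_000
N_VERIFIER_PATCHES = 8_000
RANKER_EPOCHS = 12
VERIFIER_EPOCHS = 15


def patch_feature_matrix(patches: np.ndarray) -> np.ndarray:
    """(n, 125, 125, 3) uint8 -> (n, 1536) normalized histogram features."""
    window = [Partition(0, 0, 125, 125)]
    return np.stack([extract_features(from_array(p), window)[0] for p in patches])


def train_models(seed: int, n_ranker: int = N_RANKER_PATCHES,
                 n_verifier: int = N_VERIFIER_PATCHES,
                 ranker_epochs: int = RANKER_EPOCHS,
                 verifier_epochs: int = VERIFIER_EPOCHS):
    """Generate training patches and fit both learners; returns (ranker, verifier)."""
    X, y = make_patch_dataset(n_ranker, seed=seed)
    ranker = train_ranker((patch_feature_matrix(X), y),
                          hyper={"epochs": ranker_epochs, "seed": seed})
    Xv, yv = make_patch_dataset(n_verifier, seed=seed + 1)
    verifier = train_verifier((Xv, yv),
                              hyper={"epochs": verifier_epochs, "seed": seed})
    return ranker, verifier


def white_balance_recovery_trial(n_trials: int, seed: int, size=(640, 960)) -> dict:
    """Render sheets under random casts and measure gain recovery.

    Each trial renders a sheet with known effective per-channel gains
    (white-balance shift drawn from [0.6, 1.4] per channel, normalized and
    combined with darkening), computes max-white gains from the known white
    patch, and compares them with the inverse of what was applied.  Also
    measures idempotence: gains recomputed after correction.
    """
    rng = np.random.default_rng([int(seed), 2])  # namespace 2: wb trials
    rel_errors, second_gain_devs = [], []
    for _ in range(n_trials):
        aug = AugmentationParams(
            darken=float(rng.uniform(0.4, 1.0)),
            desaturate=float(rng.uniform(0.0, 1.0)),
            wb_shift=tuple(float(v) for v in rng.uniform(0.6, 1.4, size=3)),
        )
        tpl = _random_template(rng)
        spec = SheetSpec(size=size, crc_template=tpl, skew_prob=0.0,
                         occlusion_prob=0.0, augmentation=aug,
                         n_distractors=4, seed=int(rng.integers(0, 2**31 - 1)))
        img, gt = render_sheet(spec)
        sheet = from_array(img)
        wx, wy = gt["white_patch_center"]
        half = max(2, tpl.patch_px // 4)
        region = (wx - half, wy - half, 2 * half, 2 * half)
        gains = compute_gains(sheet, region)
        expected = [1.0 / g for g in gt["gains_applied"]]
        rel_errors.append(max(
            abs(g - e) / e for g, e in zip(gains.gains, expected)
        ))
        corrected = apply_gains(sheet, gains)
        second = compute_gains(corrected, region)
        second_gain_devs.append(max(abs(g - 1.0) for g in second.gains))
    return {
        "n": n_trials,
        "max_relative_error_pct": 100.0 * float(np.max(rel_errors)),
        "mean_relative_error_pct": 100.0 * float(np.mean(rel_errors)),
        "max_idempotence_deviation_pct": 100.0 * float(np.max(second_gain_devs)),
    }


def orientation_roundtrip_trial(n_trials: int, seed: int, ranker, verifier,
                                config: DetectorConfig | None = None) -> dict:
    """Rotate canonically-placed charts by known quarter turns and restore.

    The chart is planted in the SE quadrant, the sheet rotated by a known
    k x 90 degrees, and the full pipeline (detect, precision-crop, orient)
    must undo it exactly.  Returns counts of detected and exactly-restored
    sheets.
    """
    if config is None:
        config = DetectorConfig()
    rng = np.random.default_rng([int(seed), 3])  # namespace 3: orientation
    n_detected = n_correct = 0
    for _ in range(n_trials):
        aug = AugmentationParams.random(rng, rotate=True)
        spec = SheetSpec(crc_quadrant="SE", crc_template=_random_template(rng),
                         augmentation=aug, seed=int(rng.integers(0, 2**31 - 1)))
        img, gt = render_sheet(spec)
        sheet = standardize(from_array(img), config.target_short_side)
        det = detect(sheet, ranker, verifier, config=config, mode="normal")
        if det is None:
            continue
        det = precision_crop(sheet, det, config=config)
        try:
            _, decision = orient(sheet, det, target_quadrant="SE")
        except ValueError:
            continue
        n_detected += 1
        if decision.rotation == (-gt["rotation_applied"]) % 360:
            n_correct += 1
    return {"n": n_trials, "n_detected": n_detected, "n_correct": n_correct}
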