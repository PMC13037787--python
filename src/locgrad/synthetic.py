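"""Seeded phantom datasets and a tiny trainable segmentation model.

The phantom generator emulates the structure of a lesion-delineation problem
at desk scale: blob-like foreground lesions of varying contrast on a noisy
background, plus *distractor* blobs that share the lesions' intensity range
but are background in the ground truth. Distractors are the mechanism for
inducing honest false positives — a model trained on these images genuinely
segments some of them — mirroring the benign-mimic narrative of clinical
lesion detection rather than corrupting labels.

Defaults define the standard study conditions used throughout the test-suite
and the acceptance script: 200 images on a 48 x 48 grid at 2.5 mm spacing,
1–3 Gaussian-profile lesions per image (amplitude 0.9–1.5 against unit-free
background noise of sigma 0.15), and a distractor blob in 60% of images with
amplitude 0.6–1.1: the overlap with the low end of the lesion band makes the
two populations genuinely ambiguous there, so a trained model segments some
distractors (false positives) and does so at reduced confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import TrainingError
from .model import ToyUNet
from .regions import LabelMap

__all__ = ["PhantomSpec", "ToyModelSpec", "generate_phantoms",
           "build_toy_model", "train_toy_model", "dice_score"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom dataset."""

    n_images: int = 200
    shape: tuple = (48, 48)
    spacing: tuple = (2.5, 2.5)
    n_classes: int = 2
    lesion_count: tuple = (1, 3)          # inclusive range per image
    lesion_radius: tuple = (3.0, 5.5)     # half-maximum radius, voxels
    lesion_contrast: tuple = (0.9, 1.5)   # blob amplitude range
    distractor_rate: float = 0.6          # probability an image has a distractor
    distractor_contrast: tuple = (0.6, 1.1)
    noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate must lie in [0, 1]")
        if self.lesion_count[0] < 1:
            raise ValueError("each image must contain at least one lesion")
        margin = self.lesion_radius[1] + 2
        if any(dim <= 2 * margin for dim in self.shape):
            raise ValueError("grid too small for the requested blob radius")


@dataclass(frozen=True)
class ToyModelSpec:
    """Architecture of the toy U-Net (decoder exposes 2 blocks per level)."""

    levels: int = 3
    base_channels: int = 8
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _add_blob(img: np.ndarray, truth: np.ndarray, rng: np.random.Generator,
              radius_range: tuple, amplitude: float, label: int,
              grids: tuple) -> None:
    """Add one Gaussian-profile blob; label its half-maximum footprint."""
    r = rng.uniform(*radius_range)
    center = [rng.uniform(r + 1, dim - r - 1) for dim in img.shape]
    # half-maximum of the profile falls at distance r from the center
    s = r / np.sqrt(2.0 * np.log(2.0))
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    profile = amplitude * np.exp(-d2 / (2.0 * s * s))
    img += profile
    if label > 0:
        truth[profile > 0.5 * amplitude] = label


def generate_phantoms(spec: PhantomSpec, return_meta: bool = False) -> tuple:
    """Seeded phantom images and ground-truth label maps.

    Lesions of class ``c`` get amplitudes scaled by ``1 + 0.7 (c - 1)`` so
    multi-class labels carry an intensity signature a model can learn.
    Distractors share the image-formation process but stay background in the
    truth. Bit-reproducible for a fixed spec.

    Returns ``(images, truths)`` — lists of float arrays and ``LabelMap`` —
    plus, when ``return_meta`` is set, a per-image dict with the realized
    lesion count and distractor flag.
    """
    rng = np.random.default_rng(spec.seed)
    grids = np.meshgrid(*[np.arange(d, dtype=np.float64) for d in spec.shape],
                        indexing="ij")
    images, truths, meta = [], [], []
    for _ in range(spec.n_images):
        img = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        truth = np.zeros(spec.shape, dtype=np.int32)
        n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
        for _ in range(n_lesions):
            label = int(rng.integers(1, spec.n_classes)) if spec.n_classes > 2 else 1
            amp = rng.uniform(*spec.lesion_contrast) * (1.0 + 0.7 * (label - 1))
            _add_blob(img, truth, rng, spec.lesion_radius, amp, label, grids)
        has_distractor = bool(rng.uniform() < spec.distractor_rate)
        if has_distractor:
            amp = rng.uniform(*spec.distractor_contrast)
            _add_blob(img, truth, rng, spec.lesion_radius, amp, 0, grids)
        images.append(img)
        truths.append(LabelMap(truth, spec.spacing))
        meta.append(dict(n_lesions=n_lesions, has_distractor=has_distractor))
    if return_meta:
        return images, truths, meta
    return images, truths


def build_toy_model(spec: ToyModelSpec) -> ToyUNet:
    """Deterministically initialized toy U-Net satisfying the model contract."""
    return ToyUNet(levels=spec.levels, base_channels=spec.base_channels,
                   n_classes=spec.n_classes, seed=spec.seed)


# --------------------------------------------------------------------------- #
# training                                                                    #
# --------------------------------------------------------------------------- #

_P_FLOOR = 1e-8
_DICE_SMOOTH = 1.0


def _loss_and_backward(model: ToyUNet, image: np.ndarray,
                       truth: np.ndarray) -> float:
    """Dice + cross-entropy loss; accumulates parameter gradients."""
    probs = model.predict_proba(image)
    n_classes = probs.shape[0]
    onehot = np.zeros_like(probs)
    for c in range(n_classes):
        onehot[c] = truth == c
    p = np.clip(probs, _P_FLOOR, 1.0)
    n_pix = probs[0].size

    ce = float(-(onehot * np.log(p)).sum() / n_pix)
    dprobs = -(onehot / p) / n_pix

    # soft Dice over foreground classes
    dice_loss = 0.0
    n_fg = n_classes - 1
    for c in range(1, n_classes):
        num = 2.0 * float((probs[c] * onehot[c]).sum()) + _DICE_SMOOTH
        den = float(probs[c].sum() + onehot[c].sum()) + _DICE_SMOOTH
        dice_loss += (1.0 - num / den) / n_fg
        dprobs[c] += -(2.0 * onehot[c] * den - num) / (den * den) / n_fg

    model.backward_from_probs(dprobs)
    return ce + dice_loss


def train_toy_model(model: ToyUNet, images: Sequence, truths: Sequence,
                    epochs: int = 10, batch_size: int = 8, lr: float = 3e-3,
                    seed: int = 0) -> ToyUNet:
    """Train on Dice + cross-entropy with Adam; deterministic given the seed.

    ``truths`` may be ``LabelMap`` objects or plain integer arrays. The mean
    per-epoch loss history is left on the model as ``loss_history_``.
    """
    if len(images) == 0:
        raise ValueError("phantom set must be non-empty")
    truth_arrays = [t.values if isinstance(t, LabelMap) else np.asarray(t)
                    for t in truths]
    rng = np.random.default_rng(seed)
    opt = model.make_optimizer(lr=lr)
    history = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            model.zero_grad()
            batch_loss = 0.0
            for i in batch:
                batch_loss += _loss_and_backward(model, images[i], truth_arrays[i])
            if not np.isfinite(batch_loss):
                raise TrainingError("training loss became non-finite")
            opt.step([g / len(batch) for g in model.collect_gradients()])
            epoch_loss += batch_loss
        history.append(epoch_loss / n)
    model.loss_history_ = history
    model._last_input = None
    return model


def dice_score(pred_labels: np.ndarray, truth: np.ndarray) -> float:
    """Foreground Dice coefficient (any nonzero class vs background)."""
    p = np.asarray(pred_labels) > 0
    t = np.asarray(truth) > 0
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)
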