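"""Shared fixtures: tiny models, the trained standard phantom fixture."""

from collections import OrderedDict

import numpy as np
import pytest
from hypothesis import settings

from locgrad import (PhantomSpec, ToyModelSpec, build_toy_model,
                     generate_phantoms, train_toy_model)
from locgrad.model import ToyUNet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


class MiniLogistic:
    """Single-parameter logistic 'segmentation model' with closed-form gradients.

    One voxel, two classes: p1 = sigmoid(w), p0 = 1 - p1. The only parameter
    group is ``Block_0-0`` holding the scalar w. Used to pin gradient scoring
    against hand-derived values.
    """

    n_classes = 2

    def __init__(self, w: float = 0.0) -> None:
        self.w = np.array([float(w)])
        self.grad_w = np.zeros(1)

    def predict_proba(self, image):
        p1 = 1.0 / (1.0 + np.exp(-self.w[0]))
        return np.array([[[1.0 - p1]], [[p1]]])

    def parameter_groups(self):
        return OrderedDict([("Block_0-0", OrderedDict([("w", self.w)]))])

    def default_groups(self):
        return ["Block_0-0"]

    def gradient_from_probs(self, image, dprobs, group_names):
        p1 = 1.0 / (1.0 + np.exp(-self.w[0]))
        # dp1/dw = p1 (1 - p1); dp0/dw = -p1 (1 - p1)
        dw = dprobs[1, 0, 0] * p1 * (1 - p1) - dprobs[0, 0, 0] * p1 * (1 - p1)
        self.grad_w[0] = dw
        return np.array([dw])

    def group_gradient(self, group_names):
        return self.grad_w.copy()


@pytest.fixture
def mini_logistic():
    return MiniLogistic(w=0.0)


@pytest.fixture
def small_unet():
    """Under-5k-parameter network for finite-difference comparisons."""
    return ToyUNet(levels=2, base_channels=4, n_classes=2, seed=11)


STANDARD_TRAIN = PhantomSpec(n_images=200, seed=0)
STANDARD_VAL = PhantomSpec(n_images=100, seed=1)
STANDARD_EPOCHS = 10
STANDARD_MIN_VOLUME = 0.1  # cm^3; ~16 voxels at 2.5 mm spacing


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard study conditions: toy model trained on 200 seeded phantoms.

    Trained once per session; provides the model plus a held-out validation
    set with distractor blobs for the degradation and FP-filtering checks.
    """
    images, truths = generate_phantoms(STANDARD_TRAIN)
    model = build_toy_model(ToyModelSpec(seed=0))
    train_toy_model(model, images, truths, epochs=STANDARD_EPOCHS, seed=0)
    val_images, val_truths = generate_phantoms(STANDARD_VAL)
    return dict(model=model, spacing=STANDARD_TRAIN.spacing,
                train_images=images, train_truths=truths,
                val_images=val_images, val_truths=val_truths,
                min_volume_cm3=STANDARD_MIN_VOLUME)
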