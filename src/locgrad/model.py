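"""A miniature 2-D U-Net with an inspectable parameter-group registry.

The network follows the classic encoder/decoder layout with equal-resolution
skip connections. Decoder convolutional blocks are the unit of gradient
targeting and are named ``Block_<level>-<pair>``, where level 0 sits at the
bottleneck and the highest level at output resolution, with two blocks
(pair 0 and 1) per level. A model with ``levels=5`` therefore exposes
``Block_0-0`` … ``Block_4-1``.

The implementation is pure NumPy (float64) with hand-written backpropagation
(see :mod:`locgrad._nn`), which keeps per-region gradient queries exact,
deterministic, and cheap to audit against finite differences.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from typing import Optional, Sequence

import numpy as np

from ._nn import (
    Adam,
    Conv1x1,
    ConvBlock,
    avg_pool2,
    avg_pool2_backward,
    softmax_backward,
    softmax_channels,
    upsample2,
    upsample2_backward,
)

__all__ = ["ToyUNet"]


class ToyUNet:
    """Trainable toy segmentation model satisfying the differentiable-model contract.

    Parameters
    ----------
    levels
        Number of decoder resolution levels (>= 2). The decoder exposes
        ``2 * levels`` convolutional blocks; the encoder has ``levels - 1``
        levels plus the bottleneck pair (counted as decoder level 0).
    base_channels
        Channel width at full resolution; doubled at each coarser level.
    n_classes
        Number of output classes (>= 2), class 0 being background.
    seed
        Seed for the deterministic weight initialization.
    """

    def __init__(self, levels: int = 3, base_channels: int = 8,
                 n_classes: int = 2, seed: int = 0) -> None:
        if levels < 2:
            raise ValueError("levels must be >= 2")
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.levels = int(levels)
        self.base_channels = int(base_channels)
        self.n_classes = int(n_classes)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        ch = [base_channels * 2 ** e for e in range(levels - 1)]
        cb = base_channels * 2 ** (levels - 1)

        self.enc: list[list[ConvBlock]] = []
        c_in = 1
        for e in range(levels - 1):
            self.enc.append([ConvBlock(c_in, ch[e], rng), ConvBlock(ch[e], ch[e], rng)])
            c_in = ch[e]

        self.dec: list[list[ConvBlock]] = []
        prev = cb
        for s in range(levels):
            if s == 0:
                self.dec.append([ConvBlock(ch[-1], cb, rng), ConvBlock(cb, cb, rng)])
            else:
                c_skip = ch[levels - 1 - s]
                self.dec.append([ConvBlock(prev + c_skip, c_skip, rng),
                                 ConvBlock(c_skip, c_skip, rng)])
                prev = c_skip
        self.head = Conv1x1(ch[0], n_classes, rng)

        self._last_input: Optional[np.ndarray] = None
        self._probs: Optional[np.ndarray] = None

    # ------------------------------------------------------------------ #
    # registry                                                           #
    # ------------------------------------------------------------------ #

    def parameter_groups(self) -> "OrderedDict[str, OrderedDict[str, np.ndarray]]":
        """Named decoder blocks, ordered bottleneck -> output resolution."""
        reg: "OrderedDict[str, OrderedDict[str, np.ndarray]]" = OrderedDict()
        for s, pair in enumerate(self.dec):
            for p, block in enumerate(pair):
                reg[f"Block_{s}-{p}"] = block.params
        return reg

    def _block(self, name: str) -> ConvBlock:
        try:
            lvl, pair = name.removeprefix("Block_").split("-")
            return self.dec[int(lvl)][int(pair)]
        except (ValueError, IndexError):
            raise KeyError(f"unknown parameter group {name!r}") from None

    def default_groups(self) -> list[str]:
        """The two blocks of the highest-resolution decoder level."""
        top = self.levels - 1
        return [f"Block_{top}-0", f"Block_{top}-1"]

    def all_parameters(self) -> "OrderedDict[str, np.ndarray]":
        named: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for e, pair in enumerate(self.enc):
            for p, block in enumerate(pair):
                for k, v in block.params.items():
                    named[f"Enc_{e}-{p}.{k}"] = v
        for name, params in self.parameter_groups().items():
            for k, v in params.items():
                named[f"{name}.{k}"] = v
        for k, v in self.head.params.items():
            named[f"Head.{k}"] = v
        return named

    def _all_layers(self):
        for pair in self.enc + self.dec:
            yield from pair
        yield self.head

    # ------------------------------------------------------------------ #
    # forward / backward                                                 #
    # ------------------------------------------------------------------ #

    def _prep(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[0] != 1:
            raise ValueError("expected a single-channel 2-D image")
        f = 2 ** (self.levels - 1)
        if x.shape[1] % f or x.shape[2] % f:
            raise ValueError(f"spatial dims must be divisible by {f}")
        return x

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Forward pass; returns per-voxel class probabilities ``(C, H, W)``.

        Activations are cached so that subsequent per-region backward passes
        on the *same* image object reuse this single forward pass.
        """
        x = self._prep(image)
        skips = []
        for e in range(self.levels - 1):
            x = self.enc[e][1].forward(self.enc[e][0].forward(x))
            skips.append(x)
            x = avg_pool2(x)
        self._split = [0] * self.levels
        for s in range(self.levels):
            if s > 0:
                x = upsample2(x)
                self._split[s] = x.shape[0]
                x = np.concatenate([x, skips[self.levels - 1 - s]], axis=0)
            x = self.dec[s][1].forward(self.dec[s][0].forward(x))
        self._probs = softmax_channels(self.head.forward(x))
        self._last_input = image
        return self._probs

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(image), axis=0)

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    def backward_from_probs(self, dprobs: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient seeded on the softmax probabilities.

        Requires a preceding :meth:`predict_proba`. Accumulates parameter
        gradients on every layer and returns the gradient w.r.t. the input.
        """
        if self._probs is None:
            raise RuntimeError("backward_from_probs requires a forward pass first")
        dx = self.head.backward(softmax_backward(self._probs, dprobs))
        dskips: list[Optional[np.ndarray]] = [None] * (self.levels - 1)
        for s in reversed(range(self.levels)):
            dx = self.dec[s][0].backward(self.dec[s][1].backward(dx))
            if s > 0:
                n_up = self._split[s]
                dskips[self.levels - 1 - s] = dx[n_up:]
                dx = upsample2_backward(dx[:n_up])
        d = avg_pool2_backward(dx)
        for e in reversed(range(self.levels - 1)):
            d = d + dskips[e]
            d = self.enc[e][0].backward(self.enc[e][1].backward(d))
            if e > 0:
                d = avg_pool2_backward(d)
        return d

    def gradient_from_probs(self, image: np.ndarray, dprobs: np.ndarray,
                            group_names: Sequence[str]) -> np.ndarray:
        """Gradient of a scalar (given as d(scalar)/d(probs)) w.r.t. named groups.

        Reuses the cached forward pass when ``image`` is the same object as the
        last one seen; gradient buffers are zeroed before the backward pass, so
        successive region queries never bleed into each other.
        """
        if self._last_input is not image:
            self.predict_proba(image)
        self.zero_grad()
        self.backward_from_probs(dprobs)
        return self.group_gradient(group_names)

    def group_gradient(self, group_names: Sequence[str]) -> np.ndarray:
        if not group_names:
            raise ValueError("group_names must be non-empty")
        chunks = []
        for name in group_names:
            block = self._block(name)
            chunks.extend(g.ravel() for g in block.grads.values())
        return np.concatenate(chunks)

    # ------------------------------------------------------------------ #
    # serialization                                                      #
    # ------------------------------------------------------------------ #

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.copy()) for k, v in self.all_parameters().items())

    def load_state_dict(self, state: "dict[str, np.ndarray]") -> None:
        own = self.all_parameters()
        if set(own) != set(state):
            raise ValueError("state dict does not match model architecture")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            v[...] = arr
        self._last_input = None
        self._probs = None

    def save(self, path) -> None:
        state = self.state_dict()
        config = dict(levels=self.levels, base_channels=self.base_channels,
                      n_classes=self.n_classes, seed=self.seed)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(config, sort_keys=True).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "ToyUNet":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            model = cls(**config)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model

    def make_optimizer(self, lr: float = 3e-3) -> Adam:
        return Adam(list(self.all_parameters().values()), lr=lr)

    def collect_gradients(self) -> "list[np.ndarray]":
        grads = []
        for e, pair in enumerate(self.enc):
            for block in pair:
                grads.extend(block.grads.values())
        for pair in self.dec:
            for block in pair:
                grads.extend(block.grads.values())
        grads.extend(self.head.grads.values())
        return grads
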