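"""A small symmetric encoder–decoder segmentation network.

A three-level U-Net (two downsamplings, skip connections by channel
concatenation, nearest-neighbour upsampling, sigmoid output) built on the
package's autodiff core.  It is a desk-scale stand-in that maps an H×W
grayscale image to a same-size probability mask — deliberately tiny so
that every registered loss can be exercised end to end on a CPU.

Registered descriptors: ``unet3-16`` (default, 16 base channels) and
``unet3-8`` (8 base channels, used for quick smoke training).
Parameters are float32, He-initialized from a seeded generator, so two
builds with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool2d, concat, conv2d, upsample_nearest
from .exceptions import ConfigError

__all__ = ["UNet", "build_model", "MODEL_REGISTRY"]

MODEL_REGISTRY = {"unet3-16": 16, "unet3-8": 8}


class UNet:
    """Three-level encoder–decoder with skip connections."""

    def __init__(self, base_channels: int = 16, seed: int = 0):
        self.base_channels = base_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = base_channels
        self.params: dict[str, Tensor] = {}
        # (name, in_ch, out_ch, kernel)
        spec = [
            ("enc1a", 1, c, 3), ("enc1b", c, c, 3),
            ("enc2a", c, 2 * c, 3), ("enc2b", 2 * c, 2 * c, 3),
            ("bota", 2 * c, 4 * c, 3), ("botb", 4 * c, 4 * c, 3),
            ("dec2a", 6 * c, 2 * c, 3), ("dec2b", 2 * c, 2 * c, 3),
            ("dec1a", 3 * c, c, 3), ("dec1b", c, c, 3),
            ("out", c, 1, 1),
        ]
        for name, cin, cout, k in spec:
            fan_in = cin * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
            self.params[f"{name}.w"] = Tensor(w.astype(np.float32), requires_grad=True)
            self.params[f"{name}.b"] = Tensor(np.zeros(cout, dtype=np.float32),
                                              requires_grad=True)
        # output bias starts at the logit of a small foreground prior, the
        # usual initialization for heavily imbalanced segmentation: initial
        # predictions then reflect that masses cover little of the image
        self.params["out.b"].data[:] = -2.0

    @property
    def parameters(self):
        return list(self.params.values())

    def _block(self, x, name_a, name_b):
        x = conv2d(x, self.params[f"{name_a}.w"], self.params[f"{name_a}.b"],
                   padding=1).relu()
        return conv2d(x, self.params[f"{name_b}.w"], self.params[f"{name_b}.b"],
                      padding=1).relu()

    def forward(self, images) -> Tensor:
        """Map (N, H, W) or (N, 1, H, W) images to (N, 1, H, W) probabilities."""
        x = images if isinstance(images, Tensor) else Tensor(
            np.asarray(images, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        H, W = x.shape[2], x.shape[3]
        if H % 4 or W % 4:
            raise ConfigError(f"input size {(H, W)} must be divisible by 4")
        e1 = self._block(x, "enc1a", "enc1b")
        e2 = self._block(avg_pool2d(e1, 2), "enc2a", "enc2b")
        bt = self._block(avg_pool2d(e2, 2), "bota", "botb")
        d2 = self._block(concat([upsample_nearest(bt, 2), e2], axis=1),
                         "dec2a", "dec2b")
        d1 = self._block(concat([upsample_nearest(d2, 2), e1], axis=1),
                         "dec1a", "dec1b")
        logits = conv2d(d1, self.params["out.w"], self.params["out.b"])
        return logits.sigmoid()

    def predict(self, images) -> np.ndarray:
        """Inference: probability masks as a plain (N, H, W) array."""
        return self.forward(images).data[:, 0]

    # -- checkpointing --------------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype)

    def save(self, path) -> None:
        np.savez(path, base_channels=self.base_channels, seed=self.seed,
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as z:
            model = cls(int(z["base_channels"]), int(z["seed"]))
            model.load_state_dict({k: z[k] for k in z.files
                                   if k not in ("base_channels", "seed")})
        return model


def build_model(descriptor: str = "unet3-16", seed: int = 0) -> UNet:
    """Construct a registered tiny U-Net variant."""
    if descriptor not in MODEL_REGISTRY:
        raise ConfigError(
            f"unknown model descriptor {descriptor!r}; "
            f"registered: {sorted(MODEL_REGISTRY)}")
    return UNet(MODEL_REGISTRY[descriptor], seed=seed)
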