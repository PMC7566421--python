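"""InceptionV3 feature network (channels-last, global-average-pooled).

The standard mixed-block channel plan is reproduced so the pooled
descriptor has length 2048.  Weights are randomly initialized unless a
checkpoint is supplied; the network is used here as a (optionally
pretrained) feature extractor and is not trained by this package's test
workloads.  Batch-normalisation layers are folded away: each conv is a
plain convolution + ReLU, which preserves the graph topology and all
tensor shapes.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avgpool2d_same, concat, global_avg_pool, maxpool2d
from .layers import Conv2D, Module

__all__ = ["InceptionV3"]


def _avgpool_same(x, pool=3):
    # 3x3 average pool, stride 1, same padding (branch-pool in mixed blocks)
    return avgpool2d_same(x, pool)


class _Branch(Module):
    """A chain of convolutions applied in order."""

    def __init__(self, convs):
        self.convs = list(convs)

    def __call__(self, x):
        for c in self.convs:
            x = c(x)
        return x


class InceptionV3(Module):
    def __init__(self, rng: np.random.Generator, weight_scale: float = 1.0):
        self._blocks: list = []
        self._rng = rng
        self._scale = weight_scale
        self._build()

    # conv helper: registers parameters on self so Module.parameters() finds them
    def _conv(self, cin, cout, kernel, stride=1, padding="same"):
        c = Conv2D(cin, cout, kernel, self._rng, stride=stride, padding=padding)
        if self._scale != 1.0:
            c.w.data *= self._scale
        self._blocks.append(c)
        return c

    def _build(self):
        cv = self._conv
        # stem
        self.stem = _Branch([
            cv(3, 32, 3, stride=2, padding="valid"),
            cv(32, 32, 3, padding="valid"),
            cv(32, 64, 3, padding="same"),
        ])
        self.stem2 = _Branch([
            cv(64, 80, 1, padding="valid"),
            cv(80, 192, 3, padding="valid"),
        ])

        def inception_a(cin, pool_proj):
            return [
                _Branch([cv(cin, 64, 1)]),
                _Branch([cv(cin, 48, 1), cv(48, 64, 5)]),
                _Branch([cv(cin, 64, 1), cv(64, 96, 3), cv(96, 96, 3)]),
                _Branch([cv(cin, pool_proj, 1)]),
            ]

        self.mixed_a = [inception_a(192, 32), inception_a(256, 64), inception_a(288, 64)]

        # grid reduction 288 -> 768
        self.red_a = [
            _Branch([cv(288, 384, 3, stride=2, padding="valid")]),
            _Branch([cv(288, 64, 1), cv(64, 96, 3), cv(96, 96, 3, stride=2, padding="valid")]),
        ]

        def inception_b(c7):
            return [
                _Branch([cv(768, 192, 1)]),
                _Branch([cv(768, c7, 1), cv(c7, c7, (1, 7)), cv(c7, 192, (7, 1))]),
                _Branch([cv(768, c7, 1), cv(c7, c7, (7, 1)), cv(c7, c7, (1, 7)),
                         cv(c7, c7, (7, 1)), cv(c7, 192, (1, 7))]),
                _Branch([cv(768, 192, 1)]),
            ]

        self.mixed_b = [inception_b(c) for c in (128, 160, 160, 192)]

        # grid reduction 768 -> 1280
        self.red_b = [
            _Branch([cv(768, 192, 1), cv(192, 320, 3, stride=2, padding="valid")]),
            _Branch([cv(768, 192, 1), cv(192, 192, (1, 7)), cv(192, 192, (7, 1)),
                     cv(192, 192, 3, stride=2, padding="valid")]),
        ]

        def inception_e(cin):
            return {
                "b1": _Branch([cv(cin, 320, 1)]),
                "b2_stem": _Branch([cv(cin, 384, 1)]),
                "b2a": cv(384, 384, (1, 3)),
                "b2b": cv(384, 384, (3, 1)),
                "b3_stem": _Branch([cv(cin, 448, 1), cv(448, 384, 3)]),
                "b3a": cv(384, 384, (1, 3)),
                "b3b": cv(384, 384, (3, 1)),
                "pool": _Branch([cv(cin, 192, 1)]),
            }

        self.mixed_e = [inception_e(1280), inception_e(2048)]

    # -- forward -------------------------------------------------------
    def feature_maps(self, x: Tensor) -> Tensor:
        """Final 2048-channel spatial feature maps before pooling."""
        x = self.stem(x)
        x = maxpool2d(x, 3, 2)
        x = self.stem2(x)
        x = maxpool2d(x, 3, 2)
        for block in self.mixed_a:
            parts = [block[0](x), block[1](x), block[2](x), block[3](_avgpool_same(x))]
            x = concat(parts, axis=-1)
        x = concat([self.red_a[0](x), self.red_a[1](x), maxpool2d(x, 3, 2)], axis=-1)
        for block in self.mixed_b:
            parts = [block[0](x), block[1](x), block[2](x), block[3](_avgpool_same(x))]
            x = concat(parts, axis=-1)
        x = concat([self.red_b[0](x), self.red_b[1](x), maxpool2d(x, 3, 2)], axis=-1)
        for block in self.mixed_e:
            b2 = block["b2_stem"](x)
            b3 = block["b3_stem"](x)
            parts = [
                block["b1"](x),
                concat([block["b2a"](b2), block["b2b"](b2)], axis=-1),
                concat([block["b3a"](b3), block["b3b"](b3)], axis=-1),
                block["pool"](_avgpool_same(x)),
            ]
            x = concat(parts, axis=-1)
        return x

    def __call__(self, x: Tensor) -> Tensor:
        """(B, side, side, 3) in [0,1] -> (B, 2048) pooled features."""
        return global_avg_pool(self.feature_maps(x))
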