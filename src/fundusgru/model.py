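"""Prognostic sequence models: shared-weight CNN features, interval
scaling, and a GRU head emitting a progression probability.

Two backbones are available behind one interface:

* ``inception_v3`` — the standard InceptionV3 graph, pooled to a
  2048-long descriptor.  Weights can be loaded from an ``.npz``
  checkpoint; otherwise they are randomly initialized.
* ``tiny_cnn`` — three conv/pool blocks plus global average pooling,
  small enough to train on a CPU in minutes.  Feature length is
  configurable (default 64).

The head consumes the per-visit feature vectors in time order.  When
interval scaling is on, each visit's features are first multiplied by
the deterministic weight 1/(t_pred - t_i) computed outside the network,
so the graph stays differentiable with respect to images only.  The
plain head is a single-unit GRU whose final state passes through a
sigmoid — one scalar probability.  The CAM-capable variant widens the
GRU and adds a dense layer after it, which keeps the predictive
contract while exposing a linear path from pooled features to the
positive logit for class-activation mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nn.autograd import Tensor, global_avg_pool, sigmoid
from .nn.inception import InceptionV3
from .nn.layers import GRU, Conv2D, Dense, MaxPool2D, Module
from .scaling import interval_weights

__all__ = [
    "BackboneSpec",
    "TinyCNN",
    "build_feature_extractor",
    "PrognosticModel",
    "build_prognostic_model",
    "build_cam_model",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Which feature extractor to build and at what size."""

    name: str = "tiny_cnn"
    pretrained: bool = False
    input_side: int = 48
    feature_len: int = 64
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in ("inception_v3", "tiny_cnn"):
            raise ConfigError(f"unknown backbone name {self.name!r}")
        if self.name == "inception_v3" and self.feature_len != 2048:
            object.__setattr__(self, "feature_len", 2048)
        if self.name == "inception_v3" and self.input_side < 75:
            raise ConfigError("inception_v3 needs input_side >= 75")


class TinyCNN(Module):
    """Three conv/pool blocks + global average pooling.

    The last block's pooled maps are exactly what the classifier head
    consumes, so those maps are the natural substrate for CAM.
    """

    def __init__(self, feature_len: int, rng: np.random.Generator,
                 channels: tuple[int, int] = (12, 24)):
        c1, c2 = channels
        self.conv1 = Conv2D(3, c1, 3, rng, batch_norm=True)
        self.pool1 = MaxPool2D(2)
        self.conv2 = Conv2D(c1, c2, 3, rng, batch_norm=True)
        self.pool2 = MaxPool2D(2)
        self.conv3 = Conv2D(c2, feature_len, 3, rng, batch_norm=True)
        self.pool3 = MaxPool2D(2)
        self.feature_len = feature_len

    def feature_maps(self, x: Tensor) -> Tensor:
        x = self.pool1(self.conv1(x))
        x = self.pool2(self.conv2(x))
        x = self.conv3(x)
        self._prepool = x  # higher-resolution maps for CAM
        return self.pool3(x)

    def __call__(self, x: Tensor) -> Tensor:
        return global_avg_pool(self.feature_maps(x))


class FeatureExtractor:
    """Maps images in [0,1] to fixed-length feature vectors.

    One underlying network instance, so the same (shared) weights are
    applied at every time point.
    """

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        if spec.name == "inception_v3":
            self.net = InceptionV3(rng, weight_scale=0.5)
            if spec.pretrained:
                if spec.weights_path is None:
                    raise ConfigError(
                        "pretrained=True requires weights_path pointing to an "
                        ".npz checkpoint on disk (no download is attempted)")
                self.net.load(spec.weights_path)
        else:
            self.net = TinyCNN(spec.feature_len, rng)
            if spec.pretrained and spec.weights_path:
                self.net.load(spec.weights_path)

    @property
    def feature_len(self) -> int:
        return self.spec.feature_len

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """(side, side, 3) or (B, side, side, 3) -> (F,) or (B, F)."""
        arr = np.asarray(images, dtype=np.float32)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        out = self.net(Tensor(arr)).data
        return out[0] if single else out


def build_feature_extractor(spec: BackboneSpec) -> FeatureExtractor:
    """Construct the shared-weight image-to-vector extractor."""
    return FeatureExtractor(spec)


class PrognosticModel(Module):
    """(T images, T times, prediction time) -> probability of progression.

    ``T`` is fixed at build time, but the weights are independent of T
    (one shared extractor plus one recurrent cell), so the same state can
    be loaded into a rebuild with a different T.
    """

    def __init__(self, T: int, spec: BackboneSpec, use_interval_scaling: bool = True,
                 gru_hidden: int = 1, cam_dense: int = 0, seed: int = 0):
        if T < 1:
            raise ConfigError("T must be >= 1")
        self.T = T
        self.spec = spec
        self.use_interval_scaling = use_interval_scaling
        rng = np.random.default_rng(seed)
        self.extractor = FeatureExtractor(
            BackboneSpec(**{**spec.__dict__, "seed": seed}))
        self.backbone = self.extractor.net  # registers shared weights
        F = spec.feature_len
        self.gru = GRU(F, gru_hidden, rng)
        self.head = Dense(gru_hidden, 1, rng) if cam_dense else None
        self.gru_hidden = gru_hidden

    # -- forward -------------------------------------------------------
    def _visit_weights(self, times: np.ndarray, prediction_time: np.ndarray
                       ) -> np.ndarray:
        """(B, T) interval weights, or ones when scaling is off."""
        B = times.shape[0]
        if not self.use_interval_scaling:
            return np.ones((B, self.T), dtype=np.float32)
        w = np.empty((B, self.T), dtype=np.float32)
        for i in range(B):
            w[i] = interval_weights(times[i], float(prediction_time[i])).weights
        return w

    def logits(self, images: np.ndarray, times: np.ndarray,
               prediction_time: np.ndarray, keep_maps: bool = False):
        """Forward pass on a batch.

        images: (B, T, side, side, 3); times: (B, T); prediction_time: (B,).
        Returns the logit tensor; with ``keep_maps`` also the list of
        per-visit spatial feature-map tensors (for CAM / Grad-CAM).
        """
        images = np.asarray(images, dtype=np.float32)
        times = np.atleast_2d(np.asarray(times, dtype=float))
        prediction_time = np.atleast_1d(np.asarray(prediction_time, dtype=float))
        if images.ndim != 5 or images.shape[1] != self.T or times.shape[1] != self.T:
            raise ValueError(
                f"expected images (B, {self.T}, side, side, 3) and times "
                f"(B, {self.T}); got {images.shape} and {times.shape}")
        w = self._visit_weights(times, prediction_time)
        steps, maps = [], []
        for t in range(self.T):
            x = Tensor(images[:, t])
            fmap = self.backbone.feature_maps(x)
            feats = global_avg_pool(fmap)
            steps.append(feats * Tensor(w[:, t:t + 1]))
            if keep_maps:
                maps.append(getattr(self.backbone, "_prepool", fmap))
        h = self.gru(steps)
        z = self.head(h) if self.head is not None else h
        if z.shape[1] != 1:
            raise ValueError("head must emit a single logit")
        out = z.reshape(-1)
        return (out, maps, w) if keep_maps else out

    def predict_proba(self, images, times, prediction_time) -> np.ndarray:
        """Probabilities in the open interval (0, 1)."""
        z = self.logits(images, times, prediction_time)
        return sigmoid(z).data

    # -- CAM support ----------------------------------------------------
    @property
    def has_cam_head(self) -> bool:
        return self.head is not None

    def effective_class_weights(self) -> np.ndarray:
        """Linear path from pooled features to the positive logit.

        Composes the GRU candidate-gate input weights with the dense
        head (identity for the plain single-unit model); shape (F,).
        """
        w = self.gru.candidate_input_weights  # (F, hidden)
        if self.head is not None:
            w = w @ self.head.w.data  # (F, 1)
        return w[:, 0] if w.ndim == 2 else w

    def rebuild(self, T: int) -> "PrognosticModel":
        """Same weights, different sequence length."""
        m = PrognosticModel(T, self.spec, self.use_interval_scaling,
                            gru_hidden=self.gru_hidden,
                            cam_dense=1 if self.head is not None else 0)
        m.set_state(self.get_state())
        return m


def build_prognostic_model(T: int, spec: BackboneSpec,
                           use_interval_scaling: bool = True,
                           seed: int = 0) -> PrognosticModel:
    """The main model: shared CNN -> interval scaling -> GRU(1) -> sigmoid."""
    return PrognosticModel(T, spec, use_interval_scaling,
                           gru_hidden=1, cam_dense=0, seed=seed)


def build_cam_model(T: int, spec: BackboneSpec,
                    use_interval_scaling: bool = True,
                    gru_hidden: int = 8, seed: int = 0) -> PrognosticModel:
    """CAM-capable variant: wider GRU with a dense layer after it."""
    return PrognosticModel(T, spec, use_interval_scaling,
                           gru_hidden=gru_hidden, cam_dense=1, seed=seed)
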