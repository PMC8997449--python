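"""Multimodal image + metadata fusion classifier.

The image branch is a small CNN (valid-region correlations with an
additive per-filter offset, ReLU, 2x2 max-pooling); the metadata branch
is a stack of linear layers with ReLU; the concatenation layer combines
the flattened feature map and the metadata features through a joint
linear map; a softmax head produces the class distribution.

Everything is plain numpy with handwritten gradients: the model is
desk-scale by design (tens of samples, 32x32 inputs) and deterministic
for a fixed seed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from dermokit.augmentation import resize_for_backbone
from dermokit.labels import CLASS_NAMES
from dermokit.metadata import CategoryCodebook, encode_record
from dermokit.synthetic import SyntheticSample

__all__ = [
    "ConvFilter",
    "FusionLayer",
    "SoftmaxHead",
    "ModelConfig",
    "FusionModel",
    "conv2d",
    "fuse",
    "softmax_classify",
    "build_model",
    "train",
    "predict",
    "prepare_arrays",
]


# ---------------------------------------------------------------------------
# standalone primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvFilter:
    """A single w x w x D correlation filter with additive offset."""

    weights: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 3 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be w x w x D, got shape {w.shape}")
        if w.shape[0] % 2 != 1:
            raise ValueError(f"filter size must be odd, got {w.shape[0]}")


def conv2d(plane_stack: np.ndarray, filt: ConvFilter) -> np.ndarray:
    """Valid-region correlation with a symmetric index window:

        out(x, y) = g + sum_{i,j,k} w[i,j,k] * P(x+i, y+j, k)

    with i, j running over -(w-1)/2 .. (w-1)/2. Output shape is
    (H-w+1, W-w+1)."""
    P = np.asarray(plane_stack, dtype=np.float64)
    if P.ndim != 3:
        raise ValueError(f"plane stack must be H x W x D, got shape {P.shape}")
    w = filt.weights.shape[0]
    H, W, D = P.shape
    if w > min(H, W):
        raise ValueError(f"filter size {w} exceeds image size {(H, W)}")
    if filt.weights.shape[2] != D:
        raise ValueError(f"filter depth {filt.weights.shape[2]} != image depth {D}")
    windows = np.lib.stride_tricks.sliding_window_view(P, (w, w), axis=(0, 1))
    # windows: (H', W', D, w, w); weights indexed [i+h, j+h, k] with h=(w-1)/2
    out = np.einsum("xykij,ijk->xy", windows, np.asarray(filt.weights, dtype=np.float64))
    return out + filt.offset


@dataclass(frozen=True)
class FusionLayer:
    """Joint linear map over a feature map and a metadata vector.

    image_weights: (R, C, K, L); metadata_weights: (n_meta, L)."""

    image_weights: np.ndarray
    metadata_weights: np.ndarray

    def __post_init__(self) -> None:
        iw, mw = np.asarray(self.image_weights), np.asarray(self.metadata_weights)
        if iw.ndim != 4:
            raise ValueError(f"image_weights must be R x C x K x L, got shape {iw.shape}")
        if mw.ndim != 2:
            raise ValueError(f"metadata_weights must be n_meta x L, got shape {mw.shape}")
        if iw.shape[3] != mw.shape[1]:
            raise ValueError("output dimensions of the two weight sets disagree")


def fuse(feature_map: np.ndarray, metadata: np.ndarray, layer: FusionLayer) -> np.ndarray:
    """f_l = sum_{i,j,k} x_ijk w2_ijkl + sum_i m_i w3_il — equivalent to
    flatten, concatenate and apply one linear map."""
    x = np.asarray(feature_map, dtype=np.float64)
    m = np.asarray(metadata, dtype=np.float64)
    if x.shape != layer.image_weights.shape[:3]:
        raise ValueError(
            f"feature map shape {x.shape} != weight shape {layer.image_weights.shape[:3]}"
        )
    if m.shape != (layer.metadata_weights.shape[0],):
        raise ValueError(
            f"metadata shape {m.shape} != weight rows {layer.metadata_weights.shape[0]}"
        )
    return np.einsum("ijk,ijkl->l", x, layer.image_weights) + m @ layer.metadata_weights


@dataclass(frozen=True)
class SoftmaxHead:
    """Per-class affine scores mapped through a stabilized softmax."""

    class_weights: np.ndarray  # (n_in, n_classes)
    offsets: np.ndarray  # (n_classes,)

    def __post_init__(self) -> None:
        cw, b = np.asarray(self.class_weights), np.asarray(self.offsets)
        if cw.ndim != 2 or b.shape != (cw.shape[1],):
            raise ValueError("class_weights must be (n_in, n_classes) with matching offsets")

    @property
    def n_classes(self) -> int:
        return self.class_weights.shape[1]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def softmax_classify(features: np.ndarray, head: SoftmaxHead) -> np.ndarray:
    """Probability vector over classes; log-sum-exp stabilized."""
    features = np.asarray(features, dtype=np.float64)
    logits = features @ head.class_weights + head.offsets
    return _softmax(logits)


# ---------------------------------------------------------------------------
# the trainable model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the fusion classifier and its optimizer."""

    backbone: str = "small_cnn"
    input_size: Tuple[int, int] = (32, 32)
    conv_channels: Tuple[int, ...] = (8, 16)
    kernel_size: int = 3
    metadata_dim: int = 28
    metadata_branch: Tuple[int, ...] = (32, 32)
    fusion_units: int = 64
    n_classes: int = 10
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone != "small_cnn":
            raise ValueError(
                f"unknown backbone {self.backbone!r}; this build provides 'small_cnn' "
                "(pretrained architectures are out of scope)"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if min(self.input_size) < 4 * self.kernel_size:
            raise ValueError(f"input size {self.input_size} too small for the backbone")


def _he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class FusionModel:
    """Small-CNN image branch + linear metadata branch + fusion + softmax.

    Parameters live in ``self.params`` (name -> float64 array); forward
    and backward passes are handwritten numpy.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        p: Dict[str, np.ndarray] = {}
        k = config.kernel_size
        depth = 3
        for li, ch in enumerate(config.conv_channels):
            fan_in = k * k * depth
            p[f"conv{li}_w"] = _he_init(rng, (k, k, depth, ch), fan_in)
            p[f"conv{li}_b"] = np.zeros(ch)
            depth = ch
        feat_shape = self.feature_map_shape()
        n_img = int(np.prod(feat_shape))
        dim = config.metadata_dim
        for li, width in enumerate(config.metadata_branch):
            p[f"meta{li}_w"] = _he_init(rng, (dim, width), dim)
            p[f"meta{li}_b"] = np.zeros(width)
            dim = width
        p["fuse_w2"] = _he_init(rng, (n_img, config.fusion_units), n_img + dim)
        p["fuse_w3"] = _he_init(rng, (dim, config.fusion_units), n_img + dim)
        p["fuse_b"] = np.zeros(config.fusion_units)
        p["head_w"] = _he_init(rng, (config.fusion_units, config.n_classes), config.fusion_units)
        p["head_b"] = np.zeros(config.n_classes)
        self.params = p
        self._velocity = {k_: np.zeros_like(v) for k_, v in p.items()}

    # -- architecture bookkeeping ------------------------------------------

    def feature_map_shape(self) -> Tuple[int, int, int]:
        """Shape (R, C, K) of the image-branch output feature map."""
        H, W = self.config.input_size
        k = self.config.kernel_size
        for _ in self.config.conv_channels:
            H, W = (H - k + 1) // 2, (W - k + 1) // 2
        return (H, W, self.config.conv_channels[-1])

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- layer forward/backward --------------------------------------------

    @staticmethod
    def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
        # X: (N, H, W, D); W: (k, k, D, C)
        k = W.shape[0]
        windows = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(1, 2))
        # windows: (N, H', W', D, k, k)
        out = np.einsum("nxydij,ijdc->nxyc", windows, W) + b
        return out, (X.shape, windows, W)

    @staticmethod
    def _conv_backward(dout: np.ndarray, cache):
        X_shape, windows, W = cache
        k = W.shape[0]
        dW = np.einsum("nxydij,nxyc->ijdc", windows, dout)
        db = dout.sum(axis=(0, 1, 2))
        dX = np.zeros(X_shape)
        N, Hp, Wp, C = dout.shape
        for i in range(k):
            for j in range(k):
                # contribution of filter tap (i, j) to input gradient
                dX[:, i : i + Hp, j : j + Wp, :] += np.einsum(
                    "nxyc,dc->nxyd", dout, W[i, j]
                )
        return dX, dW, db

    @staticmethod
    def _pool_forward(X: np.ndarray):
        N, H, W, C = X.shape
        H2, W2 = H // 2, W // 2
        Xc = X[:, : 2 * H2, : 2 * W2, :]
        blocks = Xc.reshape(N, H2, 2, W2, 2, C)
        out = blocks.max(axis=(2, 4))
        return out, (X.shape, Xc, blocks, out)

    @staticmethod
    def _pool_backward(dout: np.ndarray, cache):
        X_shape, Xc, blocks, out = cache
        N, H2, _, W2, _, C = blocks.shape
        winners = blocks == out[:, :, None, :, None, :]
        # split gradient evenly among tied maxima to keep the map linear
        counts = winners.sum(axis=(2, 4), keepdims=True)
        grad = winners * (dout[:, :, None, :, None, :] / counts)
        dXc = grad.reshape(Xc.shape)
        dX = np.zeros(X_shape)
        dX[:, : Xc.shape[1], : Xc.shape[2], :] = dXc
        return dX

    # -- full network -------------------------------------------------------

    def forward(self, images: np.ndarray, metas: np.ndarray):
        """Probabilities (N, n_classes) plus the cache for backward."""
        p = self.params
        cache: Dict[str, object] = {}
        X = np.asarray(images, dtype=np.float64)
        for li in range(len(self.config.conv_channels)):
            Z, cv = self._conv_forward(X, p[f"conv{li}_w"], p[f"conv{li}_b"])
            A = np.maximum(Z, 0.0)
            P_, pc = self._pool_forward(A)
            cache[f"conv{li}"] = (cv, Z, pc)
            X = P_
        N = X.shape[0]
        feat = X.reshape(N, -1)
        cache["feat_shape"] = X.shape

        M = np.asarray(metas, dtype=np.float64)
        meta_acts: List[np.ndarray] = [M]
        for li in range(len(self.config.metadata_branch)):
            Zm = meta_acts[-1] @ p[f"meta{li}_w"] + p[f"meta{li}_b"]
            meta_acts.append(np.maximum(Zm, 0.0))
            cache[f"meta{li}_z"] = Zm
        cache["meta_acts"] = meta_acts

        F = feat @ p["fuse_w2"] + meta_acts[-1] @ p["fuse_w3"] + p["fuse_b"]
        G = np.maximum(F, 0.0)
        cache["fuse"] = (feat, F, G)
        logits = G @ p["head_w"] + p["head_b"]
        probs = _softmax(logits)
        cache["probs"] = probs
        return probs, cache

    def backward(self, cache, labels: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        p = self.params
        probs = cache["probs"]
        N = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(N), labels] -= 1.0
        dlogits /= N
        grads: Dict[str, np.ndarray] = {}
        feat, F, G = cache["fuse"]
        grads["head_w"] = G.T @ dlogits
        grads["head_b"] = dlogits.sum(axis=0)
        dG = dlogits @ p["head_w"].T
        dF = dG * (F > 0)
        grads["fuse_w2"] = feat.T @ dF
        grads["fuse_w3"] = cache["meta_acts"][-1].T @ dF
        grads["fuse_b"] = dF.sum(axis=0)

        dmeta = dF @ p["fuse_w3"].T
        for li in reversed(range(len(self.config.metadata_branch))):
            Zm = cache[f"meta{li}_z"]
            dZm = dmeta * (Zm > 0)
            grads[f"meta{li}_w"] = cache["meta_acts"][li].T @ dZm
            grads[f"meta{li}_b"] = dZm.sum(axis=0)
            dmeta = dZm @ p[f"meta{li}_w"].T

        dfeat = (dF @ p["fuse_w2"].T).reshape(cache["feat_shape"])
        dX = dfeat
        for li in reversed(range(len(self.config.conv_channels))):
            cv, Z, pc = cache[f"conv{li}"]
            dA = self._pool_backward(dX, pc)
            dZ = dA * (Z > 0)
            dX, dW, db = self._conv_backward(dZ, cv)
            grads[f"conv{li}_w"] = dW
            grads[f"conv{li}_b"] = db
        return grads

    def sgd_step(self, grads: Dict[str, np.ndarray]) -> None:
        lr, mu = self.config.learning_rate, self.config.momentum
        for name, g in grads.items():
            v = self._velocity[name]
            v *= mu
            v -= lr * g
            self.params[name] += v

    # -- persistence --------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "params": self.params}, fh)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FusionModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"])
        model.params = blob["params"]
        model._velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
        return model


def build_model(config: Optional[ModelConfig] = None) -> FusionModel:
    """Seeded construction of the fusion classifier."""
    return FusionModel(config or ModelConfig())


# ---------------------------------------------------------------------------
# data preparation, training, prediction
# ---------------------------------------------------------------------------


def prepare_arrays(
    samples: Sequence[SyntheticSample],
    input_size: Tuple[int, int] = (32, 32),
    codebook: Optional[CategoryCodebook] = None,
    class_names: Sequence[str] = CLASS_NAMES,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Samples -> (images in [0,1] (N,H,W,3), metadata (N,28), labels (N,))."""
    cb = codebook or CategoryCodebook()
    imgs, metas, labels = [], [], []
    names = list(class_names)
    for s in samples:
        img = s.image
        if img.shape[:2] != tuple(input_size):
            img = resize_for_backbone(img, input_size)
        imgs.append(img.astype(np.float64) / 255.0)
        metas.append(encode_record(s.metadata, cb).astype(np.float64))
        labels.append(names.index(s.label))
    return np.stack(imgs), np.stack(metas), np.asarray(labels, dtype=np.int64)


def _cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def train(
    model: FusionModel,
    train_set: Tuple[np.ndarray, np.ndarray, np.ndarray],
    val_set: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    config: Optional[ModelConfig] = None,
) -> Tuple[FusionModel, Dict[str, List[float]]]:
    """Minibatch SGD-with-momentum on mean cross-entropy.

    ``train_set``/``val_set`` are (images, metadata, labels) triples from
    :func:`prepare_arrays`. Deterministic for a fixed config seed.
    Raises on divergence (non-finite loss).
    """
    cfg = config or model.config
    Xtr, Mtr, ytr = train_set
    if len(Xtr) == 0:
        raise ValueError("empty training set")
    history: Dict[str, List[float]] = {
        "train_loss": [],
        "train_accuracy": [],
        "val_loss": [],
        "val_accuracy": [],
    }
    rng = np.random.default_rng(cfg.seed)
    n = len(Xtr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, cache = model.forward(Xtr[idx], Mtr[idx])
            loss = _cross_entropy(probs, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            grads = model.backward(cache, ytr[idx])
            model.sgd_step(grads)
        probs, _ = model.forward(Xtr, Mtr)
        history["train_loss"].append(_cross_entropy(probs, ytr))
        history["train_accuracy"].append(float(np.mean(np.argmax(probs, axis=1) == ytr)))
        if val_set is not None and len(val_set[0]) > 0:
            Xv, Mv, yv = val_set
            pv, _ = model.forward(Xv, Mv)
            history["val_loss"].append(_cross_entropy(pv, yv))
            history["val_accuracy"].append(float(np.mean(np.argmax(pv, axis=1) == yv)))
    return model, history


def predict(
    model: FusionModel, images: np.ndarray, metas: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample probability rows and argmax labels (lowest index wins ties)."""
    probs, _ = model.forward(images, metas)
    return probs, np.argmax(probs, axis=1)
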