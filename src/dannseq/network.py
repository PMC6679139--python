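"""The domain-adversarial convolutional network, in plain NumPy.

Three components share one feature extractor:

* feature extractor Gf: conv -> ReLU -> maxpool -> conv -> ReLU -> maxpool,
  flattened (valid padding; with the default config the length chain is
  101 -> 97 -> 47 -> 43 -> 20, giving 20 x n_kernels_2 features);
* label predictor Gl: dropout -> FC -> ReLU -> FC -> softmax over
  (TFBS, non-TFBS);
* domain classifier Gd: gradient-reversal layer -> FC -> ReLU -> FC ->
  softmax over (target, source).

The gradient-reversal layer (GRL) is the identity in the forward pass and
multiplies the backward gradient by -lambda, where lambda follows the
logistic ramp ``2 / (1 + exp(-gamma * p)) - 1`` in training progress p.
Every layer implements an explicit backward pass; the composite gradients
are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sequences import SEQ_LEN

N_CLASSES = 2  # (TFBS, non-TFBS) and (target, source)


@dataclass
class DannConfig:
    """Architecture and optimisation hyperparameters.

    Defaults follow the published setting: two convolution layers with 32 and
    48 kernels of size 5 (stride 1), max pooling of size 5 (stride 2), one
    dropout layer (drop rate 0.7) before the first fully connected layer of
    the label predictor, hidden width 100, domain-adaptation weight alpha = 1,
    SGD with momentum 0.9, learning rate 0.001, batch size 128.
    """

    n_kernels_1: int = 32
    n_kernels_2: int = 48
    kernel_size: int = 5
    pool_size: int = 5
    conv_stride: int = 1
    pool_stride: int = 2
    dropout_rate: float = 0.7
    fc_width: int = 100
    alpha: float = 1.0
    grl_gamma: float = 10.0
    batch_size: int = 128
    momentum: float = 0.9
    learning_rate: float = 0.001
    max_epochs: int = 60
    patience: int = 5
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        for name in ("n_kernels_1", "n_kernels_2", "kernel_size", "pool_size", "conv_stride",
                     "pool_stride", "fc_width", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"dtype must be float32 or float64, got {self.dtype}")
        if self.conv_stride != 1:
            raise ValueError("only conv_stride=1 is supported")

    @property
    def np_dtype(self):
        return np.float64 if self.dtype == "float64" else np.float32

    def _chain(self) -> list[int]:
        def conv_out(L):  # valid padding
            return (L - self.kernel_size) // self.conv_stride + 1

        def pool_out(L):
            return (L - self.pool_size) // self.pool_stride + 1

        L1 = conv_out(SEQ_LEN)
        L2 = pool_out(L1)
        L3 = conv_out(L2)
        L4 = pool_out(L3)
        if min(L1, L2, L3, L4) <= 0:
            raise ValueError("kernel/pool sizes too large for the 101-bp input")
        return [SEQ_LEN, L1, L2, L3, L4]

    @property
    def feature_width(self) -> int:
        """Flattened feature-extractor output width (pure function of config)."""
        return self._chain()[-1] * self.n_kernels_2


def lambda_schedule(p: float, gamma: float = 10.0) -> float:
    """Adversarial-strength ramp lambda(p) = 2 / (1 + exp(-gamma p)) - 1.

    p is the fraction of training completed, in [0, 1]; lambda(0) = 0 and
    lambda is strictly increasing.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"training progress p must lie in [0, 1], got {p}")
    return 2.0 / (1.0 + math.exp(-gamma * p)) - 1.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: parameter keys by component (feature extractor / label predictor / domain classifier)
THETA_F = ("conv1_W", "conv1_b", "conv2_W", "conv2_b")
THETA_L = ("lp1_W", "lp1_b", "lp2_W", "lp2_b")
THETA_D = ("dc1_W", "dc1_b", "dc2_W", "dc2_b")


def param_shapes(config: DannConfig) -> dict[str, tuple]:
    F = config.feature_width
    H = config.fc_width
    return {
        "conv1_W": (config.n_kernels_1, 4, config.kernel_size),
        "conv1_b": (config.n_kernels_1,),
        "conv2_W": (config.n_kernels_2, config.n_kernels_1, config.kernel_size),
        "conv2_b": (config.n_kernels_2,),
        "lp1_W": (F, H),
        "lp1_b": (H,),
        "lp2_W": (H, N_CLASSES),
        "lp2_b": (N_CLASSES,),
        "dc1_W": (F, H),
        "dc1_b": (H,),
        "dc2_W": (H, N_CLASSES),
        "dc2_b": (N_CLASSES,),
    }


def init_params(config: DannConfig, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """He (fan-in scaled) normal weights, zero biases.

    Weights are drawn in a fixed order (feature extractor, label predictor,
    domain classifier) so that models with and without a domain classifier
    share identical Gf/Gl initialisations for the same seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dtype = config.np_dtype
    params: dict[str, np.ndarray] = {}
    for key, shape in param_shapes(config).items():
        if key.endswith("_b"):
            params[key] = np.zeros(shape, dtype=dtype)
        else:
            # conv W: (K, C, M) -> fan_in = C*M; FC W: (in, out) -> fan_in = in
            fan_in = int(np.prod(shape[1:])) if key.startswith("conv") else shape[0]
            std = math.sqrt(2.0 / fan_in)
            params[key] = (rng.standard_normal(shape) * std).astype(dtype)
    return params


def check_param_shapes(params: Mapping[str, np.ndarray], config: DannConfig) -> None:
    expected = param_shapes(config)
    for key, shape in expected.items():
        if key not in params:
            raise ValueError(f"missing parameter {key!r} (expected shape {shape})")
        if tuple(params[key].shape) != shape:
            raise ValueError(
                f"parameter {key!r}: expected shape {shape}, observed {tuple(params[key].shape)}"
            )


# ---------------------------------------------------------------------------
# layers (forward + backward)
# ---------------------------------------------------------------------------

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D cross-correlation: x (B,C,L), W (K,C,M) -> y (B,K,L-M+1)."""
    if x.shape[1] != W.shape[1]:
        raise ValueError(f"conv input channels: expected {W.shape[1]}, observed {x.shape[1]}")
    win = sliding_window_view(x, W.shape[2], axis=2)  # (B, C, Lout, M)
    y = np.einsum("bcim,kcm->bki", win, W, optimize=True) + b[None, :, None]
    return y, win


def conv1d_backward(dy: np.ndarray, win: np.ndarray, W: np.ndarray, x_shape: tuple):
    dW = np.einsum("bki,bcim->kcm", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.zeros(x_shape, dtype=dy.dtype)
    L_out = dy.shape[2]
    for m in range(W.shape[2]):
        dx[:, :, m:m + L_out] += np.einsum("bki,kc->bci", dy, W[:, :, m], optimize=True)
    return dx, dW, db


def maxpool_forward(x: np.ndarray, size: int, stride: int):
    """Max pooling along the last axis; returns output and argmax indices."""
    win = sliding_window_view(x, size, axis=2)[:, :, ::stride]  # (B, K, nout, size)
    win = np.ascontiguousarray(win)  # argmax over a strided view is slow
    idx = win.argmax(axis=3)
    y = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
    return y, idx


def maxpool_backward(dy: np.ndarray, idx: np.ndarray, size: int, stride: int, x_shape: tuple):
    dx = np.zeros(x_shape, dtype=dy.dtype)
    B, K, nout = dy.shape
    pos = np.arange(nout)[None, None, :] * stride + idx  # absolute positions
    bi = np.arange(B)[:, None, None]
    ki = np.arange(K)[None, :, None]
    np.add.at(dx, (bi, ki, pos), dy)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def grad_reverse(z: np.ndarray, lam: float) -> np.ndarray:
    """Gradient-reversal layer, forward pass: the identity (bit-exact)."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return z


def grad_reverse_backward(grad: np.ndarray, lam: float) -> np.ndarray:
    """GRL backward pass: multiply the downstream gradient by -lambda."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return -lam * grad


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def features_forward(params: Mapping[str, np.ndarray], config: DannConfig, x: np.ndarray,
                     want_cache: bool = True):
    """Gf: conv -> ReLU -> pool -> conv -> ReLU -> pool, flattened."""
    if x.ndim != 3 or x.shape[1:] != (4, SEQ_LEN):
        raise ValueError(f"expected input batch shaped (B, 4, {SEQ_LEN}), observed {x.shape}")
    y1, win1 = conv1d_forward(x, params["conv1_W"], params["conv1_b"])
    a1 = np.maximum(y1, 0)
    p1, idx1 = maxpool_forward(a1, config.pool_size, config.pool_stride)
    y2, win2 = conv1d_forward(p1, params["conv2_W"], params["conv2_b"])
    a2 = np.maximum(y2, 0)
    p2, idx2 = maxpool_forward(a2, config.pool_size, config.pool_stride)
    z = p2.reshape(p2.shape[0], -1)
    cache = (x.shape, win1, y1, idx1, a1.shape, p1.shape, win2, y2, idx2, a2.shape, p2.shape) if want_cache else None
    return z, cache


def features_backward(params, config: DannConfig, cache, dz: np.ndarray) -> dict[str, np.ndarray]:
    x_shape, win1, y1, idx1, a1_shape, p1_shape, win2, y2, idx2, a2_shape, p2_shape = cache
    dp2 = dz.reshape(p2_shape)
    da2 = maxpool_backward(dp2, idx2, config.pool_size, config.pool_stride, a2_shape)
    dy2 = da2 * (y2 > 0)
    dp1, dW2, db2 = conv1d_backward(dy2, win2, params["conv2_W"], p1_shape)
    da1 = maxpool_backward(dp1, idx1, config.pool_size, config.pool_stride, a1_shape)
    dy1 = da1 * (y1 > 0)
    _, dW1, db1 = conv1d_backward(dy1, win1, params["conv1_W"], x_shape)
    return {"conv1_W": dW1, "conv1_b": db1, "conv2_W": dW2, "conv2_b": db2}


def _head_forward(z, W1, b1, W2, b2, drop_mask=None, keep_prob=1.0):
    """FC -> ReLU -> FC -> softmax; optional inverted dropout on the input."""
    if z.shape[1] != W1.shape[0]:
        raise ValueError(f"feature width: expected {W1.shape[0]}, observed {z.shape[1]}")
    zd = z if drop_mask is None else z * drop_mask / keep_prob
    h = zd @ W1 + b1
    a = np.maximum(h, 0)
    logits = a @ W2 + b2
    probs = softmax(logits)
    cache = (zd, h, a, probs)
    return probs, cache


def _head_backward(dlogits, cache, W1, W2, drop_mask=None, keep_prob=1.0):
    zd, h, a, _ = cache
    dW2 = a.T @ dlogits
    db2 = dlogits.sum(axis=0)
    da = dlogits @ W2.T
    dh = da * (h > 0)
    dW1 = zd.T @ dh
    db1 = dh.sum(axis=0)
    dz = dh @ W1.T
    if drop_mask is not None:
        dz = dz * drop_mask / keep_prob
    return dz, dW1, db1, dW2, db2


def feature_extractor(x: np.ndarray, params, config: DannConfig, training: bool = False) -> np.ndarray:
    """Public Gf; the training flag is accepted for interface symmetry (the
    feature extractor itself has no stochastic layers)."""
    z, _ = features_forward(params, config, x, want_cache=False)
    return z


def label_predictor(z: np.ndarray, params, config: DannConfig, training: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Gl: per-item probability pair (TFBS, non-TFBS).

    Dropout on the input features is active only when training=True (an rng
    must then be supplied).
    """
    drop_mask, keep = None, 1.0
    if training and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("training=True requires an rng for dropout")
        keep = 1.0 - config.dropout_rate
        drop_mask = (rng.random(z.shape) < keep).astype(z.dtype)
    probs, _ = _head_forward(z, params["lp1_W"], params["lp1_b"], params["lp2_W"], params["lp2_b"],
                             drop_mask, keep)
    return probs


def domain_classifier(z: np.ndarray, params, config: DannConfig, lam: float) -> np.ndarray:
    """Gd: per-item probability pair (target, source).

    The forward pass routes z through the GRL (an identity); lam matters only
    for gradients.
    """
    z = grad_reverse(z, lam)
    probs, _ = _head_forward(z, params["dc1_W"], params["dc1_b"], params["dc2_W"], params["dc2_b"])
    return probs


def score(x: np.ndarray, params, config: DannConfig) -> np.ndarray:
    """Binding score f(T) = Gl(Gf(T)): TFBS-class probability, dropout off."""
    z = feature_extractor(x, params, config, training=False)
    return label_predictor(z, params, config, training=False)[:, 0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: Mapping[str, np.ndarray], config: DannConfig,
                    training_log: list[dict] | None = None) -> None:
    """Single-archive checkpoint: parameter tensors + config + training log."""
    meta = {"config": asdict(config), "training_log": training_log or []}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for key, arr in params.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"params/{key}.npy", buf.getvalue())


def load_checkpoint(path):
    """Load a checkpoint; fails loudly on config/shape mismatch."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        config = DannConfig(**meta["config"])
        params = {}
        for name in zf.namelist():
            if name.startswith("params/") and name.endswith(".npy"):
                key = name[len("params/"):-len(".npy")]
                params[key] = np.load(io.BytesIO(zf.read(name)))
    check_param_shapes(params, config)
    return params, config, meta["training_log"]
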