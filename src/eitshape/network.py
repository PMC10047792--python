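"""The implicit shape-classification architecture.

Three blocks map an EIT measurement vector and a continuous query point to
the probability that the point lies in an anomalous region:

* a *measure encoder* — six residual blocks taking the 208 normalised
  measurements to an embedding of dimension ``64 * scale``;
* a *point encoder* — two residual blocks taking a (normalised) point in
  R^d (d = 2 or 3) to an embedding of the same dimension;
* a *decoder* — two residual blocks applied to the elementwise sum of the
  two embeddings, producing two logits followed by a softmax.

Each residual block is Linear(in, out) -> LeakyReLU -> Linear(out, out),
plus a shortcut (identity when the sizes agree, a single linear map
otherwise), with a final LeakyReLU after the sum.  ``scale`` multiplies
every hidden width; the study's default is 2.

Everything is plain numpy (float64 parameters, float32 batch math) with
explicit forward/backward passes — the network is small enough that dense
matmuls on one CPU core suffice.  The forward pass is fully deterministic:
there is no dropout or batch normalisation anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantoms import NormalizationStats, apply_normalization, normalize_points

__all__ = [
    "NetworkConfig",
    "ModelParameters",
    "leaky_relu",
    "softmax2",
    "classify",
    "init_parameters",
    "parameter_count",
    "resnet_block",
    "measure_encoder",
    "point_encoder",
    "decode",
    "predict_points",
    "ImplicitNetwork",
    "save_model",
    "load_model",
]

LEAKY_SLOPE = 0.01


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; ``embedding_dim = 64 * scale``."""

    scale: int = 2
    point_dim: int = 2
    measurement_dim: int = 208
    leaky_slope: float = LEAKY_SLOPE

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be a positive integer")
        if self.point_dim not in (2, 3):
            raise ValueError("point_dim must be 2 or 3")

    @property
    def embedding_dim(self) -> int:
        return 64 * self.scale

    def block_dims(self) -> dict[str, list[tuple[int, int]]]:
        """(in, out) sizes of every residual block, per network part."""
        s = self.scale
        return {
            "measure": [
                (self.measurement_dim, 128 * s),
                (128 * s, 128 * s),
                (128 * s, 128 * s),
                (128 * s, 64 * s),
                (64 * s, 64 * s),
                (64 * s, 64 * s),
            ],
            "point": [(self.point_dim, 32 * s), (32 * s, 64 * s)],
            "decoder": [(64 * s, 32 * s), (32 * s, 2)],
        }


# -- primitives -----------------------------------------------------------


def leaky_relu(x: np.ndarray | float, slope: float = LEAKY_SLOPE):
    """Leaky rectified linear unit: ``slope * x`` for negative x, else x."""
    x = np.asarray(x)
    return np.where(x < 0, slope * x, x)


def softmax2(x) -> np.ndarray:
    """Numerically stable softmax over the last axis (two classes here)."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify(q: np.ndarray) -> np.ndarray:
    """0 (background) iff the background probability strictly exceeds the
    anomaly probability; ties count as anomaly."""
    q = np.asarray(q)
    return (~(q[..., 0] > q[..., 1])).astype(np.int64)


# -- parameters -----------------------------------------------------------

ModelParameters = dict  # name -> ndarray, shapes fixed by NetworkConfig


def _block_param_shapes(in_dim: int, out_dim: int) -> dict[str, tuple]:
    shapes = {
        "W1": (in_dim, out_dim),
        "b1": (out_dim,),
        "W2": (out_dim, out_dim),
        "b2": (out_dim,),
    }
    if in_dim != out_dim:
        shapes["Ws"] = (in_dim, out_dim)
        shapes["bs"] = (out_dim,)
    return shapes


def parameter_shapes(config: NetworkConfig) -> dict[str, tuple]:
    shapes: dict[str, tuple] = {}
    for part, dims in config.block_dims().items():
        for i, (din, dout) in enumerate(dims):
            for name, shp in _block_param_shapes(din, dout).items():
                shapes[f"{part}.{i}.{name}"] = shp
    return shapes


def parameter_count(config: NetworkConfig) -> int:
    """Total number of scalar parameters — a closed function of the config."""
    return sum(int(np.prod(s)) for s in parameter_shapes(config).values())


def init_parameters(config: NetworkConfig, rng: np.random.Generator) -> ModelParameters:
    """Uniform fan-in initialisation ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``."""
    params: ModelParameters = {}
    for name, shape in parameter_shapes(config).items():
        fan_in = shape[0] if len(shape) == 2 else max(shape[0], 1)
        if name.endswith(("b1", "b2", "bs")):
            params[name] = np.zeros(shape)
        else:
            a = 1.0 / np.sqrt(fan_in)
            params[name] = rng.uniform(-a, a, size=shape)
    return params


def zero_parameters(config: NetworkConfig) -> ModelParameters:
    return {n: np.zeros(s) for n, s in parameter_shapes(config).items()}


# -- forward / backward ---------------------------------------------------


def _block_forward(x, params, prefix, slope, cache=None):
    W1, b1 = params[f"{prefix}.W1"], params[f"{prefix}.b1"]
    W2, b2 = params[f"{prefix}.W2"], params[f"{prefix}.b2"]
    a1 = x @ W1 + b1
    # slope factor arrays double as activation (y = pre * f) and as the
    # exact local derivative reused by the backward pass
    f1 = np.where(a1 < 0, x.dtype.type(slope), x.dtype.type(1.0))
    h1 = a1 * f1
    a2 = h1 @ W2 + b2
    if f"{prefix}.Ws" in params:
        s = x @ params[f"{prefix}.Ws"] + params[f"{prefix}.bs"]
    else:
        s = x
    pre = a2 + s
    f2 = np.where(pre < 0, x.dtype.type(slope), x.dtype.type(1.0))
    y = pre * f2
    if cache is not None:
        cache[prefix] = (x, h1, f1, f2)
    return y


def _block_backward(dy, params, grads, prefix, slope, cache):
    x, h1, f1, f2 = cache[prefix]
    dpre = dy * f2
    # branch: a2 = h1 @ W2 + b2
    grads[f"{prefix}.W2"] += h1.T @ dpre
    grads[f"{prefix}.b2"] += dpre.sum(axis=0)
    da1 = (dpre @ params[f"{prefix}.W2"].T) * f1
    grads[f"{prefix}.W1"] += x.T @ da1
    grads[f"{prefix}.b1"] += da1.sum(axis=0)
    dx = da1 @ params[f"{prefix}.W1"].T
    # shortcut
    if f"{prefix}.Ws" in params:
        grads[f"{prefix}.Ws"] += x.T @ dpre
        grads[f"{prefix}.bs"] += dpre.sum(axis=0)
        dx += dpre @ params[f"{prefix}.Ws"].T
    else:
        dx += dpre
    return dx


def resnet_block(
    x: np.ndarray,
    in_dim: int,
    out_dim: int,
    params: ModelParameters,
    prefix: str = "block",
    slope: float = LEAKY_SLOPE,
) -> np.ndarray:
    """Standalone residual block (used directly in tests and docs)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != in_dim:
        raise ValueError(f"input dim {x.shape[1]} != declared {in_dim}")
    if params[f"{prefix}.W1"].shape != (in_dim, out_dim):
        raise ValueError("parameter shapes inconsistent with declared dims")
    return _block_forward(x, params, prefix, slope)


def _part_forward(x, params, config, part, cache=None):
    slope = config.leaky_slope
    for i, _ in enumerate(config.block_dims()[part]):
        x = _block_forward(x, params, f"{part}.{i}", slope, cache)
    return x


def _part_backward(dy, params, grads, config, part, cache):
    slope = config.leaky_slope
    for i in reversed(range(len(config.block_dims()[part]))):
        dy = _block_backward(dy, params, grads, f"{part}.{i}", slope, cache)
    return dy


def measure_encoder(
    m_normalized: np.ndarray, params: ModelParameters, config: NetworkConfig
) -> np.ndarray:
    """Encode normalised measurement vectors; output dim ``64 * scale``."""
    m = np.atleast_2d(np.asarray(m_normalized, dtype=np.float64))
    if m.shape[1] != config.measurement_dim:
        raise ValueError(
            f"measurement length {m.shape[1]} != {config.measurement_dim}"
        )
    return _part_forward(m, params, config, "measure")


def point_encoder(
    p_normalized: np.ndarray, params: ModelParameters, config: NetworkConfig
) -> np.ndarray:
    """Encode normalised points; output dim ``64 * scale``."""
    p = np.atleast_2d(np.asarray(p_normalized, dtype=np.float64))
    if p.shape[1] != config.point_dim:
        raise ValueError(f"point dim {p.shape[1]} != {config.point_dim}")
    return _part_forward(p, params, config, "point")


def decode(
    pe: np.ndarray, me: np.ndarray, params: ModelParameters, config: NetworkConfig
) -> np.ndarray:
    """Decode the summed embeddings to (background, anomaly) probabilities."""
    pe = np.atleast_2d(np.asarray(pe, dtype=np.float64))
    me = np.atleast_2d(np.asarray(me, dtype=np.float64))
    if pe.shape[-1] != config.embedding_dim or me.shape[-1] != config.embedding_dim:
        raise ValueError("embedding dimension mismatch")
    logits = _part_forward(pe + me, params, config, "decoder")
    return softmax2(logits)


# -- inference object -----------------------------------------------------


@dataclass
class ImplicitNetwork:
    """A trained (or freshly initialised) implicit classifier.

    Bundles parameters, architecture config and the normalisation statistics
    fitted on the training split, so one object answers shape queries for
    arbitrary measurement vectors and continuous points.
    """

    params: ModelParameters
    config: NetworkConfig
    stats: NormalizationStats

    def encode_measurement(self, m_values: np.ndarray) -> np.ndarray:
        mn = apply_normalization(np.asarray(m_values).reshape(1, -1), self.stats)
        return measure_encoder(mn, self.params, self.config)

    def predict_points(self, m_values: np.ndarray, points: np.ndarray):
        """Labels and probabilities at ``points`` for one measurement vector.

        The measure encoder runs once; its embedding is shared across all
        points, which changes cost but not values relative to a per-point
        evaluation.
        """
        me = self.encode_measurement(m_values)
        pts = normalize_points(np.atleast_2d(points), self.stats)
        pe = point_encoder(pts, self.params, self.config)
        q = decode(pe, np.broadcast_to(me, pe.shape), self.params, self.config)
        return classify(q), q


def predict_points(
    m_values: np.ndarray,
    points: np.ndarray,
    params: ModelParameters,
    stats: NormalizationStats,
    config: NetworkConfig,
):
    """Functional form of :meth:`ImplicitNetwork.predict_points`."""
    return ImplicitNetwork(params, config, stats).predict_points(m_values, points)


# -- serialization --------------------------------------------------------


def save_model(path: str | Path, net: ImplicitNetwork) -> None:
    """Single ``.npz`` container with an embedded JSON manifest, so a model
    file is self-describing (config + normalisation stats + shapes)."""
    manifest = {
        "config": {
            "scale": net.config.scale,
            "point_dim": net.config.point_dim,
            "measurement_dim": net.config.measurement_dim,
            "leaky_slope": net.config.leaky_slope,
        },
        "stats": net.stats.to_dict(),
        "shapes": {k: list(v.shape) for k, v in net.params.items()},
    }
    np.savez(
        path,
        __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
        **net.params,
    )


def load_model(path: str | Path) -> ImplicitNetwork:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        params = {k: data[k] for k in data.files if k != "__manifest__"}
    config = NetworkConfig(**manifest["config"])
    stats = NormalizationStats.from_dict(manifest["stats"])
    for k, shp in manifest["shapes"].items():
        if list(params[k].shape) != shp:
            raise ValueError(f"shape mismatch for {k}")
    return ImplicitNetwork(params=params, config=config, stats=stats)
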