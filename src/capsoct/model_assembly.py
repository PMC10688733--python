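"""Assembly of the CLAHE-CapsNet and the original-CapsNet baseline.

The flagship architecture interleaves parameter-free CLAHE enhancement layers
with a three-convolution feature stack, a convolutional primary-capsule layer
and a routed class-capsule layer, followed by a fully connected reconstruction
decoder:

    input 48x48x3
    -> Clahe1 (48x48x3, 0 params)
    -> Conv1 256 @ 5x5 stride 2, ReLU   -> 22x22x256
    -> Conv2 256 @ 3x3 stride 2, ReLU   -> 10x10x256
    -> Conv3 256 @ 1x1 stride 1, ReLU   -> 10x10x256
    -> Clahe2 (10x10x256, 0 params)
    -> PrimaryCaps: conv 36x8 @ 9x9 stride 3 (same) -> 4x4x36 = 576 capsules, 8-D
    -> ClassCaps: k capsules, 16-D, dynamic routing
    -> decoder: 512 -> 1024 -> H*W*C (sigmoid), masked to one capsule

The `baseline` preset reproduces the original single-convolution CapsNet
(conv 256 @ 9x9 stride 1, primary caps 32x8 @ 9x9 stride 2, no CLAHE).
`tiny` variants keep every kernel, stride and routing choice but narrow the
channel counts so the model trains in minutes on one CPU core.

Every built model carries a :class:`ShapeTrace` auditing per-layer output
shapes and trainable parameter counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, conv2d, straight_through
from .capsule_ops import (
    SquashSpec,
    apply_squash,
    capsule_lengths,
    predictions,
    route,
)
from .clahe import ClaheParams, clahe_layer

__all__ = [
    "LayerSpec",
    "ArchitectureConfig",
    "ShapeTrace",
    "conv_output_shape",
    "default_config",
    "baseline_config",
    "tiny_config",
    "tiny_baseline_config",
    "build_model",
    "CapsNetModel",
    "reconstruction_loss",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# declarative layer specs


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the feature stack (everything before the class capsules)."""

    kind: str  # clahe | conv | primary_caps
    kernel: tuple[int, int] = (1, 1)
    stride: int = 1
    padding: str = "valid"
    out_channels: int = 0  # conv only
    capsule_types: int = 0  # primary_caps only
    capsule_dim: int = 8  # primary_caps only
    activation: str = "none"
    clahe: ClaheParams | None = None

    def __post_init__(self):
        if self.kind not in ("clahe", "conv", "primary_caps"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1 or self.kernel[0] < 1 or self.kernel[1] < 1:
            raise ValueError("stride and kernel dims must be >= 1")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Declarative description of a capsule classifier."""

    input_shape: tuple[int, int, int] = (48, 48, 3)
    layers: tuple[LayerSpec, ...] = ()
    n_classes: int = 4
    class_capsule_dim: int = 16
    decoder_units: tuple[int, ...] = (512, 1024, 6912)
    routing_iters: int = 3
    coupling_mode: str = "sigmoid"
    squash: SquashSpec = SquashSpec("power", 3.0)
    recon_weight: float = 0.0005
    name: str = "clahe_capsnet"

    def __post_init__(self):
        H, W, C = self.input_shape
        if self.decoder_units and self.decoder_units[-1] != H * W * C:
            raise ValueError(
                f"decoder output ({self.decoder_units[-1]}) must equal "
                f"H*W*C ({H * W * C})"
            )
        if self.routing_iters < 1 or self.n_classes < 2:
            raise ValueError("routing_iters >= 1 and n_classes >= 2 required")

    # round-trip for checkpoints / YAML configs
    def to_dict(self):
        d = asdict(self)
        d["squash"] = {"kind": self.squash.kind, "exponent": self.squash.exponent}
        d["layers"] = []
        for spec in self.layers:
            ls = asdict(spec)
            ls["clahe"] = asdict(spec.clahe) if spec.clahe else None
            d["layers"].append(ls)
        return d

    @staticmethod
    def from_dict(d):
        d = dict(d)
        d["squash"] = SquashSpec(**d["squash"])
        layers = []
        for ls in d["layers"]:
            ls = dict(ls)
            if ls.get("clahe"):
                cp = dict(ls["clahe"])
                cp["tile_grid"] = tuple(cp["tile_grid"])
                ls["clahe"] = ClaheParams(**cp)
            ls["kernel"] = tuple(ls["kernel"])
            layers.append(LayerSpec(**ls))
        d["layers"] = tuple(layers)
        d["input_shape"] = tuple(d["input_shape"])
        d["decoder_units"] = tuple(d["decoder_units"])
        return ArchitectureConfig(**d)


@dataclass
class ShapeTrace:
    """Audited per-layer shapes and trainable parameter counts."""

    rows: list = field(default_factory=list)  # (name, in_shape, out_shape, n_params)

    def add(self, name, in_shape, out_shape, n_params):
        if self.rows:
            prev = tuple(self.rows[-1][2])
            cur = tuple(in_shape)
            # shapes chain either exactly or up to flattening (decoder input)
            if prev != cur and int(np.prod(prev)) != int(np.prod(cur)):
                raise ValueError(f"shape chain broken at {name}")
        self.rows.append((name, tuple(in_shape), tuple(out_shape), int(n_params)))

    @property
    def total_params(self):
        return sum(r[3] for r in self.rows)

    def out_shape(self, name):
        for r in self.rows:
            if r[0] == name:
                return r[2]
        raise KeyError(name)

    def params_of(self, name):
        for r in self.rows:
            if r[0] == name:
                return r[3]
        raise KeyError(name)

    def __str__(self):
        lines = [f"{'layer':<14}{'in':<16}{'out':<16}{'params':>10}"]
        for n, i, o, p in self.rows:
            lines.append(f"{n:<14}{str(i):<16}{str(o):<16}{p:>10d}")
        lines.append(f"{'total':<46}{self.total_params:>10d}")
        return "\n".join(lines)


def conv_output_shape(in_hw, kernel, stride, padding):
    """Spatial output of a 2-D convolution.

    valid: H' = floor((H - kh)/stride) + 1;  same: H' = ceil(H/stride).
    """
    H, W = in_hw
    kh, kw = kernel
    if padding == "valid":
        if kh > H or kw > W:
            raise ValueError("kernel larger than input under valid padding")
        return ((H - kh) // stride + 1, (W - kw) // stride + 1)
    if padding == "same":
        return (math.ceil(H / stride), math.ceil(W / stride))
    raise ValueError(f"unknown padding {padding!r}")


# --------------------------------------------------------------------------
# presets


def _stack(conv_channels, pc_types, pc_dim, clahe_in, clahe_mid):
    return (
        LayerSpec("clahe", clahe=clahe_in),
        LayerSpec("conv", (5, 5), 2, "valid", out_channels=conv_channels[0], activation="relu"),
        LayerSpec("conv", (3, 3), 2, "valid", out_channels=conv_channels[1], activation="relu"),
        LayerSpec("conv", (1, 1), 1, "valid", out_channels=conv_channels[2], activation="relu"),
        LayerSpec("clahe", clahe=clahe_mid),
        LayerSpec("primary_caps", (9, 9), 3, "same", capsule_types=pc_types, capsule_dim=pc_dim),
    )


_CLAHE_INPUT = ClaheParams(tile_grid=(8, 8), clip_limit=2.0, n_bins=256)
# mid-network maps are only 10x10: a 2x2 grid and 32 bins keep tiles meaningful
_CLAHE_MID = ClaheParams(tile_grid=(2, 2), clip_limit=2.0, n_bins=32)


def default_config(n_classes=4, **overrides):
    """The full CLAHE-CapsNet: 256-channel convs, 576 primary capsules."""
    H, W, C = overrides.pop("input_shape", (48, 48, 3))
    cfg = dict(
        input_shape=(H, W, C),
        layers=_stack((256, 256, 256), 36, 8, _CLAHE_INPUT, _CLAHE_MID),
        n_classes=n_classes,
        decoder_units=(512, 1024, H * W * C),
        coupling_mode="sigmoid",
        squash=SquashSpec("power", 3.0),
        name="clahe_capsnet",
    )
    cfg.update(overrides)
    return ArchitectureConfig(**cfg)


def baseline_config(n_classes=4, **overrides):
    """The original CapsNet: one 9x9 conv, 32x8 primary caps, softmax routing,
    original squash, no CLAHE."""
    H, W, C = overrides.pop("input_shape", (48, 48, 3))
    cfg = dict(
        input_shape=(H, W, C),
        layers=(
            LayerSpec("conv", (9, 9), 1, "valid", out_channels=256, activation="relu"),
            LayerSpec("primary_caps", (9, 9), 2, "valid", capsule_types=32, capsule_dim=8),
        ),
        n_classes=n_classes,
        decoder_units=(512, 1024, H * W * C),
        coupling_mode="softmax",
        squash=SquashSpec("original"),
        name="baseline_capsnet",
    )
    cfg.update(overrides)
    return ArchitectureConfig(**cfg)


def tiny_config(n_classes=4, **overrides):
    """Desk-scale CLAHE-CapsNet: same kernels/strides/routing, narrow channels."""
    H, W, C = overrides.pop("input_shape", (48, 48, 3))
    cfg = dict(
        input_shape=(H, W, C),
        layers=_stack((32, 32, 32), 8, 8, _CLAHE_INPUT, _CLAHE_MID),
        n_classes=n_classes,
        decoder_units=(128, 256, H * W * C),
        coupling_mode="sigmoid",
        squash=SquashSpec("power", 3.0),
        name="clahe_capsnet_tiny",
    )
    cfg.update(overrides)
    return ArchitectureConfig(**cfg)


def tiny_baseline_config(n_classes=4, **overrides):
    """Desk-scale original CapsNet."""
    H, W, C = overrides.pop("input_shape", (48, 48, 3))
    cfg = dict(
        input_shape=(H, W, C),
        layers=(
            LayerSpec("conv", (9, 9), 1, "valid", out_channels=16, activation="relu"),
            LayerSpec("primary_caps", (9, 9), 2, "valid", capsule_types=4, capsule_dim=8),
        ),
        n_classes=n_classes,
        decoder_units=(128, 256, H * W * C),
        coupling_mode="softmax",
        squash=SquashSpec("original"),
        name="baseline_capsnet_tiny",
    )
    cfg.update(overrides)
    return ArchitectureConfig(**cfg)


PRESETS = {
    "clahe_capsnet": default_config,
    "baseline_capsnet": baseline_config,
    "clahe_capsnet_tiny": tiny_config,
    "baseline_capsnet_tiny": tiny_baseline_config,
}


# --------------------------------------------------------------------------
# runtime layers


def _he_uniform(rng, shape, fan_in, dtype=np.float32):
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _Clahe:
    n_params = 0

    def __init__(self, params: ClaheParams, name):
        self.clahe_params = params
        self.name = name
        self.params = []

    def out_shape(self, in_shape):
        return in_shape

    def __call__(self, x: Tensor) -> Tensor:
        p = self.clahe_params
        return straight_through(
            x, lambda a: clahe_layer(a, p).astype(a.dtype)
        )


class _Conv:
    def __init__(self, spec: LayerSpec, in_ch, rng, name):
        kh, kw = spec.kernel
        fan_in = kh * kw * in_ch
        self.W = Tensor(_he_uniform(rng, (kh, kw, in_ch, spec.out_channels), fan_in),
                        requires_grad=True, name=f"{name}.W")
        self.b = Tensor(np.zeros(spec.out_channels, dtype=np.float32),
                        requires_grad=True, name=f"{name}.b")
        self.spec = spec
        self.name = name
        self.params = [self.W, self.b]
        self.n_params = self.W.data.size + self.b.data.size

    def out_shape(self, in_shape):
        hw = conv_output_shape(in_shape[:2], self.spec.kernel, self.spec.stride,
                               self.spec.padding)
        return (*hw, self.spec.out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.W, self.b, stride=self.spec.stride,
                     padding=self.spec.padding)
        return out.relu() if self.spec.activation == "relu" else out


class _PrimaryCaps:
    """Convolutional capsules: conv -> reshape to (B, N, D) -> squash."""

    def __init__(self, spec: LayerSpec, in_ch, squash: SquashSpec, rng, name):
        conv_spec = LayerSpec(
            "conv", spec.kernel, spec.stride, spec.padding,
            out_channels=spec.capsule_types * spec.capsule_dim,
        )
        self.conv = _Conv(conv_spec, in_ch, rng, name)
        self.spec = spec
        self.squash = squash
        self.name = name
        self.params = self.conv.params
        self.n_params = self.conv.n_params

    def out_shape(self, in_shape):
        h, w, _ = self.conv.out_shape(in_shape)
        return (h * w * self.spec.capsule_types, self.spec.capsule_dim)

    def __call__(self, x: Tensor) -> Tensor:
        out = self.conv(x)  # (B, h, w, types*dim)
        B, h, w, _ = out.shape
        caps = out.reshape(B, h * w * self.spec.capsule_types, self.spec.capsule_dim)
        return apply_squash(caps, self.squash, axis=-1)


class _ClassCaps:
    """Fully connected capsule layer with dynamic routing."""

    def __init__(self, n_lower, d_lower, n_classes, d_upper, cfg, rng, name):
        self.W = Tensor(
            rng.normal(0.0, 0.01, size=(n_lower, n_classes, d_upper, d_lower))
            .astype(np.float32),
            requires_grad=True, name=f"{name}.W",
        )
        self.cfg = cfg
        self.name = name
        self.params = [self.W]
        self.n_params = self.W.data.size

    def out_shape(self, in_shape):
        return (self.W.shape[1], self.W.shape[2])

    def __call__(self, u: Tensor):
        u_hat = predictions(u, self.W)
        v, state = route(u_hat, r=self.cfg.routing_iters,
                         mode=self.cfg.coupling_mode, squash=self.cfg.squash)
        return v, state


class _Dense:
    def __init__(self, n_in, n_out, activation, rng, name):
        self.W = Tensor(_he_uniform(rng, (n_in, n_out), n_in),
                        requires_grad=True, name=f"{name}.W")
        self.b = Tensor(np.zeros(n_out, dtype=np.float32),
                        requires_grad=True, name=f"{name}.b")
        self.activation = activation
        self.name = name
        self.params = [self.W, self.b]
        self.n_params = self.W.data.size + self.b.data.size

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "relu":
            return out.relu()
        if self.activation == "sigmoid":
            return out.sigmoid()
        return out


# --------------------------------------------------------------------------
# the model


class CapsNetModel:
    """A built capsule classifier with reconstruction decoder.

    Not fitted directly by users — see
    :class:`capsoct.estimators.CapsNetClassifier` for the sklearn surface.
    """

    def __init__(self, cfg: ArchitectureConfig, seed=0):
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.trace = ShapeTrace()
        self.feature_layers = []
        shape = tuple(cfg.input_shape)

        counts = {"clahe": 0, "conv": 0}
        for spec in cfg.layers:
            if spec.kind == "clahe":
                counts["clahe"] += 1
                layer = _Clahe(spec.clahe or ClaheParams(), f"clahe{counts['clahe']}")
            elif spec.kind == "conv":
                counts["conv"] += 1
                layer = _Conv(spec, shape[-1], rng, f"conv{counts['conv']}")
            else:
                layer = _PrimaryCaps(spec, shape[-1], cfg.squash, rng, "primary_caps")
            out = layer.out_shape(shape)
            self.trace.add(layer.name, shape, out, layer.n_params)
            self.feature_layers.append(layer)
            shape = out

        n_lower, d_lower = shape
        self.class_caps = _ClassCaps(n_lower, d_lower, cfg.n_classes,
                                     cfg.class_capsule_dim, cfg, rng, "class_caps")
        out = self.class_caps.out_shape(shape)
        self.trace.add("class_caps", shape, out, self.class_caps.n_params)
        shape = out

        self.decoder = []
        n_in = cfg.n_classes * cfg.class_capsule_dim
        units = cfg.decoder_units
        for i, n_out in enumerate(units):
            act = "sigmoid" if i == len(units) - 1 else "relu"
            layer = _Dense(n_in, n_out, act, rng, f"decoder{i + 1}")
            self.decoder.append(layer)
            self.trace.add(layer.name, (n_in,), (n_out,), layer.n_params)
            n_in = n_out

        self.params = [p for l in self.feature_layers for p in l.params]
        self.params += self.class_caps.params
        self.params += [p for l in self.decoder for p in l.params]

    # -- forward -----------------------------------------------------------
    def preprocess_input(self, x):
        """Apply the input CLAHE layer (if any) to a raw batch, as numpy.

        The first layer is deterministic and parameter-free, so callers that
        sweep the same data many times (the training loop) can apply it once
        and pass ``skip_input_clahe=True`` to :meth:`forward`; results are
        identical either way.
        """
        x = np.asarray(x, dtype=np.float32)
        if self.feature_layers and isinstance(self.feature_layers[0], _Clahe):
            return clahe_layer(x, self.feature_layers[0].clahe_params).astype(np.float32)
        return x

    def forward(self, x, labels=None, skip_input_clahe=False):
        """Run a batch through the network.

        x : (B, H, W, C) array in [0, 1].
        labels : optional (B,) int class indices; when given, the decoder is
            masked with the true capsule (training), otherwise with the argmax
            capsule (inference).

        Returns dict with 'lengths' (B, k), 'v' (B, k, D), 'recon'
        (B, H*W*C) as Tensors, and the final 'routing' state.
        """
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.shape[1:] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"input shape {t.shape[1:]} != expected {self.cfg.input_shape}"
            )
        layers = self.feature_layers
        if skip_input_clahe and layers and isinstance(layers[0], _Clahe):
            layers = layers[1:]
        for layer in layers:
            t = layer(t)
        v, state = self.class_caps(t)
        lengths = capsule_lengths(v, axis=-1)

        B, k = lengths.shape
        if labels is None:
            target = np.argmax(lengths.data, axis=1)
        else:
            target = np.asarray(labels, dtype=np.intp)
        mask = np.zeros((B, k, 1), dtype=v.data.dtype)
        mask[np.arange(B), target, 0] = 1.0
        masked = v * Tensor(mask)
        h = masked.reshape(B, k * self.cfg.class_capsule_dim)
        for layer in self.decoder:
            h = layer(h)
        return {"lengths": lengths, "v": v, "recon": h, "routing": state}

    def predict_scores(self, x, batch_size=256):
        """Capsule lengths for a (possibly large) input array; numpy out."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size])["lengths"].data)
        return np.concatenate(outs, axis=0)

    def get_weights(self):
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights):
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.astype(p.data.dtype)


def reconstruction_loss(recon, target, weight=1.0):
    """Sum of squared errors per sample, averaged over the batch, times weight.

    During training the decoder sees only the target-class capsule (the other
    capsules are masked to zero), so this term regularises the class capsules
    to encode enough pose to redraw the input.
    """
    if isinstance(recon, Tensor):
        tgt = target if isinstance(target, Tensor) else Tensor(
            np.asarray(target, dtype=recon.data.dtype).reshape(recon.shape)
        )
        diff = recon - tgt
        per_sample = (diff * diff).sum(axis=-1)
        out = per_sample.mean() if per_sample.ndim else per_sample
        return out * float(weight)
    r = np.asarray(recon, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64).reshape(r.shape)
    per_sample = ((r - t) ** 2).sum(axis=-1)
    return float(weight) * float(np.mean(per_sample))


def build_model(cfg: ArchitectureConfig, seed=0):
    """Build a model from a config; returns (model, shape trace)."""
    model = CapsNetModel(cfg, seed=seed)
    return model, model.trace


# --------------------------------------------------------------------------
# config and checkpoint serialization


def save_config(cfg: ArchitectureConfig, path):
    """Serialize a config as YAML (or JSON if the path ends in .json)."""
    import yaml

    d = json.loads(json.dumps(cfg.to_dict()))  # tuples -> lists
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(d, fh, indent=1)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)
    return path


def load_config(path) -> ArchitectureConfig:
    import yaml

    with open(path) as fh:
        d = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return ArchitectureConfig.from_dict(d)


# checkpoints: npz weights + JSON sidecar with config and seed


def save_checkpoint(model: CapsNetModel, path):
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(model.params)})
    sidecar = {"config": model.cfg.to_dict(), "seed": model.seed}
    with open(path[: -len(".npz")] + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_checkpoint(path):
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path[: -len(".npz")] + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ArchitectureConfig.from_dict(sidecar["config"])
    model = CapsNetModel(cfg, seed=sidecar["seed"])
    with np.load(path) as data:
        model.set_weights([data[f"p{i}"] for i in range(len(model.params))])
    return model
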