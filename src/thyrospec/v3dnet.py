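"""V3Dnet: 3D-CNN feature extraction, PCA bridge and a VGG-style head.

Dataflow for a default 50x50 block: spectral PCA reduces 196 bands to 3, two
shape-preserving 3-D convolutions (8 then 32 kernels of 3x3x3) extract
spatio-spectral features, the 32 feature volumes of 50x50x3 are recombined
into a 50x50x96 image, a per-block PCA bridge reduces the 96 channels back to
3, and a six-block VGG-style classifier (2,2,2,3,3 convolutions per block,
2x2 max pooling between blocks, then 3 fully connected layers) produces
two-class softmax probabilities.  All nonlinearities are ReLU.

Simple baselines (1-D, 2-D, 3-D CNNs and the VGG head alone) share the same
block interface for comparison experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from thyrospec import nn
from thyrospec.blockset import Block, CLASS_NAMES
from thyrospec.errors import ConfigError, ShapeError
from thyrospec.preprocess import pca_fit, pca_apply


@dataclass
class V3DnetConfig:
    """Architecture hyperparameters.

    ``vgg_conv_counts`` lists the convolutions per convolutional block; with
    the trailing fully connected block the head has six blocks.  Channel
    widths and fully connected sizes default to a canonical VGG-like ladder
    and can be scaled down for small synthetic experiments.
    """

    input_size: tuple[int, int, int] = (50, 50, 3)   # (h, w, spectral_k)
    conv1_kernels: int = 8
    conv2_kernels: int = 32
    kernel_shape: tuple[int, int, int] = (3, 3, 3)
    bridge_k: int = 3
    bridge_mode: str = "per_block"                    # or "global"
    vgg_conv_counts: tuple[int, ...] = (2, 2, 2, 3, 3)
    vgg_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    fc_sizes: tuple[int, int] = (512, 128)
    pool_size: int = 2
    adaptive_pool: tuple[int, int] = (1, 1)
    n_classes: int = 2

    @property
    def recombined_depth(self) -> int:
        return self.conv2_kernels * self.input_size[2]

    def validate(self) -> None:
        if len(self.vgg_conv_counts) != len(self.vgg_channels):
            raise ConfigError("vgg_conv_counts and vgg_channels lengths differ")
        if len(self.vgg_conv_counts) + 1 != 6:
            raise ConfigError("the head must have six blocks (5 conv + 1 FC)")
        if any(k > s for k, s in zip(self.kernel_shape, self.input_size)):
            raise ConfigError(
                f"kernel {self.kernel_shape} exceeds input {self.input_size}")
        if self.bridge_mode not in ("per_block", "global"):
            raise ConfigError(f"unknown bridge_mode {self.bridge_mode!r}")

    @classmethod
    def desk(cls) -> "V3DnetConfig":
        """Scaled-down configuration for small synthetic experiments."""
        return cls(input_size=(20, 20, 3), conv1_kernels=8, conv2_kernels=16,
                   vgg_channels=(8, 16, 16, 32, 32), fc_sizes=(64, 32))


@dataclass
class PredictionRecord:
    """Softmax output for one block, with provenance."""

    prob: np.ndarray              # length-2, sums to 1
    predicted: int                # argmax: 0 = benign, 1 = malignant
    case_id: str = ""
    origin: tuple[int, int] = (0, 0)

    @property
    def predicted_name(self) -> str:
        return CLASS_NAMES[self.predicted]


class BlockClassifier:
    """A network plus the input adapter mapping blocks to network tensors."""

    def __init__(self, net: nn.Network, cfg, seed: int, kind: str):
        self.net = net
        self.cfg = cfg
        self.seed = seed
        self.kind = kind

    # -- input adaptation -------------------------------------------------
    def prepare(self, blocks: np.ndarray) -> np.ndarray:
        """(N, h, w, s) block tensor -> network input."""
        raise NotImplementedError

    def logits(self, blocks: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self.prepare(blocks), train=train)

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(np.asarray(blocks, dtype=np.float32)))

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **self.net.state_dict())
        meta = {"kind": self.kind, "seed": self.seed,
                "config": asdict(self.cfg) if self.cfg is not None else None}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=list))
        return path

    def summary(self) -> dict:
        return {"kind": self.kind, "n_params": self.net.n_params(),
                "layers": [type(l).__name__ for l in self.net.layers]}


class V3DnetModel(BlockClassifier):
    def prepare(self, blocks: np.ndarray) -> np.ndarray:
        blocks = np.asarray(blocks, dtype=np.float32)
        if blocks.ndim == 3:
            blocks = blocks[None]
        h, w, s = self.cfg.input_size
        if blocks.shape[1:] != (h, w, s):
            raise ShapeError(
                f"blocks {blocks.shape[1:]} do not match config input {(h, w, s)}")
        # (N, h, w, s) -> single-channel 3-D volume (N, 1, h, w, s)
        return blocks[:, None]


def _vgg_head(cfg: V3DnetConfig, in_ch: int, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    ch = in_ch
    for n_convs, width in zip(cfg.vgg_conv_counts, cfg.vgg_channels):
        for _ in range(n_convs):
            layers.append(nn.Conv2D(ch, width, rng=rng))
            layers.append(nn.ReLU())
            ch = width
        layers.append(nn.MaxPool2D(cfg.pool_size))
    oh, ow = cfg.adaptive_pool
    layers.append(nn.AdaptiveAvgPool2D((oh, ow)))
    layers.append(nn.Flatten())
    f1, f2 = cfg.fc_sizes
    layers.append(nn.Dense(ch * oh * ow, f1, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(f1, f2, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(f2, cfg.n_classes, rng))
    return layers


def build_v3dnet(cfg: V3DnetConfig | None = None, seed: int = 0,
                 bridge_projection: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> V3DnetModel:
    """Build a V3Dnet with deterministic seed-driven initialization.

    ``bridge_projection`` supplies a frozen (mean, components) pair for
    ``bridge_mode="global"``; otherwise the bridge fits PCA per block.
    """
    cfg = V3DnetConfig() if cfg is None else cfg
    cfg.validate()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv3D(1, cfg.conv1_kernels, cfg.kernel_shape, rng),
        nn.ReLU(),
        nn.Conv3D(cfg.conv1_kernels, cfg.conv2_kernels, cfg.kernel_shape, rng),
        nn.ReLU(),
        nn.Recombine3DTo2D(),
        nn.PCABridge(cfg.bridge_k,
                     projection=bridge_projection
                     if cfg.bridge_mode == "global" else None),
        nn.ChannelStandardize(),
    ]
    layers += _vgg_head(cfg, cfg.bridge_k, rng)
    return V3DnetModel(nn.Network(layers), cfg, seed, "v3dnet")


def forward(model: BlockClassifier, block: np.ndarray | Block) -> PredictionRecord:
    """Classify a single block; returns its softmax probability record."""
    case_id, origin = "", (0, 0)
    if isinstance(block, Block):
        case_id, origin = block.case_id, block.origin
        block = block.data
    prob = model.predict_proba(np.asarray(block, dtype=np.float32)[None])[0]
    return PredictionRecord(prob=prob, predicted=int(np.argmax(prob)),
                            case_id=case_id, origin=origin)


def pca_bridge(features: np.ndarray, k: int = 3) -> np.ndarray:
    """Standalone per-block PCA bridge: (h, w, C) -> (h, w, k).

    Fits PCA over the h*w pixel feature vectors with the deterministic sign
    convention and projects every pixel.
    """
    features = np.asarray(features, dtype=float)
    h, w, c = features.shape
    if h * w < k:
        raise ShapeError(f"need >= {k} pixels, got {h * w}")
    proj = pca_fit(features.reshape(h * w, c), k)
    return pca_apply(proj, features)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineConfig:
    """Shared knobs for the small reference architectures."""

    input_size: tuple[int, int, int] = (50, 50, 3)
    channels: tuple[int, int] = (8, 16)
    fc_size: int = 32
    n_classes: int = 2
    vgg: V3DnetConfig | None = None


class _Spectra1DModel(BlockClassifier):
    def prepare(self, blocks):
        blocks = np.asarray(blocks, dtype=np.float32)
        # pool spatially -> one mean spectrum per block, as (N, 1, B)
        return blocks.mean(axis=(1, 2))[:, None, :]


class _Image2DModel(BlockClassifier):
    def prepare(self, blocks):
        blocks = np.asarray(blocks, dtype=np.float32)
        return np.ascontiguousarray(blocks.transpose(0, 3, 1, 2))


class _Volume3DModel(BlockClassifier):
    def prepare(self, blocks):
        return np.asarray(blocks, dtype=np.float32)[:, None]


def build_baseline(kind: str, cfg: BaselineConfig | None = None,
                   seed: int = 0) -> BlockClassifier:
    """Reference architectures: ``cnn1d``, ``cnn2d``, ``cnn3d``, ``vgg16``.

    cnn1d consumes the spatially pooled spectrum of each block; cnn2d and
    vgg16 consume the PCA-reduced 3-channel image; cnn3d is the two-stage 3-D
    extractor with a fully connected head.
    """
    cfg = BaselineConfig() if cfg is None else cfg
    rng = np.random.default_rng(seed)
    c1, c2 = cfg.channels
    k = cfg.input_size[2]
    if kind == "cnn1d":
        layers = [nn.Conv1D(1, c1, rng=rng), nn.ReLU(),
                  nn.Conv1D(c1, c2, rng=rng), nn.ReLU(),
                  nn.GlobalAvgPoolND(),
                  nn.Dense(c2, cfg.fc_size, rng), nn.ReLU(),
                  nn.Dense(cfg.fc_size, cfg.n_classes, rng)]
        return _Spectra1DModel(nn.Network(layers), cfg, seed, kind)
    if kind == "cnn2d":
        layers = [nn.Conv2D(k, c1, rng=rng), nn.ReLU(), nn.MaxPool2D(),
                  nn.Conv2D(c1, c2, rng=rng), nn.ReLU(),
                  nn.GlobalAvgPoolND(),
                  nn.Dense(c2, cfg.fc_size, rng), nn.ReLU(),
                  nn.Dense(cfg.fc_size, cfg.n_classes, rng)]
        return _Image2DModel(nn.Network(layers), cfg, seed, kind)
    if kind == "cnn3d":
        layers = [nn.Conv3D(1, c1, rng=rng), nn.ReLU(),
                  nn.Conv3D(c1, c2, rng=rng), nn.ReLU(),
                  nn.GlobalAvgPoolND(),
                  nn.Dense(c2, cfg.fc_size, rng), nn.ReLU(),
                  nn.Dense(cfg.fc_size, cfg.n_classes, rng)]
        return _Volume3DModel(nn.Network(layers), cfg, seed, kind)
    if kind == "vgg16":
        vgg = cfg.vgg if cfg.vgg is not None else V3DnetConfig(
            input_size=cfg.input_size,
            vgg_channels=(c1, c2, c2, 2 * c2, 2 * c2),
            fc_sizes=(cfg.fc_size * 2, cfg.fc_size))
        layers = [nn.ChannelStandardize()] + _vgg_head(vgg, k, rng)
        return _Image2DModel(nn.Network(layers), vgg, seed, kind)
    raise ConfigError(f"unknown baseline kind {kind!r}")


def load_model(path: str | Path) -> BlockClassifier:
    """Rebuild a saved classifier from its npz checkpoint + json sidecar."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["kind"] == "v3dnet":
        cfg_d = dict(meta["config"])
        for key in ("input_size", "kernel_shape", "vgg_conv_counts",
                    "vgg_channels", "fc_sizes", "adaptive_pool"):
            cfg_d[key] = tuple(cfg_d[key])
        model = build_v3dnet(V3DnetConfig(**cfg_d), seed=meta["seed"])
    else:
        cfg_d = dict(meta["config"])
        if "conv1_kernels" in cfg_d:  # vgg16 baseline stores a V3DnetConfig
            model = build_baseline("vgg16", seed=meta["seed"])
        else:
            for key in ("input_size", "channels"):
                cfg_d[key] = tuple(cfg_d[key])
            cfg_d.pop("vgg", None)
            model = build_baseline(meta["kind"], BaselineConfig(**cfg_d),
                                   seed=meta["seed"])
    state = dict(np.load(str(path) if str(path).endswith(".npz")
                         else str(path) + ".npz"))
    model.net.load_state_dict(state)
    return model
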