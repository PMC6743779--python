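"""The paired-cell inpainting model and its fitted results object.

Architecture: an AlexNet-family *source cell encoder* (five 3x3 conv +
batchnorm + ReLU blocks, 2x2 max-pooling after blocks 1, 2 and 5), a small
*target marker encoder* (three blocks, 16/32/32 filters, pooled after each),
and a *decoder* that mirrors the source encoder with nearest-neighbour
upsampling and a sigmoid head over the protein channels.  The two encoder
bottlenecks are concatenated along the channel axis at matched spatial
resolution.  After training everything but the source encoder is discarded:
features are read from the named taps Conv1..Conv5 of the source encoder.

Usage follows the model/results convention::

    model = PairedCellInpainting(crops, layout, ModelConfig.reduced())
    res = model.fit(TrainConfig(epochs=5, seed=0))
    table = res.extract_features(layer="Conv3")
    print(res.summary())

An ``autoencoder`` mode reuses the source encoder + decoder to reconstruct
the input crop's own channels (the target marker encoder is unused); it is
the baseline the inpainting features are judged against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CellCrop, ChannelLayout, ContractError
from .nn import (
    Adam,
    BatchNorm,
    Conv3x3,
    Layer,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    Upsample2,
)
from .pretext import (
    augment_pair,
    inpainting_loss,
    inpainting_loss_grad,
    make_pair,
    sample_epoch_pairs,
)

LAYER_NAMES = ("Conv1", "Conv2", "Conv3", "Conv4", "Conv5")

# canonical AlexNet filter counts for the source encoder
ALEXNET_WIDTHS = (96, 256, 384, 384, 256)


@dataclass
class ModelConfig:
    source_encoder_widths: tuple[int, ...] = ALEXNET_WIDTHS
    target_encoder_widths: tuple[int, ...] = (16, 32, 32)
    crop_size: int = 64
    n_structural: int = 1
    n_protein: int = 1
    batchnorm: bool = True

    def __post_init__(self) -> None:
        self.source_encoder_widths = tuple(self.source_encoder_widths)
        self.target_encoder_widths = tuple(self.target_encoder_widths)
        if len(self.source_encoder_widths) != 5:
            raise ContractError("source encoder must have exactly 5 convolutional layers")
        if len(self.target_encoder_widths) != 3:
            raise ContractError("target encoder must have exactly 3 convolutional layers")
        if self.crop_size % 8:
            raise ContractError("crop_size must be divisible by 8 (three 2x2 pools)")

    @classmethod
    def reduced(
        cls, crop_size: int = 32, n_structural: int = 1, n_protein: int = 1
    ) -> "ModelConfig":
        """CPU-scale profile: narrow source encoder, 32-px crops."""
        return cls(
            source_encoder_widths=(16, 32, 32, 32, 32),
            target_encoder_widths=(16, 32, 32),
            crop_size=crop_size,
            n_structural=n_structural,
            n_protein=n_protein,
        )

    @property
    def n_channels(self) -> int:
        return self.n_structural + self.n_protein

    def layer_width(self, layer: str) -> int:
        if layer not in LAYER_NAMES:
            raise ContractError(f"unknown layer {layer!r}; expected one of {LAYER_NAMES}")
        return self.source_encoder_widths[LAYER_NAMES.index(layer)]


@dataclass
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-4
    batch_size: int = 64
    seed: int = 0
    augment: bool = True
    mode: str = "paired_inpainting"  # or "autoencoder"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be positive")
        if self.mode not in ("paired_inpainting", "autoencoder"):
            raise ContractError(f"unknown training mode {self.mode!r}")


class _ConvBlock(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str) -> None:
        self.conv = Conv3x3(cin, cout, rng, name)
        self.bn = BatchNorm(cout, name=name)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


# source-encoder pooling after blocks 1, 2, 5 (AlexNet placement)
_SOURCE_POOL_AFTER = (0, 1, 4)
# decoder mirrors: upsample before decoder blocks 1, 4, 5
_DECODER_UP_BEFORE = (0, 3, 4)


class InpaintingNet:
    """Forward/backward graph for either training mode."""

    def __init__(self, config: ModelConfig, mode: str, rng: np.random.Generator) -> None:
        self.config = config
        self.mode = mode
        sw = config.source_encoder_widths
        tw = config.target_encoder_widths

        cin = config.n_channels
        self.source_blocks: list[_ConvBlock] = []
        for i, wdt in enumerate(sw):
            self.source_blocks.append(_ConvBlock(cin, wdt, rng, f"src{i + 1}"))
            cin = wdt
        self.source_pools = {i: MaxPool2() for i in _SOURCE_POOL_AFTER}

        if mode == "paired_inpainting":
            cin = config.n_structural
            self.target_blocks: list[_ConvBlock] = []
            self.target_pools: list[MaxPool2] = []
            for i, wdt in enumerate(tw):
                self.target_blocks.append(_ConvBlock(cin, wdt, rng, f"tgt{i + 1}"))
                self.target_pools.append(MaxPool2())
                cin = wdt
            dec_in = sw[-1] + tw[-1]
            out_ch = config.n_protein
        else:
            self.target_blocks = []
            self.target_pools = []
            dec_in = sw[-1]
            out_ch = config.n_channels

        dec_widths = tuple(reversed(sw))
        layers: list[Layer] = []
        cin = dec_in
        for i, wdt in enumerate(dec_widths):
            if i in _DECODER_UP_BEFORE:
                layers.append(Upsample2())
            layers.append(_ConvBlock(cin, wdt, rng, f"dec{i + 1}"))
            cin = wdt
        final = Conv3x3(cin, out_ch, rng, "head")
        layers.extend([final, Sigmoid()])
        self.decoder = Sequential(layers)
        self.out_channels = out_ch

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.source_blocks:
            ps.extend(b.params())
        for b in self.target_blocks:
            ps.extend(b.params())
        ps.extend(self.decoder.params())
        return ps

    def batchnorms(self) -> list[BatchNorm]:
        bns = [b.bn for b in self.source_blocks + self.target_blocks]
        bns.extend(l.bn for l in self.decoder.layers if isinstance(l, _ConvBlock))
        return bns

    # -- source encoder with taps ------------------------------------------
    def forward_source(
        self, x: np.ndarray, train: bool, taps: dict | None = None
    ) -> np.ndarray:
        h = x
        for i, block in enumerate(self.source_blocks):
            h = block.forward(h, train)
            if i in self.source_pools:
                h = self.source_pools[i].forward(h, train)
            # tap after the block's pool (if any): the spatial max is
            # unchanged by max-pooling, and shapes follow the pooled grid
            if taps is not None:
                taps[LAYER_NAMES[i]] = h
        return h

    def backward_source(self, dout: np.ndarray) -> np.ndarray:
        for i in reversed(range(len(self.source_blocks))):
            if i in self.source_pools:
                dout = self.source_pools[i].backward(dout)
            dout = self.source_blocks[i].backward(dout)
        return dout

    def forward_target(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for block, pool in zip(self.target_blocks, self.target_pools):
            h = pool.forward(block.forward(h, train), train)
        return h

    def backward_target(self, dout: np.ndarray) -> np.ndarray:
        for block, pool in zip(reversed(self.target_blocks), reversed(self.target_pools)):
            dout = block.backward(pool.backward(dout))
        return dout

    # -- full passes --------------------------------------------------------
    def forward(self, xs_ys: np.ndarray, xt: np.ndarray, train: bool = False) -> np.ndarray:
        if self.mode != "paired_inpainting":
            raise ContractError("forward(xs_ys, xt) is only defined in paired_inpainting mode")
        zs = self.forward_source(xs_ys, train)
        zt = self.forward_target(xt, train)
        if zs.shape[1:3] != zt.shape[1:3]:
            raise ContractError("encoder spatial resolutions do not match for concatenation")
        self._split = zs.shape[-1]
        return self.decoder.forward(np.concatenate([zs, zt], axis=-1), train)

    def backward(self, dyhat: np.ndarray) -> None:
        dz = self.decoder.backward(dyhat)
        self.backward_source(dz[..., : self._split])
        self.backward_target(dz[..., self._split :])

    def forward_auto(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = self.forward_source(x, train)
        return self.decoder.forward(z, train)

    def backward_auto(self, dyhat: np.ndarray) -> None:
        self.backward_source(self.decoder.backward(dyhat))

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        d = {}
        for p in self.params():
            d[p.name] = p.v
        for i, bn in enumerate(self.batchnorms()):
            d[f"bn{i}.running_mean"] = bn.running_mean
            d[f"bn{i}.running_var"] = bn.running_var
        return d

    def load_state_arrays(self, d: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.v[...] = d[p.name]
        for i, bn in enumerate(self.batchnorms()):
            bn.running_mean = np.asarray(d[f"bn{i}.running_mean"])
            bn.running_var = np.asarray(d[f"bn{i}.running_var"])


def build_model(
    config: ModelConfig, mode: str = "paired_inpainting", seed: int = 0
) -> InpaintingNet:
    """Construct the network with He-initialized weights from a seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return InpaintingNet(config, mode, rng)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PairedCellInpainting:
    """Self-supervised inpainting model over a store of single-cell crops."""

    def __init__(
        self,
        crops: Sequence[CellCrop],
        channel_layout: ChannelLayout,
        model_config: ModelConfig | None = None,
        mode: str = "paired_inpainting",
    ) -> None:
        crops = list(crops)
        if not crops:
            raise ContractError("cannot build a model from an empty crop store")
        h, w, z = crops[0].pixels.shape
        if z != channel_layout.n_channels:
            raise ContractError("crop channels do not match the channel layout")
        if model_config is None:
            model_config = ModelConfig(
                crop_size=h,
                n_structural=channel_layout.n_structural,
                n_protein=channel_layout.n_protein,
            )
        if model_config.crop_size != h:
            raise ContractError(
                f"model crop_size {model_config.crop_size} != crop size {h}"
            )
        if (model_config.n_structural, model_config.n_protein) != (
            channel_layout.n_structural,
            channel_layout.n_protein,
        ):
            raise ContractError("model channel counts do not match the layout")
        self.crops = crops
        self.layout = channel_layout
        self.config = model_config
        self.mode = mode

    @classmethod
    def from_store(cls, path, model_config=None, mode="paired_inpainting"):
        from .core import read_crop_store

        crops, layout = read_crop_store(path)
        return cls(crops, layout, model_config, mode)

    # -- batch assembly -----------------------------------------------------
    def _pair_batch(self, pairs, rng, augment: bool):
        xs_ys, xt, yt = [], [], []
        for src, tgt in pairs:
            pair = make_pair(self.crops, self.layout, src, tgt)
            if augment:
                pair = augment_pair(pair, rng)
            xs_ys.append(
                np.concatenate([pair.source_structural, pair.source_protein], axis=-1)
            )
            xt.append(pair.target_structural)
            yt.append(pair.target_protein)
        return (
            np.ascontiguousarray(np.stack(xs_ys), dtype=np.float32),
            np.ascontiguousarray(np.stack(xt), dtype=np.float32),
            np.ascontiguousarray(np.stack(yt), dtype=np.float32),
        )

    def _auto_batch(self, indices, rng, augment: bool):
        z1 = list(self.layout.structural_indices)
        z2 = list(self.layout.protein_indices)
        xs = []
        for i in indices:
            pix = self.crops[i].pixels[..., z1 + z2]
            if augment:
                hflip, vflip = rng.integers(0, 2, size=2).astype(bool)
                if vflip:
                    pix = pix[::-1]
                if hflip:
                    pix = pix[:, ::-1]
            xs.append(pix)
        return np.ascontiguousarray(np.stack(xs), dtype=np.float32)

    # -- fitting ------------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None, **kwargs) -> "InpaintingResults":
        if train_config is None:
            kwargs.setdefault("mode", self.mode)
            cfg = TrainConfig(**kwargs)
        else:
            cfg = train_config
        mode = cfg.mode
        ss = np.random.SeedSequence(cfg.seed)
        init_ss, pair_ss, aug_ss = ss.spawn(3)
        rng_init = np.random.default_rng(init_ss)
        rng_pair = np.random.default_rng(pair_ss)
        rng_aug = np.random.default_rng(aug_ss)

        net = InpaintingNet(self.config, mode, rng_init)
        opt = Adam(net.params(), lr=cfg.learning_rate)
        history: list[float] = []

        n = len(self.crops)
        for _epoch in range(cfg.epochs):
            if mode == "paired_inpainting":
                order = sample_epoch_pairs(self.crops, rng_pair)
            else:
                order = [(int(i),) for i in rng_pair.permutation(n)]
            total, count = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                chunk = order[start : start + cfg.batch_size]
                opt.zero_grad()
                if mode == "paired_inpainting":
                    xs_ys, xt, yt = self._pair_batch(chunk, rng_aug, cfg.augment)
                    y_hat = net.forward(xs_ys, xt, train=True)
                    loss = inpainting_loss(y_hat, yt)
                    net.backward(inpainting_loss_grad(y_hat, yt).astype(np.float32))
                else:
                    x = self._auto_batch([c[0] for c in chunk], rng_aug, cfg.augment)
                    y_hat = net.forward_auto(x, train=True)
                    loss = inpainting_loss(y_hat, x)
                    net.backward_auto(inpainting_loss_grad(y_hat, x).astype(np.float32))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {_epoch + 1}"
                    )
                opt.step()
                total += loss * len(chunk)
                count += len(chunk)
            history.append(total / count)

        return InpaintingResults(self, net, cfg, history)


class InpaintingResults:
    """Fitted model: weights, per-epoch loss history, feature extraction."""

    def __init__(
        self,
        model: PairedCellInpainting,
        net: InpaintingNet,
        train_config: TrainConfig,
        loss_history: list[float],
    ) -> None:
        self.model = model
        self.net = net
        self.train_config = train_config
        self.loss_history = list(loss_history)

    def extract_features(self, layer: str = "Conv3", crops: Sequence[CellCrop] | None = None):
        from .features import extract_features

        return extract_features(
            self.net, crops if crops is not None else self.model.crops, layer,
            self.model.layout,
        )

    def predict(self, xs_ys: np.ndarray, xt: np.ndarray) -> np.ndarray:
        """Inpaint a target cell's protein channel (inference mode)."""
        single = xs_ys.ndim == 3
        if single:
            xs_ys, xt = xs_ys[None], xt[None]
        out = self.net.forward(
            np.asarray(xs_ys, dtype=np.float32), np.asarray(xt, dtype=np.float32), train=False
        )
        return out[0] if single else out

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Paired cell inpainting results",
            "==============================",
            f"mode:              {self.net.mode}",
            f"crop size:         {cfg.crop_size}",
            f"channels:          {cfg.n_structural} structural + {cfg.n_protein} protein",
            f"source widths:     {cfg.source_encoder_widths}",
            f"target widths:     {cfg.target_encoder_widths}",
            f"cells:             {len(self.model.crops)}",
            f"epochs:            {self.train_config.epochs}",
            f"learning rate:     {self.train_config.learning_rate}",
            f"seed:              {self.train_config.seed}",
            "epoch   mean loss",
        ]
        for e, loss in enumerate(self.loss_history, start=1):
            lines.append(f"{e:5d}   {loss:.6f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "mode": self.net.mode,
            "model_config": {
                "source_encoder_widths": list(self.model.config.source_encoder_widths),
                "target_encoder_widths": list(self.model.config.target_encoder_widths),
                "crop_size": self.model.config.crop_size,
                "n_structural": self.model.config.n_structural,
                "n_protein": self.model.config.n_protein,
            },
            "train_config": {
                "epochs": self.train_config.epochs,
                "learning_rate": self.train_config.learning_rate,
                "batch_size": self.train_config.batch_size,
                "seed": self.train_config.seed,
                "augment": self.train_config.augment,
                "mode": self.train_config.mode,
            },
            "loss_history": self.loss_history,
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.net.state_arrays())

    @staticmethod
    def load_net(path) -> tuple[InpaintingNet, dict]:
        """Rebuild just the network (enough for feature extraction)."""
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            arrays = {k: f[k] for k in f.files if k != "__meta__"}
        cfg = ModelConfig(
            source_encoder_widths=tuple(meta["model_config"]["source_encoder_widths"]),
            target_encoder_widths=tuple(meta["model_config"]["target_encoder_widths"]),
            crop_size=meta["model_config"]["crop_size"],
            n_structural=meta["model_config"]["n_structural"],
            n_protein=meta["model_config"]["n_protein"],
        )
        net = build_model(cfg, meta["mode"], seed=0)
        net.load_state_arrays(arrays)
        return net, meta
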