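"""Multimodal QA network: encoders, task-specific fusion and decoders.

The GPR path pools both modality embeddings, projects them to a shared
width and combines them with softmax attention weights derived from
learned scalar scores; restricting to a modality subset forces the
combination coefficients to (1,0), (0,1) or (0,0).  The dose-difference
path folds the tabular embedding into feature maps and concatenates it
channel-wise with the image feature maps (tabular channels first), then
decodes with an upsampling convolutional stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .autograd import Tensor, concat, conv2d, dropout, upsample2x
from .layers import Adam, Conv2d, Linear, Module

#: Modality subsets, in power-set order.
EMPTY: frozenset[str] = frozenset()
IMG = frozenset({"img"})
TAB = frozenset({"tab"})
BOTH = frozenset({"img", "tab"})
SUBSETS: tuple[frozenset[str], ...] = (EMPTY, IMG, TAB, BOTH)


@dataclass
class SubsetPredictions:
    """GPR predictions keyed by modality subset; exactly four entries."""

    by_subset: dict[frozenset[str], np.ndarray]

    def __post_init__(self) -> None:
        if set(self.by_subset) != set(SUBSETS):
            raise ValueError("by_subset must cover exactly the four subsets")
        for s, v in self.by_subset.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite prediction for subset {set(s)}")

    def __getitem__(self, subset: frozenset[str]) -> np.ndarray:
        return self.by_subset[subset]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``n_tab_channels`` must be strictly smaller than ``n_img_channels``
    (the dose-difference path is meant to be image-dominated).
    """

    grid: tuple[int, int] = (64, 64)
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128)  # stride 2 each
    n_tab_channels: int = 2
    tab_hidden: int = 64
    fused_width: int = 512                 # D_f; matches the head width
    decoder_channels: tuple[int, ...] = (96, 48, 24, 16, 8)
    dropout: float = 0.1
    pool_tabular: bool = True
    bias: bool = True

    def __post_init__(self) -> None:
        if self.n_tab_channels >= self.n_img_channels:
            raise ValueError(
                f"n_tab_channels ({self.n_tab_channels}) must be < "
                f"n_img_channels ({self.n_img_channels})"
            )
        h, w = self.grid
        s = 2 ** len(self.encoder_channels)
        if h % s or w % s:
            raise ValueError("grid must be divisible by the encoder stride")
        n_up = len(self.decoder_channels) - 1
        if (h // s) * 2**n_up != h:
            raise ValueError(
                f"decoder schedule of length {len(self.decoder_channels)} "
                f"cannot upsample {h // s} back to {h}"
            )

    @property
    def n_img_channels(self) -> int:
        return self.encoder_channels[-1]

    @classmethod
    def full_scale(cls) -> "NetworkConfig":
        """Clinical-resolution preset: 512x512 grid, 512-wide head and the
        [768, 384, 192, 128, 32] decoder schedule."""
        return cls(
            grid=(512, 512),
            encoder_channels=(64, 128, 256, 512),
            n_tab_channels=2,
            fused_width=512,
            decoder_channels=(768, 384, 192, 128, 32),
        )

    @property
    def latent_hw(self) -> tuple[int, int]:
        s = 2 ** len(self.encoder_channels)
        return self.grid[0] // s, self.grid[1] // s


class ImageEncoder(Module):
    """Strided conv stack: (B, 1, H, W) -> (B, N_c, H_z, W_z).

    Pluggable contract: any module producing N_c x H_z x W_z feature maps
    is admissible in its place.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = (1,) + tuple(cfg.encoder_channels)
        self.stages = [
            Conv2d(chans[i], chans[i + 1], 3, rng, stride=2, padding=1,
                   bias=cfg.bias)
            for i in range(len(cfg.encoder_channels))
        ]
        self.n_calls = 0

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != 1 \
                or x.data.shape[2:] != self.cfg.grid:
            raise ValueError(
                f"expected (B, 1, {self.cfg.grid[0]}, {self.cfg.grid[1]}), "
                f"got {x.data.shape}"
            )
        self.n_calls += 1
        for stage in self.stages:
            x = stage(x).relu()
        return x


class TabularEncoder(Module):
    """MLP: (B, 33) -> (B, N_t * H_z * W_z)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        hz, wz = cfg.latent_hw
        out_dim = cfg.n_tab_channels * hz * wz
        self.fc1 = Linear(33, cfg.tab_hidden, rng, bias=cfg.bias)
        self.fc2 = Linear(cfg.tab_hidden, out_dim, rng, bias=cfg.bias)
        self.n_calls = 0

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 2 or x.data.shape[1] != 33:
            raise ValueError(f"expected (B, 33) input, got {x.data.shape}")
        self.n_calls += 1
        return self.fc2(self.fc1(x).relu())


class GPRFusion(Module):
    """Attention fusion for the GPR task (score projections + embedding
    projections to the fused width)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        hz, wz = cfg.latent_hw
        tab_dim = (
            cfg.n_tab_channels if cfg.pool_tabular
            else cfg.n_tab_channels * hz * wz
        )
        self.score_img = Linear(cfg.n_img_channels, 1, rng, bias=False)
        self.score_tab = Linear(tab_dim, 1, rng, bias=False)
        self.proj_img = Linear(cfg.n_img_channels, cfg.fused_width, rng, bias=False)
        self.proj_tab = Linear(tab_dim, cfg.fused_width, rng, bias=False)

    def _pool(self, z_img: Tensor, z_tab: Tensor) -> tuple[Tensor, Tensor]:
        pooled_img = z_img.mean(axis=(2, 3))  # global average pooling
        if self.cfg.pool_tabular:
            hz, wz = self.cfg.latent_hw
            b = z_tab.data.shape[0]
            pooled_tab = z_tab.reshape(
                b, self.cfg.n_tab_channels, hz * wz
            ).mean(axis=2)
        else:
            pooled_tab = z_tab
        return pooled_img, pooled_tab

    def attention(self, z_img: Tensor, z_tab: Tensor) -> tuple[Tensor, Tensor]:
        """Softmax attention weights over the two modality scores."""
        pooled_img, pooled_tab = self._pool(z_img, z_tab)
        s_img = self.score_img(pooled_img)   # (B, 1)
        s_tab = self.score_tab(pooled_tab)   # (B, 1)
        # softmax over two scores via the logistic form (stable for large
        # score gaps): alpha_img = 1 / (1 + exp(s_tab - s_img))
        alpha_img = Tensor(1.0) / ((s_tab - s_img).exp() + 1.0)
        alpha_tab = Tensor(1.0) - alpha_img
        return alpha_img, alpha_tab

    def __call__(self, z_img: Tensor, z_tab: Tensor,
                 subset: frozenset[str] = BOTH) -> Tensor:
        if subset not in SUBSETS:
            raise ValueError(f"unknown modality subset {subset!r}")
        b = z_img.data.shape[0] if "img" in subset or subset == EMPTY \
            else z_tab.data.shape[0]
        if subset == EMPTY:
            return Tensor(np.zeros((b, self.cfg.fused_width)))
        pooled_img, pooled_tab = self._pool(z_img, z_tab)
        if subset == IMG:
            return self.proj_img(pooled_img)
        if subset == TAB:
            return self.proj_tab(pooled_tab)
        alpha_img, alpha_tab = self.attention(z_img, z_tab)
        return alpha_img * self.proj_img(pooled_img) \
            + alpha_tab * self.proj_tab(pooled_tab)


class GPRHead(Module):
    """ReLU -> dropout (train only) -> affine D_f -> 3."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.fc = Linear(cfg.fused_width, 3, rng, bias=True)

    def __call__(self, z: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if z.data.shape[1] != self.cfg.fused_width:
            raise ValueError(
                f"expected width {self.cfg.fused_width}, got {z.data.shape[1]}"
            )
        out = z.relu()
        if train:
            if rng is None:
                raise ValueError("training forward needs a dropout rng")
            out = dropout(out, self.cfg.dropout, rng, train=True)
        return self.fc(out)

    def set_bias(self, bias: np.ndarray) -> None:
        self.fc.bias.data = np.asarray(bias, dtype=np.float64).copy()


def fuse_ddp(z_img: Tensor, z_tab: Tensor, n_tab_channels: int,
             latent_hw: tuple[int, int]) -> Tensor:
    """Fold z_tab to (B, N_t, H_z, W_z) row-major and concatenate with the
    image feature maps along channels, tabular channels first."""
    hz, wz = latent_hw
    b = z_tab.data.shape[0]
    if z_tab.data.shape[1] != n_tab_channels * hz * wz:
        raise ValueError(
            f"tabular embedding length {z_tab.data.shape[1]} is not "
            f"N_t*H_z*W_z = {n_tab_channels * hz * wz}"
        )
    folded = z_tab.reshape(b, n_tab_channels, hz, wz)
    return concat([folded, z_img], axis=1)


class DDPDecoder(Module):
    """Upsampling conv stack decoding the concatenated feature maps to a
    1-channel dose-difference map at input resolution (no encoder skips)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        in_ch = cfg.n_img_channels + cfg.n_tab_channels
        chans = (in_ch,) + tuple(cfg.decoder_channels)
        self.stages = [
            Conv2d(chans[i], chans[i + 1], 3, rng, stride=1, padding=1,
                   bias=cfg.bias)
            for i in range(len(cfg.decoder_channels))
        ]
        self.head = Conv2d(cfg.decoder_channels[-1], 1, 1, rng, bias=True)

    def __call__(self, z_ddp: Tensor) -> Tensor:
        expected = self.cfg.n_img_channels + self.cfg.n_tab_channels
        if z_ddp.data.shape[1] != expected:
            raise ValueError(
                f"expected {expected} channels, got {z_ddp.data.shape[1]}"
            )
        x = self.stages[0](z_ddp).relu()
        for stage in self.stages[1:]:
            x = stage(upsample2x(x)).relu()
        out = self.head(x)
        b = out.data.shape[0]
        return out.reshape(b, *self.cfg.grid)


class QAModel(Module):
    """Full dual-task model with shared encoders.

    Tabular inputs are standardized with statistics fixed at fit time
    (identity until :meth:`set_tab_stats` is called).
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.image_encoder = ImageEncoder(cfg, rng)
        self.tabular_encoder = TabularEncoder(cfg, rng)
        self.fusion = GPRFusion(cfg, rng)
        self.gpr_head = GPRHead(cfg, rng)
        self.decoder = DDPDecoder(cfg, rng)
        self.tab_mean = np.zeros(33)
        self.tab_std = np.ones(33)

    def set_tab_stats(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.tab_mean = np.asarray(mean, dtype=np.float64).copy()
        self.tab_std = np.where(np.asarray(std) > 0, std, 1.0).astype(np.float64)

    def encode(self, x_img: np.ndarray, x_tab: np.ndarray
               ) -> tuple[Tensor, Tensor]:
        """One encoder invocation per modality; inputs are raw arrays
        (B, H, W) and (B, 33)."""
        img = Tensor(np.asarray(x_img, dtype=np.float64)[:, None, :, :])
        tab = Tensor((np.asarray(x_tab, dtype=np.float64) - self.tab_mean)
                     / self.tab_std)
        return self.image_encoder(img), self.tabular_encoder(tab)

    def predict_gpr(self, z_img: Tensor, z_tab: Tensor,
                    subset: frozenset[str] = BOTH, train: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        return self.gpr_head(self.fusion(z_img, z_tab, subset), train=train,
                             rng=rng)

    def predict_ddp(self, z_img: Tensor, z_tab: Tensor) -> Tensor:
        z = fuse_ddp(z_img, z_tab, self.cfg.n_tab_channels, self.cfg.latent_hw)
        return self.decoder(z)


def multi_subset_forward(model: QAModel, x_img: np.ndarray,
                         x_tab: np.ndarray) -> SubsetPredictions:
    """GPR predictions for all four modality subsets from a single pair of
    encoder invocations (eval mode, dropout off).

    Bit-identical to four independent forward passes sharing weights,
    because each subset reuses the same encoder outputs.
    """
    z_img, z_tab = model.encode(x_img, x_tab)
    preds = {
        s: model.predict_gpr(z_img, z_tab, subset=s, train=False).data.copy()
        for s in SUBSETS
    }
    return SubsetPredictions(preds)


__all__ = [
    "EMPTY", "IMG", "TAB", "BOTH", "SUBSETS",
    "SubsetPredictions", "NetworkConfig", "ImageEncoder", "TabularEncoder",
    "GPRFusion", "GPRHead", "fuse_ddp", "DDPDecoder", "QAModel",
    "multi_subset_forward", "Adam",
]
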