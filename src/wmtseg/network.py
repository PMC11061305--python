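"""Segmentation architectures: axial-attention U-Net and the dual-branch
coarse/fine fusion model.

The full model ("wmt") processes an image twice: a coarse branch partitions
it into 4 blocks of side I/2 and a fine branch into 16 blocks of side I/4.
Each block runs independently through a branch-specific U-Net backbone whose
encoder blocks are gated axial attention layers; block outputs are
reassembled at their original positions, the two branch feature maps are
summed, and a 1x1 convolution produces the single-channel mask logits.
Intra-block detail comes from the fine branch, inter-block boundary context
from the coarse branch.

``build_variant`` constructs every rung of the ablation ladder from one
config:

========================  ====================================================
variant                   architecture
========================  ====================================================
unet                      plain convolutional U-Net
unet_axial                U-Net, encoder convs replaced by axial attention
unet_weighted_axial       as above, with learnable positional gates
unet_coarse_fine          plain U-Net backbones in the dual-branch head
wmt                       gated axial backbones in the dual-branch head
========================  ====================================================
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from ._tensor import (
    Module,
    Parameter,
    Tensor,
    astensor,
    avg_pool2d,
    concat,
    conv2d,
    upsample2,
)
from .attention import AxialAttention2D

VARIANTS = ("unet", "unet_axial", "unet_weighted_axial", "unet_coarse_fine", "wmt")

__all__ = [
    "PatchGrid",
    "VariantConfig",
    "SegmentationOutput",
    "make_grid",
    "partition",
    "reassemble",
    "fuse",
    "build_variant",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]


# ---------------------------------------------------------------------------
# patch grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping square-block tiling of a square image."""

    image_side: int
    block_side: int
    grid_n: int
    origins: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.grid_n * self.block_side != self.image_side:
            raise ValueError(
                f"grid_n ({self.grid_n}) x block_side ({self.block_side}) "
                f"must equal image_side ({self.image_side})"
            )


def make_grid(image_side: int, granularity: str) -> PatchGrid:
    """Coarse grid: 4 blocks of side I/2.  Fine grid: 16 blocks of side I/4."""
    if granularity not in ("coarse", "fine"):
        raise ValueError(f"granularity must be 'coarse' or 'fine', got {granularity!r}")
    n = 2 if granularity == "coarse" else 4
    if image_side % 4:
        raise ValueError(
            f"image side {image_side} must be divisible by 4 for the "
            f"coarse/fine decomposition"
        )
    side = image_side // n
    origins = tuple((r * side, c * side) for r in range(n) for c in range(n))
    return PatchGrid(image_side, side, n, origins)


def partition(image, grid: PatchGrid) -> list[Tensor]:
    """Slice a (..., H, W) map into row-major blocks (differentiable)."""
    image = astensor(image)
    H, W = image.shape[-2:]
    if H != grid.image_side or W != grid.image_side:
        raise ValueError(
            f"image spatial size {(H, W)} does not match grid side {grid.image_side}"
        )
    s = grid.block_side
    return [image[..., r:r + s, c:c + s] for r, c in grid.origins]


def reassemble(blocks, grid: PatchGrid) -> Tensor:
    """Place blocks back at their recorded origins (inverse of partition)."""
    blocks = [astensor(b) for b in blocks]
    if len(blocks) != grid.grid_n**2:
        raise ValueError(
            f"expected {grid.grid_n ** 2} blocks for a {grid.grid_n}x{grid.grid_n} "
            f"grid, got {len(blocks)}"
        )
    s = grid.block_side
    for b in blocks:
        if b.shape[-2:] != (s, s):
            raise ValueError(f"block shape {b.shape[-2:]} != ({s}, {s})")
    n = grid.grid_n
    rows = [concat(blocks[r * n:(r + 1) * n], axis=-1) for r in range(n)]
    return concat(rows, axis=-2)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class VariantConfig:
    """Which architecture rung to build, and its size hyperparameters."""

    variant: str = "wmt"
    input_side: int = 128
    base_channels: int = 16
    depth: int = 4
    heads: int = 1
    seed: int = 0
    logit_scaling: bool = False
    relative_tables: bool = True
    share_branch_weights: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid names: {', '.join(VARIANTS)}"
            )
        if self.input_side % 4:
            raise ValueError(f"input_side {self.input_side} must be divisible by 4")
        side = self.input_side
        if self.variant in ("unet_coarse_fine", "wmt"):
            side = self.input_side // 4   # fine blocks are the smallest unit
        if side % (2**self.depth):
            raise ValueError(
                f"side {side} (fine-block side for dual-branch variants) must be "
                f"divisible by 2^depth = {2 ** self.depth}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VariantConfig":
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Pre-sigmoid logits and the matching probability map (B, 1, H, W)."""

    logits: Tensor
    prob_map: Tensor

    @property
    def prob(self) -> np.ndarray:
        return self.prob_map.data

    def mask(self, threshold: float = 0.5) -> np.ndarray:
        return (self.prob_map.data >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _he(rng, *shape):
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, (2.0 / max(fan_in, 1)) ** 0.5, size=shape)


class Conv2D(Module):
    def __init__(self, c_in, c_out, k, rng, padding=None):
        self.w = Parameter(_he(rng, c_out, c_in, k, k))
        self.b = Parameter(np.zeros(c_out))
        self.padding = (k // 2) if padding is None else padding

    def forward(self, x):
        return conv2d(x, self.w, self.b, padding=self.padding)


class ConvBlock(Module):
    """Double 3x3 convolution + ReLU, the classic U-Net block."""

    def __init__(self, c_in, c_out, side, rng, **_):
        self.c1 = Conv2D(c_in, c_out, 3, rng)
        self.c2 = Conv2D(c_out, c_out, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


class AxialBlock(Module):
    """Encoder block with a 2-D axial attention layer in place of the convs."""

    def __init__(self, c_in, c_out, side, rng, gated=True, heads=1,
                 relative=True, scale_logits=False):
        self.attn = AxialAttention2D(c_in, c_out, side, side, rng, gated=gated,
                                     heads=heads, relative=relative,
                                     scale_logits=scale_logits)
        self.proj = Conv2D(c_out, c_out, 1, rng)

    def forward(self, x):
        return self.proj(self.attn(x).relu()).relu()


class UNet(Module):
    """Encoder-decoder with skip connections.

    ``block_cls`` builds the encoder blocks (conv or axial); the decoder is
    always convolutional (upsample + concat skip + double conv).  With
    ``head=True`` the output is single-channel mask logits; with
    ``head=False`` the network returns a ``base``-channel feature map for
    use inside the dual-branch model.
    """

    def __init__(self, input_side, base, depth, rng, block_cls=ConvBlock,
                 head=True, **block_kw):
        self.input_side = input_side
        self.depth = depth
        chans = [base * 2**l for l in range(depth + 1)]
        self.enc = []
        side = input_side
        c_prev = 1
        for l in range(depth):
            self.enc.append(block_cls(c_prev, chans[l], side, rng, **block_kw))
            c_prev = chans[l]
            side //= 2
        self.bottleneck = block_cls(c_prev, chans[depth], side, rng, **block_kw)
        self.dec = []
        for l in reversed(range(depth)):
            self.dec.append(ConvBlock(chans[l + 1] + chans[l], chans[l], None, rng))
        self.head = Conv2D(base, 1, 1, rng) if head else None

    def forward(self, x):
        x = astensor(x)
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = avg_pool2d(x)
        x = self.bottleneck(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = concat([upsample2(x), skip], axis=1)
            x = block(x)
        if self.head is not None:
            x = self.head(x)
        return x


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def fuse(coarse_map, fine_map, head: Conv2D) -> SegmentationOutput:
    """Sum the two branch feature maps and apply the 1x1 convolution head."""
    coarse_map, fine_map = astensor(coarse_map), astensor(fine_map)
    if coarse_map.shape != fine_map.shape:
        raise ValueError(
            f"branch feature maps differ in shape: coarse {coarse_map.shape} "
            f"vs fine {fine_map.shape}"
        )
    logits = head(coarse_map + fine_map)
    return SegmentationOutput(logits=logits, prob_map=logits.sigmoid())


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------


class SingleBranchModel(Module):
    """Whole-image U-Net (the first three ablation rungs)."""

    def __init__(self, cfg: VariantConfig, rng, block_cls, **block_kw):
        self.cfg = cfg
        self.net = UNet(cfg.input_side, cfg.base_channels, cfg.depth, rng,
                        block_cls=block_cls, head=True, **block_kw)

    def forward(self, x) -> SegmentationOutput:
        x = _as_batch(x, self.cfg.input_side)
        logits = self.net(x)
        return SegmentationOutput(logits=logits, prob_map=logits.sigmoid())


class DualBranchModel(Module):
    """Coarse/fine patch branches, each a full per-block encoder-decoder."""

    def __init__(self, cfg: VariantConfig, rng, block_cls, **block_kw):
        self.cfg = cfg
        side = cfg.input_side
        self.coarse_grid = make_grid(side, "coarse")
        self.fine_grid = make_grid(side, "fine")
        self.coarse_net = UNet(side // 2, cfg.base_channels, cfg.depth, rng,
                               block_cls=block_cls, head=False, **block_kw)
        if cfg.share_branch_weights:
            if side // 2 != side // 4:
                # shared weights require shared positional-table sizes, which
                # only conv blocks satisfy; attention tables are size-bound
                if block_cls is not ConvBlock:
                    raise ValueError(
                        "share_branch_weights is only available for the "
                        "convolutional backbone (attention tables are bound "
                        "to the block side)"
                    )
            self.fine_net = self.coarse_net
        else:
            self.fine_net = UNet(side // 4, cfg.base_channels, cfg.depth, rng,
                                 block_cls=block_cls, head=False, **block_kw)
        self.fuse_head = Conv2D(cfg.base_channels, 1, 1, rng)

    def _branch(self, x, grid, net):
        blocks = partition(x, grid)
        stacked = concat(blocks, axis=0)          # fold blocks into the batch
        feats = net(stacked)
        B = x.shape[0]
        outs = [feats[i * B:(i + 1) * B] for i in range(len(blocks))]
        return reassemble(outs, grid)

    def forward(self, x) -> SegmentationOutput:
        x = _as_batch(x, self.cfg.input_side)
        coarse = self._branch(x, self.coarse_grid, self.coarse_net)
        fine = self._branch(x, self.fine_grid, self.fine_net)
        return fuse(coarse, fine, self.fuse_head)


def _as_batch(x, side: int) -> Tensor:
    x = astensor(x)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(1, *x.shape)
    if x.shape[-1] != side or x.shape[-2] != side:
        raise ValueError(
            f"model was built for {side}x{side} inputs, got {x.shape[-2:]}"
        )
    return x


def build_variant(cfg: VariantConfig):
    """Construct one rung of the ablation ladder from its config."""
    rng = np.random.default_rng(cfg.seed)
    kw = dict(heads=cfg.heads, relative=cfg.relative_tables,
              scale_logits=cfg.logit_scaling)
    if cfg.variant == "unet":
        return SingleBranchModel(cfg, rng, ConvBlock)
    if cfg.variant == "unet_axial":
        return SingleBranchModel(cfg, rng, AxialBlock, gated=False, **kw)
    if cfg.variant == "unet_weighted_axial":
        return SingleBranchModel(cfg, rng, AxialBlock, gated=True, **kw)
    if cfg.variant == "unet_coarse_fine":
        return DualBranchModel(cfg, rng, ConvBlock)
    if cfg.variant == "wmt":
        return DualBranchModel(cfg, rng, AxialBlock, gated=True, **kw)
    raise ValueError(  # unreachable: config validates on construction
        f"unknown variant {cfg.variant!r}; valid names: {', '.join(VARIANTS)}")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model) -> None:
    """Serialize parameters + embedded config YAML to one .npz archive."""
    state = model.state_dict()
    cfg_yaml = yaml.safe_dump(model.cfg.to_dict())
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(
            zlib.compress(cfg_yaml.encode()), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Rebuild the model recorded in a checkpoint and load its weights."""
    archive = np.load(path)
    cfg_yaml = zlib.decompress(archive["__config__"].tobytes()).decode()
    cfg = VariantConfig.from_dict(yaml.safe_load(cfg_yaml))
    model = build_variant(cfg)
    state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model
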