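"""Volumetric encoder-decoder mapping multi-angle projections to a 3D volume.

The stack of boundary-luminescence projections is treated as a single-channel
3D volume (views along the depth axis).  The encoder applies convolutional
blocks (3D conv + batch norm + LeakyReLU + max pool); two fully connected
layers re-mix the encoded features and reshape them to the output depth; the
decoder mirrors the encoder with zero-insertion upsampling + convolution
(i.e. transposed convolution) blocks, optional channel-attention
(dual-sampling) gates and optional resampled encoder skip connections.  The
output head is a nonnegative activation: ReLU by default, or a sigmoid
(suited to max-normalized targets, and immune to the dying-unit collapse a
final ReLU can suffer when the truth is mostly zero).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Adam, BatchNorm3d, ChannelAttention, Conv3d, Linear, Module


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The full-scale defaults map a (24, 128, 128) projection stack to a
    (7, 128, 128) volume through five encoder and five decoder blocks with a
    1024-wide bottleneck.  ``scaled_network_config`` gives a CPU-sized
    three-block variant.
    """

    in_views: int = 24
    in_size: int = 128
    out_depth: int = 7
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    kernel: int = 3
    bottleneck: int = 1024
    leaky_slope: float = 0.2
    skip_connections: bool = True
    dual_sampling: bool = True
    output_activation: str = "relu"   # "relu" or "sigmoid"
    dtype: str = "float32"

    def pool_schedule(self) -> list[tuple[int, int, int]]:
        """Spatial pooling is always (2,2); the view/depth axis pools by 2
        while it stays divisible (24 -> 12 -> 6 -> 3 for five blocks)."""
        sched = []
        d = self.in_views
        for _ in self.encoder_channels:
            fd = 2 if d % 2 == 0 and d > 1 else 1
            d //= fd
            sched.append((fd, 2, 2))
        return sched

    @property
    def base_size(self) -> int:
        b = self.in_size >> len(self.encoder_channels)
        if b << len(self.encoder_channels) != self.in_size or b < 1:
            raise ValueError(
                f"in_size {self.in_size} not divisible by 2^{len(self.encoder_channels)}")
        return b

    @property
    def encoded_depth(self) -> int:
        d = self.in_views
        for fd, _, _ in self.pool_schedule():
            d //= fd
        return d


def scaled_network_config(**overrides) -> NetworkConfig:
    """Three-block network for the 48 x 48, 12-view scaled-down conditions."""
    base = dict(in_views=12, in_size=48, out_depth=5,
                encoder_channels=(8, 16, 32), bottleneck=256,
                output_activation="sigmoid")
    base.update(overrides)
    return NetworkConfig(**base)


class EncDec3D(Module):
    """The encoder / FC bottleneck / decoder reconstruction network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        ch = config.encoder_channels
        self.enc_convs: list[Module] = []
        self.enc_bns: list[Module] = []
        c_prev = 1
        for c in ch:
            self.enc_convs.append(Conv3d(c_prev, c, config.kernel, rng=rng, dtype=dtype))
            self.enc_bns.append(BatchNorm3d(c, dtype=dtype))
            c_prev = c
        self.pools = config.pool_schedule()

        base = config.base_size
        enc_d = config.encoded_depth
        flat = ch[-1] * enc_d * base * base
        self.fc1 = Linear(flat, config.bottleneck, rng=rng, dtype=dtype)
        self.fc2 = Linear(config.bottleneck, ch[-1] * config.out_depth * base * base,
                          rng=rng, dtype=dtype)

        dec_in = list(ch[::-1])          # channels entering each decoder stage
        dec_out = list(ch[::-1][1:]) + [ch[0]]
        self.dec_convs: list[Module] = []
        self.dec_bns: list[Module] = []
        self.attn: list[Module] = []
        n_blocks = len(ch)
        for j, (ci, co) in enumerate(zip(dec_in, dec_out)):
            cin = ci
            if config.skip_connections:
                cin += ch[max(n_blocks - 2 - j, 0)]
            self.dec_convs.append(Conv3d(cin, co, config.kernel, rng=rng, dtype=dtype))
            self.dec_bns.append(BatchNorm3d(co, dtype=dtype))
            if config.dual_sampling:
                self.attn.append(ChannelAttention(ci, rng=rng, dtype=dtype))
        self.out_conv = Conv3d(dec_out[-1], 1, config.kernel, rng=rng, dtype=dtype)
        if config.output_activation == "sigmoid":
            # start the sigmoid head at the sparse-background prior so early
            # training refines targets instead of un-saturating a fog
            self.out_conv.b.data[:] = -3.0

    # ------------------------------------------------------------------
    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        feats = []
        h = x
        for conv, bn, pool in zip(self.enc_convs, self.enc_bns, self.pools):
            h = ag.leaky_relu(bn(conv(h)), cfg.leaky_slope)
            feats.append(h)
            h = ag.maxpool3d(h, pool)

        n = h.shape[0]
        h = ag.reshape(h, (n, -1))
        h = ag.leaky_relu(self.fc1(h), cfg.leaky_slope)
        h = self.fc2(h)
        base = cfg.base_size
        h = ag.reshape(h, (n, cfg.encoder_channels[-1], cfg.out_depth, base, base))

        n_blocks = len(cfg.encoder_channels)
        for j in range(n_blocks):
            if cfg.dual_sampling:
                h = self.attn[j](h)
            h = ag.zero_insert(h, (1, 2, 2))
            if cfg.skip_connections:
                skip = feats[max(n_blocks - 2 - j, 0)]
                skip = ag.resize_trilinear(skip, tuple(h.shape[2:]))
                h = ag.concat([h, skip], axis=1)
            h = ag.relu(self.dec_bns[j](self.dec_convs[j](h)))
        out = self.out_conv(h)
        # a sigmoid head suits max-normalized targets and cannot die the way
        # a final ReLU can when the truth is mostly zero
        if cfg.output_activation == "sigmoid":
            return ag.sigmoid(out)
        return ag.relu(out)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


def build_network(config: NetworkConfig, seed: int = 0) -> EncDec3D:
    """Construct the network; raises on shape-incompatible configurations."""
    _ = config.base_size  # validates divisibility
    return EncDec3D(config, seed=seed)


def network_config_to_json(config: NetworkConfig) -> dict:
    return asdict(config)


def network_config_from_json(d: dict) -> NetworkConfig:
    d = dict(d)
    d["encoder_channels"] = tuple(d["encoder_channels"])
    return NetworkConfig(**d)
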