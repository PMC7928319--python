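"""Segmentation network assembly.

Builds the U-shaped encoder-decoder family used throughout the ablations:

* plain U-Net (double 3x3 conv blocks) and a width-matched "wide U-Net",
* MSU-Net: every conv block replaced by a multi-scale block, with
  encoder-only / decoder-only placements,
* residual variants (Res MSU-Net 0/1) and fusion/serial/dilated variants,
* attention-gated U-Net (AttU-Net) and MSAttU-Net,
* nested dense-skip U-Net++ and MSU-Net++.

All networks map (B, C, H, W) image batches to per-pixel foreground
probabilities of identical spatial size (1x1 conv + sigmoid head); H and W
must be divisible by 2^(levels-1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import (KernelSpec, MSBlockConfig, _conv_params, build_block,
                     config_from_name, count_parameters)

__all__ = [
    "NetworkSpec", "UNet", "UNetPP", "AttentionGate",
    "build_network", "build_wide_unet", "count_network_parameters",
    "ARCHITECTURES", "network_from_name", "save_network", "load_network",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Assembly recipe for one architecture."""

    levels: int = 5
    base_width: int = 64
    width_multiplier: float = 1.0
    block: str = "plain"            # "plain" or a multi-scale block name ("37", "res0:37", ...)
    placement: str = "both"         # both | encoder_only | decoder_only
    upsampling: str = "transposed_conv"  # transposed_conv | bilinear
    skip_mode: str = "plain"        # plain | attention_gate | nested
    in_channels: int = 1
    out_classes: int = 1
    norm: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least two levels")
        if self.placement not in ("both", "encoder_only", "decoder_only"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.upsampling not in ("transposed_conv", "bilinear"):
            raise ValueError(f"unknown upsampling {self.upsampling!r}")
        if self.skip_mode not in ("plain", "attention_gate", "nested"):
            raise ValueError(f"unknown skip mode {self.skip_mode!r}")
        if self.width_multiplier <= 0:
            raise ValueError("width multiplier must be positive")

    def width(self, level: int) -> int:
        """Channel width at encoder level (0-based); doubles per level."""
        return max(1, round(self.base_width * self.width_multiplier * 2 ** level))


# ---------------------------------------------------------------------------
# building blocks shared by the assemblies
# ---------------------------------------------------------------------------

def _stage_block(spec: NetworkSpec, cin: int, cout: int, multiscale: bool) -> nn.Module:
    if multiscale and spec.block != "plain":
        return build_block(config_from_name(spec.block, cin, cout, norm=spec.norm))
    cfg = MSBlockConfig(kernels=(KernelSpec(3), KernelSpec(3)), in_channels=cin,
                        out_channels=cout, topology="serial", norm=spec.norm,
                        convs_per_branch=1, label="plain")
    return build_block(cfg)  # two chained 3x3 conv units = original U-Net block


def _stage_block_params(spec: NetworkSpec, cin: int, cout: int, multiscale: bool) -> int:
    if multiscale and spec.block != "plain":
        return count_parameters(config_from_name(spec.block, cin, cout, norm=spec.norm))
    return (_conv_params(cin, cout, 3, spec.norm)
            + _conv_params(cout, cout, 3, spec.norm))


class _Upsampler(nn.Module):
    """Doubles spatial dims; transposed-conv learns weights, bilinear is fixed."""

    def __init__(self, cin: int, cout: int, mode: str):
        super().__init__()
        self.mode = mode
        if mode == "transposed_conv":
            self.op = nn.ConvTranspose2d(cin, cout, kernel=2, stride=2)
            self.out_channels = cout
        else:
            self.op = nn.BilinearUpsample2d()
            self.out_channels = cin

    def forward(self, x):
        return self.op(x)


def _upsampler_params(cin: int, cout: int, mode: str) -> int:
    return 4 * cin * cout + cout if mode == "transposed_conv" else 0


class AttentionGate(nn.Module):
    """Additive attention gate modulating a skip feature with a coarser gate.

    Both inputs are projected to an intermediate width by 1x1 convolutions
    (the skip projection is average-pooled down to the gate resolution),
    summed, passed through ReLU, reduced to one channel, squashed by a
    sigmoid, and upsampled back to the skip resolution; the skip is scaled
    per pixel by the resulting coefficient in [0, 1].
    """

    def __init__(self, skip_channels: int, gate_channels: int, inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(1, skip_channels // 2)
        self.theta = nn.Conv2d(skip_channels, inter, 1, bias=False)
        self.phi = nn.Conv2d(gate_channels, inter, 1, bias=True)
        self.psi = nn.Conv2d(inter, 1, 1, bias=True)

    @staticmethod
    def _ratio(skip_hw, gate_hw) -> int:
        r = skip_hw[0] // gate_hw[0]
        if (r < 1 or skip_hw[0] != r * gate_hw[0] or skip_hw[1] != r * gate_hw[1]
                or (r & (r - 1)) != 0):
            raise ValueError(
                f"skip/gate spatial ratio must be a power of 2, got {skip_hw} vs {gate_hw}")
        return r

    def coefficients(self, skip: nn.Tensor, gate: nn.Tensor) -> nn.Tensor:
        r = self._ratio(skip.shape[2:], gate.shape[2:])
        t = self.theta(skip)
        while r > 1:
            t = nn.avg_pool2d(t, 2)
            r //= 2
        a = nn.sigmoid(self.psi(nn.relu(nn.add(t, self.phi(gate)))))
        while a.shape[2] < skip.shape[2]:
            a = nn.nearest_upsample2d(a, 2)
        return a

    def forward(self, skip: nn.Tensor, gate: nn.Tensor) -> nn.Tensor:
        return nn.mul(skip, self.coefficients(skip, gate))


def _attention_gate_params(skip_channels: int, gate_channels: int) -> int:
    inter = max(1, skip_channels // 2)
    return (skip_channels * inter) + (gate_channels * inter + inter) + (inter + 1)


# ---------------------------------------------------------------------------
# U-Net (plain skips or attention gates)
# ---------------------------------------------------------------------------

class UNet(nn.Module):
    def __init__(self, spec: NetworkSpec):
        super().__init__()
        if spec.skip_mode == "nested":
            raise ValueError("use UNetPP for nested skips")
        self.spec = spec
        L = spec.levels
        enc_ms = spec.placement in ("both", "encoder_only")
        dec_ms = spec.placement in ("both", "decoder_only")
        w = [spec.width(i) for i in range(L)]

        self.encoders = nn.ModuleList()
        cin = spec.in_channels
        for i in range(L):  # level L-1 is the bottleneck
            self.encoders.append(_stage_block(spec, cin, w[i], enc_ms))
            cin = w[i]
        self.pool = nn.MaxPool2d(2)

        self.ups = nn.ModuleList()
        self.decoders = nn.ModuleList()
        self.gates = nn.ModuleList() if spec.skip_mode == "attention_gate" else None
        for i in range(L - 2, -1, -1):
            up = _Upsampler(w[i + 1], w[i], spec.upsampling)
            self.ups.append(up)
            self.decoders.append(
                _stage_block(spec, w[i] + up.out_channels, w[i], dec_ms))
            if self.gates is not None:
                self.gates.append(AttentionGate(w[i], w[i + 1]))
        self.head = nn.Conv2d(w[0], spec.out_classes, 1)

    def _check_input(self, x):
        stride = 2 ** (self.spec.levels - 1)
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by {stride}")
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels")

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        self._check_input(x)
        skips = []
        for i, enc in enumerate(self.encoders):
            if i > 0:
                x = self.pool(x)
            x = enc(x)
            if i < len(self.encoders) - 1:
                skips.append(x)
        for j, (up, dec) in enumerate(zip(self.ups, self.decoders)):
            skip = skips[-1 - j]
            if self.gates is not None:
                skip = self.gates[j](skip, x)  # gate on the coarser feature
            x = dec(nn.concat([skip, up(x)], axis=1))
        return nn.sigmoid(self.head(x))


# ---------------------------------------------------------------------------
# U-Net++ (nested dense skips)
# ---------------------------------------------------------------------------

class UNetPP(nn.Module):
    """Nested grid: node (i, j) consumes the upsampled (i+1, j-1) feature
    concatenated with all previous same-row features (i, 0..j-1)."""

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        self.spec = spec
        L = spec.levels
        ms = spec.placement == "both"
        w = [spec.width(i) for i in range(L)]
        self.pool = nn.MaxPool2d(2)
        self.nodes = nn.ModuleList()
        self.ups = nn.ModuleList()
        cin = spec.in_channels
        for i in range(L):  # backbone column j=0
            self.nodes.append(_stage_block(spec, cin, w[i], ms))
            cin = w[i]
        for j in range(1, L):
            for i in range(L - j):
                up = _Upsampler(w[i + 1], w[i], spec.upsampling)
                self.ups.append(up)
                self.nodes.append(
                    _stage_block(spec, j * w[i] + up.out_channels, w[i], ms))
        self.head = nn.Conv2d(w[0], spec.out_classes, 1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        spec = self.spec
        L = spec.levels
        stride = 2 ** (L - 1)
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by {stride}")
        grid: dict[tuple[int, int], nn.Tensor] = {}
        node_it = iter(self.nodes)
        up_it = iter(self.ups)
        for i in range(L):
            inp = x if i == 0 else self.pool(grid[(i - 1, 0)])
            grid[(i, 0)] = next(node_it)(inp)
        for j in range(1, L):
            for i in range(L - j):
                up = next(up_it)(grid[(i + 1, j - 1)])
                cat = nn.concat([grid[(i, jj)] for jj in range(j)] + [up], axis=1)
                grid[(i, j)] = next(node_it)(cat)
        return nn.sigmoid(self.head(grid[(0, L - 1)]))


# ---------------------------------------------------------------------------
# construction and parameter accounting
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpec, seed: int | None = None) -> nn.Module:
    """Build a network; with ``seed`` the initial weights are reproducible."""
    if seed is not None:
        nn.manual_seed(seed)
    return UNetPP(spec) if spec.skip_mode == "nested" else UNet(spec)


def count_network_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count (no network is built)."""
    L = spec.levels
    w = [spec.width(i) for i in range(L)]
    total = 0
    if spec.skip_mode == "nested":
        ms = spec.placement == "both"
        cin = spec.in_channels
        for i in range(L):
            total += _stage_block_params(spec, cin, w[i], ms)
            cin = w[i]
        for j in range(1, L):
            for i in range(L - j):
                up_out = w[i] if spec.upsampling == "transposed_conv" else w[i + 1]
                total += _upsampler_params(w[i + 1], w[i], spec.upsampling)
                total += _stage_block_params(spec, j * w[i] + up_out, w[i], ms)
    else:
        enc_ms = spec.placement in ("both", "encoder_only")
        dec_ms = spec.placement in ("both", "decoder_only")
        cin = spec.in_channels
        for i in range(L):
            total += _stage_block_params(spec, cin, w[i], enc_ms)
            cin = w[i]
        for i in range(L - 2, -1, -1):
            up_out = w[i] if spec.upsampling == "transposed_conv" else w[i + 1]
            total += _upsampler_params(w[i + 1], w[i], spec.upsampling)
            total += _stage_block_params(spec, w[i] + up_out, w[i], dec_ms)
            if spec.skip_mode == "attention_gate":
                total += _attention_gate_params(w[i], w[i + 1])
    total += w[0] * spec.out_classes + spec.out_classes
    return total


def build_wide_unet(reference: nn.Module, tolerance: float = 0.10,
                    seed: int | None = None,
                    bounds: tuple[float, float] = (1.0, 8.0)):
    """Plain U-Net whose width multiplier is bisected so its parameter count
    is within ``tolerance`` of the reference network's.

    Returns ``(network, multiplier)``.
    """
    ref_spec: NetworkSpec = reference.spec
    target = reference.num_parameters()

    def plain(mult: float) -> NetworkSpec:
        return dataclasses.replace(
            ref_spec, block="plain", placement="both", skip_mode="plain",
            width_multiplier=mult)

    lo, hi = bounds
    if count_network_parameters(plain(lo)) > target:
        hi = lo  # reference is narrower than a plain net; clamp at lower bound
    elif count_network_parameters(plain(hi)) < target:
        raise ValueError("target parameter count unreachable within multiplier bounds")
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if count_network_parameters(plain(mid)) < target:
                lo = mid
            else:
                hi = mid
    best = min((count_network_parameters(plain(m)), m) for m in (lo, hi))
    rel = abs(best[0] - target) / target
    if rel > tolerance:
        raise ValueError(
            f"could not match parameter count within {tolerance:.0%} (best {rel:.1%})")
    return build_network(plain(best[1]), seed=seed), best[1]


# ---------------------------------------------------------------------------
# registry keyed by the names used in the ablation tables
# ---------------------------------------------------------------------------

def _spec_for(name: str, **overrides) -> NetworkSpec:
    key = name.lower()
    base: dict = {}
    if key == "unet":
        base = dict(block="plain")
    elif key == "attunet":
        base = dict(block="plain", skip_mode="attention_gate")
    elif key == "unetpp":
        base = dict(block="plain", skip_mode="nested")
    elif key == "msattunet":
        base = dict(block="37", skip_mode="attention_gate")
    elif key == "msunetpp":
        base = dict(block="37", skip_mode="nested")
    elif key == "msunet_encoder":
        base = dict(block="37", placement="encoder_only")
    elif key == "msunet_decoder":
        base = dict(block="37", placement="decoder_only")
    elif key == "res_msunet_0":
        base = dict(block="res0:37")
    elif key == "res_msunet_1":
        base = dict(block="res1:37")
    elif key == "msunet":
        base = dict(block="37")
    elif key.startswith("msunet:"):
        base = dict(block=name.split(":", 1)[1])
    else:
        raise KeyError(f"unknown architecture {name!r}")
    base.update(overrides)
    return NetworkSpec(**base)


ARCHITECTURES = ("unet", "wide_unet", "msunet", "msunet_encoder", "msunet_decoder",
                 "res_msunet_0", "res_msunet_1", "attunet", "msattunet",
                 "unetpp", "msunetpp")


def network_from_name(name: str, seed: int | None = None, **overrides) -> nn.Module:
    """Build a registered architecture ("msunet:NAME" selects the block).

    "wide_unet" solves its width against an "msunet" reference built with the
    same overrides.
    """
    if name.lower() == "wide_unet":
        ref = network_from_name("msunet", seed=seed, **overrides)
        net, _ = build_wide_unet(ref, seed=seed)
        return net
    return build_network(_spec_for(name, **overrides), seed=seed)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_network(net: nn.Module, path) -> None:
    """Single-file checkpoint: weights plus the embedded NetworkSpec."""
    state = net.state_dict()
    state["__spec__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(net.spec)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_network(path) -> nn.Module:
    with np.load(path) as data:
        spec = NetworkSpec(**json.loads(bytes(data["__spec__"]).decode()))
        net = build_network(spec)
        net.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return net
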