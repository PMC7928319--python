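"""Multi-scale convolution blocks.

A multi-scale block runs several branches of stacked convolutions with
different receptive fields over the *same* input, fuses the branch outputs
(channel concatenation by default, elementwise sum as a variant), and reduces
the fused features back to the target width with a 1x1 convolution:

    x1 = conv_k1(conv_k1(x))        # branch with kernel k1
    x2 = conv_k2(conv_k2(x))        # branch with kernel k2
    X  = Cat[x1, x2]                # fusion
    F  = conv_1x1(X)                # reduction

Kernel sizes are drawn from {1, 2, 3, 5, 7, 9}; the canonical family is every
combination of the 3x3 kernel with a subset of the remaining five sizes,
giving 31 parallel blocks.  Variants cover sum fusion, serial (chained)
arrangement of two kernels, a dilated substitution for the 7x7 branch, and
two residual wirings.

Every convolution is followed by batch normalization and ReLU by default
(``norm=False`` recovers bare conv+ReLU in the style of the original U-Net).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from . import nn

VALID_KERNEL_SIZES = (1, 2, 3, 5, 7, 9)

FUSION_MODES = ("concat", "sum")
TOPOLOGIES = ("parallel", "serial")
RESIDUAL_MODES = ("none", "additive_0", "concat_1")


@dataclass(frozen=True)
class KernelSpec:
    """A square convolution kernel: side length and dilation rate."""

    size: int
    dilation: int = 1

    def __post_init__(self):
        if self.size not in VALID_KERNEL_SIZES:
            raise ValueError(f"kernel size {self.size} not in {VALID_KERNEL_SIZES}")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")

    @property
    def receptive_width(self) -> int:
        """Effective width: dilation*(size-1)+1."""
        return self.dilation * (self.size - 1) + 1


@dataclass(frozen=True)
class MSBlockConfig:
    """Complete description of one multi-scale block variant."""

    kernels: tuple[KernelSpec, ...]
    in_channels: int
    out_channels: int
    fusion: str = "concat"
    topology: str = "parallel"
    residual: str = "none"
    convs_per_branch: int = 2
    norm: bool = True
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.kernels:
            raise ValueError("kernels must be non-empty")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.residual not in RESIDUAL_MODES:
            raise ValueError(f"unknown residual mode {self.residual!r}")
        if self.topology == "serial" and len(self.kernels) != 2:
            raise ValueError("serial topology requires exactly two kernel specs")
        if self.residual != "none" and self.topology != "parallel":
            raise ValueError("residual wiring is only defined for parallel blocks")
        if min(self.in_channels, self.out_channels, self.convs_per_branch) < 1:
            raise ValueError("channel and depth counts must be positive")

    @property
    def name(self) -> str:
        if self.label is not None:
            return self.label
        return "".join(str(k.size) for k in self.kernels)


# ---------------------------------------------------------------------------
# enumeration of the canonical parallel family
# ---------------------------------------------------------------------------

def enumerate_block_configs(in_channels: int = 64, out_channels: int = 64,
                            norm: bool = True) -> list[MSBlockConfig]:
    """All 31 parallel multi-scale blocks: {3} plus each non-empty subset of
    {1, 2, 5, 7, 9}, named by their sorted kernel digits ("37", "123579", ...).
    """
    others = [1, 2, 5, 7, 9]
    configs = []
    for r in range(1, len(others) + 1):
        for combo in itertools.combinations(others, r):
            sizes = tuple(sorted(combo + (3,)))
            configs.append(MSBlockConfig(
                kernels=tuple(KernelSpec(s) for s in sizes),
                in_channels=in_channels, out_channels=out_channels, norm=norm))
    configs.sort(key=lambda c: (len(c.kernels), c.name))
    return configs


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _conv_unit(cin: int, cout: int, kernel: KernelSpec, norm: bool) -> nn.Sequential:
    layers = [nn.Conv2d(cin, cout, kernel.size, dilation=kernel.dilation)]
    if norm:
        layers.append(nn.BatchNorm2d(cout))
    layers.append(nn.ReLU())
    return nn.Sequential(*layers)


def build_conv_branch(kernel: KernelSpec, in_channels: int, out_channels: int,
                      convs_per_branch: int = 2, norm: bool = True) -> nn.Sequential:
    """One branch: `convs_per_branch` stacked same-padded convolutions of the
    given kernel (first in->out, rest out->out), each conv+[BN]+ReLU."""
    units = [_conv_unit(in_channels, out_channels, kernel, norm)]
    for _ in range(convs_per_branch - 1):
        units.append(_conv_unit(out_channels, out_channels, kernel, norm))
    return nn.Sequential(*units)


class MultiScaleBlock(nn.Module):
    """Parallel multi-scale block with optional residual wiring.

    residual="concat_1": the raw input joins the branch outputs in the fused
    concatenation before the 1x1 reduction.
    residual="additive_0": the reduced output is summed with the input
    (1x1-projected when channel widths differ); no activation follows the
    addition so a zero block path is an exact identity.
    """

    def __init__(self, cfg: MSBlockConfig):
        super().__init__()
        if cfg.topology != "parallel":
            raise ValueError("MultiScaleBlock implements parallel topology only")
        self.cfg = cfg
        self.branches = nn.ModuleList([
            build_conv_branch(k, cfg.in_channels, cfg.out_channels,
                              cfg.convs_per_branch, cfg.norm)
            for k in cfg.kernels])
        fused = cfg.out_channels if cfg.fusion == "sum" else len(cfg.kernels) * cfg.out_channels
        if cfg.residual == "concat_1":
            fused += cfg.in_channels
        self.fuse = _conv_unit(fused, cfg.out_channels, KernelSpec(1), cfg.norm)
        if cfg.residual == "additive_0" and cfg.in_channels != cfg.out_channels:
            self.project = nn.Conv2d(cfg.in_channels, cfg.out_channels, 1)
        else:
            self.project = nn.Identity()

    @property
    def fusion_conv(self) -> nn.Conv2d:
        """The 1x1 reduction convolution applied after fusion."""
        return self.fuse.layers[0]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        outs = [branch(x) for branch in self.branches]
        if self.cfg.fusion == "sum":
            fused = outs[0]
            for o in outs[1:]:
                fused = nn.add(fused, o)
        else:
            fused = nn.concat(outs, axis=1) if len(outs) > 1 else outs[0]
        if self.cfg.residual == "concat_1":
            fused = nn.concat([x, fused], axis=1)
        out = self.fuse(fused)
        if self.cfg.residual == "additive_0":
            out = nn.add(out, self.project(x))
        return out


class SerialBlock(nn.Module):
    """Two kernel stages chained in series (no parallel split, no 1x1 fusion):
    two convs of the first kernel, then two convs of the second."""

    def __init__(self, cfg: MSBlockConfig):
        super().__init__()
        if cfg.topology != "serial":
            raise ValueError("SerialBlock requires serial topology")
        self.cfg = cfg
        k1, k2 = cfg.kernels
        self.stage1 = build_conv_branch(k1, cfg.in_channels, cfg.out_channels,
                                        cfg.convs_per_branch, cfg.norm)
        self.stage2 = build_conv_branch(k2, cfg.out_channels, cfg.out_channels,
                                        cfg.convs_per_branch, cfg.norm)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.stage2(self.stage1(x))


def multiscale_forward(x: nn.Tensor, cfg: MSBlockConfig) -> nn.Tensor:
    """Build a block for ``cfg`` and run one forward pass (convenience)."""
    return build_block(cfg)(x)


def serial_forward(x: nn.Tensor, order, in_channels: int, out_channels: int,
                   norm: bool = True) -> nn.Tensor:
    cfg = MSBlockConfig(kernels=tuple(order), in_channels=in_channels,
                        out_channels=out_channels, topology="serial", norm=norm)
    return SerialBlock(cfg)(x)


def build_block(cfg: MSBlockConfig) -> nn.Module:
    if cfg.topology == "serial":
        return SerialBlock(cfg)
    return MultiScaleBlock(cfg)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def dilated_variant(cfg: MSBlockConfig) -> MSBlockConfig:
    """Replace the 7x7 branch with a 3x3 kernel at dilation 3 (same effective
    receptive width of 7, far fewer weights)."""
    if not any(k.size == 7 and k.dilation == 1 for k in cfg.kernels):
        raise ValueError("dilated variant requires a dense 7x7 branch")
    kernels = tuple(KernelSpec(3, 3) if (k.size == 7 and k.dilation == 1) else k
                    for k in cfg.kernels)
    return replace(cfg, kernels=kernels, label=cfg.name + "+dilated")


# ---------------------------------------------------------------------------
# parameter counting (closed form, independent of construction)
# ---------------------------------------------------------------------------

def _conv_params(cin: int, cout: int, k: int, norm: bool) -> int:
    n = k * k * cin * cout + cout          # weights + bias
    if norm:
        n += 2 * cout                      # BN affine scale and shift
    return n


def count_parameters(cfg: MSBlockConfig) -> int:
    """Exact number of trainable scalars in the block described by ``cfg``."""
    total = 0
    if cfg.topology == "serial":
        k1, k2 = cfg.kernels
        total += _conv_params(cfg.in_channels, cfg.out_channels, k1.size, cfg.norm)
        for _ in range(cfg.convs_per_branch - 1):
            total += _conv_params(cfg.out_channels, cfg.out_channels, k1.size, cfg.norm)
        for _ in range(cfg.convs_per_branch):
            total += _conv_params(cfg.out_channels, cfg.out_channels, k2.size, cfg.norm)
        return total
    for k in cfg.kernels:
        total += _conv_params(cfg.in_channels, cfg.out_channels, k.size, cfg.norm)
        for _ in range(cfg.convs_per_branch - 1):
            total += _conv_params(cfg.out_channels, cfg.out_channels, k.size, cfg.norm)
    fused = cfg.out_channels if cfg.fusion == "sum" else len(cfg.kernels) * cfg.out_channels
    if cfg.residual == "concat_1":
        fused += cfg.in_channels
    total += _conv_params(fused, cfg.out_channels, 1, cfg.norm)
    if cfg.residual == "additive_0" and cfg.in_channels != cfg.out_channels:
        total += _conv_params(cfg.in_channels, cfg.out_channels, 1, norm=False)
    return total


# ---------------------------------------------------------------------------
# string-addressable factory
# ---------------------------------------------------------------------------

def config_from_name(name: str, in_channels: int, out_channels: int,
                     norm: bool = True) -> MSBlockConfig:
    """Parse a block name into a config.

    Grammar: ``[res0:|res1:]DIGITS[+sum|+concatenated|+dilated]`` where DIGITS
    are kernel sizes, e.g. "37", "37+sum", "73+concatenated", "37+dilated",
    "res0:37", "res1:37", "123579".
    """
    base = name
    residual = "none"
    if base.startswith("res0:"):
        residual, base = "additive_0", base[5:]
    elif base.startswith("res1:"):
        residual, base = "concat_1", base[5:]
    digits, plus, suffix = base.partition("+")
    if not digits.isdigit() or not digits:
        raise ValueError(f"cannot parse block name {name!r}")
    kernels = tuple(KernelSpec(int(d)) for d in digits)
    common = dict(in_channels=in_channels, out_channels=out_channels,
                  norm=norm, residual=residual, label=name)
    if not plus:
        return MSBlockConfig(kernels=kernels, **common)
    if suffix == "sum":
        return MSBlockConfig(kernels=kernels, fusion="sum", **common)
    if suffix == "concatenated":
        if residual != "none":
            raise ValueError("serial blocks have no residual form")
        return MSBlockConfig(kernels=kernels, topology="serial", **common)
    if suffix == "dilated":
        cfg = MSBlockConfig(kernels=kernels, **common)
        return replace(dilated_variant(cfg), label=name)
    raise ValueError(f"unknown block variant suffix {suffix!r} in {name!r}")


def make_block(name: str, in_channels: int, out_channels: int,
               norm: bool = True) -> nn.Module:
    """Build a block module addressable by its ablation-table name."""
    return build_block(config_from_name(name, in_channels, out_channels, norm))
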