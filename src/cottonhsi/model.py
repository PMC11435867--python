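"""The multi-branch hierarchical-residual patch classifier.

Architecture (default configuration, a 9x9x16 input patch):

* ``Conv0``: one valid (unpadded) k x k convolution, d -> C0 channels
  (9x9x16 with k=3 gives 7x7x64).
* First hierarchical residual block: four convolutional branches
  ``C1..C4``, each a chain of ``blocks_per_branch`` BN-ReLU-Conv units
  (pre-activation, channel- and spatial-preserving). Branch inputs chain:
  ``y1 = C1(xn)``, ``y_i = C_i(xn + y_{i-1})``; the block output is the
  elementwise sum ``xp = xn + y1 + y2 + y3 + y4``.
* Second hierarchical residual block on ``xp``: ``y6 = C6(xp)`` (k x k
  units) and ``y7 = C7(xp + y6)`` (1x1 units); output ``Y = xp + y6 + y7``.
* The two block outputs are concatenated along channels (2*C0 = 128),
  recalibrated by a squeeze-and-excitation gate, globally average-pooled
  and classified by a fully connected head.

With every convolution weight at zero each branch maps to zero, so both
hierarchical blocks collapse to the identity — the residual paths carry
the signal unimpeded, which is what makes the deep stack trainable.

Ablation variants keep the same machinery: ``dhr_only`` removes the SE
gate; ``first_block_only`` keeps only the first hierarchical block (SE on
C0 channels); ``single_multibranch`` replaces the two chained blocks by a
single block with the same inventory of convolutional branches (five k x k
plus one 1x1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import BatchNorm2d, Conv2d, Linear, ReLU, SEBlock, Sequential

__all__ = [
    "ModelConfig",
    "MJHResNet",
    "count_parameters",
    "parameter_breakdown",
    "layer_trace",
    "model_summary",
]

VARIANTS = ("full", "dhr_only", "first_block_only", "single_multibranch")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``kernel`` applies to Conv0 and all k x k branch units (the final
    branch of a block always uses 1x1 units). ``se_reduction`` must divide
    the SE input channel count. Biases are off on convolutions that feed
    batch norm and on the SE bottleneck, on for the classification head.
    """

    in_bands: int = 16
    patch_size: int = 9
    channels: int = 64
    kernel: int = 3
    blocks_per_branch: int = 6
    se_reduction: int = 16
    n_classes: int = 9
    variant: str = "full"
    conv_bias: bool = False
    se_bias: bool = False
    fc_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.patch_size < self.kernel:
            raise ValueError("patch size must be at least the kernel size")
        feat = self.feature_channels
        if feat % self.se_reduction != 0:
            raise ValueError(
                f"se_reduction {self.se_reduction} must divide the SE input channels ({feat})"
            )

    @property
    def feature_channels(self) -> int:
        """Channel count entering the SE gate / pooling stage."""
        return 2 * self.channels if self.variant in ("full", "dhr_only") else self.channels

    @property
    def use_se(self) -> bool:
        return self.variant != "dhr_only"


def _branch(c: int, k: int, n_units: int, bias: bool, rng) -> Sequential:
    """A chain of ``n_units`` BN-ReLU-Conv units, channel- and size-preserving."""
    layers = []
    for _ in range(n_units):
        layers += [BatchNorm2d(c), ReLU(), Conv2d(c, c, k, pad=k // 2, bias=bias, rng=rng)]
    return Sequential(layers)


def _hier_forward(x: np.ndarray, branches: list, train: bool) -> tuple:
    """y_1 = B_1(x); y_i = B_i(x + y_{i-1}); returns (x + sum(y_i), ys)."""
    ys = []
    acc = x.copy()
    prev = None
    for branch in branches:
        a = x if prev is None else x + prev
        y = branch.forward(a, train)
        ys.append(y)
        acc += y
        prev = y
    return acc, ys


def _hier_backward(dout: np.ndarray, branches: list) -> np.ndarray:
    """Backward of :func:`_hier_forward` given the gradient of the block sum."""
    dys = [dout.copy() for _ in branches]
    dx = dout.copy()
    for i in range(len(branches) - 1, -1, -1):
        da = branches[i].backward(dys[i])
        dx += da
        if i > 0:
            dys[i - 1] += da
    return dx


class MJHResNet:
    """The patch classifier: Conv0 -> hierarchical residual blocks -> SE -> head.

    Operates on NCHW float32 batches; ``forward``/``backward`` are explicit
    so the training loop owns the optimizer. Class outputs are 0-based
    indices into the label set handed to the estimator wrapper.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        c = config.channels
        k = config.kernel
        n = config.blocks_per_branch
        rng = np.random.default_rng(config.seed)

        self.conv0 = Conv2d(config.in_bands, c, k, pad=0, bias=config.conv_bias, rng=rng)
        if config.variant == "single_multibranch":
            self.block1 = [_branch(c, k, n, config.conv_bias, rng) for _ in range(5)]
            self.block1.append(_branch(c, 1, n, config.conv_bias, rng))
            self.block2 = []
        else:
            self.block1 = [_branch(c, k, n, config.conv_bias, rng) for _ in range(4)]
            if config.variant == "first_block_only":
                self.block2 = []
            else:
                self.block2 = [
                    _branch(c, k, n, config.conv_bias, rng),
                    _branch(c, 1, n, config.conv_bias, rng),
                ]
        feat = config.feature_channels
        self.se = (
            SEBlock(feat, config.se_reduction, bias=config.se_bias, rng=rng)
            if config.use_se
            else None
        )
        self.fc = Linear(feat, config.n_classes, bias=config.fc_bias, rng=rng)

    # ----- pieces exposed for inspection and testing -----

    def conv0_forward(self, x: np.ndarray) -> np.ndarray:
        return self.conv0.forward(np.asarray(x, dtype=np.float32), train=False)

    def dhr_forward(self, xn: np.ndarray, train: bool = False) -> tuple:
        """Run the hierarchical residual block(s) on ``xn``; returns ``(xp, Y)``.

        For single-block variants ``Y`` is ``xp`` itself.
        """
        xp, _ = _hier_forward(xn, self.block1, train)
        if self.block2:
            Y, _ = _hier_forward(xp, self.block2, train)
        else:
            Y = xp
        return xp, Y

    def se_forward(self, F: np.ndarray) -> np.ndarray:
        if self.se is None:
            return F
        return self.se.forward(F, train=False)

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """The (pre-SE) feature map: concatenated block outputs."""
        xn = self.conv0.forward(x, train)
        xp, Y = self.dhr_forward(xn, train)
        if self.config.variant in ("full", "dhr_only"):
            return np.concatenate([xp, Y], axis=1)
        return xp

    # ----- full passes -----

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        xn = self.conv0.forward(x, train)
        xp, ys1 = _hier_forward(xn, self.block1, train)
        if self.block2:
            Y, ys2 = _hier_forward(xp, self.block2, train)
            F = np.concatenate([xp, Y], axis=1)
        else:
            F = xp
        if self.se is not None:
            F = self.se.forward(F, train)
        self._fshape = F.shape
        self._hw = F.shape[2] * F.shape[3]
        pooled = F.mean(axis=(2, 3))
        return self.fc.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        c = self.config.channels
        dpool = self.fc.backward(dlogits)
        dF = np.broadcast_to(dpool[:, :, None, None] / self._hw, self._fshape).astype(np.float32).copy()
        if self.se is not None:
            dF = self.se.backward(dF)
        if self.block2:
            dxp = dF[:, :c].copy()
            dY = np.ascontiguousarray(dF[:, c:])
            dxp += _hier_backward(dY, self.block2)
        else:
            dxp = np.ascontiguousarray(dF)
        dxn = _hier_backward(dxp, self.block1)
        self.conv0.backward(dxn)

    def params(self) -> list:
        out = self.conv0.params()
        for branch in self.block1 + self.block2:
            out += branch.params()
        if self.se is not None:
            out += self.se.params()
        out += self.fc.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def predict_logits(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Batched inference on NHWC patches; returns (n, n_classes) logits."""
        X = np.asarray(X, dtype=np.float32)
        outs = []
        for i in range(0, X.shape[0], batch_size):
            xb = X[i : i + batch_size].transpose(0, 3, 1, 2)
            outs.append(self.forward(xb, train=False))
        return np.concatenate(outs, axis=0)

    # ----- serialization -----

    def state_arrays(self) -> list:
        arrs = [p.value for p in self.params()]
        for layer in self._bn_layers():
            arrs += [layer.running_mean, layer.running_var]
        return arrs

    def _bn_layers(self) -> list:
        out = []
        for branch in self.block1 + self.block2:
            out += [l for l in branch.layers if isinstance(l, BatchNorm2d)]
        return out

    def save(self, path: str) -> None:
        import json

        from dataclasses import asdict

        np.savez_compressed(
            path,
            config=np.array(json.dumps(asdict(self.config))),
            **{f"arr_{i}": a for i, a in enumerate(self.state_arrays())},
        )

    @classmethod
    def load(cls, path: str) -> "MJHResNet":
        import json

        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig(**json.loads(str(z["config"])))
            model = cls(config)
            arrs = model.state_arrays()
            for i, a in enumerate(arrs):
                a[...] = z[f"arr_{i}"]
        return model


def count_parameters(model: MJHResNet) -> int:
    """Exact count of independently trainable scalars (incl. BN scale/shift)."""
    return int(sum(p.size for p in model.params()))


def parameter_breakdown(model: MJHResNet) -> list:
    """Per-stage (name, parameter count) pairs summing to the total."""

    def seq_count(seq: Sequential) -> int:
        return int(sum(p.size for p in seq.params()))

    rows = [("conv0", int(sum(p.size for p in model.conv0.params())))]
    for i, br in enumerate(model.block1, start=1):
        rows.append((f"block1_branch{i}", seq_count(br)))
    for i, br in enumerate(model.block2, start=1):
        rows.append((f"block2_branch{i}", seq_count(br)))
    if model.se is not None:
        rows.append(("se", int(sum(p.size for p in model.se.params()))))
    rows.append(("head", int(sum(p.size for p in model.fc.params()))))
    return rows


def layer_trace(model: MJHResNet, patch: np.ndarray) -> list:
    """(stage, output shape as H x W x C) pairs for one NHWC patch."""
    x = np.asarray(patch, dtype=np.float32)[None].transpose(0, 3, 1, 2)
    rows = [("input", (x.shape[2], x.shape[3], x.shape[1]))]
    xn = model.conv0.forward(x, train=False)
    rows.append(("conv0", (xn.shape[2], xn.shape[3], xn.shape[1])))
    xp, Y = model.dhr_forward(xn)
    rows.append(("block1_sum", (xp.shape[2], xp.shape[3], xp.shape[1])))
    if model.block2:
        rows.append(("block2_sum", (Y.shape[2], Y.shape[3], Y.shape[1])))
        F = np.concatenate([xp, Y], axis=1)
    else:
        F = xp
    rows.append(("se_input", (F.shape[2], F.shape[3], F.shape[1])))
    if model.se is not None:
        F = model.se.forward(F, train=False)
        rows.append(("se_output", (F.shape[2], F.shape[3], F.shape[1])))
    pooled = F.mean(axis=(2, 3))
    rows.append(("avg_pool", (1, 1, pooled.shape[1])))
    logits = model.fc.forward(pooled, train=False)
    rows.append(("output", (logits.shape[1],)))
    return rows


def model_summary(config: ModelConfig | None = None) -> str:
    """Human-readable per-layer table with totals and convention sensitivity.

    Besides the per-stage breakdown under the given configuration, the
    footer reports the totals obtained under alternative SE reduction
    ratios and bias conventions, the two free knobs of the parameter
    accounting.
    """
    cfg = config or ModelConfig()
    model = MJHResNet(cfg)
    total = count_parameters(model)
    dummy = np.zeros((cfg.patch_size, cfg.patch_size, cfg.in_bands), dtype=np.float32)
    trace = {name: shape for name, shape in layer_trace(model, dummy)}

    lines = [
        f"MJHResNet variant={cfg.variant} kernel={cfg.kernel} channels={cfg.channels} "
        f"blocks/branch={cfg.blocks_per_branch} se_reduction={cfg.se_reduction}",
        f"{'stage':<18}{'params':>12}",
    ]
    for name, cnt in parameter_breakdown(model):
        lines.append(f"{name:<18}{cnt:>12,}")
    lines.append(f"{'total':<18}{total:>12,}")
    lines.append(f"total (M): {total / 1e6:.2f}")
    lines.append("layer trace: " + " -> ".join(f"{k}:{'x'.join(map(str, v))}" for k, v in trace.items()))

    lines.append("convention sensitivity (total in M):")
    for r in (4, 8, 16, 32):
        if cfg.feature_channels % r:
            continue
        alt = count_parameters(MJHResNet(replace(cfg, se_reduction=r)))
        lines.append(f"  se_reduction={r:<3} -> {alt / 1e6:.4f}")
    for bias_combo, label in (
        ((True, True, True), "all biases on"),
        ((False, False, False), "all biases off"),
    ):
        alt_cfg = replace(cfg, conv_bias=bias_combo[0], se_bias=bias_combo[1], fc_bias=bias_combo[2])
        alt = count_parameters(MJHResNet(alt_cfg))
        lines.append(f"  {label:<17} -> {alt / 1e6:.4f}")
    return "\n".join(lines)
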