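"""Independent re-implementations used as oracles in tests.

These deliberately avoid the package's own conv/im2col machinery:
convolutions go through scipy.signal.correlate2d and the hierarchical
block equations are composed term by term.
"""

import numpy as np
from scipy.signal import correlate2d

from cottonhsi.nn.layers import BN_EPS, BatchNorm2d, Conv2d, ReLU


def oracle_branch(branch, x):
    """Evaluate one BN-ReLU-Conv chain on a single (C, H, W) sample, eval-mode BN."""
    for layer in branch.layers:
        if isinstance(layer, BatchNorm2d):
            g, b = layer.gamma.value, layer.beta.value
            rm, rv = layer.running_mean, layer.running_var
            x = g[:, None, None] * (x - rm[:, None, None]) / np.sqrt(rv + BN_EPS)[:, None, None] + b[:, None, None]
        elif isinstance(layer, ReLU):
            x = np.maximum(x, 0.0)
        elif isinstance(layer, Conv2d):
            K = layer.kernel.astype(np.float64)
            mode = "same" if layer.pad == layer.k // 2 else "valid"
            out = np.stack(
                [sum(correlate2d(x[i], K[o, i], mode=mode) for i in range(K.shape[1])) for o in range(K.shape[0])]
            )
            if layer.b is not None:
                out += layer.b.value[:, None, None]
            x = out
        else:  # pragma: no cover
            raise TypeError(layer)
    return x


def oracle_dhr(model, xn):
    """Term-by-term evaluation of the chained hierarchical residual equations.

    First block: y1 = C1(xn), y_i = C_i(xn + y_{i-1}), xp = xn + y1 + ... ;
    second block: y6 = C6(xp), y7 = C7(xp + y6), Y = xp + y6 + y7.
    Single-sample (C, H, W) input; returns (xp, Y).
    """
    ys = []
    prev = None
    for branch in model.block1:
        a = xn if prev is None else xn + prev
        y = oracle_branch(branch, a)
        ys.append(y)
        prev = y
    xp = xn + sum(ys)
    if not model.block2:
        return xp, xp
    y6 = oracle_branch(model.block2[0], xp)
    y7 = oracle_branch(model.block2[1], xp + y6)
    return xp, xp + y6 + y7


def tally_metrics(truth, pred, n_classes):
    """Per-sample TP/FP/FN recount; returns (recall %, precision %) with NaNs."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    recall = np.full(n_classes, np.nan)
    precision = np.full(n_classes, np.nan)
    for c in range(1, n_classes + 1):
        tp = int(np.sum((truth == c) & (pred == c)))
        fn = int(np.sum((truth == c) & (pred != c)))
        fp = int(np.sum((truth != c) & (pred == c)))
        if tp + fn:
            recall[c - 1] = 100.0 * tp / (tp + fn)
        if tp + fp:
            precision[c - 1] = 100.0 * tp / (tp + fp)
    return recall, precision


def randomize_bn_stats(model, rng):
    """Give batch-norm layers non-trivial statistics so eval-mode tests bite."""
    for bn in model._bn_layers():
        bn.running_mean = rng.normal(0, 0.5, bn.c).astype(np.float32)
        bn.running_var = rng.uniform(0.5, 2.0, bn.c).astype(np.float32)
        bn.gamma.value = rng.uniform(0.5, 1.5, bn.c).astype(np.float32)
        bn.beta.value = rng.normal(0, 0.3, bn.c).astype(np.float32)
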