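"""Independent scalar-loop oracles used by the test suite.

Every function here recomputes a quantity with explicit Python loops over
pixels (or windows), deliberately sharing no code with the package
implementation they check.
"""

import math

import numpy as np


def bce_oracle(pred, gt, clamp=1e-7):
    total = 0.0
    H, W = pred.shape
    for i in range(H):
        for j in range(W):
            p = min(max(pred[i, j], clamp), 1.0 - clamp)
            total += -(gt[i, j] * math.log(p) + (1 - gt[i, j]) * math.log(1 - p))
    return total / (H * W)


def dice_oracle(pred, gt, epsilon=1.0, factor=1.0):
    inter = sp = sy = 0.0
    H, W = pred.shape
    for i in range(H):
        for j in range(W):
            inter += pred[i, j] * gt[i, j]
            sp += pred[i, j]
            sy += gt[i, j]
    return 1.0 - (factor * inter + epsilon) / (sp + sy + epsilon)


def focal_oracle(pred, gt, upsilon, clamp=1e-7):
    total = 0.0
    H, W = pred.shape
    for i in range(H):
        for j in range(W):
            p = min(max(pred[i, j], clamp), 1.0 - clamp)
            yt = p if gt[i, j] == 1 else 1.0 - p
            total += -((1.0 - yt) ** upsilon) * math.log(yt)
    return total / (H * W)


def ssim_uniform_oracle(pred, gt, window, c1, c2):
    """Mean of 1 - SSIM over valid positions with a uniform window."""
    H, W = pred.shape
    losses = []
    n = window * window
    for i in range(H - window + 1):
        for j in range(W - window + 1):
            xs, ys, xy, x2, y2 = 0.0, 0.0, 0.0, 0.0, 0.0
            for a in range(window):
                for b in range(window):
                    x = pred[i + a, j + b]
                    y = gt[i + a, j + b]
                    xs += x
                    ys += y
                    xy += x * y
                    x2 += x * x
                    y2 += y * y
            mx, my = xs / n, ys / n
            vx, vy = x2 / n - mx * mx, y2 / n - my * my
            cov = xy / n - mx * my
            ssim = ((2 * mx * my + c1) * (2 * cov + c2)) / \
                   ((mx * mx + my * my + c1) * (vx + vy + c2))
            losses.append(1.0 - ssim)
    return sum(losses) / len(losses)


def confusion_oracle(pred_bin, gt):
    tp = tn = fp = fn = 0
    H, W = pred_bin.shape
    for i in range(H):
        for j in range(W):
            p, y = pred_bin[i, j], gt[i, j]
            if p == 1 and y == 1:
                tp += 1
            elif p == 0 and y == 0:
                tn += 1
            elif p == 1 and y == 0:
                fp += 1
            else:
                fn += 1
    return tp, tn, fp, fn


def kmeans2_oracle(values):
    """Exact 1-D 2-means by brute force over all sorted split points."""
    x = np.sort(np.asarray(values, dtype=float))
    best = (math.inf, None)
    for cut in range(1, len(x)):
        left, right = x[:cut], x[cut:]
        cost = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if cost < best[0]:
            best = (cost, (left.mean(), right.mean()))
    return best[1]


def numeric_grad(f, x, eps=1e-5):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
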