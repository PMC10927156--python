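"""Brute-force reference implementations used as independent oracles.

Deliberately naive — per-pixel loops and all-pairs distances — so they
share no code path with the vectorized implementations they check.
"""

from collections import deque

import numpy as np

from ambbem.evaluation_metrics import ConfusionCounts, boundary_tolerance


def confusion_oracle(pred, truth):
    """Per-pixel loop tally."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel().tolist(), truth.ravel().tolist()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def boundary_oracle(mask):
    """Foreground pixel with any 8-neighbor background (border = background)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                        out[y, x] = 1
    return out


def mbf_oracle(pred, truth):
    """All-pairs boundary-distance mean boundary F1."""
    theta = boundary_tolerance(pred.shape)

    def bf(pb, tb):
        pset = np.argwhere(pb)
        tset = np.argwhere(tb)
        if len(pset) == 0 and len(tset) == 0:
            return 1.0
        if len(pset) == 0 or len(tset) == 0:
            return 0.0
        d = np.sqrt(((pset[:, None, :] - tset[None, :, :]) ** 2).sum(-1))
        precision = float(np.mean(d.min(axis=1) <= theta))
        recall = float(np.mean(d.min(axis=0) <= theta))
        return 0.0 if precision + recall == 0 else \
            2 * precision * recall / (precision + recall)

    scores = [bf(boundary_oracle(pred), boundary_oracle(truth)),
              bf(boundary_oracle(1 - pred), boundary_oracle(1 - truth))]
    return float(np.mean(scores))


def flood_fill_oracle(mask, seed, connectivity=8):
    """BFS component extraction from a seed point."""
    mask = np.asarray(mask)
    out = np.zeros_like(mask, dtype=np.uint8)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    queue = deque([(seed.row, seed.col)])
    out[seed.row, seed.col] = 1
    h, w = mask.shape
    while queue:
        y, x = queue.popleft()
        for dy, dx in steps:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not out[ny, nx]:
                out[ny, nx] = 1
                queue.append((ny, nx))
    return out
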