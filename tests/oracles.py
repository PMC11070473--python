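"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most literal style possible (explicit loops,
exhaustive enumeration) so it shares no code path with the package.
"""

import numpy as np


def otsu_brute_force(hist):
    """Exhaustive argmax of between-class variance over all 256 levels."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_level, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[:t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[:t + 1] * np.arange(t + 1)).sum() / w0
            mu1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:  # strict: keeps the smallest tie
            best_var, best_level = var, t
    return best_level


def thin_reference(mask):
    """Naive per-pixel two-subiteration thinning (clockwise from north)."""
    img = np.asarray(mask).astype(np.uint8).copy()
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1),
               (1, 0), (1, -1), (0, -1), (-1, -1)]  # N NE E SE S SW W NW

    def neighbors(padded, r, c):
        return [int(padded[r + dr, c + dc]) for dr, dc in offsets]

    while True:
        changed = False
        for step in ("A", "B"):
            padded = np.pad(img, 1)
            kill = []
            for r in range(img.shape[0]):
                for c in range(img.shape[1]):
                    if not img[r, c]:
                        continue
                    nb = neighbors(padded, r + 1, c + 1)
                    n = sum(nb)
                    s = sum(1 for a, b in zip(nb, nb[1:] + nb[:1])
                            if a == 0 and b == 1)
                    N_, E_, S_, W_ = nb[0], nb[2], nb[4], nb[6]
                    if not (2 <= n <= 6 and s == 1):
                        continue
                    if step == "A" and N_ * E_ * S_ == 0 and E_ * S_ * W_ == 0:
                        kill.append((r, c))
                    if step == "B" and N_ * E_ * W_ == 0 and N_ * S_ * W_ == 0:
                        kill.append((r, c))
            for r, c in kill:
                img[r, c] = 0
            changed = changed or bool(kill)
        if not changed:
            return img


def flood_fill_components(mask):
    """8-connected labeling by explicit BFS flood fill; returns label array."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0]
                                    and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels, current


def wilcoxon_exact_enumeration(diffs):
    """Two-sided exact signed-rank p-value over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    # midranks for ties
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in range(2 ** n):
        w = sum(ranks[k] for k in range(n) if (signs >> k) & 1)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2 ** n
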