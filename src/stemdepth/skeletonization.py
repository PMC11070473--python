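"""Two-subiteration thinning of the stem mask to a one-pixel centerline.

The classical two-subiteration (Zhang–Suen) scheme repeatedly peels
boundary pixels.  A foreground pixel P0 with 8-neighborhood written in
compass directions (clockwise from north: N, NE, E, SE, S, SW, W, NW) is
deleted when

* 2 <= N(P0) <= 6, where N(P0) counts foreground neighbors,
* S(P0) = 1, where S(P0) counts 0->1 transitions along the clockwise
  cyclic neighbor sequence starting at north,
* sub-step A additionally requires  N·E·S = 0  and  E·S·W = 0,
* sub-step B additionally requires  N·E·W = 0  and  N·S·W = 0.

Deletions within a sub-step are simultaneous (conditions are evaluated on
the sub-step's input), which keeps the skeleton orientation-unbiased.  The
iteration runs to a fixed point, so the operation is idempotent, and only
ever deletes pixels, so the skeleton is a subset of the input mask.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConvergenceError, EmptyRoiError, ParameterError

__all__ = ["neighbor_stats", "thin", "skeleton_points_in_roi",
           "select_scanline_rows", "prune_spurs"]

# clockwise offsets from north: (drow, dcol)
_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_N, _NE, _E, _SE, _S, _SW, _W, _NW = range(8)


def neighbor_stats(window: np.ndarray) -> tuple[int, int]:
    """Count foreground neighbors and 0->1 transitions of a 3x3 window.

    Returns ``(N, S)``: N is the number of foreground pixels among the 8
    neighbors of the center; S is the number of 0->1 transitions along the
    cyclic clockwise sequence starting at the north neighbor.
    """
    w = np.asarray(window)
    if w.shape != (3, 3):
        raise ParameterError("window must be 3x3")
    seq = [int(bool(w[1 + dr, 1 + dc])) for dr, dc in _CLOCKWISE]
    n = sum(seq)
    s = sum(1 for a, b in zip(seq, seq[1:] + seq[:1]) if a == 0 and b == 1)
    return n, s


def _neighbors(img: np.ndarray) -> list[np.ndarray]:
    """Shifted copies of a padded binary image, clockwise from north."""
    out = []
    for dr, dc in _CLOCKWISE:
        out.append(img[1 + dr:img.shape[0] - 1 + dr,
                       1 + dc:img.shape[1] - 1 + dc])
    return out

def _substep(img: np.ndarray, step: str) -> np.ndarray:
    """One simultaneous deletion pass; returns the deletion mask."""
    padded = np.pad(img, 1, mode="constant")
    nb = _neighbors(padded)
    n_count = sum(x.astype(np.uint8) for x in nb)
    s_count = sum(((a == 0) & (b == 1)).astype(np.uint8)
                  for a, b in zip(nb, nb[1:] + nb[:1]))
    if step == "A":
        c1 = ~(nb[_N] & nb[_E] & nb[_S])
        c2 = ~(nb[_E] & nb[_S] & nb[_W])
    else:
        c1 = ~(nb[_N] & nb[_E] & nb[_W])
        c2 = ~(nb[_N] & nb[_S] & nb[_W])
    return (img & (n_count >= 2) & (n_count <= 6) & (s_count == 1) & c1 & c2)


def thin(mask: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Thin a binary mask to its one-pixel skeleton.

    Parameters
    ----------
    mask : binary raster
    max_iter : int, optional
        Safety bound on full A+B iterations; exceeding it raises
        :class:`ConvergenceError`.  The default (half the larger image
        side plus two) always suffices for finite masks.

    Returns
    -------
    uint8 {0, 1} skeleton, a subset of the input mask.
    """
    img = np.asarray(mask).astype(bool)
    if max_iter is None:
        max_iter = max(img.shape) // 2 + 2
    for _ in range(max_iter):
        changed = False
        for step in ("A", "B"):
            kill = _substep(img, step)
            if kill.any():
                img = img & ~kill
                changed = True
        if not changed:
            return img.astype(np.uint8)
    raise ConvergenceError(f"thinning did not converge in {max_iter} iterations")


def skeleton_points_in_roi(skeleton: np.ndarray,
                           roi: tuple[int, int]) -> list[tuple[int, int]]:
    """Skeleton pixels whose row lies in the inclusive interval ``roi``.

    Returns (col, row) tuples sorted by row (then column).  Raises
    :class:`EmptyRoiError` when the region contains no skeleton pixel.
    """
    skel = np.asarray(skeleton).astype(bool)
    lo, hi = int(roi[0]), int(roi[1])
    rows, cols = np.nonzero(skel)
    keep = (rows >= lo) & (rows <= hi)
    if not keep.any():
        raise EmptyRoiError(f"no skeleton pixel in rows [{lo}, {hi}]")
    order = np.lexsort((cols[keep], rows[keep]))
    return [(int(c), int(r)) for r, c in
            zip(rows[keep][order], cols[keep][order])]


def select_scanline_rows(skeleton: np.ndarray, roi: tuple[int, int],
                         n_scanlines: int = 3) -> list[tuple[int, int]]:
    """Pick ``n_scanlines`` skeleton points at evenly spaced rows of the ROI.

    Target rows are spaced evenly across the inclusive ROI; for each target
    the skeleton point with the nearest row is chosen (ties to the smaller
    row), and when several skeleton pixels share that row the one closest
    to the skeleton's median column is used.  Duplicate picks collapse, so
    fewer than ``n_scanlines`` points may be returned on short skeletons.
    """
    pts = skeleton_points_in_roi(skeleton, roi)
    rows = np.array([r for _, r in pts])
    cols = np.array([c for c, _ in pts])
    med_col = np.median(cols)
    targets = np.linspace(roi[0], roi[1], max(n_scanlines, 1))
    chosen: dict[int, tuple[int, int]] = {}
    for t in targets:
        i = int(np.argmin(np.abs(rows - t)))
        row = int(rows[i])
        on_row = cols[rows == row]
        col = int(on_row[np.argmin(np.abs(on_row - med_col))])
        chosen[row] = (col, row)
    return [chosen[r] for r in sorted(chosen)]


def prune_spurs(skeleton: np.ndarray, min_length: int) -> np.ndarray:
    """Remove skeleton branches shorter than ``min_length`` pixels.

    Line-termination pixels — those whose foreground neighbors form a
    single contiguous run (one 0->1 transition around the 8-neighborhood)
    — are peeled iteratively ``min_length`` times.  The transition-count
    criterion also catches spur bases that sit diagonally against the
    centerline, which a plain degree-1 endpoint test misses.  Peeling also
    shortens the free ends of the centerline by the same amount, which is
    why pruning is off by default in the pipeline.
    """
    img = np.asarray(skeleton).astype(bool)
    for _ in range(int(min_length)):
        padded = np.pad(img, 1, mode="constant")
        nb = _neighbors(padded)
        n_count = sum(x.astype(np.uint8) for x in nb)
        s_count = sum(((a == 0) & (b == 1)).astype(np.uint8)
                      for a, b in zip(nb, nb[1:] + nb[:1]))
        terminations = img & (n_count >= 1) & (s_count == 1)
        if not terminations.any():
            break
        img = img & ~terminations
    return img.astype(np.uint8)
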