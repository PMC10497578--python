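"""Boundary tracing and outward-normal estimation on binary masks.

Chains are ordered lists of ``(row, col)`` pixels; normals are unit vectors
in ``(x, y)`` = ``(col, row)`` coordinates.  Orientation is normalized so the
shoelace signed area in ``(x, y)`` is non-negative (counter-clockwise in the
mathematical axes).
"""

from __future__ import annotations

import numpy as np

# Moore neighborhood in clockwise order starting from "west", as
# (drow, dcol) offsets.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def trace_perimeter(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single blob (Moore-neighbor tracing).

    Parameters
    ----------
    mask
        Boolean 2-D array containing exactly one 8-connected component whose
        boundary does not touch the image edge.

    Returns
    -------
    (n, 2) int array of ``(row, col)`` boundary pixels, ordered
    counter-clockwise, each pixel listed once; first and last pixels are
    8-adjacent (closed chain).  Pixels in one-pixel-thick necks or spurs are
    traversed from both sides but listed at their first visit only, which
    locally breaks chain adjacency there (such degenerate geometry is also
    excluded from normal estimation downstream).

    Raises
    ------
    ValueError
        If the mask is empty or touches the image border (a vessel truncated
        by the field of view cannot be traced reliably).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("mask touches the image border; object truncated by field of view")

    rows, cols = np.nonzero(mask)
    # uppermost-leftmost pixel; its west and north neighbors are background
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))

    if mask.sum() == 1:
        return np.array([start], dtype=int)

    chain: list[tuple[int, int]] = [start]
    current = start
    backtrack = (0, -1)  # entered the start pixel from the west
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        # scan the Moore neighborhood clockwise starting just after backtrack
        base = _MOORE_INDEX[backtrack]
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(base + k) % 8]
            r, c = current[0] + dr, current[1] + dc
            if mask[r, c]:
                nxt = (r, c)
                # new backtrack: the background neighbor checked just before,
                # expressed as an offset from the new pixel
                pr, pc = _MOORE[(base + k - 1) % 8]
                new_backtrack = (current[0] + pr - r, current[1] + pc - c)
                break
        if nxt is None:  # isolated pixel handled above; unreachable here
            break
        # a diagonal step cuts a corner: the shared 4-neighbor on the inside
        # of the turn is a boundary pixel too (it is 8-adjacent to the
        # background cell the scan just passed) — insert it so the chain
        # covers every foreground pixel with a background 8-neighbor
        if abs(nxt[0] - current[0]) == 1 and abs(nxt[1] - current[1]) == 1:
            for corner in ((current[0], nxt[1]), (nxt[0], current[1])):
                if mask[corner] and corner != chain[-1]:
                    chain.append(corner)
        # Jacob's stopping criterion: back at the start pixel about to leave
        # it in the same direction as the first step
        if nxt == start and new_backtrack == (0, -1):
            break
        current, backtrack = nxt, new_backtrack
        if current != start:
            chain.append(current)

    # each pixel once, first occurrence kept (spur pixels are revisited)
    seen: set[tuple[int, int]] = set()
    unique = []
    for p in chain:
        if p not in seen:
            seen.add(p)
            unique.append(p)
    out = np.array(unique, dtype=int)

    # normalize orientation: shoelace area >= 0 in (x=col, y=row) axes
    x, y = out[:, 1].astype(float), out[:, 0].astype(float)
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        out = out[::-1]
    return out


def estimate_outward_normals(
    chain: np.ndarray,
    filled_mask: np.ndarray,
    window: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit normals along a closed boundary chain.

    The tangent at pixel ``i`` is the central difference between the chain
    neighbors ``i±window``; the normal is the tangent rotated 90° and signed
    to point away from ``filled_mask`` (the vessel wall plus lumen).  Pixels
    with a degenerate tangent (e.g. the tip of a one-pixel protrusion, where
    the two window neighbors coincide) are flagged invalid and excluded from
    measurement.

    Returns
    -------
    normals : (n, 2) float array of unit ``(x, y)`` vectors (NaN where invalid)
    valid : (n,) bool array
    """
    chain = np.asarray(chain, int)
    n = len(chain)
    if n < 2 * window + 1:
        raise ValueError(f"chain of {n} pixels too short for window ±{window}")
    filled_mask = np.asarray(filled_mask, bool)

    xy = chain[:, ::-1].astype(float)  # (x, y) per pixel
    fwd = np.roll(xy, -window, axis=0)
    bwd = np.roll(xy, window, axis=0)
    tangent = fwd - bwd
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    valid = norm > 0

    normals = np.full((n, 2), np.nan)
    t = tangent[valid] / norm[valid, None]
    # rotate +90 degrees: (tx, ty) -> (-ty, tx)
    cand = np.column_stack([-t[:, 1], t[:, 0]])

    centroid = xy.mean(axis=0)
    pts = xy[valid]
    signs = np.zeros(len(pts))
    for probe in (1.5, 2.5):
        undecided = signs == 0
        if not undecided.any():
            break
        for s in (+1.0, -1.0):
            pos = pts[undecided] + s * probe * cand[undecided]
            r = np.clip(np.rint(pos[:, 1]).astype(int), 0, filled_mask.shape[0] - 1)
            c = np.clip(np.rint(pos[:, 0]).astype(int), 0, filled_mask.shape[1] - 1)
            outside = ~filled_mask[r, c]
            if s > 0:
                plus_outside = outside
            else:
                minus_outside = outside
        decided = plus_outside != minus_outside
        idx = np.nonzero(undecided)[0][decided]
        signs[idx] = np.where(plus_outside[decided], +1.0, -1.0)
    # fallback for still-ambiguous pixels: point away from the centroid
    undecided = signs == 0
    if undecided.any():
        radial = pts[undecided] - centroid
        dots = np.einsum("ij,ij->i", cand[undecided], radial)
        signs[undecided] = np.where(dots >= 0, +1.0, -1.0)

    normals[valid] = cand * signs[:, None]
    return normals, valid
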