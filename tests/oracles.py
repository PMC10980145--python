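"""Brute-force reference implementations used only as test oracles.

Deliberately naive: flood fill with an explicit queue, erosion/dilation by
direct neighborhood scans, point-in-polygon by ray casting.  They share no
code with the package so agreement is meaningful.
"""

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by BFS, numbering in raster order."""
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    current = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                q = deque([(r, c)])
                labels[r, c] = current
                while q:
                    rr, cc = q.popleft()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols:
                            if mask[nr, nc] and labels[nr, nc] == 0:
                                labels[nr, nc] = current
                                q.append((nr, nc))
    return labels


def disk_offsets(radius: int):
    offs = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                offs.append((dr, dc))
    return offs


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion; pixels outside the frame count as foreground."""
    rows, cols = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and not mask[nr, nc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation; pixels outside the frame count as background."""
    rows, cols = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            hit = False
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc]:
                    hit = True
                    break
            out[r, c] = hit
    return out


def brute_open(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.copy()
    return brute_dilate(brute_erode(mask, radius), radius)


def point_in_polygon(r: float, c: float, vertices, eps: float = 1e-9) -> bool:
    """Ray casting with an explicit on-boundary check (boundary counts in)."""
    n = len(vertices)
    inside = False
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # on-segment check
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        if abs(cross) < eps:
            if min(r1, r2) - eps <= r <= max(r1, r2) + eps and min(c1, c2) - eps <= c <= max(c1, c2) + eps:
                return True
        if (r1 > r) != (r2 > r):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_int:
                inside = not inside
    return inside
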