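"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-implement the algorithms in the most literal way
possible (python loops, flood fill, dense sampling) and share no code
with the package.
"""

from __future__ import annotations

import numpy as np


def naive_detect_puncta(img, max_cutoff=255, min_cutoff=95, min_region=25,
                        margin=5.0):
    """Literal iterative-threshold detection with stack-based flood fill.

    Returns a list of (cutoff, row, col, area) tuples in acceptance order.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    masked = np.zeros((h, w), dtype=bool)
    centers: list[tuple[float, float]] = []
    results = []
    for cut in range(max_cutoff, min_cutoff - 1, -1):
        visited = np.zeros((h, w), dtype=bool)
        for r0 in range(h):
            for c0 in range(w):
                if (visited[r0, c0] or masked[r0, c0]
                        or img[r0, c0] < cut):
                    continue
                stack = [(r0, c0)]
                visited[r0, c0] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < h and 0 <= nc < w
                                    and not visited[nr, nc]
                                    and not masked[nr, nc]
                                    and img[nr, nc] >= cut):
                                visited[nr, nc] = True
                                stack.append((nr, nc))
                if len(comp) <= min_region:
                    continue
                wsum = sum(img[p] for p in comp)
                cy = sum(p[0] * img[p] for p in comp) / wsum
                cx = sum(p[1] * img[p] for p in comp) / wsum
                if any((cy - py) ** 2 + (cx - px) ** 2 < margin**2
                       for py, px in centers):
                    continue
                centers.append((cy, cx))
                results.append((cut, cy, cx, len(comp)))
                for rr in range(h):
                    for cc in range(w):
                        if (rr - cy) ** 2 + (cc - cx) ** 2 <= margin**2:
                            masked[rr, cc] = True
    return results


def train_recursion(n0, p, r, q, n_pulses, rate_hz):
    """Literal depletion recursion loop."""
    dt = 1.0 / rate_hz
    pool = n0
    amps = []
    for _ in range(n_pulses):
        released = p * pool
        amps.append(q * released)
        pool = pool - released + r * dt
    return np.array(amps)


def sholl_dense(edges_a, edges_b, radii, ds=0.01):
    """Dense-sampling crossing count: sample each edge at ds spacing and
    count sign changes of (distance - r)."""
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(len(radii), dtype=np.int64)
    for p0, p1 in zip(edges_a, edges_b):
        length = float(np.linalg.norm(p1 - p0))
        n = max(2, int(np.ceil(length / ds)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        d = np.linalg.norm(pts, axis=1)
        f = d[None, :] - radii[:, None]           # (R, n)
        s = np.sign(f)
        # a sample can land exactly on the sphere (f == 0); carry the
        # previous nonzero sign forward so the transition is still counted
        for row in s:
            last = 0.0
            for i in range(len(row)):
                if row[i] == 0.0:
                    row[i] = last
                else:
                    last = row[i]
            # leading zeros: backfill with first nonzero sign
            nz = np.nonzero(row)[0]
            if len(nz) and nz[0] > 0:
                row[:nz[0]] = row[nz[0]]
        counts += ((s[:, :-1] != s[:, 1:]) & (s[:, :-1] != 0)
                   & (s[:, 1:] != 0)).sum(axis=1)
    return counts


def ols_line(x, y):
    """Closed-form least squares (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm
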