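"""Smallest enclosing circle of a 2-D point set (Welzl's algorithm).

Expected linear time after a seeded random shuffle; exact up to floating
point.  Used for the gaze-dispersion feature (radius of the minimal bounding
circle of all valid gaze points in a trial).
"""

from __future__ import annotations

import numpy as np

__all__ = ["minimal_enclosing_circle"]

_EPS = 1e-10


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = 0.5 * (p + q)
    return c, float(np.hypot(*(p - c)))


def _circle_three(p: np.ndarray, q: np.ndarray, r: np.ndarray
                  ) -> tuple[np.ndarray, float] | None:
    ax, ay = p; bx, by = q; cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None  # collinear
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.hypot(*(p - c)))


def _contains(c: np.ndarray, r: float, p: np.ndarray) -> bool:
    return float(np.hypot(*(p - c))) <= r + _EPS


def minimal_enclosing_circle(points, seed: int = 0
                             ) -> tuple[tuple[float, float], float]:
    """Return ``((cx, cy), radius)`` of the unique smallest enclosing circle.

    Raises ``ValueError`` on an empty or non-finite point set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("minimal_enclosing_circle of empty point set")
    pts = pts.reshape(-1, 2)
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    rng = np.random.default_rng(seed)
    pts = pts[rng.permutation(len(pts))]

    c: np.ndarray = pts[0].copy()
    r = 0.0
    for i in range(1, len(pts)):
        if _contains(c, r, pts[i]):
            continue
        # pts[i] is on the boundary of the circle over pts[:i+1]
        c, r = pts[i].copy(), 0.0
        for j in range(i):
            if _contains(c, r, pts[j]):
                continue
            c, r = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _contains(c, r, pts[k]):
                    continue
                cr = _circle_three(pts[i], pts[j], pts[k])
                if cr is not None:
                    c, r = cr
                else:
                    # collinear triple: diameter over the two farthest
                    trio = np.array([pts[i], pts[j], pts[k]])
                    d = ((trio[:, None, :] - trio[None, :, :]) ** 2).sum(-1)
                    a, b = np.unravel_index(np.argmax(d), d.shape)
                    c, r = _circle_two(trio[a], trio[b])
    return (float(c[0]), float(c[1])), float(r)
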