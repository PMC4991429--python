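"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit double sums, shoelace,
gift-wrap hull membership) that share no code with the package paths
they check.
"""

import numpy as np


def shoelace_area(poly: np.ndarray) -> float:
    """|area| of a closed polygon ((row, col) vertices, first == last)."""
    y, x = poly[:-1, 0], poly[:-1, 1]
    y2, x2 = poly[1:, 0], poly[1:, 1]
    return abs(float(np.sum(x * y2 - x2 * y))) / 2.0


def arc_length(poly: np.ndarray) -> float:
    total = 0.0
    for (y1, x1), (y2, x2) in zip(poly[:-1], poly[1:]):
        total += ((y2 - y1) ** 2 + (x2 - x1) ** 2) ** 0.5
    return total


def hu_moments_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Seven Hu invariants from explicit raw-moment double sums."""
    rows, cols = np.nonzero(mask)
    rows = rows.astype(float)
    cols = cols.astype(float)

    def raw(p, q):
        return float(np.sum(rows ** p * cols ** q))

    m00 = raw(0, 0)
    rbar, cbar = raw(1, 0) / m00, raw(0, 1) / m00
    dr, dc = rows - rbar, cols - cbar

    def mu(p, q):
        return float(np.sum(dr ** p * dc ** q))

    def eta(p, q):
        return mu(p, q) / m00 ** (1.0 + (p + q) / 2.0)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03 = eta(3, 0), eta(0, 3)
    n21, n12 = eta(2, 1), eta(1, 2)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11 ** 2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = ((n30 - 3 * n12) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          + (3 * n21 - n03) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    h6 = ((n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
          + 4 * n11 * (n30 + n12) * (n21 + n03))
    h7 = ((3 * n21 - n03) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          - (n30 - 3 * n12) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def hull_vertices_bruteforce(points: np.ndarray) -> set:
    """Indices of convex-hull vertices by exhaustive edge testing.

    An ordered pair (i, j) is a hull edge iff every other point lies
    strictly on one side (or on the segment); a point on some hull edge
    endpoint is a hull vertex. O(n^3), for tiny vertex sets only.
    """
    n = len(points)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            side_pos = side_neg = False
            for k in range(n):
                if k in (i, j):
                    continue
                cross = d[0] * (points[k][1] - points[i][1]) - d[1] * (points[k][0] - points[i][0])
                if cross > 1e-9:
                    side_pos = True
                elif cross < -1e-9:
                    side_neg = True
            if not (side_pos and side_neg):
                on_hull.add(i)
                on_hull.add(j)
    return on_hull
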