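"""Independent brute-force oracles used by the acceptance tests."""

import numpy as np


def double_loop_L(points, area, r_grid):
    """O(n²) pair-count Ripley's L, written as plainly as possible."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    L = np.empty(len(r_grid))
    for k, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = points[i, 0] - points[j, 0]
                dy = points[i, 1] - points[j, 1]
                if np.sqrt(dx * dx + dy * dy) <= r:
                    count += 1
        K = area * count / (n * (n - 1))
        L[k] = np.sqrt(K / np.pi)
    return L
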