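"""Independent reference implementations used to validate the package.

The maxima oracle decides each candidate separately from first principles
(superlevel-set reachability), with no intensity ordering, no region claiming
and no shared code with the production detector:

a candidate maximum of value ``v`` is merged away exactly when the connected
component of ``{pixels > v - tol}`` containing it also contains either a
strictly brighter pixel, or an equal-valued candidate that precedes it in the
deterministic (lexicographic) plateau order.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_S8 = np.ones((3, 3), dtype=bool)


def _candidate_reps_bruteforce(a: np.ndarray) -> list[tuple[int, int]]:
    """Plateau representatives of local maxima, by explicit neighbour loops."""
    rows, cols = a.shape
    cand = np.zeros_like(a, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            v = a[r, c]
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and a[rr, cc] > v:
                        ok = False
            cand[r, c] = ok
    labels, n = ndimage.label(cand, _S8)
    reps = []
    for k in range(1, n + 1):
        coords = np.argwhere(labels == k)
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        reps.append((int(coords[order[0]][0]), int(coords[order[0]][1])))
    return reps


def reference_find_maxima(a: np.ndarray, noise_tolerance: float) -> list[tuple[int, int]]:
    """Peaks of the prominence-merged maxima detector, decided independently
    per candidate. Returns sorted (row, col) coordinates."""
    a = np.asarray(a, dtype=float)
    if np.ptp(a) == 0:
        return []
    reps = _candidate_reps_bruteforce(a)
    peaks: list[tuple[int, int]] = []
    for r, c in reps:
        v = a[r, c]
        comp_labels, _ = ndimage.label(a > v - noise_tolerance, _S8)
        comp = comp_labels == comp_labels[r, c]
        if (a[comp] > v).any():
            continue  # within tolerance of brighter ground
        shadowed = any(
            (r2, c2) != (r, c) and a[r2, c2] == v and comp[r2, c2] and (r2, c2) < (r, c)
            for r2, c2 in reps
        )
        if not shadowed:
            peaks.append((r, c))
    return sorted(peaks)


def random_grid(rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One random small integer frame and noise tolerance for oracle checks."""
    shape = rng.integers(3, 9, size=2)
    grid = rng.integers(0, 4, size=shape).astype(float)
    tol = float(rng.choice([0.5, 1.0, 1.5, 2.0, 2.5, 3.0]))
    return grid, tol
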