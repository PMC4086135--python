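"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's solvers: assignment scores are found
by exhaustive enumeration over injective mappings, and superpositions by
enumerating every orientation x every injective atom mapping that respects
the distance threshold.
"""

import itertools
import math

import numpy as np

from chempred.superposer import _ORIENT4, _ORIENT24


def brute_force_assignment(matrix: np.ndarray) -> float:
    """Maximum assignment sum over injective mappings of the smaller side
    into the larger, normalized by min(n, m)."""
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    if n == 0 or m == 0:
        return 0.0
    transposed = n > m
    if transposed:
        matrix = matrix.T
        n, m = m, n
    best = -math.inf
    for perm in itertools.permutations(range(m), n):
        best = max(best, sum(matrix[i, j] for i, j in enumerate(perm)))
    return best / n


def brute_force_superpose(a, b, max_dist: float) -> tuple[int, float]:
    """Best (n_mapped, rmsd) over all orientations and all injective partial
    atom mappings whose every pair distance is <= max_dist."""
    orientations = _ORIENT24 if (a.degenerate or b.degenerate) else _ORIENT4
    best = None
    for orient in orientations:
        bc = b.coords @ orient.T
        diff = a.coords[:, None, :] - bc[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        n, m = dist.shape
        for k in range(min(n, m), -1, -1):
            found_rmsd = None
            for rows in itertools.combinations(range(n), k):
                for cols in itertools.permutations(range(m), k):
                    ds = dist[list(rows), list(cols)]
                    if (ds <= max_dist).all():
                        rmsd = math.sqrt((ds ** 2).mean()) if k else 0.0
                        if found_rmsd is None or rmsd < found_rmsd:
                            found_rmsd = rmsd
            if found_rmsd is not None:
                cand = (k, found_rmsd)
                if best is None or (-cand[0], cand[1]) < (-best[0], best[1]):
                    best = cand
                break
    return best
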