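"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most literal route available —
a sliding probe/target search for palindromes and a numerical minimization
over rotations for superposition — and stay independent of the code paths
they validate.
"""

from __future__ import annotations

import numpy as np


def probe_target_scan(seq: str, min_len: int = 5, max_len: int = 9,
                      exclude_carp: bool = True) -> set[tuple[int, int]]:
    """Literal sliding probe/target palindrome search.

    For every window ('probe'), invert it to a 'target' and slide the target
    over the whole sequence one residue at a time recording exact matches;
    probe/target duplicates collapse into one record.  A window is a
    palindrome when the target matches at the probe's own position.  'X'
    never matches any letter (itself included); CARP windows (single repeated
    letter) are excluded when requested.  Returns {(start, length)}.
    """
    n = len(seq)
    found: set[tuple[int, int]] = set()
    max_len = min(max_len, n)
    for L in range(min_len, max_len + 1):
        for i in range(n - L + 1):
            probe = seq[i:i + L]
            target = probe[::-1]
            for j in range(n - L + 1):
                window = seq[j:j + L]
                match = all(a == b and a != "X"
                            for a, b in zip(window, target))
                if match and j == i:
                    if exclude_carp and len(set(probe)) == 1:
                        continue
                    found.add((i, L))
    return found


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray,
                         n_starts: int = 60, seed: int = 0) -> float:
    """Minimum RMSD of b onto a over all proper rotations + translations,
    found by direct numerical minimization over rotation vectors with many
    restarts (no closed-form solution used)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec)
        return float(np.sqrt(np.mean(np.sum((rot.apply(bc) - ac) ** 2,
                                            axis=1))))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + list(rng.normal(size=(n_starts, 3)) * 2.0)
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 2000})
        best = min(best, res.fun)
    return best
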