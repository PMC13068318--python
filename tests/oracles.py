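"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's spatial-index code paths: plain loops
over all atoms, dense Fibonacci point grids, no prefilter and no KD-trees.
"""

from __future__ import annotations

import math

import numpy as np

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}


def fib_points(n: int) -> np.ndarray:
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n, dtype=float)
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, 1))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def one_sided_csa_bruteforce(res_a, all_residues, probe=1.4, n_points=2560):
    """Surface area of residue ``res_a`` attributed to each other residue.

    ``res_a`` and the entries of ``all_residues`` are lists of
    (element, xyz) tuples; ``all_residues`` is a dict name -> atom list and
    must contain res_a under some key.  Returns {name: area}.
    """
    a_atoms = [(e, np.asarray(x, dtype=float)) for e, x in res_a]
    others = []  # (name, element, xyz, radius)
    for name, atoms in all_residues.items():
        if atoms is res_a:
            continue
        for e, x in atoms:
            others.append((name, VDW.get(e.upper(), 1.8), np.asarray(x, float)))
    dirs = fib_points(n_points)
    areas: dict[str, float] = {}
    for ci, (elem, center) in enumerate(a_atoms):
        r = VDW.get(elem.upper(), 1.8)
        pts = center + (r + probe) * dirs
        keep = np.ones(len(pts), dtype=bool)
        for cj, (elem2, center2) in enumerate(a_atoms):
            if cj == ci:
                continue
            r2 = VDW.get(elem2.upper(), 1.8)
            keep &= np.linalg.norm(pts - center2, axis=1) >= r2 + probe - 1e-9
        w = 4 * math.pi * (r + probe) ** 2 / n_points
        for p in pts[keep]:
            best_name, best_r, best_d = None, None, None
            for name, rb, xb in others:
                d = float(np.linalg.norm(p - xb))
                if best_d is None or d < best_d:
                    best_name, best_r, best_d = name, rb, d
            if best_name is not None and best_d <= best_r + 2 * probe:
                areas[best_name] = areas.get(best_name, 0.0) + w
    return areas


def pair_csa_bruteforce(res_a, res_b, context=None, probe=1.4, n_points=2560):
    """Symmetric (mean) contact surface area between two residues."""
    residues = {"a": res_a, "b": res_b}
    if context:
        residues.update(context)
    fwd = one_sided_csa_bruteforce(res_a, residues, probe, n_points).get("b", 0.0)
    rev = one_sided_csa_bruteforce(res_b, residues, probe, n_points).get("a", 0.0)
    return 0.5 * (fwd + rev)


def gotoh_global_score(a: str, b: str, matrix, open_gap=10.0, extend_gap=1.0):
    """Affine-gap Needleman-Wunsch global alignment score (end gaps penalized),
    as an independent check on the alignment backend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_gap - extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -open_gap - extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_gap, X[i - 1][j] - extend_gap,
                          Y[i - 1][j] - open_gap)
            Y[i][j] = max(M[i][j - 1] - open_gap, Y[i][j - 1] - extend_gap,
                          X[i][j - 1] - open_gap)
    return max(M[n][m], X[n][m], Y[n][m])
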