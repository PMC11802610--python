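"""Independent brute-force oracles used to cross-check the main code paths.

These deliberately avoid the library routines they verify: rank is computed
by hand-rolled fraction-exact Gaussian elimination, singular values via the
eigenvalues of A^T A.
"""

from __future__ import annotations

import random
from fractions import Fraction

import numpy as np
import sympy as sp


def row_reduce_rank(rows: list[list[Fraction]]) -> int:
    """Rank by exact Gaussian elimination over the rationals."""
    rows = [list(map(Fraction, r)) for r in rows]
    if not rows:
        return 0
    ncols = len(rows[0])
    rank = 0
    pivot_row = 0
    for col in range(ncols):
        pivot = next(
            (i for i in range(pivot_row, len(rows)) if rows[i][col] != 0), None
        )
        if pivot is None:
            continue
        rows[pivot_row], rows[pivot] = rows[pivot], rows[pivot_row]
        pv = rows[pivot_row][col]
        for i in range(len(rows)):
            if i != pivot_row and rows[i][col] != 0:
                factor = rows[i][col] / pv
                rows[i] = [a - factor * b for a, b in zip(rows[i], rows[pivot_row])]
        pivot_row += 1
        rank += 1
        if pivot_row == len(rows):
            break
    return rank


def symbolic_matrix_rank(M: sp.Matrix, seed: int, trials: int = 3) -> int:
    """Generic rank of a symbolic matrix via random rational substitution
    followed by fraction-exact row reduction (independent of sympy's rank)."""
    syms = sorted(M.free_symbols, key=str)
    rng = random.Random(seed)
    best = 0
    for _ in range(trials):
        sub = {
            s: sp.Rational(rng.randint(1, 10**6), rng.randint(1, 10**3))
            for s in syms
        }
        N = M.xreplace(sub)
        rows = [
            [Fraction(int(sp.nsimplify(N[i, j]).p), int(sp.nsimplify(N[i, j]).q))
             for j in range(N.cols)]
            for i in range(N.rows)
        ]
        best = max(best, row_reduce_rank(rows))
    return best


def singular_values_via_gram(A: np.ndarray) -> np.ndarray:
    """Singular values as sqrt of the eigenvalues of A^T A (descending)."""
    gram = A.T @ A
    eig = np.linalg.eigvalsh(gram)
    eig = np.clip(eig, 0.0, None)
    return np.sqrt(eig)[::-1]
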