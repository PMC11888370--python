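"""Arithmetic over GF(4), the four-element Galois field.

Elements are the integers 0..3, encoding {0, 1, omega, omega^2} as the
polynomials {0, 1, x, x+1} over GF(2) modulo x^2 + x + 1.  Addition is
therefore bitwise XOR of the 2-bit values and the nonzero elements form a
cyclic multiplicative group of order 3.  All tables are plain numpy arrays
so vectorised field arithmetic is just fancy indexing.
"""

from __future__ import annotations

import numpy as np

#: Addition table: a + b == a XOR b in the 2-bit polynomial encoding.
ADD = np.array(
    [[0, 1, 2, 3],
     [1, 0, 3, 2],
     [2, 3, 0, 1],
     [3, 2, 1, 0]], dtype=np.uint8)

#: Multiplication table (x * x = x + 1 mod x^2 + x + 1).
MUL = np.array(
    [[0, 0, 0, 0],
     [0, 1, 2, 3],
     [0, 2, 3, 1],
     [0, 3, 1, 2]], dtype=np.uint8)

#: Multiplicative inverses of the nonzero elements (index 0 unused).
INV = np.array([0, 1, 3, 2], dtype=np.uint8)


def add(a, b):
    """Field addition, elementwise; identical to XOR on the encoding."""
    return np.bitwise_xor(a, b)


def mul(a, b):
    """Field multiplication, elementwise via table lookup."""
    return MUL[a, b]


def dot(u, v) -> int:
    """Inner product of two GF(4) vectors."""
    prods = MUL[np.asarray(u, dtype=np.uint8), np.asarray(v, dtype=np.uint8)]
    return int(np.bitwise_xor.reduce(prods))


def matvec(m: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Matrix--vector product ``m @ v`` over GF(4)."""
    prods = MUL[m, np.asarray(v, dtype=np.uint8)[np.newaxis, :]]
    return np.bitwise_xor.reduce(prods, axis=1)


def matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix product over GF(4) (small operands; loops over the inner dim)."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    out = np.zeros((a.shape[0], b.shape[1]), dtype=np.uint8)
    for t in range(a.shape[1]):
        out ^= MUL[a[:, t][:, None], b[t][None, :]]
    return out


def rref(m: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Reduced row echelon form over GF(4).

    Returns the reduced matrix and the list of pivot column indices.
    """
    m = np.array(m, dtype=np.uint8, copy=True)
    rows, cols = m.shape
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        if r == rows:
            break
        nz = np.nonzero(m[r:, c])[0]
        if nz.size == 0:
            continue
        p = r + int(nz[0])
        if p != r:
            m[[r, p]] = m[[p, r]]
        m[r] = MUL[INV[m[r, c]], m[r]]
        for rr in range(rows):
            if rr != r and m[rr, c]:
                m[rr] = np.bitwise_xor(m[rr], MUL[m[rr, c], m[r]])
        pivots.append(c)
        r += 1
    return m, pivots


def null_space_basis(h: np.ndarray) -> np.ndarray:
    """Basis (rows) of the right null space of ``h`` over GF(4).

    Standard construction from the RREF: one basis vector per free column,
    with the pivot coordinates solved so that h @ v = 0.
    """
    h = np.asarray(h, dtype=np.uint8)
    red, pivots = rref(h)
    n = h.shape[1]
    free = [c for c in range(n) if c not in pivots]
    basis = np.zeros((len(free), n), dtype=np.uint8)
    for i, f in enumerate(free):
        basis[i, f] = 1
        for r, p in enumerate(pivots):
            # pivot coordinate must cancel the free column's contribution
            basis[i, p] = red[r, f]
    return basis
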