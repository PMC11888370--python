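"""Error-correcting DNA barcode codes over GF(4).

DNA tags for combinatorial libraries need to survive sequencing errors: a
single substitution in a building-block tag must not silently turn one
compound into another.  The natural fix is a code over the four-letter
alphabet with guaranteed minimum Hamming distance.  This module builds
shortened quaternary Hamming codes of any length 7-16 bp (minimum distance
3: single-substitution correction) and, in parity mode, distance-4 codes
(single-substitution correction plus two-substitution detection), together
with the syndrome decoder and a hash-map decoder for arbitrary tag sets
that do not come from a single code.

The symbol map is fixed: A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _gf4

SYMBOLS = "ACGT"
_SYM_TO_VAL = {b: i for i, b in enumerate(SYMBOLS)}

MIN_LENGTH = 7
MAX_LENGTH = 16


def seq_to_vals(seq: str) -> np.ndarray:
    try:
        return np.array([_SYM_TO_VAL[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in {seq!r}") from None


def vals_to_seq(vals: Iterable[int]) -> str:
    return "".join(SYMBOLS[int(v)] for v in vals)


def _projective_points(r: int) -> list[tuple[int, ...]]:
    """Lexicographically sorted representatives of the projective space
    PG(r-1, 4): all nonzero vectors in GF(4)^r whose first nonzero entry is 1.
    """
    pts = []
    for v in itertools.product(range(4), repeat=r):
        nz = next((x for x in v if x), None)
        if nz == 1:
            pts.append(v)
    return sorted(pts)


def _hamming_columns(n: int) -> np.ndarray:
    """First ``n`` columns (lexicographic) of the full [21, 18] GF(4)
    Hamming parity-check matrix; shortening = taking a column subset."""
    pts = _projective_points(3)
    return np.array(pts[:n], dtype=np.uint8).T


def _ovoid_columns(n: int) -> np.ndarray:
    """``n`` columns from an elliptic quadric (ovoid) in PG(3, 4).

    The quadric x0*x1 + x2^2 + x2*x3 + w*x3^2 = 0 (w = element 2, a root of
    the irreducible y^2 + y + w) carries 4^2 + 1 = 17 projective points with
    no three collinear, so any n <= 16 of them form the parity-check matrix
    of an [n, n-4] code of minimum distance 4.
    """
    mul = _gf4.MUL
    pts = []
    for v in _projective_points(4):
        x0, x1, x2, x3 = v
        q = mul[x0, x1] ^ mul[x2, x2] ^ mul[x2, x3] ^ mul[2, mul[x3, x3]]
        if q == 0:
            pts.append(v)
    if len(pts) < n:  # pragma: no cover - the quadric always has 17 points
        raise RuntimeError("quadric cap smaller than expected")
    return np.array(pts[:n], dtype=np.uint8).T


def _check_distance3_certificate(h: np.ndarray) -> None:
    """No zero column and no column a scalar multiple of another."""
    n = h.shape[1]
    if np.any(np.all(h == 0, axis=0)):
        raise AssertionError("parity-check matrix has a zero column")
    seen = set()
    for j in range(n):
        col = h[:, j]
        nz = col[np.nonzero(col)[0][0]]
        rep = tuple(_gf4.MUL[_gf4.INV[nz], col])
        if rep in seen:
            raise AssertionError("two columns are scalar multiples")
        seen.add(rep)


def _check_distance4_certificate(h: np.ndarray) -> None:
    """No three columns linearly dependent over GF(4)."""
    _check_distance3_certificate(h)
    n = h.shape[1]
    cols = h.T
    for i, j, k in itertools.combinations(range(n), 3):
        for a in range(4):
            for b in range(4):
                if a == 0 and b == 0:
                    continue
                if np.array_equal(
                    _gf4.MUL[a, cols[i]] ^ _gf4.MUL[b, cols[j]], cols[k]
                ):
                    raise AssertionError("three columns are linearly dependent")


@dataclass(frozen=True)
class TagDecodeResult:
    """Outcome of syndrome-decoding one observed tag."""

    status: str  # valid | corrected | detected_uncorrectable | invalid
    codeword: Optional[str] = None
    error_position: Optional[int] = None
    error_magnitude: Optional[int] = None


class QuaternaryCode:
    """A linear code over GF(4) mapped onto the DNA alphabet.

    Non-parity codes are shortenings of the [21, 18, 3] quaternary Hamming
    code (columns of H = lexicographically first n projective points of
    PG(2,4)); parity codes take their H columns from an ovoid in PG(3,4),
    which certifies minimum distance 4.  Both certificates are re-verified
    explicitly at construction time.

    Attributes
    ----------
    n : barcode length in symbols (= base pairs)
    k : message dimension; 4**k codewords
    parity : whether the distance-4 construction is used
    H : parity-check matrix, shape (3, n) or (4, n)
    """

    def __init__(self, n: int, parity: bool = False):
        if not MIN_LENGTH <= n <= MAX_LENGTH:
            raise ValueError(
                f"barcode length {n} unsupported; supported range is "
                f"{MIN_LENGTH}-{MAX_LENGTH} bp"
            )
        self.n = int(n)
        self.parity = bool(parity)
        if parity:
            self.H = _ovoid_columns(n)
            _check_distance4_certificate(self.H)
        else:
            self.H = _hamming_columns(n)
            _check_distance3_certificate(self.H)
        self.G = _gf4.null_space_basis(self.H)  # k x n generator
        self.k = self.G.shape[0]
        assert self.k == n - self.H.shape[0]
        # syndrome -> (position, magnitude) for all single-symbol errors;
        # distance >= 3 makes these 3n entries distinct.
        self._syndromes: dict[tuple[int, ...], tuple[int, int]] = {}
        for j in range(self.n):
            for a in range(1, 4):
                s = tuple(_gf4.MUL[a, self.H[:, j]])
                self._syndromes[s] = (j, a)

    # -- encoding ---------------------------------------------------------

    def encode(self, message: Sequence[int]) -> str:
        """Encode a length-k GF(4) message vector into an n-bp barcode."""
        msg = np.asarray(list(message), dtype=np.uint8)
        if msg.shape != (self.k,):
            raise ValueError(f"message must have length k={self.k}, got {len(msg)}")
        if msg.max(initial=0) > 3:
            raise ValueError("message symbols must be in 0..3")
        cw = _gf4.matmul(msg[None, :], self.G)[0]
        return vals_to_seq(cw)

    def encode_many(self, messages: np.ndarray) -> np.ndarray:
        """Vectorised encode: (N, k) message array -> (N, n) symbol array."""
        return _gf4.matmul(np.asarray(messages, dtype=np.uint8), self.G)

    def codewords(self) -> list[str]:
        """All 4**k codewords (use only for small k)."""
        msgs = np.array(list(itertools.product(range(4), repeat=self.k)),
                        dtype=np.uint8)
        return [vals_to_seq(row) for row in self.encode_many(msgs)]

    # -- decoding ---------------------------------------------------------

    def syndrome(self, observed: str) -> tuple[int, ...]:
        vals = seq_to_vals(observed)
        if vals.shape[0] != self.n:
            raise ValueError(
                f"observed tag length {len(observed)} != code length {self.n}"
            )
        return tuple(_gf4.matvec(self.H, vals))

    def decode_tag(self, observed: str) -> TagDecodeResult:
        """Bounded-distance decode of one observed n-bp tag.

        Zero syndrome -> ``valid``.  A syndrome matching a scalar multiple of
        one H column -> ``corrected`` at that position.  Any other nonzero
        syndrome means more than one substitution happened: in parity mode
        (distance 4) this is reported as ``detected_uncorrectable``; without
        parity the code cannot tell a double error from a shortened-out
        single error, so the status is ``invalid``.
        """
        s = self.syndrome(observed)
        if not any(s):
            return TagDecodeResult(status="valid", codeword=observed)
        hit = self._syndromes.get(s)
        if hit is not None:
            j, a = hit
            vals = seq_to_vals(observed)
            vals[j] ^= a  # subtract the error (char 2: add = subtract)
            return TagDecodeResult(
                status="corrected",
                codeword=vals_to_seq(vals),
                error_position=j,
                error_magnitude=a,
            )
        return TagDecodeResult(
            status="detected_uncorrectable" if self.parity else "invalid"
        )


def build_code(n: int, parity: bool = False) -> QuaternaryCode:
    """Construct the deterministic quaternary code for (n, parity)."""
    return QuaternaryCode(n, parity=parity)


def generate_barcode_set(
    n: int, count: int, parity: bool = False, seed: int = 0
) -> list[str]:
    """Sample ``count`` distinct barcodes from the (n, parity) code.

    Linearity guarantees every pair of distinct codewords differs in at
    least the code's minimum distance (3, or 4 with parity), so any subset
    is a valid barcode set.  Sampling is without replacement and
    reproducible from ``seed``.
    """
    code = build_code(n, parity=parity)
    capacity = 4 ** code.k
    if count > capacity:
        raise ValueError(
            f"requested {count} barcodes but the length-{n} "
            f"{'parity ' if parity else ''}code holds only {capacity} codewords"
        )
    rng = np.random.default_rng(seed)
    if capacity <= 4 ** 9:
        idx = rng.choice(capacity, size=count, replace=False)
    else:
        chosen: set[int] = set()
        while len(chosen) < count:
            for v in rng.integers(0, capacity, size=count):
                chosen.add(int(v))
                if len(chosen) == count:
                    break
        idx = np.array(sorted(chosen))
        rng.shuffle(idx)
    digits = np.zeros((len(idx), code.k), dtype=np.uint8)
    rem = np.asarray(idx, dtype=np.int64)
    for pos in range(code.k - 1, -1, -1):
        digits[:, pos] = rem % 4
        rem //= 4
    return [vals_to_seq(row) for row in code.encode_many(digits)]


class LookupDecoder:
    """Hash-map decoder for an arbitrary set of equal-length DNA tags.

    Tag sets designed by random generation (or stitched together from
    several codes) have no algebraic structure to exploit, so correction is
    done by direct enumeration: each tag maps to itself, and each
    single-substitution neighbour maps to its tag if and only if exactly one
    tag claims it and it is not itself a tag.  Neighbours claimed by two or
    more tags are ambiguous and decode as invalid.
    """

    def __init__(self, tags: Sequence[str]):
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tags in lookup decoder input")
        lengths = {len(t) for t in tags}
        if len(lengths) > 1:
            raise ValueError("lookup decoder tags must all have the same length")
        self.tags = list(tags)
        self.length = lengths.pop() if lengths else 0
        self._exact = set(self.tags)
        neighbour_claims: dict[str, set[str]] = {}
        for tag in self.tags:
            for nb in self._neighbours(tag):
                neighbour_claims.setdefault(nb, set()).add(tag)
        self._corrections = {
            nb: next(iter(claimants))
            for nb, claimants in neighbour_claims.items()
            if len(claimants) == 1 and nb not in self._exact
        }
        self._ambiguous = {
            nb
            for nb, claimants in neighbour_claims.items()
            if len(claimants) > 1 and nb not in self._exact
        }

    @staticmethod
    def _neighbours(tag: str):
        for i, base in enumerate(tag):
            for other in SYMBOLS:
                if other != base:
                    yield tag[:i] + other + tag[i + 1:]

    def decode_tag(self, observed: str) -> TagDecodeResult:
        if observed in self._exact:
            return TagDecodeResult(status="valid", codeword=observed)
        hit = self._corrections.get(observed)
        if hit is not None:
            pos = next(i for i, (a, b) in enumerate(zip(observed, hit)) if a != b)
            return TagDecodeResult(status="corrected", codeword=hit,
                                   error_position=pos)
        return TagDecodeResult(status="invalid")


def build_lookup_decoder(tags: Sequence[str]) -> LookupDecoder:
    return LookupDecoder(tags)


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def min_code_distance(code: QuaternaryCode, max_k: int = 10) -> int:
    """Exact minimum distance of the full codebook.

    The codebook is closed under addition, so the minimum pairwise distance
    equals the minimum Hamming weight over the nonzero codewords — an
    O(4^k * n) enumeration instead of O(4^k^2) pairwise comparisons.
    """
    if code.k > max_k:
        raise ValueError(f"codebook with k={code.k} too large to enumerate")
    total = 4 ** code.k
    best = code.n
    chunk = 1 << 16
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        digits = np.zeros((len(idx), code.k), dtype=np.uint8)
        rem = idx.copy()
        for pos in range(code.k - 1, -1, -1):
            digits[:, pos] = rem % 4
            rem //= 4
        weights = np.count_nonzero(code.encode_many(digits), axis=1)
        nz = weights[weights > 0]
        if nz.size:
            best = min(best, int(nz.min()))
    return best


def min_pairwise_distance(tags: Sequence[str]) -> int:
    """Minimum pairwise Hamming distance of a tag set (numpy, O(N^2 * L))."""
    arr = np.array([seq_to_vals(t) for t in tags])
    best = arr.shape[1]
    for i in range(len(tags) - 1):
        d = np.count_nonzero(arr[i + 1:] != arr[i], axis=1).min()
        best = min(best, int(d))
    return best
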