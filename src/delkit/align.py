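"""Semi-global alignment of a barcode pattern against a read.

The pattern (a library tag, or the full barcode reference with wildcards at
variable positions) must be aligned end to end, while read overhangs on
either side are penalty-free — the classic adapter-trimming alignment mode.
Scoring follows an affine-gap Gotoh scheme: match +1, mismatch -1, first
gapped base -2 and each further base -1, and a wildcard pattern position
scores 0 against anything, so constant regions anchor the alignment while
tag/UMI regions neither attract nor repel it.

The dynamic program runs row-wise over the pattern with numpy vectors over
the read axis; the within-row affine gap recursion collapses to a running
prefix maximum.  Scores are kept as integers, so the traceback can recover
the optimal path by exact score comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2  # cost of the first base of a gap
GAP_EXTEND = -1  # each further base
WILDCARD = "N"

_NEG = -(2 ** 30)


@dataclass
class AlignmentHit:
    """One semi-global alignment of a pattern inside a read.

    ``pattern_map[i]`` is the 0-based read index aligned to pattern position
    ``i``, or -1 where the pattern base was deleted from the read.  Errors
    count substitutions at non-wildcard pattern positions plus every
    inserted or deleted base.
    """

    score: int
    read_start: int
    read_end: int  # half-open
    errors: int
    pattern_map: np.ndarray
    section_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def span_for(self, pat_start: int, pat_end: int) -> tuple[int, int]:
        """Read span [start, end) covering pattern range [pat_start, pat_end).

        Deleted pattern positions contribute nothing; an entirely deleted
        range yields an empty span at the nearest aligned boundary.
        """
        seg = self.pattern_map[pat_start:pat_end]
        aligned = seg[seg >= 0]
        if aligned.size == 0:
            right = self.pattern_map[pat_end:]
            nxt = right[right >= 0]
            pos = int(nxt[0]) if nxt.size else self.read_end
            return pos, pos
        return int(aligned[0]), int(aligned[-1]) + 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def semi_global_align(
    read: str,
    pattern: str,
    max_error_rate: Optional[float] = None,
) -> Optional[AlignmentHit]:
    """Best semi-global alignment of ``pattern`` within ``read``.

    Returns ``None`` when no alignment satisfies
    ``errors / len(pattern) <= max_error_rate``.  Ties in score are broken
    toward the leftmost read position, then (via traceback preference for
    diagonal moves) toward fewer gaps.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if max_error_rate is not None and not (0.0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    m = len(pattern)
    R = len(read)
    if R == 0:
        return None

    read_u = _encode(read)
    wild = ord(WILDCARD)
    ncols = R + 1

    # score matrices, row-major over pattern positions 0..m
    M = np.full((m + 1, ncols), _NEG, dtype=np.int32)
    Ix = np.full((m + 1, ncols), _NEG, dtype=np.int32)  # gap in pattern (read char consumed)
    Iy = np.full((m + 1, ncols), _NEG, dtype=np.int32)  # gap in read (pattern char skipped)
    M[0, :] = 0  # free leading read overhang

    js = np.arange(ncols, dtype=np.int32)
    for i in range(1, m + 1):
        p = pattern[i - 1]
        if p == WILDCARD:
            srow = np.zeros(R, dtype=np.int32)
        else:
            srow = np.where(read_u == ord(p), MATCH, MISMATCH).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = srow + prev_best[:-1]
        Iy[i] = np.maximum(M[i - 1] + GAP_OPEN, Iy[i - 1] + GAP_EXTEND)
        # Ix[i, j] = max_{j' < j} M[i, j'] + GAP_OPEN + (j - j' - 1) * GAP_EXTEND
        b = M[i] - js * GAP_EXTEND
        cummax = np.maximum.accumulate(b)
        Ix[i, 1:] = cummax[:-1] + GAP_OPEN + (js[1:] - 1) * GAP_EXTEND

    final = np.maximum(M[m], Iy[m])  # trailing read overhang is free
    end = int(np.argmax(final))  # first maximum -> leftmost end
    score = int(final[end])

    # traceback by exact score reconstruction
    pattern_map = np.full(m, -1, dtype=np.int64)
    errors = 0
    i, j = m, end
    state = "M" if M[m, end] >= Iy[m, end] else "Iy"
    while i > 0:
        if state == "M":
            pj = pattern[i - 1]
            s = 0 if pj == WILDCARD else (MATCH if read[j - 1] == pj else MISMATCH)
            pattern_map[i - 1] = j - 1
            if pj != WILDCARD and read[j - 1] != pj:
                errors += 1
            target = M[i, j] - s
            if M[i - 1, j - 1] == target:
                state = "M"
            elif Ix[i - 1, j - 1] == target:
                state = "Ix"
            else:
                state = "Iy"
            i -= 1
            j -= 1
        elif state == "Ix":
            errors += 1  # inserted read base
            if Ix[i, j] == M[i, j - 1] + GAP_OPEN:
                state = "M"
            j -= 1
        else:  # Iy: pattern base deleted
            errors += 1
            if Iy[i, j] == M[i - 1, j] + GAP_OPEN:
                state = "M"
            i -= 1

    read_start = j
    if max_error_rate is not None and errors / m > max_error_rate:
        return None
    return AlignmentHit(score=score, read_start=read_start, read_end=end,
                        errors=errors, pattern_map=pattern_map)
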