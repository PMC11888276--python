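"""Bit-packed inner loops for the gapped k-mer string kernel.

Each l-mer is packed into a uint32 (2 bits per base, A=0,C=1,G=2,T=3, 5' base
in the high bits).  The Hamming distance between two packed l-mers is the
popcount of ``(x ^ y) | ((x ^ y) >> 1)`` restricted to the even bit positions,
evaluated with a 16-bit lookup table.  The pair contribution C(l-m, k) is a
table lookup; pairs with more than ``dmax`` mismatches contribute nothing, so
the high half of the popcount is skipped once the low half already exceeds the
cutoff.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# popcount of each 16-bit value, restricted use: inputs already have one bit
# set per mismatching base position
_POP16 = np.zeros(1 << 16, dtype=np.uint8)
for _i in range(1, 1 << 16):
    _POP16[_i] = _POP16[_i >> 1] + (_i & 1)


def even_bit_mask(l: int) -> np.uint32:
    """Mask selecting the low bit of each of l 2-bit base slots."""
    m = 0
    for _ in range(l):
        m = (m << 2) | 1
    return np.uint32(m)


@njit(cache=True, fastmath=False)
def _pair_sum(xc, yc, coeff, dmax, mask, pop16):
    acc = 0.0
    for i in range(xc.size):
        x = xc[i]
        for j in range(yc.size):
            z = x ^ yc[j]
            z = (z | (z >> np.uint32(1))) & mask
            m = pop16[z & np.uint32(0xFFFF)]
            if m <= dmax:
                m = m + pop16[z >> np.uint32(16)]
                if m <= dmax:
                    acc += coeff[m]
    return acc


@njit(cache=True)
def _gram(codes, offsets, ycodes, yoffsets, coeff, dmax, mask, pop16, out):
    n = offsets.size - 1
    for i in range(n):
        xi = codes[offsets[i]:offsets[i + 1]]
        for j in range(i, n):
            v = _pair_sum(xi, ycodes[yoffsets[j]:yoffsets[j + 1]],
                          coeff, dmax, mask, pop16)
            out[i, j] = v
            out[j, i] = v


@njit(cache=True)
def _cross(codes, offsets, ycodes, yoffsets, coeff, dmax, mask, pop16, out):
    n = offsets.size - 1
    m = yoffsets.size - 1
    for i in range(n):
        xi = codes[offsets[i]:offsets[i + 1]]
        for j in range(m):
            out[i, j] = _pair_sum(xi, ycodes[yoffsets[j]:yoffsets[j + 1]],
                                  coeff, dmax, mask, pop16)


def pair_sum(xc: np.ndarray, yc: np.ndarray, coeff: np.ndarray, dmax: int,
             l: int) -> float:
    """Raw kernel between one sequence's forward l-mers and another's l-mers."""
    return float(_pair_sum(xc.astype(np.uint32), yc.astype(np.uint32),
                           coeff.astype(np.float64), np.int64(dmax),
                           even_bit_mask(l), _POP16))


def gram_matrix(codes_list: list[np.ndarray], ycodes_list: list[np.ndarray],
                coeff: np.ndarray, dmax: int, l: int) -> np.ndarray:
    """Symmetric raw kernel matrix; x side forward l-mers, y side may include
    the reverse strand (the kernel is symmetric either way)."""
    codes, offsets = _flatten(codes_list)
    ycodes, yoffsets = _flatten(ycodes_list)
    out = np.empty((len(codes_list), len(codes_list)), dtype=np.float64)
    _gram(codes, offsets, ycodes, yoffsets, coeff.astype(np.float64),
          np.int64(dmax), even_bit_mask(l), _POP16, out)
    return out


def cross_matrix(codes_list: list[np.ndarray], ycodes_list: list[np.ndarray],
                 coeff: np.ndarray, dmax: int, l: int) -> np.ndarray:
    codes, offsets = _flatten(codes_list)
    ycodes, yoffsets = _flatten(ycodes_list)
    out = np.empty((len(codes_list), len(ycodes_list)), dtype=np.float64)
    _cross(codes, offsets, ycodes, yoffsets, coeff.astype(np.float64),
           np.int64(dmax), even_bit_mask(l), _POP16, out)
    return out


def _flatten(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(len(arrays) + 1, dtype=np.int64)
    for i, a in enumerate(arrays):
        offsets[i + 1] = offsets[i] + a.size
    flat = np.empty(offsets[-1], dtype=np.uint32)
    for i, a in enumerate(arrays):
        flat[offsets[i]:offsets[i + 1]] = a
    return flat, offsets


def hamming_codes(a: np.ndarray, b: np.ndarray, l: int) -> np.ndarray:
    """Vectorised Hamming distance between aligned arrays of packed l-mers."""
    z = (np.asarray(a, dtype=np.uint32) ^ np.asarray(b, dtype=np.uint32))
    z = (z | (z >> np.uint32(1))) & even_bit_mask(l)
    return (_POP16[z & np.uint32(0xFFFF)].astype(np.int64)
            + _POP16[z >> np.uint32(16)])
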