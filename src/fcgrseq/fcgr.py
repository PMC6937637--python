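"""Frequency Chaos Game Representation (FCGR) of nucleotide sequences.

The chaos game places the four nucleotides at the corners of the unit
square (A bottom-left, C top-left, G top-right, T bottom-right — Jeffrey's
convention, purines and pyrimidines diagonally opposed) and iterates
"move halfway toward the corner of the next base" starting from the
centre. Pixelating the square at resolution 2^k puts every iterate into
the pixel uniquely associated with the last k bases read, so the pixelated
dot density is exactly a k-mer count table. The count matrix is rendered
as an image by normalising the maximum to one and taking the elementwise
fifth root, a nonlinear stretch that keeps the typical pixel away from
pure black or white.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

# Corner bits. x (column) bit: A,C -> 0 ; G,T -> 1. y bit: A,T -> 0 ; C,G -> 1.
# Matrix row 0 is the TOP of the square (y near 1), so row = 2^k - 1 - y_index.
_XBIT = {"A": 0, "C": 0, "G": 1, "T": 1}
_YBIT = {"A": 0, "C": 1, "G": 1, "T": 0}

# 256-entry lookup tables for vectorised counting over raw ASCII bytes.
_X_LUT = np.full(256, -1, dtype=np.int64)
_Y_LUT = np.full(256, -1, dtype=np.int64)
for _b, _x in _XBIT.items():
    _X_LUT[ord(_b)] = _x
    _X_LUT[ord(_b.lower())] = _x
for _b, _y in _YBIT.items():
    _Y_LUT[ord(_b)] = _y
    _Y_LUT[ord(_b.lower())] = _y


@dataclass(frozen=True)
class FCGRParams:
    """Pixelation level k: the image is 2^k x 2^k, one pixel per k-mer."""

    k: int = 7

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 12:
            raise ValueError("pixelation level k must be in [1, 12]")

    @property
    def side(self) -> int:
        return 1 << self.k


@dataclass
class FCGRImage:
    """FCGR count matrix and its rescaled image at pixelation level k."""

    k: int
    counts: np.ndarray  # 2^k x 2^k integer k-mer tallies
    image: np.ndarray   # 2^k x 2^k float in [0, 1]


def kmer_to_pixel(kmer: str, k: int | None = None) -> tuple[int, int]:
    """Map a k-mer to its (row, col) pixel in the 2^k x 2^k FCGR grid.

    The mapping is the bijection induced by the chaos-game iteration: the
    pixel containing the CGR iterate after reading the k-mer. Bitwise, the
    j-th base of the k-mer contributes bit j of the column / y index, so
    the last base supplies the most significant bit.
    """
    k = len(kmer) if k is None else k
    if len(kmer) != k:
        raise ValueError(f"expected k-mer of length {k}, got {len(kmer)}")
    col = y = 0
    for j, base in enumerate(kmer.upper()):
        if base not in _XBIT:
            raise ValueError(f"invalid nucleotide {base!r} in k-mer {kmer!r}")
        col |= _XBIT[base] << j
        y |= _YBIT[base] << j
    return ( (1 << k) - 1 - y, col )


def fcgr_counts(seq: str, params: FCGRParams = FCGRParams()) -> np.ndarray:
    """Count all k-mer occurrences of ``seq`` into the FCGR pixel grid.

    Every sliding window of length k over A/C/G/T contributes one count to
    its pixel; windows containing any other character (IUPAC ambiguity
    codes such as N) are skipped entirely, and the skipped fraction is
    logged when nonzero.
    """
    k = params.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    xb = _X_LUT[codes]
    yb = _Y_LUT[codes]
    valid = xb >= 0

    n_win = len(seq) - k + 1
    weights = 1 << np.arange(k, dtype=np.int64)
    win_x = np.lib.stride_tricks.sliding_window_view(np.where(valid, xb, 0), k)
    win_y = np.lib.stride_tricks.sliding_window_view(np.where(valid, yb, 0), k)
    win_ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)

    cols = win_x[win_ok] @ weights
    ys = win_y[win_ok] @ weights
    side = params.side
    rows = side - 1 - ys

    counts = np.bincount(rows * side + cols, minlength=side * side)
    skipped = n_win - int(win_ok.sum())
    if skipped:
        logger.info(
            "skipped %d/%d windows containing ambiguity codes (%.2f%%)",
            skipped, n_win, 100.0 * skipped / n_win,
        )
    return counts.reshape(side, side).astype(np.int64)


def fcgr_image(counts: np.ndarray) -> np.ndarray:
    """Rescale a count matrix to [0, 1]: normalise the max to 1, then take
    the elementwise fifth root. An all-zero count matrix maps to all zeros."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    peak = counts.max()
    if peak == 0:
        return np.zeros(counts.shape, dtype=float)
    return (counts / peak) ** 0.2


def fcgr(seq: str, params: FCGRParams = FCGRParams()) -> FCGRImage:
    """Full FCGR of a sequence: k-mer counts and the rescaled image."""
    counts = fcgr_counts(seq, params)
    return FCGRImage(k=params.k, counts=counts, image=fcgr_image(counts))
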