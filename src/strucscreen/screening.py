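"""First pipeline stage: windows, row/window filters, species subsampling.

Alignment blocks are cut into overlapping windows (120 columns, stride
20), rows with excessive gaps are removed, windows with too few columns
or atypical mean pairwise identity (MPI below 40% or exactly 100%) are
rejected, and windows with more than 10 species are subsampled into up
to five 10-species alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment_io import GAP, AlignmentBlock, AlignmentRow, row_forward_interval
from .intervals import GenomicInterval

WINDOW_SIZE = 120
WINDOW_STRIDE = 20
MAX_GAP_FRACTION = 0.7
MIN_WINDOW_COLS = 50
MPI_MIN = 40.0
MAX_SAMPLE_SPECIES = 10
N_SAMPLES = 5


@dataclass
class Window:
    """A column slice [c0, c1) of a parent block."""

    block_id: str
    c0: int
    c1: int
    rows: list[AlignmentRow]
    reference_interval: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        self.reference_interval = row_forward_interval(self.rows[0])

    @property
    def n_cols(self) -> int:
        return self.c1 - self.c0

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[0]


@dataclass
class SampleSet:
    """Up to five row subsets of at most 10 rows, reference always included."""

    samples: list[list[AlignmentRow]]
    seed: int


def slice_windows(
    block: AlignmentBlock, size: int = WINDOW_SIZE, stride: int = WINDOW_STRIDE
) -> list[Window]:
    """Cut a block into overlapping windows.

    Starts form the arithmetic sequence 0, stride, 2*stride, ... while
    start+size <= n_cols.  Blocks shorter than *size* yield one window
    covering the whole block.  If the lattice leaves an uncovered tail,
    one end-anchored window [n_cols-size, n_cols) is appended.
    """
    n = block.n_cols
    if n <= size:
        spans = [(0, n)]
    else:
        spans = [(s, s + size) for s in range(0, n - size + 1, stride)]
        if spans[-1][1] < n:
            spans.append((n - size, n))
    return [
        Window(block.source_id, c0, c1, [r.slice_cols(c0, c1) for r in block.rows])
        for c0, c1 in spans
    ]


def filter_gappy_rows(window: Window, max_gap: float = MAX_GAP_FRACTION) -> Window:
    """Drop rows whose gap fraction exceeds *max_gap* (reference kept)."""
    kept = [window.rows[0]] + [
        r for r in window.rows[1:] if r.gap_fraction() <= max_gap
    ]
    return Window(window.block_id, window.c0, window.c1, kept)


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4, GAP: 5}


def encode_rows(texts: Sequence[str]) -> np.ndarray:
    """Rows as an int8 matrix over A,C,G,U,N,- = 0..5 (case-folded)."""
    mat = np.empty((len(texts), len(texts[0])), dtype=np.int8)
    for i, t in enumerate(texts):
        mat[i] = [_ENC.get(c, 4) for c in t.upper()]
    return mat


def mean_pairwise_identity(
    rows: Sequence, count_gap_columns: bool = False
) -> float:
    """MPI in percent, averaged over all unordered row pairs.

    By default only columns where both sequences are non-gap enter a
    pair's identity; with *count_gap_columns* a column where exactly one
    sequence is gapped counts as a mismatch.  A pair with no scorable
    column contributes 0.
    """
    texts = [r.text if isinstance(r, AlignmentRow) else r for r in rows]
    if len(texts) < 2:
        raise ValueError("MPI requires at least two rows")
    mat = encode_rows(texts)
    nongap = mat != 5
    k = len(texts)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            both = nongap[i] & nongap[j]
            if count_gap_columns:
                scorable = nongap[i] | nongap[j]
            else:
                scorable = both
            n_scor = int(scorable.sum())
            if n_scor == 0:
                continue
            ident = int((both & (mat[i] == mat[j])).sum())
            total += 100.0 * ident / n_scor
    return total / (k * (k - 1) / 2)


def window_accept(
    window: Window,
    min_cols: int = MIN_WINDOW_COLS,
    mpi_min: float = MPI_MIN,
) -> bool:
    """Accept a gap-filtered window: >=2 rows, >=50 columns, 40 <= MPI < 100."""
    if len(window.rows) < 2 or window.n_cols < min_cols:
        return False
    mpi = mean_pairwise_identity(window.rows)
    return mpi_min <= mpi < 100.0


def subsample_species(
    window: Window,
    max_n: int = MAX_SAMPLE_SPECIES,
    n_samples: int = N_SAMPLES,
    seed: int = 0,
) -> SampleSet:
    """Reduce windows with more than *max_n* species to up to *n_samples*
    samples of exactly *max_n* rows each, reference always included.

    Samples are drawn uniformly without replacement within each sample;
    distinct samples are enforced whenever enough distinct subsets exist.
    """
    rows = window.rows
    if len(rows) <= max_n:
        return SampleSet(samples=[list(rows)], seed=seed)
    rng = np.random.default_rng(seed)
    others = rows[1:]
    n_choose = max_n - 1
    n_distinct = math.comb(len(others), n_choose)
    require_distinct = n_distinct >= n_samples
    samples: list[list[AlignmentRow]] = []
    seen: set[frozenset] = set()
    attempts = 0
    while len(samples) < n_samples and attempts < 100 * n_samples:
        attempts += 1
        idx = rng.choice(len(others), size=n_choose, replace=False)
        key = frozenset(int(i) for i in idx)
        if require_distinct and key in seen:
            continue
        seen.add(key)
        samples.append([rows[0]] + [others[i] for i in sorted(idx)])
    return SampleSet(samples=samples, seed=seed)
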