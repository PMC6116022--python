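"""Locus assembly and refinement.

Windowed hits are grouped into loci (overlapping or book-ended
reference intervals merge, irrespective of strand), loci spanning
several alignment blocks are merged where possible by fetching up to 20
missing nucleotides per species from the genomes, 20-nt flanks are
added, boundaries are re-predicted from per-column reliabilities of the
consensus structure, and the refined loci are re-scored per strand.

Boundary prediction is a built-in stand-in for structural-alignment
reliability profiling: paired columns are scored by the fraction of
rows that can actually form the consensus pair (compensatory pairs
count in full), unpaired columns by down-weighted sequence agreement.
A realigner for the flanked loci can be plugged in through the
registered adapter contract ``(rows) -> realigned rows``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .alignment_io import (
    GAP,
    AlignmentBlock,
    AlignmentRow,
    GenomeSet,
    revcomp,
    row_forward_interval,
)
from .intervals import GenomicInterval, merge_intervals
from .screening import Window, encode_rows, mean_pairwise_identity
from .structure_scoring import BasePairScorer, ScoreParams, ScoreResult, consensus_weight_matrix, fold_consensus

log = logging.getLogger(__name__)

HIT_P = 0.5
MERGE_MAX_FETCH = 20
MERGE_MAX_SPECIES = 5
MERGE_MAX_COLS = 400
FLANK = 20
BOUNDARY_THETA = 0.85
BOUNDARY_SMOOTH = 5
UNPAIRED_WEIGHT = 0.8
MIN_LOCUS_COLS = 50


@dataclass
class Hit:
    """One accepted window scoring P > 0.5 on one strand."""

    window: Window
    strand: str
    score: ScoreResult
    sample_ps: list[float]

    @property
    def interval(self) -> GenomicInterval:
        return self.window.reference_interval


@dataclass
class Locus:
    """A merged genomic structure element and its supporting alignment."""

    interval: GenomicInterval
    hits: list[Hit]
    block_ids: list[str]
    rows: list[AlignmentRow]
    strand: str = "+"
    sample_ps: list[float] = field(default_factory=list)
    strand_ps: dict = field(default_factory=dict)
    stage: str = "initial"
    consensus_structure: str = ""
    mpi: float = 0.0
    flank_cols: tuple[int, int] = (0, 0)
    name: str = ""

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return self.rows[0].n_cols if self.rows else 0

    @property
    def best_p(self) -> float:
        if self.sample_ps:
            return max(self.sample_ps)
        return max((h.score.p for h in self.hits), default=0.0)


# ---------------------------------------------------------------------------
# Grouping


def group_hits_into_loci(
    hits: Sequence[Hit], blocks: dict[str, AlignmentBlock]
) -> list[Locus]:
    """Merge hits with overlapping or book-ended reference intervals into
    loci, irrespective of strand."""
    if not hits:
        return []
    merged = merge_intervals([h.interval for h in hits], book_ended=True)
    loci = []
    for iv in merged:
        members = [
            h
            for h in hits
            if h.interval.chrom == iv.chrom
            and h.interval.start >= iv.start
            and h.interval.end <= iv.end
        ]
        block_ids = sorted(
            {h.window.block_id for h in members},
            key=lambda b: blocks[b].reference_interval().start,
        )
        loci.append(
            Locus(interval=iv, hits=members, block_ids=block_ids, rows=[])
        )
    return loci


def locus_block_slices(
    locus: Locus, blocks: dict[str, AlignmentBlock]
) -> list[list[AlignmentRow]]:
    """Per contributing block, the column span covered by the locus' hits."""
    parts = []
    for bid in locus.block_ids:
        spans = [
            (h.window.c0, h.window.c1) for h in locus.hits if h.window.block_id == bid
        ]
        c0 = min(s for s, _ in spans)
        c1 = max(e for _, e in spans)
        parts.append([r.slice_cols(c0, c1) for r in blocks[bid].rows])
    return parts


# ---------------------------------------------------------------------------
# Cross-block merging


def _row_gap(left: AlignmentRow, right: AlignmentRow) -> int | None:
    """Unaligned genomic distance between two row pieces of one species,
    None if they are not simply consecutive on the same strand."""
    if (
        left.species != right.species
        or left.chrom != right.chrom
        or left.strand != right.strand
    ):
        return None
    gap = right.start - (left.start + left.size)
    return gap if gap >= 0 else None


def _fetch_row_gap(
    row: AlignmentRow, gap: int, genomes: GenomeSet | None
) -> str | None:
    if gap == 0:
        return ""
    if genomes is None or not genomes.has(row.species):
        return None
    end_rel = row.start + row.size
    if row.strand == "+":
        return genomes.fetch(row.species, row.chrom, end_rel, end_rel + gap)
    fwd_start = row.src_size - end_rel - gap
    seq = genomes.fetch(row.species, row.chrom, fwd_start, fwd_start + gap)
    return revcomp(seq)


def merge_locus_blocks(
    locus: Locus,
    blocks: dict[str, AlignmentBlock],
    genomes: GenomeSet | None,
    max_fetch: int = MERGE_MAX_FETCH,
    max_species: int = MERGE_MAX_SPECIES,
    max_cols: int = MERGE_MAX_COLS,
    greedy: bool = True,
) -> list[Locus]:
    """Merge the per-block pieces of a multi-block locus, greedily left to
    right.  A merge succeeds iff, after dropping species absent from one
    side or with an inter-block gap above *max_fetch*: (a) at least two
    species remain, (b) both initial blocks had at most *max_species*
    rows, (c) the merged width stays below *max_cols*.  Fetched
    nucleotides enter unaligned (gap-padded).  On failure the locus is
    split at the block boundary."""
    parts = locus_block_slices(locus, blocks)
    if len(parts) == 1:
        return [
            replace(
                locus,
                rows=parts[0],
                interval=row_forward_interval(parts[0][0]).with_fields(strand="."),
            )
        ]
    groups: list[list[AlignmentRow]] = [parts[0]]
    group_blocks: list[list[str]] = [[locus.block_ids[0]]]
    sizes = {bid: blocks[bid].n_species for bid in locus.block_ids}
    for bid, part in zip(locus.block_ids[1:], parts[1:]):
        cur = groups[-1]
        merged = _try_merge(
            cur, part, genomes, max_fetch, max_cols
        ) if greedy and all(
            sizes[b] <= max_species for b in group_blocks[-1] + [bid]
        ) else None
        if merged is not None:
            groups[-1] = merged
            group_blocks[-1].append(bid)
        else:
            groups.append(part)
            group_blocks.append([bid])
    out = []
    for rows, bids in zip(groups, group_blocks):
        out.append(
            replace(
                locus,
                rows=rows,
                block_ids=bids,
                hits=[h for h in locus.hits if h.window.block_id in bids],
                interval=row_forward_interval(rows[0]).with_fields(strand="."),
                stage="merged",
            )
        )
    return out


def _try_merge(
    left_rows: list[AlignmentRow],
    right_rows: list[AlignmentRow],
    genomes: GenomeSet | None,
    max_fetch: int,
    max_cols: int,
) -> list[list] | None:
    right_by_sp = {r.species: r for r in right_rows}
    keep: list[tuple[AlignmentRow, AlignmentRow, str]] = []
    for lr in left_rows:
        rr = right_by_sp.get(lr.species)
        if rr is None:
            continue
        gap = _row_gap(lr, rr)
        if gap is None or gap > max_fetch:
            if lr is left_rows[0]:
                return None  # reference not mergeable -> split
            continue
        fetched = _fetch_row_gap(lr, gap, genomes)
        if fetched is None:
            if lr is left_rows[0]:
                return None
            continue  # genome unavailable: drop species, never fabricate
        keep.append((lr, rr, fetched))
    if len(keep) < 2:
        return None
    pad = max(len(f) for _, _, f in keep)
    width = left_rows[0].n_cols + pad + right_rows[0].n_cols
    if width >= max_cols:
        return None
    merged = []
    for lr, rr, fetched in keep:
        text = lr.text + fetched + GAP * (pad - len(fetched)) + rr.text
        merged.append(
            replace(
                lr,
                text=text,
                size=lr.size + len(fetched) + rr.size,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Flanks


def add_flanks(
    locus: Locus, genomes: GenomeSet | None, flank: int = FLANK
) -> Locus:
    """Extend every row by up to *flank* genomic nucleotides per side,
    appended unaligned (gap-padded), clipped at chromosome ends."""
    if flank == 0 or genomes is None:
        return replace(locus, flank_cols=(0, 0))
    lefts, rights = [], []
    for r in locus.rows:
        if not genomes.has(r.species):
            lefts.append("")
            rights.append("")
            continue
        fwd = row_forward_interval(r)
        size = r.src_size
        lf = genomes.fetch(r.species, r.chrom, max(0, fwd.start - flank), fwd.start)
        rf = genomes.fetch(r.species, r.chrom, fwd.end, min(size, fwd.end + flank))
        if r.strand == "-":
            lf, rf = revcomp(rf), revcomp(lf)
        lefts.append(lf)
        rights.append(rf)
    lpad = max((len(x) for x in lefts), default=0)
    rpad = max((len(x) for x in rights), default=0)
    rows = []
    for r, lf, rf in zip(locus.rows, lefts, rights):
        text = GAP * (lpad - len(lf)) + lf + r.text + rf + GAP * (rpad - len(rf))
        rows.append(
            replace(
                r,
                start=r.start - len(lf),
                size=r.size + len(lf) + len(rf),
                text=text,
            )
        )
    return replace(locus, rows=rows, flank_cols=(lpad, rpad))


# ---------------------------------------------------------------------------
# Realigner adapter


_REALIGNERS: dict[str, Callable] = {"none": lambda rows: rows}


def register_realigner(name: str, fn: Callable) -> None:
    _REALIGNERS[name] = fn


def get_realigner(name: str) -> Callable:
    return _REALIGNERS[name]


# ---------------------------------------------------------------------------
# Boundary prediction


MIN_HELIX = 6


def column_reliability(
    texts: Sequence[str],
    params: ScoreParams | None = None,
    unpaired_weight: float = UNPAIRED_WEIGHT,
    min_helix: int = MIN_HELIX,
) -> np.ndarray:
    """Per-column reliability r_c in [0,1].

    Columns paired in the consensus structure score the fraction of rows
    able to form a complementary pair there (a compensatory pair counts
    in full), discounted by the length of the helix the pair belongs to
    (stacked-pair run, saturating at *min_helix*): isolated short
    helices arise abundantly by chance in any alignment and are not
    evidence of a reliably aligned structure, while the extended helices
    of a conserved element score in full.  Unpaired columns score the
    fraction of rows matching the modal non-gap character, down-weighted
    by *unpaired_weight* because mere sequence agreement is weaker
    evidence than consistent pairing.
    """
    params = params or ScoreParams()
    _, struct = fold_consensus(texts, params)
    mat = encode_rows(texts)
    k, n = mat.shape
    tab = params.table()
    r = np.zeros(n)
    pairs = []
    stack: list[int] = []
    for c, ch in enumerate(struct):
        if ch == "(":
            stack.append(c)
        elif ch == ")":
            pairs.append((stack.pop(), c))
    pairs.sort()
    # group stacked pairs (i,j),(i+1,j-1),... into helices
    helix_len: dict[tuple[int, int], int] = {}
    pair_set = set(pairs)
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not a helix start
        run = []
        a, b = i, j
        while (a, b) in pair_set:
            run.append((a, b))
            a, b = a + 1, b - 1
        for p in run:
            helix_len[p] = len(run)
    paired = np.zeros(n, dtype=bool)
    for i, j in pairs:
        able = tab[mat[:, i], mat[:, j]] > 0
        weight = min(1.0, helix_len[(i, j)] / min_helix)
        r[i] = r[j] = able.mean() * weight
        paired[i] = paired[j] = True
    for c in range(n):
        if paired[c]:
            continue
        col = mat[:, c]
        nongap = col[col != 5]
        if len(nongap) == 0:
            r[c] = 0.0
            continue
        counts = np.bincount(nongap, minlength=5)
        r[c] = unpaired_weight * counts.max() / k
    return r


def predict_boundaries(
    locus: Locus,
    theta: float = BOUNDARY_THETA,
    smooth: int = BOUNDARY_SMOOTH,
    params: ScoreParams | None = None,
    unpaired_weight: float = UNPAIRED_WEIGHT,
) -> list[tuple[int, int]]:
    """Maximal column ranges where the centered moving average of the
    per-column reliability reaches *theta*."""
    texts = [r.text for r in locus.rows]
    r = column_reliability(texts, params, unpaired_weight)
    if smooth > 1:
        kernel = np.ones(smooth)
        # centered moving average; edges average over the columns present
        r = np.convolve(r, kernel, mode="same") / np.convolve(
            np.ones_like(r), kernel, mode="same"
        )
    above = r >= theta
    ranges = []
    start = None
    for c, flag in enumerate(above):
        if flag and start is None:
            start = c
        elif not flag and start is not None:
            ranges.append((start, c))
            start = None
    if start is not None:
        ranges.append((start, len(above)))
    return ranges


def merge_reliable_regions(
    ranges: Sequence[tuple[int, int]], original_range: tuple[int, int]
) -> tuple[int, int] | None:
    """Span of all ranges overlapping the original (un-flanked) locus by
    at least one column, including the columns in between; None if no
    range touches the original."""
    o0, o1 = original_range
    touching = [(a, b) for a, b in ranges if a < o1 and b > o0]
    if not touching:
        return None
    return (min(a for a, _ in touching), max(b for _, b in touching))


# ---------------------------------------------------------------------------
# Re-scoring


def _subsample_rows(
    rows: list[AlignmentRow], max_n: int, n_samples: int, seed: int
) -> list[list[AlignmentRow]]:
    from .screening import Window, subsample_species

    win = Window("locus", 0, rows[0].n_cols, rows)
    return subsample_species(win, max_n=max_n, n_samples=n_samples, seed=seed).samples


def rescore_locus(
    locus: Locus,
    refined_range: tuple[int, int],
    scorer: BasePairScorer,
    min_cols: int = MIN_LOCUS_COLS,
    max_sample: int = 10,
    n_samples: int = 5,
    seed: int = 0,
    strands: Sequence[str] = ("+", "-"),
) -> Locus | None:
    """Slice the locus to its refined boundaries and re-classify it with
    the structural decision weights on its candidate strands.

    Returns None (dropped) when fewer than *min_cols* columns or fewer
    than two informative rows remain.  The surviving locus carries
    per-sample probabilities for its best strand (stage ``raw`` iff at
    least one sample scores above 0.5) and records both strands' scores.
    """
    c0, c1 = refined_range
    if c1 - c0 < min_cols:
        log.info("locus %s dropped: refined width %d < %d", locus.name, c1 - c0, min_cols)
        return None
    rows = [r.slice_cols(c0, c1) for r in locus.rows]
    rows = [rows[0]] + [r for r in rows[1:] if r.size > 0]
    if len(rows) < 2 or rows[0].size == 0:
        log.info("locus %s dropped: <2 informative rows after refinement", locus.name)
        return None
    hit_strands = {h.strand for h in locus.hits} or set(strands)
    candidate_strands = [s for s in strands if s in hit_strands] or list(strands)
    samples = _subsample_rows(rows, max_sample, n_samples, seed)
    strand_results: dict[str, tuple[list[float], ScoreResult]] = {}
    for strand in candidate_strands:
        ps, best = [], None
        for smp in samples:
            res = scorer(smp, strand, model="structural")
            ps.append(res.p)
            if best is None or res.p > best.p:
                best = res
        strand_results[strand] = (ps, best)
    best_strand = max(strand_results, key=lambda s: max(strand_results[s][0]))
    ps, best = strand_results[best_strand]
    stage = "raw" if max(ps) > HIT_P else "refined"
    return replace(
        locus,
        rows=rows,
        interval=row_forward_interval(rows[0]).with_fields(strand=best_strand),
        strand=best_strand,
        sample_ps=ps,
        strand_ps={s: max(r[0]) for s, r in strand_results.items()},
        stage=stage,
        consensus_structure=best.consensus_structure,
        mpi=best.mpi,
        flank_cols=(0, 0),
    )
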