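"""High-confidence tiers, shuffled decoy construction, FDR estimation.

The decoy screen runs the unmodified pipeline on input alignments in
which every fifth chunk of 100 consecutive blocks has had its alignment
columns permuted.  Column permutation preserves the per-column
conservation pattern and gap structure (the property of the
conservation-preserving shufflers used for such controls) while
destroying base-pair covariation and dinucleotide adjacency; a per-row
dinucleotide shuffle is available as an alternative control.  The FDR
is the fraction of nucleotides predicted inside the shuffled fifth,
scaled by 5, over the nucleotides predicted in the true screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignmentBlock, AlignmentRow
from .intervals import GenomicInterval, merge_intervals, overlap_nt
from .locus_pipeline import Locus
from .structure_scoring import dinucleotide_shuffle

DECOY_CHUNK = 100
DECOY_EVERY = 5
FDR_SCALE = 5.0
SPECIES_BINS = ((2, 2), (3, 6), (7, 10), (11, 10**9))
MPI_BIN_WIDTH = 10.0


@dataclass(frozen=True)
class ConfidenceRule:
    """Species-count-dependent probability cutoffs for the
    high-confidence tier."""

    two_species_p: float = 0.99
    few_species_p: float = 0.9
    sampled_high_p: float = 0.90
    sampled_low_p: float = 0.5
    sampled_max_low: int = 1


def is_high_confidence(locus: Locus, rule: ConfidenceRule = ConfidenceRule()) -> bool:
    """Tiered cutoffs: 2 species need max P > 0.99; 3-10 species need
    max P > 0.9; sampled loci (>10 species) need at most one sample
    below 0.5 and at least one above 0.90."""
    ps = locus.sample_ps
    if not ps:
        return False
    n = locus.n_species
    if n == 2:
        return max(ps) > rule.two_species_p
    if n <= 10:
        return max(ps) > rule.few_species_p
    n_low = sum(1 for p in ps if p < rule.sampled_low_p)
    return n_low <= rule.sampled_max_low and max(ps) > rule.sampled_high_p


def high_confidence_set(
    loci: Iterable[Locus], rule: ConfidenceRule = ConfidenceRule()
) -> list[Locus]:
    return [
        replace(l, stage="high_confidence")
        for l in loci
        if l.stage == "raw" and is_high_confidence(l, rule)
    ]


# ---------------------------------------------------------------------------
# Decoy construction


def shuffle_block_columns(
    block: AlignmentBlock, seed: int | np.random.Generator
) -> AlignmentBlock:
    """Permute alignment columns uniformly at random (column content
    intact); genomic provenance of the rows is unchanged."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm = rng.permutation(block.n_cols)
    rows = [
        replace(r, text="".join(r.text[c] for c in perm)) for r in block.rows
    ]
    return AlignmentBlock(rows=rows, source_id=block.source_id + "|shuf")


def shuffle_block_rows_dinucleotide(
    block: AlignmentBlock, seed: int | np.random.Generator
) -> AlignmentBlock:
    """Alternative control: dinucleotide-shuffle each ungapped row
    independently, re-inserting gaps at their original columns."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for r in block.rows:
        shuffled = iter(dinucleotide_shuffle(r.ungapped(), rng))
        text = "".join(c if c == "-" else next(shuffled) for c in r.text)
        rows.append(replace(r, text=text))
    return AlignmentBlock(rows=rows, source_id=block.source_id + "|shuf")


def make_decoy(
    blocks: Sequence[AlignmentBlock],
    chunk: int = DECOY_CHUNK,
    every: int = DECOY_EVERY,
    seed: int = 0,
    mode: str = "columns",
) -> tuple[list[AlignmentBlock], list[GenomicInterval]]:
    """Shuffle every *every*-th chunk of *chunk* consecutive blocks.

    Chunks are numbered from 1; chunks whose index is divisible by
    *every* are shuffled; a final partial chunk is never shuffled.
    Returns the decoy blocks (genomic order preserved) and the mask of
    reference intervals lying in shuffled chunks.
    """
    shuffler = {
        "columns": shuffle_block_columns,
        "dinucleotide": shuffle_block_rows_dinucleotide,
    }[mode]
    rng = np.random.default_rng(seed)
    out: list[AlignmentBlock] = []
    mask: list[GenomicInterval] = []
    n_full_chunks = len(blocks) // chunk
    for i, block in enumerate(blocks):
        chunk_idx = i // chunk + 1  # 1-based
        shuffle = chunk_idx % every == 0 and chunk_idx <= n_full_chunks
        if shuffle:
            out.append(shuffler(block, rng))
            mask.append(block.reference_interval())
        else:
            out.append(block)
            _ = rng  # unshuffled blocks consume no randomness
    return out, merge_intervals(mask)


# ---------------------------------------------------------------------------
# FDR estimation


def adaptive_scale(
    input_footprint: Sequence[GenomicInterval],
    mask: Sequence[GenomicInterval],
) -> float:
    """Up-scaling factor for the shuffled control: screened-input
    nucleotides over screened-input nucleotides inside the shuffled
    mask.  Equals ~5 when exactly a fifth of the input is shuffled; for
    inputs whose block count is not a multiple of chunk*every the exact
    shuffled fraction differs, and the factor adapts accordingly."""
    masked = overlap_nt(input_footprint, mask)
    if masked == 0:
        return float("nan")
    from .intervals import total_length

    return total_length(input_footprint) / masked


@dataclass
class FDRReport:
    stratum: str
    true_nt: int
    control_nt: int
    scale: float
    fdr_nt: float | None
    true_loci: int
    control_loci: int
    fdr_loci: float | None
    plus_strand_only: bool = True  # estimated on + and assumed equal on -


def _species_bin(n: int) -> str:
    for lo, hi in SPECIES_BINS:
        if lo <= n <= hi:
            return f"{lo}" if lo == hi else (f"{lo}-{hi}" if hi < 10**9 else f">{lo - 1}")
    return "?"


def _mpi_bin(mpi: float, width: float = MPI_BIN_WIDTH) -> str:
    lo = int(mpi // width * width)
    return f"{lo}-{lo + int(width)}"


def _locus_nt(loci: Iterable[Locus]) -> int:
    return sum(len(l.interval) for l in loci)


def _masked_nt(loci: Iterable[Locus], mask: Sequence[GenomicInterval]) -> int:
    return sum(overlap_nt([l.interval], mask) for l in loci)


def _in_mask(locus: Locus, mask: Sequence[GenomicInterval]) -> bool:
    return overlap_nt([locus.interval], mask) * 2 >= len(locus.interval)


def estimate_fdr(
    true_loci: Sequence[Locus],
    decoy_loci: Sequence[Locus],
    mask: Sequence[GenomicInterval],
    scale: float = FDR_SCALE,
    stratify: bool = True,
) -> list[FDRReport]:
    """FDR = scale * (decoy locus nucleotides inside the shuffled mask)
    / (true locus nucleotides); analogous at locus counts (a decoy locus
    counts when the majority of its nucleotides lie in the mask).
    Reported overall and, optionally, per species-count x MPI stratum.
    """
    strata: dict[str, tuple[list[Locus], list[Locus]]] = {"overall": ([], [])}
    for l in true_loci:
        strata["overall"][0].append(l)
    for l in decoy_loci:
        strata["overall"][1].append(l)
    if stratify:
        for l in true_loci:
            key = f"species:{_species_bin(l.n_species)}|mpi:{_mpi_bin(l.mpi)}"
            strata.setdefault(key, ([], []))[0].append(l)
        for l in decoy_loci:
            key = f"species:{_species_bin(l.n_species)}|mpi:{_mpi_bin(l.mpi)}"
            strata.setdefault(key, ([], []))[1].append(l)
    reports = []
    for key in sorted(strata, key=lambda k: (k != "overall", k)):
        tl, dl = strata[key]
        true_nt = _locus_nt(tl)
        control_nt = _masked_nt(dl, mask)
        n_true = len(tl)
        n_control = sum(1 for l in dl if _in_mask(l, mask))
        reports.append(
            FDRReport(
                stratum=key,
                true_nt=true_nt,
                control_nt=control_nt,
                scale=scale,
                fdr_nt=scale * control_nt / true_nt if true_nt else None,
                true_loci=n_true,
                control_loci=n_control,
                fdr_loci=scale * n_control / n_true if n_true else None,
            )
        )
    return reports


def fdr_report_frame(reports: Sequence[FDRReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "true_nt": r.true_nt,
                "control_nt": r.control_nt,
                "scale": r.scale,
                "fdr_nt": r.fdr_nt,
                "true_loci": r.true_loci,
                "control_loci": r.control_loci,
                "fdr_loci": r.fdr_loci,
            }
            for r in reports
        ]
    )


# ---------------------------------------------------------------------------
# Covariance-model candidate eligibility


def cm_eligible(loci: Iterable[Locus]) -> list[Locus]:
    """High-confidence loci eligible for covariance-model building:
    at least three sequences and 50-200 alignment columns."""
    return [l for l in loci if l.n_species >= 3 and 50 <= l.n_cols <= 200]
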