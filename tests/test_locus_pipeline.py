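"""Locus grouping, cross-block merging, flanking, boundary refinement."""

import numpy as np
import pytest

from strucscreen.alignment_io import AlignmentBlock, AlignmentRow, InMemoryGenomes
from strucscreen.intervals import GenomicInterval
from strucscreen.locus_pipeline import (
    Hit,
    Locus,
    add_flanks,
    group_hits_into_loci,
    merge_locus_blocks,
    merge_reliable_regions,
    predict_boundaries,
    rescore_locus,
)
from strucscreen.screening import Window
from strucscreen.structure_scoring import BasePairScorer, ScoreParams, ScoreResult


def _score(p=0.9, strand="+"):
    return ScoreResult(strand, 80.0, 0.5, 1.0, 1.0, p, "", 0.0, 2)


def _hit(start, end, strand="+", block="b0", chrom="chr1"):
    size = end - start
    rows = [
        AlignmentRow("ref", chrom, start, size, "+", 10_000, "A" * size),
        AlignmentRow("sp1", chrom, start, size, "+", 10_000, "A" * size),
    ]
    win = Window(block, 0, size, rows)
    return Hit(window=win, strand=strand, score=_score(strand=strand), sample_ps=[0.9])


def _blockmap(*hits):
    out = {}
    for h in hits:
        out.setdefault(
            h.window.block_id,
            AlignmentBlock(h.window.rows, source_id=h.window.block_id),
        )
    return out


def test_group_overlapping_hits():
    hits = [_hit(100, 220, block="b0"), _hit(200, 320, block="b1")]
    loci = group_hits_into_loci(hits, _blockmap(*hits))
    assert len(loci) == 1
    assert (loci[0].interval.start, loci[0].interval.end) == (100, 320)


def test_group_book_ended_hits():
    hits = [_hit(100, 220, block="b0"), _hit(220, 340, block="b1")]
    loci = group_hits_into_loci(hits, _blockmap(*hits))
    assert len(loci) == 1 and len(loci[0].interval) == 240


def test_group_is_strand_agnostic():
    hits = [_hit(100, 220, "+", block="b0"), _hit(150, 270, "-", block="b0")]
    loci = group_hits_into_loci(hits, _blockmap(*hits))
    assert len(loci) == 1 and len(loci[0].hits) == 2


def test_grouped_intervals_disjoint_and_cover_inputs(rng):
    hits = []
    for i in range(40):
        s = int(rng.integers(0, 5000))
        hits.append(_hit(s, s + int(rng.integers(50, 200)), block=f"b{i}"))
    loci = group_hits_into_loci(hits, _blockmap(*hits))
    ivs = sorted((l.interval.start, l.interval.end) for l in loci)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 < s2  # disjoint and not book-ended
    from strucscreen.intervals import merge_intervals

    total_in = sum(len(iv) for iv in merge_intervals([h.interval for h in hits]))
    assert sum(e - s for s, e in ivs) == total_in


# ---------------------------------------------------------------------------
# Cross-block merging


def _two_block_locus(gap=5, n_species=3, width_each=60, max_sp_exceeded=False):
    g = {"chr1": "ACGU" * 5000}
    genomes = InMemoryGenomes({f"s{i}": g for i in range(max(n_species, 6))} | {"ref": g})
    species = ["ref"] + [f"s{i}" for i in range(n_species - 1)]
    if max_sp_exceeded:
        species += [f"s{i}" for i in range(n_species - 1, 6)]
    rows1, rows2 = [], []
    for sp in species:
        rows1.append(
            AlignmentRow(sp, "chr1", 100, width_each, "+", 20_000, "A" * width_each)
        )
        rows2.append(
            AlignmentRow(
                sp, "chr1", 100 + width_each + gap, width_each, "+", 20_000,
                "C" * width_each,
            )
        )
    b1 = AlignmentBlock(rows1, "b0")
    b2 = AlignmentBlock(rows2, "b1")
    hits = []
    for bid, rows in (("b0", rows1), ("b1", rows2)):
        win = Window(bid, 0, width_each, rows)
        hits.append(Hit(win, "+", _score(), [0.9]))
    locus = Locus(
        interval=GenomicInterval("chr1", 100, 100 + 2 * width_each + gap),
        hits=hits,
        block_ids=["b0", "b1"],
        rows=[],
    )
    return locus, {"b0": b1, "b1": b2}, genomes


def test_merge_succeeds_with_fetch():
    locus, blocks, genomes = _two_block_locus(gap=5)
    out = merge_locus_blocks(locus, blocks, genomes)
    assert len(out) == 1
    merged = out[0]
    assert merged.n_cols == 60 + 5 + 60
    assert merged.rows[0].size == 125
    # fetched nucleotides come from the actual genome sequence
    fetched = merged.rows[0].text[60:65]
    assert fetched == genomes.fetch("ref", "chr1", 160, 165)


def test_merge_split_when_gap_exceeds_fetch_limit():
    locus, blocks, genomes = _two_block_locus(gap=25)
    out = merge_locus_blocks(locus, blocks, genomes)
    assert len(out) == 2


def test_merge_split_when_too_many_species():
    locus, blocks, genomes = _two_block_locus(n_species=3, max_sp_exceeded=True)
    out = merge_locus_blocks(locus, blocks, genomes)
    assert len(out) == 2


def test_merge_split_when_too_wide():
    locus, blocks, genomes = _two_block_locus(width_each=200, gap=5)
    out = merge_locus_blocks(locus, blocks, genomes)  # 405 cols >= 400
    assert len(out) == 2


def test_merge_drops_species_missing_genome():
    locus, blocks, _ = _two_block_locus(gap=5, n_species=4)
    genomes = InMemoryGenomes({"ref": {"chr1": "ACGU" * 5000}, "s0": {"chr1": "ACGU" * 5000}})
    out = merge_locus_blocks(locus, blocks, genomes)
    assert len(out) == 1
    assert {r.species for r in out[0].rows} == {"ref", "s0"}


# ---------------------------------------------------------------------------
# Flanks


def _simple_locus(start=50, size=40):
    g = {"chr1": "".join("ACGU"[i % 4] for i in range(1000))}
    genomes = InMemoryGenomes({"ref": g, "sp1": g})
    rows = [
        AlignmentRow("ref", "chr1", start, size, "+", 1000, g["chr1"][start : start + size]),
        AlignmentRow("sp1", "chr1", start, size, "+", 1000, g["chr1"][start : start + size]),
    ]
    locus = Locus(
        interval=GenomicInterval("chr1", start, start + size),
        hits=[],
        block_ids=["b0"],
        rows=rows,
    )
    return locus, genomes


def test_add_flanks_interior():
    locus, genomes = _simple_locus(start=50)
    fl = add_flanks(locus, genomes, flank=20)
    assert fl.flank_cols == (20, 20)
    assert fl.rows[0].size == 40 + 40
    assert fl.rows[0].start == 30


def test_add_flanks_clipped_at_chromosome_start():
    locus, genomes = _simple_locus(start=5)
    fl = add_flanks(locus, genomes, flank=20)
    assert fl.rows[0].start == 0
    assert fl.flank_cols[0] == 5


def test_add_flanks_zero_is_identity():
    locus, genomes = _simple_locus()
    fl = add_flanks(locus, genomes, flank=0)
    assert [r.text for r in fl.rows] == [r.text for r in locus.rows]


# ---------------------------------------------------------------------------
# Boundary prediction


def _locus_from_texts(texts):
    rows = [
        AlignmentRow(f"s{i}", "c", 0, len(t) - t.count("-"), "+", 2000, t)
        for i, t in enumerate(texts)
    ]
    return Locus(
        interval=GenomicInterval("c", 0, rows[0].size),
        hits=[],
        block_ids=["b"],
        rows=rows,
    )


def test_perfectly_conserved_alignment_single_full_range():
    seq = "GGGGGGAAAACCCCCC" * 5
    locus = _locus_from_texts([seq] * 5)
    ranges = predict_boundaries(locus, theta=0.6)
    assert ranges == [(0, len(seq))]


def test_random_alignment_yields_no_range(rng):
    empties = 0
    for _ in range(10):
        texts = ["".join(rng.choice(list("ACGU"), size=80)) for _ in range(6)]
        if not predict_boundaries(_locus_from_texts(texts)):
            empties += 1
    assert empties >= 9


def test_conserved_core_recovered_within_tolerance(rng):
    core = "".join(rng.choice(list("ACGU"), size=24))
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    hairpin = core + "AAAAA" + "".join(comp[c] for c in reversed(core))
    texts = []
    for _ in range(6):
        left = "".join(rng.choice(list("ACGU"), size=20))
        right = "".join(rng.choice(list("ACGU"), size=20))
        texts.append(left + hairpin + right)
    locus = _locus_from_texts(texts)
    ranges = predict_boundaries(locus)
    span = merge_reliable_regions(ranges, (20, 20 + len(hairpin)))
    assert span is not None
    assert abs(span[0] - 20) <= 5 and abs(span[1] - (20 + len(hairpin))) <= 5


def test_merge_reliable_regions_examples():
    assert merge_reliable_regions([(10, 60), (80, 130)], (40, 120)) == (10, 130)
    assert merge_reliable_regions([(0, 200)], (40, 120)) == (0, 200)
    assert merge_reliable_regions([(0, 30), (130, 150)], (40, 120)) is None


# ---------------------------------------------------------------------------
# Re-scoring


def _scorer():
    return BasePairScorer(ScoreParams(n_shuffles=8, seed=0))


def test_rescore_drops_short_locus():
    locus = _locus_from_texts(["A" * 80] * 3)
    assert rescore_locus(locus, (0, 49), _scorer()) is None


def test_rescore_conserved_hairpin_is_raw(rng):
    core = "".join(rng.choice(list("GC"), size=25))
    comp = {"G": "C", "C": "G"}
    hairpin = core + "AAAAA" + "".join(comp[c] for c in reversed(core))
    texts = [hairpin + "AAAA" for _ in range(4)]
    locus = _locus_from_texts(texts)
    out = rescore_locus(locus, (0, len(texts[0])), _scorer(), strands=("+",))
    assert out is not None and out.stage == "raw"
    assert max(out.sample_ps) > 0.5
    assert len(out.consensus_structure) == out.n_cols


def test_rescore_not_raw_when_all_samples_below_half():
    locus = _locus_from_texts(["A" * 80, "A" * 80, "A" * 80])
    out = rescore_locus(locus, (0, 80), _scorer(), strands=("+",))
    assert out is not None and out.stage != "raw"
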