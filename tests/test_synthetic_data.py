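"""Benchmark generator: simulation model, implants, fixture coherence."""

import numpy as np
import pytest

from strucscreen.alignment_io import read_maf
from strucscreen.genome_annotation import build_partition_map
from strucscreen.intervals import GenomicInterval
from strucscreen.structure_scoring import ScoreParams, fold_consensus
from strucscreen.synthetic_data import (
    FixtureConfig,
    ImplantError,
    TreeModel,
    TruthSet,
    TruthEntry,
    evaluate_against_truth,
    implant_conserved_structure,
    simulate_neutral_alignment,
)


def test_zero_branch_lengths_yield_identical_rows():
    tree = TreeModel(
        newick="(a:0.0,b:0.0,c:0.0)ref;", indel_rate=0.0
    )
    block = simulate_neutral_alignment(tree, 100, seed=1)
    texts = {r.text for r in block.rows}
    assert len(texts) == 1 and "-" not in texts.pop()


def test_pairwise_identity_matches_closed_form():
    tree = TreeModel(newick="(a:1.0)ref;", indel_rate=0.0)
    expected = tree.expected_identity(1.0)
    idents = []
    for seed in range(50):
        block = simulate_neutral_alignment(tree, 300, seed=seed)
        a, b = (r.text for r in block.rows)
        idents.append(np.mean([x == y for x, y in zip(a, b)]))
    assert np.mean(idents) == pytest.approx(expected, abs=0.05)


def test_simulation_deterministic():
    tree = TreeModel()
    b1 = simulate_neutral_alignment(tree, 150, seed=9)
    b2 = simulate_neutral_alignment(tree, 150, seed=9)
    assert [r.text for r in b1.rows] == [r.text for r in b2.rows]


def test_implant_zero_rate_identical_hairpins():
    tree = TreeModel(newick="(a:0.3,b:0.5)ref;", indel_rate=0.0)
    block = simulate_neutral_alignment(tree, 120, seed=3)
    out, entry = implant_conserved_structure(block, 10, 15, 5, 0.0, seed=4)
    span = slice(10, 10 + 35)
    hairpins = {r.text[span] for r in out.rows}
    assert len(hairpins) == 1
    assert entry.n_compensatory == 0
    assert len(entry.pairs) == 15


def test_implant_compensatory_count_within_binomial_bounds():
    tree = TreeModel(newick="(a:0.1,b:0.1,c:0.1,d:0.1)ref;", indel_rate=0.0)
    total, n_trials = 0, 0
    for seed in range(20):
        block = simulate_neutral_alignment(tree, 120, seed=seed)
        _, entry = implant_conserved_structure(block, 10, 10, 5, 0.5, seed=seed)
        total += entry.n_compensatory
        n_trials += 10 * 4  # pairs x non-reference rows
    p_hat = total / n_trials
    se = (0.5 * 0.5 / n_trials) ** 0.5
    assert abs(p_hat - 0.5) < 3 * se


def test_implant_pairs_preserved_in_all_rows():
    tree = TreeModel(newick="(a:0.4,b:0.6)ref;", indel_rate=0.0)
    block = simulate_neutral_alignment(tree, 120, seed=5)
    out, entry = implant_conserved_structure(block, 20, 12, 6, 0.8, seed=6)
    comp = {"GC", "CG", "AU", "UA", "GU", "UG"}
    g0 = entry.interval.start
    for r in out.rows:
        for i, j in entry.pairs:
            assert r.text[20 + (i - g0)] + r.text[20 + (j - g0)] in comp


def test_implant_region_folds_to_stem(rng):
    tree = TreeModel(newick="(a:0.2,b:0.3)ref;", indel_rate=0.0)
    block = simulate_neutral_alignment(tree, 120, seed=7)
    stem = 14
    out, entry = implant_conserved_structure(block, 30, stem, 5, 0.5, seed=8)
    span = [r.text[30 : 30 + 2 * stem + 5] for r in out.rows]
    _, struct = fold_consensus(span, ScoreParams())
    assert struct.count("(") >= stem


def test_implant_errors():
    tree = TreeModel(newick="(a:0.1)ref;", indel_rate=0.0)
    block = simulate_neutral_alignment(tree, 50, seed=1)
    with pytest.raises(ImplantError):
        implant_conserved_structure(block, 30, 15, 5, 0.5, seed=1)


# ---------------------------------------------------------------------------
# Full fixture coherence


def test_fixture_files_roundtrip_and_consistency(small_fixture, tmp_path):
    fx = small_fixture
    fx.write(tmp_path)
    blocks = list(read_maf(tmp_path / "alignment.maf"))
    assert len(blocks) == len(fx.blocks)
    for orig, reread in zip(fx.blocks[:30], blocks[:30]):
        assert [r.text.upper() for r in orig.rows] == [
            r.text.upper() for r in reread.rows
        ]
    # MAF rows agree with the emitted genomes
    for blk in fx.blocks:
        for r in blk.rows:
            seq = fx.genomes.fetch(r.species, r.chrom, r.start, r.start + r.size)
            assert seq.upper() == r.ungapped().upper()


def test_truth_intervals_lie_inside_blocks(small_fixture):
    fx = small_fixture
    refs = [b.reference_interval() for b in fx.blocks]
    for e in fx.truth.structures:
        assert any(
            r.start <= e.interval.start and e.interval.end <= r.end for r in refs
        )
        # nested, disjoint pair table
        for (i1, j1), (i2, j2) in zip(e.pairs, e.pairs[1:]):
            assert i1 < i2 < j2 < j1


def test_truth_structure_content_is_a_hairpin(small_fixture):
    fx = small_fixture
    comp = {"GC", "CG", "AU", "UA", "GU", "UG"}
    for e in fx.truth.structures[:10]:
        seq = fx.genomes.fetch(
            "ref", e.interval.chrom, e.interval.start, e.interval.end
        ).upper()
        for i, j in e.pairs:
            a = seq[i - e.interval.start]
            b = seq[j - e.interval.start]
            assert a + b in comp


def test_fixture_partition_covers_genome(small_fixture):
    pm = build_partition_map(
        small_fixture.gene_features, small_fixture.chrom_sizes
    )
    pm.validate()


def test_fixture_annotations_within_chromosome(small_fixture):
    size = small_fixture.chrom_sizes["chr1"]
    for iv in small_fixture.repeats + small_fixture.small_rnas:
        assert 0 <= iv.start < iv.end <= size


def test_neutral_blocks_shared_across_rates():
    from strucscreen.synthetic_data import generate_screen_fixture

    a = generate_screen_fixture(
        FixtureConfig(n_neutral_blocks=20, n_implant_blocks=5,
                      compensatory_rate=0.2),
        seed=3,
    )
    b = generate_screen_fixture(
        FixtureConfig(n_neutral_blocks=20, n_implant_blocks=5,
                      compensatory_rate=0.8),
        seed=3,
    )
    implanted_a = {e.interval.start for e in a.truth.structures}
    shared = 0
    for ba, bb in zip(a.blocks, b.blocks):
        if ba.reference_interval().start not in {
            s for s in implanted_a
        } and not any(
            e.interval.overlaps(ba.reference_interval())
            for e in a.truth.structures
        ):
            assert [r.text for r in ba.rows] == [r.text for r in bb.rows]
            shared += 1
    assert shared >= 15


# ---------------------------------------------------------------------------
# Evaluation


def _truth(*ivs):
    return TruthSet(
        structures=[
            TruthEntry(interval=iv, pairs=[], n_compensatory=0) for iv in ivs
        ]
    )


def test_evaluate_perfect_recovery():
    t = _truth(GenomicInterval("c", 10, 60, strand="+"))
    loci = [GenomicInterval("c", 10, 60, strand="+")]
    ev = evaluate_against_truth(loci, t)
    assert ev["recall"] == 1.0 and ev["realised_fdr_nt"] == 0.0


def test_evaluate_empty_loci():
    t = _truth(GenomicInterval("c", 10, 60, strand="+"))
    ev = evaluate_against_truth([], t)
    assert ev["recall"] == 0.0


def test_evaluate_sixty_percent_rule():
    t = _truth(GenomicInterval("c", 0, 100, strand="+"))
    just = [GenomicInterval("c", 0, 60, strand="+")]
    short = [GenomicInterval("c", 0, 59, strand="+")]
    assert evaluate_against_truth(just, t)["recall"] == 1.0
    assert evaluate_against_truth(short, t)["recall"] == 0.0
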