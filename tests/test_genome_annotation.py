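"""Genome partitions, enrichment statistics, GO and sensitivity."""

import math

import numpy as np
import pandas as pd
import pytest

from strucscreen.genome_annotation import (
    PartitionError,
    bh_adjust,
    build_partition_map,
    coverage_enrichment,
    fisher_exact,
    gene_models_from_features,
    go_enrichment,
    mrna_meta_profile,
    repeat_enrichment,
    sensitivity_analysis,
    sensitivity_percent,
)
from strucscreen.intervals import GenomicInterval


def _feat(chrom, start, end, feature, strand="+", gene="g1", tx="t1",
          biotype="protein_coding"):
    return GenomicInterval(
        chrom, start, end, strand=strand, name=gene,
        attributes={
            "Feature": feature,
            "gene_id": gene,
            "transcript_id": tx if feature != "gene" else None,
            "gene_type": biotype,
            "transcript_type": biotype,
        },
    )


def _transcript(start, end, cds_start, cds_end, strand="+", gene="g1", tx="t1",
                chrom="chr1", biotype="protein_coding"):
    feats = [
        _feat(chrom, start, end, "gene", strand, gene, tx, biotype),
        _feat(chrom, start, end, "transcript", strand, gene, tx, biotype),
        _feat(chrom, start, end, "exon", strand, gene, tx, biotype),
    ]
    if cds_start is not None:
        feats.append(_feat(chrom, cds_start, cds_end, "CDS", strand, gene, tx, biotype))
    return feats


SIZES = {"chr1": 1000}


def test_single_transcript_utr_cds_partition():
    feats = _transcript(100, 400, 150, 350)
    pm = build_partition_map(feats, SIZES)
    mrna = pm.classes("mRNA")
    assert [(iv.start, iv.end) for iv in mrna["5UTR"]] == [(100, 150)]
    assert [(iv.start, iv.end) for iv in mrna["CDS"]] == [(150, 350)]
    assert [(iv.start, iv.end) for iv in mrna["3UTR"]] == [(350, 400)]


def test_minus_strand_utr_orientation():
    feats = _transcript(100, 400, 150, 350, strand="-")
    pm = build_partition_map(feats, SIZES)
    mrna = pm.classes("mRNA")
    assert [(iv.start, iv.end) for iv in mrna["3UTR"]] == [(100, 150)]
    assert [(iv.start, iv.end) for iv in mrna["5UTR"]] == [(350, 400)]


def test_overlapping_isoforms_cds_precedence():
    feats = _transcript(100, 400, 150, 350, tx="t1")
    feats += _transcript(100, 500, 150, 300, tx="t2")  # 3'UTR of t2 covers 300-500
    pm = build_partition_map(feats, SIZES)
    cds = pm.classes("mRNA")["CDS"]
    # 300-350 is CDS in t1 and 3'UTR in t2 -> labelled CDS
    assert any(iv.start <= 300 and iv.end >= 350 for iv in cds)
    for iv in pm.classes("mRNA")["3UTR"]:
        assert iv.start >= 350


def test_empty_annotation_everything_intergenic():
    pm = build_partition_map([], SIZES)
    assert [(iv.start, iv.end) for iv in pm.classes("genomic")["intergenic"]] == [
        (0, 1000)
    ]
    assert pm.classes("genomic")["genic"] == []


def test_partition_levels_are_exact(small_fixture):
    pm = build_partition_map(
        small_fixture.gene_features, small_fixture.chrom_sizes
    )
    pm.validate()  # raises on overlap or territory mismatch


def test_cds_outside_exons_rejected():
    feats = [
        _feat("chr1", 100, 200, "transcript"),
        _feat("chr1", 100, 200, "exon"),
        _feat("chr1", 150, 250, "CDS"),
    ]
    with pytest.raises(PartitionError):
        gene_models_from_features(feats)


# ---------------------------------------------------------------------------
# Coverage enrichment


def test_coverage_enrichment_arithmetic():
    classes = {
        "a": [GenomicInterval("c", 0, 1000)],
        "b": [GenomicInterval("c", 1000, 10_000)],
    }
    inputs = [GenomicInterval("c", 0, 10_000)]
    hits = [GenomicInterval("c", 0, 200), GenomicInterval("c", 1000, 1800)]
    rows = {r.label: r for r in coverage_enrichment(hits, inputs, classes)}
    assert rows["a"].enrichment == pytest.approx((200 / 1000) / (1000 / 10_000))


def test_proportional_hits_enrichment_one():
    classes = {
        "a": [GenomicInterval("c", 0, 1000)],
        "b": [GenomicInterval("c", 1000, 4000)],
    }
    inputs = [GenomicInterval("c", 0, 4000)]
    hits = [GenomicInterval("c", 500, 600), GenomicInterval("c", 2000, 2300)]
    for r in coverage_enrichment(hits, inputs, classes):
        assert r.enrichment == pytest.approx(1.0)


def test_enrichment_weighted_mean_is_one(rng):
    bounds = sorted(rng.choice(np.arange(1, 10_000), size=4, replace=False))
    edges = [0, *map(int, bounds), 10_000]
    classes = {
        f"c{i}": [GenomicInterval("c", edges[i], edges[i + 1])]
        for i in range(len(edges) - 1)
    }
    inputs = [GenomicInterval("c", 0, 10_000)]
    hits = []
    for _ in range(40):
        s = int(rng.integers(0, 9900))
        hits.append(GenomicInterval("c", s, s + int(rng.integers(5, 100))))
    rows = coverage_enrichment(hits, inputs, classes)
    tot_inp = sum(r.input_nt for r in rows)
    weighted = sum(r.enrichment * r.input_nt / tot_inp for r in rows)
    assert weighted == pytest.approx(1.0, abs=1e-9)


def test_enrichment_matches_bruteforce_tally(rng):
    """Agreement with a per-nucleotide count over a 10-kb toy genome."""
    size = 10_000
    hits_m = np.zeros(size, bool)
    inp_m = np.zeros(size, bool)
    hits, inputs = [], []
    for _ in range(60):
        s = int(rng.integers(0, size - 120))
        e = s + int(rng.integers(10, 120))
        hits.append(GenomicInterval("c", s, e))
        hits_m[s:e] = True
    for _ in range(40):
        s = int(rng.integers(0, size - 400))
        e = s + int(rng.integers(100, 400))
        inputs.append(GenomicInterval("c", s, e))
        inp_m[s:e] = True
    classes, class_m = {}, {}
    edges = [0, 2500, 5000, 9000, size]
    for i in range(4):
        classes[f"c{i}"] = [GenomicInterval("c", edges[i], edges[i + 1])]
        m = np.zeros(size, bool)
        m[edges[i] : edges[i + 1]] = True
        class_m[f"c{i}"] = m
    rows = {r.label: r for r in coverage_enrichment(hits, inputs, classes)}
    tot_hit = hits_m.sum()
    tot_inp = inp_m.sum()
    for label, m in class_m.items():
        h = int((hits_m & m).sum())
        i = int((inp_m & m).sum())
        assert rows[label].hit_nt == h
        assert rows[label].enrichment == pytest.approx(
            (h / tot_hit) / (i / tot_inp)
        )


def test_repeat_enrichment_consistency_and_floor():
    inputs = [GenomicInterval("c", 0, 10_000)]
    loci = [GenomicInterval("c", i * 500, i * 500 + 50) for i in range(10)]
    repeats = {
        "SINE": [GenomicInterval("c", i * 100, i * 100 + 60) for i in range(30)],
        "rare": [GenomicInterval("c", 9000, 9100)],
    }
    rows = repeat_enrichment(loci, inputs, repeats, min_loci_per_class=5)
    labels = [r.label for r in rows]
    assert labels == ["SINE"]  # class under the floor dropped
    r = rows[0]
    overall = sum(len(l) for l in loci) / 10_000
    assert r.enrichment == pytest.approx(r.coverage / overall)


# ---------------------------------------------------------------------------
# Meta profile


def test_meta_profile_trivial_ratios():
    feats = _transcript(100, 500, 200, 400)
    tx = gene_models_from_features(feats)
    sizes = {"chr1": 1000}
    inputs = [GenomicInterval("chr1", 0, 1000)]
    prof = mrna_meta_profile(inputs, inputs, tx, sizes, bin=10, n_bins_per_segment=5)
    for seg, vals in prof.items():
        assert np.allclose(vals, 1.0), seg
    prof0 = mrna_meta_profile([], inputs, tx, sizes, bin=10, n_bins_per_segment=5)
    for vals in prof0.values():
        assert np.allclose(vals, 0.0)


def test_meta_profile_excludes_short_segments():
    feats = _transcript(100, 500, 130, 470)  # UTRs of 30 nt < 50-nt span
    tx = gene_models_from_features(feats)
    inputs = [GenomicInterval("chr1", 0, 1000)]
    prof = mrna_meta_profile(inputs, inputs, tx, {"chr1": 1000}, bin=10,
                             n_bins_per_segment=5)
    assert np.allclose(prof["utr5"], 0.0) and np.allclose(prof["utr3"], 0.0)
    assert np.allclose(prof["cds_start"], 1.0)


# ---------------------------------------------------------------------------
# Fisher / BH


def _fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration over tables with
    the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, a2) * math.comb(r2, c1 - a2)
        if w <= obs:
            num += w
    return num / math.comb(n, c1)


def test_fisher_examples_and_boundaries():
    assert fisher_exact(0, 5, 5, 0) == pytest.approx(_fisher_oracle(0, 5, 5, 0))
    assert fisher_exact(0, 0, 0, 0) == 1.0
    with pytest.raises(ValueError):
        fisher_exact(-1, 2, 3, 4)


def test_fisher_matches_oracle_on_random_tables(rng):
    for _ in range(150):
        a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
        assert fisher_exact(a, b, c, d) == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12
        )


def test_bh_worked_example():
    adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert all(rej)


def test_bh_order_invariant_and_monotone(rng):
    ps = rng.random(20).tolist()
    adj, _ = bh_adjust(ps)
    perm = rng.permutation(20)
    adj_p, _ = bh_adjust([ps[i] for i in perm])
    assert np.allclose([adj[i] for i in perm], adj_p)
    order = np.argsort(ps)
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# GO enrichment


def _go_setup():
    feats = []
    for k in range(6):
        start = 1000 * k
        feats += _transcript(
            start, start + 900, start + 100, start + 600,
            gene=f"g{k}", tx=f"g{k}.t",
        )
    tx = gene_models_from_features(feats)
    return tx


def test_go_single_term_all_genes_is_unity():
    tx = _go_setup()
    g2g = pd.DataFrame(
        {"gene_id": [f"g{k}" for k in range(6)], "term": "T", "ontology": "MF"}
    )
    loci = [GenomicInterval("chr1", 1000 * k + 650, 1000 * k + 700) for k in range(3)]
    rows = [r for r in go_enrichment(loci, tx, g2g) if r.region == "3UTR"]
    assert len(rows) == 1
    assert rows[0].cov_e == pytest.approx(1.0)
    assert rows[0].cnt_e == pytest.approx(1.0)
    assert rows[0].p == pytest.approx(1.0)


def test_go_enriched_term_detected():
    tx = _go_setup()
    g2g = pd.DataFrame(
        {
            "gene_id": [f"g{k}" for k in range(6)],
            "term": ["RICH"] * 3 + ["POOR"] * 3,
            "ontology": "MF",
        }
    )
    loci = [GenomicInterval("chr1", 1000 * k + 650, 1000 * k + 700) for k in range(3)]
    rows = {
        r.term: r for r in go_enrichment(loci, tx, g2g) if r.region == "3UTR"
    }
    assert rows["RICH"].cov_e == pytest.approx(2.0)
    assert rows["POOR"].cov_e == 0.0
    assert rows["RICH"].p_adj >= rows["RICH"].p - 1e-12


def test_go_count_rule_requires_half_locus_overlap():
    tx = _go_setup()
    g2g = pd.DataFrame({"gene_id": ["g0"], "term": ["T"], "ontology": ["MF"]})
    # locus of 100 nt overlapping the 3'UTR of g0 by 49 nt only
    locus = GenomicInterval("chr1", 549, 649)
    rows = [r for r in go_enrichment([locus], tx, g2g) if r.region == "3UTR"]
    assert rows[0].cnt_e == 0.0


# ---------------------------------------------------------------------------
# Sensitivity


def test_sensitivity_percent_rounding():
    assert sensitivity_percent(201, 450) == 45
    assert sensitivity_percent(1, 2) == 50


def _ann(start, end, strand="+", cls="miRNA"):
    return GenomicInterval(
        "c", start, end, strand=strand, name=cls, attributes={"rna_class": cls}
    )


def test_sensitivity_filter_and_found_rules():
    footprint = [GenomicInterval("c", 0, 200), GenomicInterval("c", 300, 500)]
    anns = [
        _ann(50, 150),              # inside footprint
        _ann(150, 250),             # only 50% inside one interval -> filtered out
        _ann(380, 480),             # inside; locus below covers 60%
        _ann(0, 100, strand="-"),   # inside; locus on wrong strand
    ]
    loci = [
        GenomicInterval("c", 50, 150, strand="+"),
        GenomicInterval("c", 380, 440, strand="+"),
        GenomicInterval("c", 0, 100, strand="+"),
    ]
    rows = sensitivity_analysis(anns, footprint, loci)
    (r,) = rows
    assert (r.annotated, r.filtered, r.found) == (4, 3, 2)
    assert r.percent == 67


def test_sensitivity_79_percent_inside_not_filtered():
    footprint = [GenomicInterval("c", 0, 79)]
    anns = [_ann(0, 100)]
    (r,) = sensitivity_analysis(anns, footprint, [])
    assert r.filtered == 0 and r.percent is None
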