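"""Hierarchical genome partitions and downstream enrichment statistics.

The genome is labelled level by level — genomic (genic, intergenic),
genic (exonic, intronic), exonic (mRNA, noncoding, other), mRNA
(5'UTR, CDS, 3'UTR) and noncoding (lncRNA, sncRNA) — with precedence
rules resolving overlapping isoforms (CDS > 3'UTR > 5'UTR, mRNA >
noncoding > other, sncRNA > lncRNA), so that every level is an exact,
disjoint partition of its parent's territory.

On top of the partitions: nucleotide-coverage enrichment of screen hits
per class, repeat-class enrichment, an mRNA meta-profile anchored at the
start/stop codons, Fisher/Benjamini-Hochberg GO enrichment, and the
small-RNA sensitivity tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import (
    GenomicInterval,
    by_chrom,
    complement,
    intersect,
    merge_intervals,
    overlap_nt,
    subtract,
    total_length,
)

MRNA_BIOTYPES = {"protein_coding"}
LNC_BIOTYPES = {"lncRNA", "lincRNA", "antisense", "processed_transcript"}
SNC_BIOTYPES = {
    "miRNA",
    "snRNA",
    "snoRNA",
    "scaRNA",
    "tRNA",
    "sncRNA",
    "misc_RNA",
    "rRNA",
}


class PartitionError(ValueError):
    pass


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def utrs(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """(5'UTR, 3'UTR) intervals: exonic sequence before/after the CDS
        in transcript orientation."""
        if not self.cds:
            return [], []
        cds_start = min(iv.start for iv in self.cds)
        cds_end = max(iv.end for iv in self.cds)
        non_cds = subtract(self.exons, self.cds)
        before = [iv for iv in non_cds if iv.end <= cds_start]
        after = [iv for iv in non_cds if iv.start >= cds_end]
        if self.strand == "+":
            return before, after
        return after, before


def gene_models_from_features(
    features: Iterable[GenomicInterval],
) -> list[TranscriptModel]:
    """Assemble transcript models from GTF-derived intervals (expects
    'transcript'/'exon'/'CDS' feature rows with transcript_id)."""
    tx: dict[str, TranscriptModel] = {}
    for iv in features:
        feat = iv.attributes.get("Feature")
        tid = iv.attributes.get("transcript_id")
        if not tid:
            continue
        if tid not in tx:
            bt = (
                iv.attributes.get("transcript_type")
                or iv.attributes.get("transcript_biotype")
                or iv.attributes.get("gene_type")
                or "other"
            )
            tx[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=iv.attributes.get("gene_id", tid),
                chrom=iv.chrom,
                strand=iv.strand,
                biotype=bt,
            )
        elif tx[tid].biotype == "other":
            bt = iv.attributes.get("transcript_type") or iv.attributes.get(
                "gene_type"
            )
            if bt:
                tx[tid].biotype = bt
        if feat == "exon":
            tx[tid].exons.append(iv)
        elif feat == "CDS":
            tx[tid].cds.append(iv)
    for t in tx.values():
        if t.cds and total_length(t.cds) != overlap_nt(t.cds, t.exons):
            raise PartitionError(
                f"transcript {t.transcript_id}: CDS outside exons"
            )
    return list(tx.values())


@dataclass
class PartitionMap:
    """Level-wise disjoint labelling of the genome."""

    levels: dict[str, dict[str, list[GenomicInterval]]]
    chrom_sizes: dict[str, int]

    PARENTS = {
        "genic": ("genomic", "genic"),
        "exonic": ("genic", "exonic"),
        "mRNA": ("exonic", "mRNA"),
        "noncoding": ("exonic", "noncoding"),
    }

    def classes(self, level: str) -> dict[str, list[GenomicInterval]]:
        return self.levels[level]

    def territory(self, level: str) -> list[GenomicInterval]:
        if level == "genomic":
            return [
                GenomicInterval(c, 0, s) for c, s in self.chrom_sizes.items()
            ]
        parent_level, parent_label = self.PARENTS[level]
        return self.levels[parent_level][parent_label]

    def validate(self) -> None:
        for level, classes in self.levels.items():
            terr = total_length(self.territory(level))
            tot = 0
            all_ivs: list[GenomicInterval] = []
            for ivs in classes.values():
                tot += total_length(ivs)
                all_ivs.extend(ivs)
            if total_length(all_ivs) != tot:
                raise PartitionError(f"level {level}: classes overlap")
            if tot != terr:
                raise PartitionError(
                    f"level {level}: classes cover {tot} nt of {terr} nt territory"
                )


def build_partition_map(
    features: Iterable[GenomicInterval], chrom_sizes: dict[str, int]
) -> PartitionMap:
    """Project gene annotation hierarchically onto the genome."""
    features = list(features)
    transcripts = gene_models_from_features(features)
    genes = [f for f in features if f.attributes.get("Feature") == "gene"]
    if not genes:  # fall back to transcript spans
        genes = [
            GenomicInterval(t.chrom, min(e.start for e in t.exons),
                            max(e.end for e in t.exons))
            for t in transcripts
            if t.exons
        ]
    genic = merge_intervals(genes)
    intergenic = complement(genic, chrom_sizes)
    all_exons = merge_intervals(
        [e for t in transcripts for e in t.exons]
    )
    exonic = intersect(all_exons, genic)
    intronic = subtract(genic, exonic)

    mrna_tx = [t for t in transcripts if t.biotype in MRNA_BIOTYPES and t.cds]
    mrna = merge_intervals([e for t in mrna_tx for e in t.exons])
    snc = subtract(
        [e for t in transcripts if t.biotype in SNC_BIOTYPES for e in t.exons],
        mrna,
    )
    lnc = subtract(
        [e for t in transcripts if t.biotype in LNC_BIOTYPES for e in t.exons],
        mrna + snc,
    )
    noncoding = merge_intervals(snc + lnc)
    other = subtract(exonic, mrna + noncoding)

    cds = merge_intervals([c for t in mrna_tx for c in t.cds])
    utr5_raw, utr3_raw = [], []
    for t in mrna_tx:
        u5, u3 = t.utrs()
        utr5_raw.extend(u5)
        utr3_raw.extend(u3)
    utr3 = subtract(utr3_raw, cds)
    utr5 = subtract(utr5_raw, cds + utr3)

    pm = PartitionMap(
        levels={
            "genomic": {"genic": genic, "intergenic": intergenic},
            "genic": {"exonic": exonic, "intronic": intronic},
            "exonic": {"mRNA": mrna, "noncoding": noncoding, "other": other},
            "mRNA": {"5UTR": utr5, "CDS": cds, "3UTR": utr3},
            "noncoding": {"lncRNA": lnc, "sncRNA": snc},
        },
        chrom_sizes=dict(chrom_sizes),
    )
    # mRNA territory may exceed CDS+UTRs when isoform UTR/CDS overlap; fold
    # any residue into the UTR classes by precedence order
    residue = subtract(pm.levels["exonic"]["mRNA"], utr5 + cds + utr3)
    if residue:
        pm.levels["mRNA"]["3UTR"] = merge_intervals(utr3 + residue)
    pm.validate()
    return pm


# ---------------------------------------------------------------------------
# Coverage enrichment


@dataclass
class EnrichmentRow:
    label: str
    hit_nt: int
    input_nt: int
    coverage: float
    enrichment: float


def coverage_enrichment(
    hits: Sequence[GenomicInterval],
    input_windows: Sequence[GenomicInterval],
    classes: dict[str, Sequence[GenomicInterval]],
    min_overlap_nt: int = 1,
) -> list[EnrichmentRow]:
    """Per class: enrichment = (class hit nt / total hit nt) /
    (class input nt / total input nt), strand-agnostic.

    The input-fraction-weighted mean enrichment over a partition is 1 by
    construction.  Classes with zero input nucleotides are excluded.
    """
    del min_overlap_nt  # any positive overlap contributes nucleotides
    per_class = {}
    for label, ivs in classes.items():
        per_class[label] = (
            overlap_nt(hits, ivs),
            overlap_nt(input_windows, ivs),
        )
    tot_hit = sum(h for h, _ in per_class.values())
    tot_inp = sum(i for _, i in per_class.values())
    rows = []
    for label, (h, i) in per_class.items():
        if i == 0:
            continue
        rows.append(
            EnrichmentRow(
                label=label,
                hit_nt=h,
                input_nt=i,
                coverage=h / i,
                enrichment=(h / tot_hit) / (i / tot_inp) if tot_hit else 0.0,
            )
        )
    return rows


def repeat_enrichment(
    loci: Sequence[GenomicInterval],
    input_windows: Sequence[GenomicInterval],
    repeats_by_class: dict[str, Sequence[GenomicInterval]],
    min_loci_per_class: int = 1000,
) -> list[EnrichmentRow]:
    """Repeat-class enrichment of high-confidence loci.

    enrichment = (locus nt overlapping the class / total locus nt) /
    (input nt overlapping the class / total input nt); coverage is the
    fraction of the class's input nucleotides covered by loci.  Classes
    with *min_loci_per_class* or fewer annotated elements are dropped.
    """
    tot_locus = total_length(loci)
    tot_input = total_length(input_windows)
    rows = []
    for label, ivs in repeats_by_class.items():
        if len(ivs) <= min_loci_per_class:
            continue
        class_input = intersect(ivs, input_windows)
        ci = total_length(class_input)
        if ci == 0 or tot_locus == 0:
            continue
        ovl = overlap_nt(loci, class_input)
        rows.append(
            EnrichmentRow(
                label=label,
                hit_nt=ovl,
                input_nt=ci,
                coverage=ovl / ci,
                enrichment=(ovl / tot_locus) / (ci / tot_input),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# mRNA meta-profile


def _mask(intervals: Sequence[GenomicInterval], sizes: dict[str, int]):
    masks = {c: np.zeros(s, dtype=bool) for c, s in sizes.items()}
    for iv in merge_intervals(intervals):
        if iv.chrom in masks:
            masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mrna_meta_profile(
    hits: Sequence[GenomicInterval],
    input_windows: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    chrom_sizes: dict[str, int],
    bin: int = 10,
    n_bins_per_segment: int = 5,
) -> dict[str, np.ndarray]:
    """Hit/input coverage ratio per 10-nt bin around the start and stop
    codons (segments: 5'UTR into start, CDS after start, CDS before
    stop, 3'UTR after stop), in spliced transcript coordinates.
    Transcripts whose segment is shorter than the profiled span are
    excluded from that segment.
    """
    hit_m = _mask(hits, chrom_sizes)
    inp_m = _mask(input_windows, chrom_sizes)
    span = bin * n_bins_per_segment
    hit_counts = {
        seg: np.zeros(n_bins_per_segment)
        for seg in ("utr5", "cds_start", "cds_end", "utr3")
    }
    inp_counts = {
        seg: np.zeros(n_bins_per_segment)
        for seg in ("utr5", "cds_start", "cds_end", "utr3")
    }
    for t in transcripts:
        if t.biotype not in MRNA_BIOTYPES or not t.cds:
            continue
        u5, u3 = t.utrs()
        cds = merge_intervals(t.cds)
        segments = {
            "utr5": (u5, "end"),      # positions walking away from start codon
            "cds_start": (cds, "start"),
            "cds_end": (cds, "end"),
            "utr3": (u3, "start"),
        }
        for seg, (ivs, anchor) in segments.items():
            positions = _spliced_positions(ivs, t.strand)
            if len(positions) < span:
                continue
            window = (
                positions[:span] if anchor == "start" else positions[-span:][::-1]
            )
            hm, im = hit_m[t.chrom], inp_m[t.chrom]
            for b in range(n_bins_per_segment):
                for pos in window[b * bin : (b + 1) * bin]:
                    hit_counts[seg][b] += hm[pos]
                    inp_counts[seg][b] += im[pos]
    out = {}
    for seg in hit_counts:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[seg] = np.where(
                inp_counts[seg] > 0, hit_counts[seg] / inp_counts[seg], 0.0
            )
    return out


def _spliced_positions(ivs: Sequence[GenomicInterval], strand: str) -> list[int]:
    pos: list[int] = []
    for iv in sorted(ivs, key=lambda x: x.start):
        pos.extend(range(iv.start, iv.end))
    return pos if strand == "+" else pos[::-1]


# ---------------------------------------------------------------------------
# Fisher / Benjamini-Hochberg


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a,b],[c,d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(
    p_list: Sequence[float], q: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up adjustment and significance at FDR q."""
    if len(p_list) == 0:
        return [], []
    reject, p_adj, _, _ = multipletests(p_list, alpha=q, method="fdr_bh")
    return [float(x) for x in p_adj], [bool(x) for x in reject]


# ---------------------------------------------------------------------------
# GO enrichment


@dataclass
class GOEnrichmentRow:
    term: str
    region: str
    ontology: str
    cov_e: float
    cnt_e: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False


def read_gene2go(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str
    )
    df.columns = ["gene_id", "term"] + (
        ["ontology"] if df.shape[1] > 2 else []
    )
    if "ontology" not in df:
        df["ontology"] = "all"
    return df


def go_enrichment(
    loci: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    gene2go: pd.DataFrame,
    q: float = 0.05,
) -> list[GOEnrichmentRow]:
    """GO-term enrichment of locus coverage in 5'UTR/CDS/3'UTR.

    Per gene, protein-coding isoform coordinates are collapsed per
    region.  COV_E compares nucleotide coverage fractions; CNT_E
    compares gene counts, a gene counting as hit when at least one locus
    overlaps it with >=50% of the locus length.  Fisher p is computed on
    the count table and BH-adjusted within each ontology separately.
    Genes without GO annotation are excluded throughout.
    """
    regions: dict[str, dict[str, list[GenomicInterval]]] = {
        "5UTR": {},
        "CDS": {},
        "3UTR": {},
    }
    for t in transcripts:
        if t.biotype not in MRNA_BIOTYPES or not t.cds:
            continue
        u5, u3 = t.utrs()
        for reg, ivs in (("5UTR", u5), ("CDS", t.cds), ("3UTR", u3)):
            regions[reg].setdefault(t.gene_id, []).extend(ivs)
    for reg in regions:
        regions[reg] = {
            g: merge_intervals(ivs) for g, ivs in regions[reg].items() if ivs
        }
    annotated = set(gene2go["gene_id"])
    rows: list[GOEnrichmentRow] = []
    for reg, per_gene in regions.items():
        genes = {g: ivs for g, ivs in per_gene.items() if g in annotated}
        if not genes:
            continue
        gene_len = {g: total_length(ivs) for g, ivs in genes.items()}
        gene_hit_nt = {g: overlap_nt(loci, ivs) for g, ivs in genes.items()}
        gene_hit = {
            g: any(
                overlap_nt([l], ivs) * 2 >= len(l)
                for l in loci
                if l.chrom == ivs[0].chrom
            )
            for g, ivs in genes.items()
        }
        tot_len = sum(gene_len.values())
        tot_hit_nt = sum(gene_hit_nt.values())
        n_genes = len(genes)
        n_hit_genes = sum(gene_hit.values())
        for ontology, sub in gene2go.groupby("ontology"):
            for term, term_genes_df in sub.groupby("term"):
                tg = [g for g in set(term_genes_df["gene_id"]) if g in genes]
                if not tg:
                    continue
                t_len = sum(gene_len[g] for g in tg)
                t_hit_nt = sum(gene_hit_nt[g] for g in tg)
                t_genes = len(tg)
                t_hit_genes = sum(gene_hit[g] for g in tg)
                cov_e = (
                    (t_hit_nt / tot_hit_nt) / (t_len / tot_len)
                    if tot_hit_nt and t_len
                    else 0.0
                )
                cnt_e = (
                    (t_hit_genes / n_hit_genes) / (t_genes / n_genes)
                    if n_hit_genes and t_genes
                    else 0.0
                )
                p = fisher_exact(
                    t_hit_genes,
                    t_genes - t_hit_genes,
                    n_hit_genes - t_hit_genes,
                    (n_genes - t_genes) - (n_hit_genes - t_hit_genes),
                )
                rows.append(
                    GOEnrichmentRow(
                        term=term,
                        region=reg,
                        ontology=str(ontology),
                        cov_e=cov_e,
                        cnt_e=cnt_e,
                        p=p,
                    )
                )
    for ontology in {r.ontology for r in rows}:
        group = [r for r in rows if r.ontology == ontology]
        p_adj, rej = bh_adjust([r.p for r in group], q=q)
        for r, pa, rj in zip(group, p_adj, rej):
            r.p_adj = pa
            r.significant = rj
    return rows


# ---------------------------------------------------------------------------
# Small-RNA sensitivity


def sensitivity_percent(found: int, filtered: int) -> int:
    """Nearest-integer percentage of filtered annotations recovered."""
    return int(np.floor(100.0 * found / filtered + 0.5))


@dataclass
class SensitivityRow:
    rna_class: str
    annotated: int
    filtered: int
    found: int
    percent: int | None


def sensitivity_analysis(
    annotations: Sequence[GenomicInterval],
    footprint: Sequence[GenomicInterval],
    loci: Sequence[GenomicInterval],
    class_key: str = "rna_class",
    min_inside: float = 0.8,
    min_found: float = 0.6,
) -> list[SensitivityRow]:
    """Recovery statistics for annotated small RNAs.

    filtered: annotations with at least *min_inside* of their length
    inside a single contiguous interval of the screened-alignment
    footprint.  found: filtered annotations with at least *min_found* of
    their length covered by one locus reported on the annotated strand.
    """
    fp = merge_intervals(footprint)
    fp_by_chrom = by_chrom(fp)
    loci_by_chrom = by_chrom(loci)
    per_class: dict[str, list[int]] = {}
    for ann in annotations:
        label = str(ann.attributes.get(class_key, ann.name or "all"))
        tallies = per_class.setdefault(label, [0, 0, 0])
        tallies[0] += 1
        best_inside = max(
            (ann.overlap_len(iv) for iv in fp_by_chrom.get(ann.chrom, [])),
            default=0,
        )
        if best_inside < min_inside * len(ann):
            continue
        tallies[1] += 1
        hit = any(
            l.strand == ann.strand
            and ann.overlap_len(l) >= min_found * len(ann)
            for l in loci_by_chrom.get(ann.chrom, [])
        )
        if hit:
            tallies[2] += 1
    rows = []
    for label in sorted(per_class):
        annotated, filtered, found = per_class[label]
        rows.append(
            SensitivityRow(
                rna_class=label,
                annotated=annotated,
                filtered=filtered,
                found=found,
                percent=sensitivity_percent(found, filtered) if filtered else None,
            )
        )
    return rows


def sensitivity_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.rna_class,
                "annotated": r.annotated,
                "filtered": r.filtered,
                "found": r.found,
                "percent": r.percent,
            }
            for r in rows
        ]
    )
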