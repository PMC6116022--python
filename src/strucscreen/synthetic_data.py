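"""Self-contained benchmark genomes with known ground truth.

A reference-rooted phylogeny (the substitution model is reversible, so
rooting at the reference leaf is distribution-preserving) generates
neutral alignment blocks with F81 substitutions and geometric-length
indels.  Conserved hairpins with compensatory (structure-preserving)
mutations are implanted into a configurable subset of blocks, biased
towards 3'-UTR territory.  The generator emits a coherent mini-genome
per species: MAF blocks, FASTA genomes, GTF gene models (protein-coding
with UTRs/CDS/introns, lncRNA, small-RNA genes at implants), repeat and
small-RNA BED annotations, a gene-to-GO-term table, and the TruthSet
used for recall and FDR evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import (
    GAP,
    AlignmentBlock,
    AlignmentRow,
    InMemoryGenomes,
    write_maf,
)
from .intervals import GenomicInterval

BASES = "ACGU"
#: directional pair types and sampling weights for implanted stems
STEM_PAIRS = ("GC", "CG", "AU", "UA", "GU", "UG")
STEM_PAIR_WEIGHTS = (0.2, 0.2, 0.2, 0.2, 0.1, 0.1)

DEFAULT_TREE_NEWICK = (
    "(sister:0.12,(sp3:0.15,(sp4:0.25,(sp5:0.35,"
    "(sp6:0.5,(sp7:0.6,sp8:0.8):0.15):0.12):0.1):0.1):0.2)ref;"
)


@dataclass
class _Node:
    name: str
    length: float
    children: list


def _parse_newick(newick: str) -> _Node:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(nd) -> _Node:
        name = nd.taxon.label if nd.taxon else (nd.label or "")
        return _Node(
            name=name,
            length=nd.edge.length or 0.0,
            children=[convert(c) for c in nd.child_nodes()],
        )

    return convert(tree.seed_node)


@dataclass
class TreeModel:
    """Reference-rooted phylogeny with an F81 substitution model.

    Branch lengths are expected substitutions per site; ``indel_rate``
    is indel events per site per unit branch length, with geometric
    lengths of mean ``indel_mean_len``.
    """

    newick: str = DEFAULT_TREE_NEWICK
    freqs: tuple[float, float, float, float] = (0.27, 0.23, 0.23, 0.27)
    indel_rate: float = 0.01
    indel_mean_len: float = 3.0
    reference: str = "ref"

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("equilibrium frequencies must sum to 1")
        self.root = _parse_newick(self.newick)
        if self.root.name != self.reference:
            raise ValueError("tree must be rooted at the reference species")
        self.beta = 1.0 / (1.0 - sum(f * f for f in self.freqs))

    def leaves(self) -> list[str]:
        out = []

        def walk(nd):
            if not nd.children:
                out.append(nd.name)
            for c in nd.children:
                walk(c)

        walk(self.root)
        return out

    def species(self) -> list[str]:
        return [self.reference] + self.leaves()

    def expected_identity(self, distance: float) -> float:
        """Closed-form probability that two sequences at the given total
        path distance show the same base at a site (F81)."""
        e = math.exp(-self.beta * distance)
        return e + (1.0 - e) * sum(f * f for f in self.freqs)

    def distance_from_reference(self, species: str) -> float:
        def walk(nd, acc):
            if nd.name == species and not nd.children:
                return acc
            for c in nd.children:
                hit = walk(c, acc + c.length)
                if hit is not None:
                    return hit
            return None

        if species == self.reference:
            return 0.0
        d = walk(self.root, 0.0)
        if d is None:
            raise KeyError(species)
        return d


# ---------------------------------------------------------------------------
# Neutral alignment simulation


def _simulate_alignment(
    tree: TreeModel,
    length: int,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
    protected: Sequence[tuple[int, int]] = (),
) -> tuple[dict[str, str], list]:
    """Evolve a root sequence down the tree; returns gapped texts per
    species (root = reference) and the column-origin list.

    ``protected`` spans (root coordinates) are shielded from indels so
    that implanted structures keep a gap-free footprint in every row.
    """
    freqs = np.asarray(tree.freqs)
    root_seq = rng.choice(4, size=length, p=freqs)
    protected_ids = set()
    for a, b in protected:
        protected_ids.update(range(a, b))
    order: list = list(range(length))
    ins_counter = [length]
    states: dict[str, list[tuple[int, int]]] = {
        tree.reference: [(i, int(c)) for i, c in enumerate(root_seq)]
    }

    def evolve(parent_state, node):
        t = node.length * rate_scale
        state = list(parent_state)
        if t > 0:
            codes = np.array([c for _, c in state])
            keep = rng.random(len(state)) < math.exp(-tree.beta * t)
            redraw = rng.choice(4, size=len(state), p=freqs)
            codes = np.where(keep, codes, redraw)
            state = [(cid, int(c)) for (cid, _), c in zip(state, codes)]
            n_events = rng.poisson(tree.indel_rate * t * len(state))
            for _ in range(n_events):
                if not state:
                    break
                ln = int(rng.geometric(1.0 / tree.indel_mean_len))
                if rng.random() < 0.5:  # deletion
                    pos = int(rng.integers(len(state)))
                    chunk = state[pos : pos + ln]
                    if any(cid in protected_ids for cid, _ in chunk):
                        continue
                    del state[pos : pos + ln]
                else:  # insertion
                    pos = int(rng.integers(len(state) + 1))
                    prev_id = state[pos - 1][0] if pos > 0 else None
                    next_id = state[pos][0] if pos < len(state) else None
                    if prev_id in protected_ids and next_id in protected_ids:
                        continue
                    new_ids = []
                    anchor = order.index(prev_id) if prev_id is not None else -1
                    for k in range(ln):
                        nid = ins_counter[0]
                        ins_counter[0] += 1
                        order.insert(anchor + 1 + k, nid)
                        new_ids.append(nid)
                    chars = rng.choice(4, size=ln, p=freqs)
                    state[pos:pos] = [
                        (nid, int(c)) for nid, c in zip(new_ids, chars)
                    ]
        if node.children:
            for child in node.children:
                evolve(state, child)
        if node.name:
            states[node.name] = state

    for child in tree.root.children:
        evolve(states[tree.reference], child)

    texts = {}
    col_index = {cid: k for k, cid in enumerate(order)}
    for name, state in states.items():
        arr = [GAP] * len(order)
        for cid, code in state:
            arr[col_index[cid]] = BASES[code]
        texts[name] = "".join(arr)
    return texts, order


def _drop_all_gap_columns(texts: dict[str, str]) -> dict[str, str]:
    keys = list(texts)
    cols = [
        c
        for c in range(len(texts[keys[0]]))
        if any(texts[k][c] != GAP for k in keys)
    ]
    return {k: "".join(texts[k][c] for c in cols) for k in keys}


def simulate_neutral_alignment(
    tree: TreeModel,
    length: int,
    seed: int,
    rate_scale: float = 1.0,
    species: Sequence[str] | None = None,
) -> AlignmentBlock:
    """One neutral alignment block (reference row first, placeholder
    provenance on chromosome ``sim``)."""
    rng = np.random.default_rng(seed)
    texts, _ = _simulate_alignment(tree, length, rng, rate_scale)
    keep = list(species) if species else tree.species()
    if tree.reference not in keep:
        keep = [tree.reference] + keep
    texts = _drop_all_gap_columns({k: texts[k] for k in keep})
    rows = []
    for name in keep:
        t = texts[name]
        size = len(t) - t.count(GAP)
        rows.append(
            AlignmentRow(
                species=name,
                chrom="sim",
                start=0,
                size=size,
                strand="+",
                src_size=max(size, 1),
                text=t,
            )
        )
    return AlignmentBlock(rows=rows, source_id=f"sim{seed}")


# ---------------------------------------------------------------------------
# Structure implantation


@dataclass
class TruthEntry:
    interval: GenomicInterval
    pairs: list[tuple[int, int]]
    n_compensatory: int
    rna_class: str = ""


@dataclass
class TruthSet:
    structures: list[TruthEntry] = field(default_factory=list)
    neutral: list[GenomicInterval] = field(default_factory=list)


class ImplantError(ValueError):
    pass


def _sample_pair(rng: np.random.Generator, exclude: str | None = None) -> str:
    pairs = [p for p in STEM_PAIRS if p != exclude]
    w = np.array(
        [STEM_PAIR_WEIGHTS[STEM_PAIRS.index(p)] for p in pairs], dtype=float
    )
    return pairs[int(rng.choice(len(pairs), p=w / w.sum()))]


def implant_conserved_structure(
    block: AlignmentBlock,
    position: int,
    stem_len: int,
    loop_len: int,
    compensatory_rate: float,
    seed: int | np.random.Generator,
) -> tuple[AlignmentBlock, TruthEntry]:
    """Write a conserved hairpin into the block at column *position*.

    The reference row receives complementary stems around a loop; every
    other row carries the same hairpin, with each pair independently
    mutated to a different complementary pair with probability
    *compensatory_rate* (both partners change; pairing is preserved).
    The implant span must be gap-free in all rows.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    span = 2 * stem_len + loop_len
    if position < 0 or position + span > block.n_cols:
        raise ImplantError(
            f"implant span [{position},{position + span}) exceeds block "
            f"of {block.n_cols} columns"
        )
    for r in block.rows:
        if GAP in r.text[position : position + span]:
            raise ImplantError(
                f"implant span contains gaps in row {r.species}"
            )
    ref_pairs = [_sample_pair(rng) for _ in range(stem_len)]
    freqs = np.ones(4) / 4
    loop = "".join(BASES[i] for i in rng.choice(4, size=loop_len, p=freqs))
    n_comp = 0
    new_rows = []
    for ridx, r in enumerate(block.rows):
        if ridx == 0:
            row_pairs = ref_pairs
        else:
            row_pairs = []
            for p in ref_pairs:
                if rng.random() < compensatory_rate:
                    row_pairs.append(_sample_pair(rng, exclude=p))
                    n_comp += 1
                else:
                    row_pairs.append(p)
        stem5 = "".join(p[0] for p in row_pairs)
        stem3 = "".join(p[1] for p in reversed(row_pairs))
        hairpin = stem5 + loop + stem3
        text = r.text[:position] + hairpin + r.text[position + span :]
        new_rows.append(replace(r, text=text))
    ref = new_rows[0]
    offset = position - ref.text[:position].count(GAP)
    gstart = ref.start + offset
    pairs = [
        (gstart + k, gstart + span - 1 - k) for k in range(stem_len)
    ]
    entry = TruthEntry(
        interval=GenomicInterval(
            ref.chrom, gstart, gstart + span, strand="+"
        ),
        pairs=pairs,
        n_compensatory=n_comp,
    )
    return AlignmentBlock(new_rows, source_id=block.source_id), entry


# ---------------------------------------------------------------------------
# Full screen fixture


@dataclass
class FixtureConfig:
    """Study conditions for the benchmark mini-genome."""

    n_neutral_blocks: int = 800
    n_implant_blocks: int = 200
    compensatory_rate: float = 0.5
    stem_len: tuple[int, int] = (26, 34)
    loop_len: tuple[int, int] = (5, 9)
    #: block lengths are offset + exponential, emulating the decaying
    #: length spectrum of fragmented genome alignments
    block_len_offset: int = 30
    block_len_mean: float = 90.0
    block_len_range: tuple[int, int] = (30, 400)
    spacer_len: tuple[int, int] = (40, 120)
    rate_scale_mu: float = -0.1
    rate_scale_sigma: float = 0.4
    n_other_species_probs: tuple = (0.12, 0.18, 0.2, 0.15, 0.13, 0.12, 0.1)
    split_block_prob: float = 0.07
    utr3_bias: float = 0.6
    repeat_fraction: float = 0.15
    gene_block_span: int = 8
    tree: TreeModel = field(default_factory=TreeModel)

    def validate(self) -> None:
        span = 2 * self.stem_len[1] + self.loop_len[1]
        if span + 6 > self.block_len_range[1]:
            raise ValueError("implants cannot exceed the maximum block length")
        if self.n_implant_blocks < 0 or self.n_neutral_blocks < 0:
            raise ValueError("negative block counts")


REPEAT_CLASSES = ("SINE-like", "LINE-like", "Simple-like", "Satellite-like")
REPEAT_CLASS_P = (0.4, 0.3, 0.2, 0.1)
SMALL_RNA_CLASSES = ("miRNA", "snoRNA", "snRNA", "scaRNA", "tRNA")
SMALL_RNA_CLASS_P = (0.4, 0.25, 0.15, 0.1, 0.1)


@dataclass
class ScreenFixture:
    blocks: list[AlignmentBlock]
    genomes: InMemoryGenomes
    chrom_sizes: dict[str, int]
    gene_features: list[GenomicInterval]
    repeats: list[GenomicInterval]
    small_rnas: list[GenomicInterval]
    gene2go: "object"
    truth: TruthSet
    config: FixtureConfig
    seed: int

    def write(self, outdir) -> None:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_maf(self.blocks, outdir / "alignment.maf")
        self.genomes.write_fasta_dir(outdir / "genomes")
        _write_gtf(self.gene_features, outdir / "genes.gtf")
        from .alignment_io import write_bed

        write_bed(
            [iv.with_fields(name=iv.attributes.get("repeat_class", iv.name))
             for iv in self.repeats],
            outdir / "repeats.bed",
        )
        write_bed(
            [iv.with_fields(name=iv.attributes.get("rna_class", iv.name))
             for iv in self.small_rnas],
            outdir / "small_rnas.bed",
        )
        pd.DataFrame(self.gene2go).to_csv(
            outdir / "gene2go.tsv", sep="\t", header=False, index=False
        )
        truth = {
            "structures": [
                {
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "strand": e.interval.strand,
                    "pairs": e.pairs,
                    "n_compensatory": e.n_compensatory,
                    "rna_class": e.rna_class,
                }
                for e in self.truth.structures
            ],
            "neutral": [
                [iv.chrom, iv.start, iv.end] for iv in self.truth.neutral
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _write_gtf(features: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in features:
            attrs = iv.attributes
            feat = attrs.get("Feature", "exon")
            parts = []
            for key in (
                "gene_id",
                "transcript_id",
                "gene_type",
                "transcript_type",
                "gene_name",
            ):
                if key in attrs:
                    parts.append(f'{key} "{attrs[key]}";')
            fh.write(
                f"{iv.chrom}\tsynthetic\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand in '+-' else '+'}\t.\t"
                + " ".join(parts)
                + "\n"
            )


def generate_screen_fixture(
    config: FixtureConfig | None = None, seed: int = 0
) -> ScreenFixture:
    """Build the benchmark mini-genome (see module docstring)."""
    cfg = config or FixtureConfig()
    cfg.validate()
    tree = cfg.tree
    rng = np.random.default_rng(seed)
    n_blocks = cfg.n_neutral_blocks + cfg.n_implant_blocks

    # ---- plan layout --------------------------------------------------
    lengths = np.clip(
        (cfg.block_len_offset + rng.exponential(cfg.block_len_mean, n_blocks))
        .round()
        .astype(int),
        *cfg.block_len_range,
    )
    min_implant_len = 2 * cfg.stem_len[0] + cfg.loop_len[0] + 8
    spacers = rng.integers(
        cfg.spacer_len[0], cfg.spacer_len[1] + 1, size=n_blocks + 1
    )
    starts = np.zeros(n_blocks, dtype=int)
    pos = int(spacers[0])
    for i in range(n_blocks):
        starts[i] = pos
        pos += int(lengths[i]) + int(spacers[i + 1])
    ref_len = pos

    genes, gene_features = _plan_genes(cfg, rng, starts, lengths, ref_len)
    utr3_territory = [
        g["utr3"] for g in genes if g["biotype"] == "protein_coding"
    ]

    # ---- choose implant blocks (3'UTR-biased) -------------------------
    fits = lengths >= min_implant_len
    in_utr3 = np.zeros(n_blocks, dtype=bool)
    for i in range(n_blocks):
        bi = GenomicInterval("chr1", int(starts[i]), int(starts[i] + lengths[i]))
        in_utr3[i] = any(bi.overlap_len(u) >= min_implant_len for u in utr3_territory)
    implant_ids: list[int] = []
    n_biased = int(round(cfg.utr3_bias * cfg.n_implant_blocks))
    utr3_pool = list(np.flatnonzero(fits & in_utr3))
    rng.shuffle(utr3_pool)
    implant_ids.extend(utr3_pool[:n_biased])
    rest_pool = [i for i in np.flatnonzero(fits) if i not in set(implant_ids)]
    rng.shuffle(rest_pool)
    implant_ids.extend(rest_pool[: cfg.n_implant_blocks - len(implant_ids)])
    if len(implant_ids) < cfg.n_implant_blocks:
        raise ValueError("not enough blocks can host the requested implants")
    implant_set = set(int(i) for i in implant_ids)

    # ---- generate blocks ---------------------------------------------
    other_species = [s for s in tree.species() if s != tree.reference]
    blocks: list[AlignmentBlock] = []
    truth = TruthSet()
    species_cursor: dict[str, int] = {sp: 0 for sp in tree.species()}
    species_parts: dict[str, list[str]] = {sp: [] for sp in tree.species()}
    ref_parts: list[str] = []
    ref_cursor = 0

    def ref_emit(seq: str) -> int:
        nonlocal ref_cursor
        start = ref_cursor
        ref_parts.append(seq)
        ref_cursor += len(seq)
        return start

    freqs = np.asarray(tree.freqs)

    def random_seq(n: int, r=None) -> str:
        r = r if r is not None else rng
        return "".join(BASES[i] for i in r.choice(4, size=n, p=freqs))

    sp_spacer = 30
    for i in range(n_blocks):
        # a private stream per block keeps neutral blocks bit-identical
        # across fixtures that differ only in implant parameters
        brng = np.random.default_rng([seed & 0x7FFFFFFF, i])
        ref_emit(random_seq(int(spacers[i]), brng))
        L = int(lengths[i])
        n_other = 1 + int(
            brng.choice(len(cfg.n_other_species_probs), p=cfg.n_other_species_probs)
        )
        chosen = list(
            brng.choice(other_species, size=min(n_other, len(other_species)), replace=False)
        )
        rate_scale = float(
            np.exp(brng.normal(cfg.rate_scale_mu, cfg.rate_scale_sigma))
        )
        implant_here = i in implant_set
        protected: list[tuple[int, int]] = []
        implant_plan = None
        if implant_here:
            span_cap = L - 6
            stem_hi = min(cfg.stem_len[1], (span_cap - cfg.loop_len[0]) // 2)
            stem = int(brng.integers(cfg.stem_len[0], stem_hi + 1))
            loop_hi = min(cfg.loop_len[1], span_cap - 2 * stem)
            loop = int(brng.integers(cfg.loop_len[0], loop_hi + 1))
            span = 2 * stem + loop
            lo, hi = 2, L - span - 1
            p0 = None
            bs = int(starts[i])
            for u in utr3_territory:  # prefer 3'UTR placement when it fits
                plo = max(lo, u.start - bs)
                phi = min(hi, u.end - bs - span)
                if phi > plo:
                    p0 = int(brng.integers(plo, phi))
                    break
            if p0 is None:
                p0 = int(brng.integers(lo, hi))
            protected = [(p0, p0 + span)]
            implant_plan = (stem, loop)
        texts, _ = _simulate_alignment(
            tree,
            L,
            brng,
            rate_scale=rate_scale,
            protected=protected,
        )
        keep = [tree.reference] + sorted(
            chosen, key=tree.distance_from_reference
        )
        texts = _drop_all_gap_columns({k: texts[k] for k in keep})
        block_start = ref_emit(texts[tree.reference].replace(GAP, ""))
        rows = []
        for sp in keep:
            t = texts[sp]
            size = len(t) - t.count(GAP)
            if sp == tree.reference:
                start = block_start
            else:
                start = species_cursor[sp]
                species_parts[sp].append(t.replace(GAP, ""))
                species_parts[sp].append(random_seq(sp_spacer, brng))
                species_cursor[sp] += size + sp_spacer
            rows.append(
                AlignmentRow(
                    species=sp,
                    chrom="chr1",
                    start=start,
                    size=size,
                    strand="+",
                    src_size=10**9,  # patched after assembly
                    text=t,
                )
            )
        block = AlignmentBlock(rows, source_id=f"b{i:05d}")
        block_iv = GenomicInterval("chr1", block_start, block_start + rows[0].size)
        if implant_here:
            stem, loop = implant_plan
            span = 2 * stem + loop
            # root coordinates were shielded from indels: locate the span
            # as block columns by walking the reference row
            col0 = _ref_offset_to_col(texts[tree.reference], protected[0][0])
            block, entry = implant_conserved_structure(
                block, col0, stem, loop, cfg.compensatory_rate, brng
            )
            entry.rna_class = SMALL_RNA_CLASSES[
                int(brng.choice(len(SMALL_RNA_CLASSES), p=SMALL_RNA_CLASS_P))
            ]
            truth.structures.append(entry)
            # the implant rewrites row texts only; regenerate the emitted
            # reference sequence accordingly
            ref_parts[-1] = block.reference.ungapped()
            for k, sp in enumerate(keep[1:], start=1):
                if species_parts[sp]:
                    species_parts[sp][-2] = block.rows[k].ungapped()
        else:
            truth.neutral.append(block_iv)
        if (
            cfg.split_block_prob > 0
            and block.n_species <= 5
            and block.n_cols >= 100
            and brng.random() < cfg.split_block_prob
            and not implant_here
        ):
            cut = int(brng.integers(30, block.n_cols - 30))
            for part_idx, (c0, c1) in enumerate(((0, cut), (cut, block.n_cols))):
                part_rows = [r.slice_cols(c0, c1) for r in block.rows]
                part_rows = [part_rows[0]] + [
                    r for r in part_rows[1:] if r.size > 0
                ]
                if len(part_rows) >= 2:
                    blocks.append(
                        AlignmentBlock(
                            part_rows, source_id=f"{block.source_id}.{part_idx}"
                        )
                    )
        else:
            blocks.append(block)
    ref_emit(random_seq(int(spacers[-1])))

    # ---- assemble genomes and patch src_size --------------------------
    seqs = {tree.reference: {"chr1": "".join(ref_parts)}}
    for sp in other_species:
        seqs[sp] = {"chr1": "".join(species_parts[sp]) or random_seq(50)}
    genomes = InMemoryGenomes(seqs)
    sizes = {sp: len(seqs[sp]["chr1"]) for sp in seqs}
    patched = []
    for b in blocks:
        rows = [replace(r, src_size=sizes[r.species]) for r in b.rows]
        patched.append(AlignmentBlock(rows, source_id=b.source_id))
    blocks = patched
    chrom_sizes = {"chr1": sizes[tree.reference]}

    # ---- annotations ---------------------------------------------------
    small_rnas = [
        e.interval.with_fields(
            name=e.rna_class, attributes={"rna_class": e.rna_class}
        )
        for e in truth.structures
    ]
    gene_features = gene_features + _small_rna_gene_features(truth)
    repeats = _plan_repeats(cfg, rng, starts, lengths, implant_set)
    gene2go = _assign_go_terms(genes, truth, rng)

    return ScreenFixture(
        blocks=blocks,
        genomes=genomes,
        chrom_sizes=chrom_sizes,
        gene_features=gene_features,
        repeats=repeats,
        small_rnas=small_rnas,
        gene2go=gene2go,
        truth=truth,
        config=cfg,
        seed=seed,
    )


def _ref_offset_to_col(ref_text: str, offset: int) -> int:
    seen = 0
    for col, ch in enumerate(ref_text):
        if ch != GAP:
            if seen == offset:
                return col
            seen += 1
    raise ImplantError("reference offset beyond block")


def _plan_genes(cfg, rng, starts, lengths, ref_len):
    """Gene territories over consecutive block groups: 65% protein-coding
    (two exons, CDS flanked by a short 5'UTR and a long 3'UTR), 15%
    lncRNA, 20% intergenic."""
    genes = []
    features: list[GenomicInterval] = []
    n_blocks = len(starts)
    gid = 0
    for g0 in range(0, n_blocks, cfg.gene_block_span):
        g1 = min(g0 + cfg.gene_block_span, n_blocks) - 1
        gstart = max(0, int(starts[g0]) - 10)
        gend = min(ref_len, int(starts[g1] + lengths[g1]) + 10)
        if gend - gstart < 400:
            continue
        u = rng.random()
        if u < 0.20:
            continue  # intergenic
        gid += 1
        strand = "+" if rng.random() < 0.8 else "-"
        glen = gend - gstart
        if u < 0.35:
            biotype = "lncRNA"
            gene = {
                "gene_id": f"g{gid}",
                "biotype": biotype,
                "start": gstart,
                "end": gend,
                "strand": strand,
                "utr3": GenomicInterval("chr1", gstart, gstart + 1),
            }
            genes.append(gene)
            features.extend(
                _gene_feature_rows(
                    f"g{gid}", "chr1", strand, biotype,
                    exons=[(gstart, gend)], cds=[],
                )
            )
            continue
        biotype = "protein_coding"
        # exon1 | intron (20%) | exon2 ; 5'UTR 12%, 3'UTR 28% of the gene
        e1_end = gstart + int(0.40 * glen)
        e2_start = gstart + int(0.60 * glen)
        cds_lo = gstart + int(0.12 * glen)
        cds_hi = gend - int(0.28 * glen)
        if strand == "-":
            cds_lo = gstart + int(0.28 * glen)
            cds_hi = gend - int(0.12 * glen)
        exons = [(gstart, e1_end), (e2_start, gend)]
        cds = []
        for es, ee in exons:
            s, e = max(es, cds_lo), min(ee, cds_hi)
            if s < e:
                cds.append((s, e))
        utr3 = (
            GenomicInterval("chr1", cds_hi, gend)
            if strand == "+"
            else GenomicInterval("chr1", gstart, cds_lo)
        )
        genes.append(
            {
                "gene_id": f"g{gid}",
                "biotype": biotype,
                "start": gstart,
                "end": gend,
                "strand": strand,
                "utr3": utr3,
            }
        )
        features.extend(
            _gene_feature_rows(
                f"g{gid}", "chr1", strand, biotype, exons=exons, cds=cds
            )
        )
    return genes, features


def _gene_feature_rows(gene_id, chrom, strand, biotype, exons, cds):
    gstart = min(s for s, _ in exons)
    gend = max(e for _, e in exons)
    base = {
        "gene_id": gene_id,
        "transcript_id": f"{gene_id}.t1",
        "gene_type": biotype,
        "transcript_type": biotype,
    }
    rows = [
        GenomicInterval(
            chrom, gstart, gend, strand=strand,
            name=gene_id,
            attributes={**base, "Feature": "gene"},
        ),
        GenomicInterval(
            chrom, gstart, gend, strand=strand,
            name=gene_id,
            attributes={**base, "Feature": "transcript"},
        ),
    ]
    for s, e in exons:
        rows.append(
            GenomicInterval(
                chrom, s, e, strand=strand, name=gene_id,
                attributes={**base, "Feature": "exon"},
            )
        )
    for s, e in cds:
        rows.append(
            GenomicInterval(
                chrom, s, e, strand=strand, name=gene_id,
                attributes={**base, "Feature": "CDS"},
            )
        )
    return rows


def _small_rna_gene_features(truth: TruthSet):
    rows = []
    for k, e in enumerate(truth.structures):
        rows.extend(
            _gene_feature_rows(
                f"srna{k}",
                e.interval.chrom,
                e.interval.strand,
                e.rna_class or "sncRNA",
                exons=[(e.interval.start, e.interval.end)],
                cds=[],
            )
        )
    return rows


def _plan_repeats(cfg, rng, starts, lengths, implant_set):
    repeats = []
    for i in range(len(starts)):
        if i in implant_set or rng.random() >= cfg.repeat_fraction:
            continue
        cls = REPEAT_CLASSES[int(rng.choice(len(REPEAT_CLASSES), p=REPEAT_CLASS_P))]
        L = int(lengths[i])
        w = max(20, int(0.6 * L))
        off = int(rng.integers(0, L - w + 1))
        repeats.append(
            GenomicInterval(
                "chr1",
                int(starts[i]) + off,
                int(starts[i]) + off + w,
                name=cls,
                attributes={"repeat_class": cls},
            )
        )
    return repeats


def _assign_go_terms(genes, truth: TruthSet, rng):
    """Gene-to-GO table with one term tracking structure-rich 3'UTRs."""
    rows = []
    ontologies = ("MF", "BP", "CC")
    generic = [f"GO:G{k}" for k in range(6)]
    for g in genes:
        if g["biotype"] != "protein_coding":
            continue
        has_struct = any(
            s.interval.overlaps(g["utr3"]) for s in truth.structures
        )
        term = "GO:STRUCT3UTR" if has_struct else "GO:PLAIN3UTR"
        rows.append((g["gene_id"], term, "MF"))
        for k, t in enumerate(generic):
            if rng.random() < 0.3:
                rows.append((g["gene_id"], t, ontologies[k % 3]))
    return rows


# ---------------------------------------------------------------------------
# Evaluation against ground truth


def load_truth(path) -> TruthSet:
    data = json.loads(Path(path).read_text())
    return TruthSet(
        structures=[
            TruthEntry(
                interval=GenomicInterval(
                    s["chrom"], s["start"], s["end"], strand=s["strand"]
                ),
                pairs=[tuple(p) for p in s["pairs"]],
                n_compensatory=s["n_compensatory"],
                rna_class=s.get("rna_class", ""),
            )
            for s in data["structures"]
        ],
        neutral=[GenomicInterval(c, s, e) for c, s, e in data["neutral"]],
    )


def evaluate_against_truth(
    loci: Sequence,
    truth: TruthSet,
    min_cov: float = 0.6,
) -> dict:
    """Recall (a structure counts as recovered when a single locus on its
    strand covers >= *min_cov* of it), precision at the locus level, the
    realised nucleotide FDR (fraction of locus nucleotides outside all
    truth intervals), and boundary-error distribution of recovered
    structures."""
    intervals = [
        l.interval if hasattr(l, "interval") else l for l in loci
    ]
    recovered = 0
    boundary_errors = []
    for s in truth.structures:
        best = None
        for iv in intervals:
            if iv.strand not in (s.interval.strand, "."):
                continue
            ov = s.interval.overlap_len(iv)
            if ov >= min_cov * len(s.interval) and (
                best is None or ov > s.interval.overlap_len(best)
            ):
                best = iv
        if best is not None:
            recovered += 1
            boundary_errors.append(
                (
                    best.start - s.interval.start,
                    best.end - s.interval.end,
                )
            )
    n_struct = len(truth.structures)
    total_nt = sum(len(iv) for iv in intervals)
    truth_ivs = [s.interval for s in truth.structures]
    from .intervals import overlap_nt

    in_truth = sum(overlap_nt([iv], truth_ivs) for iv in intervals)
    true_loci = sum(
        1
        for iv in intervals
        if overlap_nt([iv], truth_ivs) * 2 >= len(iv)
    )
    return {
        "n_structures": n_struct,
        "n_loci": len(intervals),
        "recall": recovered / n_struct if n_struct else float("nan"),
        "precision": true_loci / len(intervals) if intervals else float("nan"),
        "realised_fdr_nt": 1.0 - in_truth / total_nt if total_nt else float("nan"),
        "boundary_errors": boundary_errors,
        "median_abs_length_error": (
            float(
                np.median(
                    [abs((e - s)) for s, e in boundary_errors]
                )
            )
            if boundary_errors
            else float("nan")
        ),
    }
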