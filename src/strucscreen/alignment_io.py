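"""Reading and writing the standard formats the screen touches.

MAF blocks come in with strand-relative start coordinates (the MAF
convention); everything downstream of this module uses 0-based half-open
forward-strand coordinates.  The sequence alphabet is RNA internally:
``T`` is converted to ``U`` on input, with case (soft-masking) preserved.

MAF parsing/writing and Stockholm output are delegated to Biopython;
BED and GTF reading to pyranges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

GAP = "-"

_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def to_rna(seq: str) -> str:
    """DNA→RNA relabelling (T→U), case preserved."""
    return seq.replace("T", "U").replace("t", "u")


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MafParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRow:
    """One 's' line of a MAF block.

    ``start`` is the MAF strand-relative offset; ``size`` the ungapped
    length; ``src_size`` the chromosome length.  ``text`` is the gapped
    sequence over {A,C,G,U,N,-} (lowercase = soft-masked).
    """

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self) -> None:
        ungapped = len(self.text) - self.text.count(GAP)
        if ungapped != self.size:
            raise ValidationError(
                f"row {self.species}.{self.chrom}: {ungapped} non-gap "
                f"characters != declared size {self.size}"
            )
        if not (0 <= self.start and self.start + self.size <= self.src_size):
            raise ValidationError(
                f"row {self.species}.{self.chrom}: interval "
                f"[{self.start},{self.start + self.size}) outside "
                f"src_size {self.src_size}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def n_cols(self) -> int:
        return len(self.text)

    def ungapped(self) -> str:
        return self.text.replace(GAP, "")

    def gap_fraction(self) -> float:
        return self.text.count(GAP) / len(self.text) if self.text else 0.0

    def slice_cols(self, c0: int, c1: int) -> "AlignmentRow":
        """Row restricted to columns [c0, c1); start/size updated."""
        before = self.text[:c0]
        sub = self.text[c0:c1]
        off = len(before) - before.count(GAP)
        return replace(
            self,
            start=self.start + off,
            size=len(sub) - sub.count(GAP),
            text=sub,
        )


def row_forward_interval(row: AlignmentRow) -> GenomicInterval:
    """Forward-strand half-open interval covered by a MAF row."""
    if row.strand == "+":
        s, e = row.start, row.start + row.size
    else:
        s = row.src_size - row.start - row.size
        e = row.src_size - row.start
    return GenomicInterval(row.chrom, s, e, strand=row.strand, name=row.species)


def forward_to_maf_start(
    interval: GenomicInterval, strand: str, src_size: int
) -> int:
    """Inverse of :func:`row_forward_interval`: MAF strand-relative start."""
    if strand == "+":
        return interval.start
    return src_size - interval.end


@dataclass
class AlignmentBlock:
    """One MAF block; the reference species is the first row (strand +)."""

    rows: list[AlignmentRow]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("empty alignment block")
        n = self.rows[0].n_cols
        for r in self.rows:
            if r.n_cols != n:
                raise ValidationError(
                    f"block {self.source_id}: row {r.species} has "
                    f"{r.n_cols} columns, expected {n}"
                )
        if self.rows[0].strand != "+":
            raise ValidationError(
                f"block {self.source_id}: reference row must be on +"
            )

    @property
    def n_cols(self) -> int:
        return self.rows[0].n_cols

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[0]

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def reference_interval(self) -> GenomicInterval:
        return row_forward_interval(self.reference)


def _prevalidate_maf(path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.startswith("s"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise MafParseError(
                    f"{path}: malformed 's' line at line {lineno}: "
                    f"expected 7 fields, got {len(fields)}"
                )
            for idx in (2, 3, 5):
                if not fields[idx].lstrip("-").isdigit():
                    raise MafParseError(
                        f"{path}: malformed 's' line at line {lineno}: "
                        f"non-numeric field {fields[idx]!r}"
                    )


def _record_to_row(rec: SeqRecord) -> AlignmentRow:
    species, _, chrom = rec.id.partition(".")
    ann = rec.annotations
    strand = "+" if ann.get("strand", 1) in (1, "+") else "-"
    return AlignmentRow(
        species=species,
        chrom=chrom or species,
        start=int(ann["start"]),
        size=int(ann["size"]),
        strand=strand,
        src_size=int(ann["srcSize"]),
        text=to_rna(str(rec.seq)),
    )


def read_maf(path) -> Iterator[AlignmentBlock]:
    """Parse a MAF file into AlignmentBlocks (file order, 's' lines only)."""
    _prevalidate_maf(path)
    with open(path) as handle:
        for i, aln in enumerate(AlignIO.parse(handle, "maf")):
            rows = [_record_to_row(rec) for rec in aln]
            yield AlignmentBlock(rows=rows, source_id=f"{Path(path).stem}.{i}")


def write_maf(blocks: Iterable[AlignmentBlock], path) -> None:
    alns = []
    for block in blocks:
        recs = []
        for r in block.rows:
            recs.append(
                SeqRecord(
                    Seq(r.text),
                    id=f"{r.species}.{r.chrom}",
                    annotations={
                        "start": r.start,
                        "size": r.size,
                        "strand": 1 if r.strand == "+" else -1,
                        "srcSize": r.src_size,
                    },
                )
            )
        alns.append(MultipleSeqAlignment(recs))
    with open(path, "w") as handle:
        AlignIO.write(alns, handle, "maf")


# ---------------------------------------------------------------------------
# Feature annotation input (BED / GTF)

def read_features(path, format: str) -> list[GenomicInterval]:
    """Read BED or GTF features into forward-strand half-open intervals.

    GTF attributes (gene_id, transcript_id, biotypes, ...) are retained in
    ``interval.attributes``; unknown keys are kept, never dropped.
    """
    import pyranges as pr

    if format == "bed":
        df = pr.read_bed(str(path)).df
    elif format == "gtf":
        df = pr.read_gtf(str(path)).df
    else:
        raise ValueError(f"unknown feature format {format!r}")
    core = {"Chromosome", "Start", "End", "Strand", "Name", "Score"}
    out = []
    for rec in df.to_dict("records"):
        attrs = {
            k: v
            for k, v in rec.items()
            if k not in core and v is not None and v == v  # drop NaN
        }
        out.append(
            GenomicInterval(
                chrom=str(rec["Chromosome"]),
                start=int(rec["Start"]),
                end=int(rec["End"]),
                strand=str(rec.get("Strand", ".")) or ".",
                name=str(rec.get("Name", "") or attrs.get("gene_id", "")),
                score=float(rec["Score"])
                if str(rec.get("Score", ".")) not in (".", "nan")
                else 0.0,
                attributes=attrs,
            )
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{int(round(iv.score))}\t{iv.strand if iv.strand in '+-' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Locus output (BED score = 1000*P; Stockholm with #=GC SS_cons)

class StockholmWriteError(ValueError):
    pass


def write_outputs(loci: Sequence, path, format: str) -> None:
    """Export loci as BED6 (score = round(1000*P)) or Stockholm 1.0.

    The Stockholm file carries the refined per-species alignment plus the
    consensus structure as a ``#=GC SS_cons`` line.
    """
    if format == "bed":
        ivs = [
            loc.interval.with_fields(
                score=round(1000 * loc.best_p),
                name=loc.name or f"locus{idx}",
                strand=loc.strand,
            )
            for idx, loc in enumerate(loci)
        ]
        write_bed(ivs, path)
    elif format == "stockholm":
        alns = []
        for idx, loc in enumerate(loci):
            if not loc.consensus_structure:
                raise StockholmWriteError(
                    f"locus {loc.name or idx} has no consensus structure"
                )
            recs = [
                SeqRecord(Seq(r.text), id=f"{r.species}.{r.chrom}", description="")
                for r in loc.rows
            ]
            aln = MultipleSeqAlignment(recs)
            aln.column_annotations["secondary_structure"] = (
                loc.consensus_structure
            )
            alns.append(aln)
        with open(path, "w") as fh:
            AlignIO.write(alns, fh, "stockholm")
    else:
        raise ValueError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# Genome sequence access (per-species FASTA, or in-memory for simulations)

class GenomeSet:
    """Lookup of genomic sequence by (species, chrom, start, end), forward
    strand, clipped at chromosome bounds."""

    def fetch(self, species: str, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def chrom_size(self, species: str, chrom: str) -> int:
        raise NotImplementedError

    def has(self, species: str) -> bool:
        raise NotImplementedError


class InMemoryGenomes(GenomeSet):
    def __init__(self, seqs: dict[str, dict[str, str]]):
        self.seqs = {
            sp: {c: to_rna(s) for c, s in chroms.items()}
            for sp, chroms in seqs.items()
        }

    def fetch(self, species, chrom, start, end):
        seq = self.seqs[species][chrom]
        return seq[max(0, start) : max(0, min(len(seq), end))]

    def chrom_size(self, species, chrom):
        return len(self.seqs[species][chrom])

    def has(self, species):
        return species in self.seqs

    def write_fasta_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, chroms in self.seqs.items():
            with open(outdir / f"{sp}.fa", "w") as fh:
                for chrom, seq in chroms.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")


class FastaGenomes(GenomeSet):
    """Directory of per-species FASTA files (``<species>.fa``), read lazily
    through pyfaidx."""

    def __init__(self, directory):
        self.directory = Path(directory)
        self._handles: dict = {}

    def _fa(self, species):
        if species not in self._handles:
            from pyfaidx import Fasta

            self._handles[species] = Fasta(
                str(self.directory / f"{species}.fa"), as_raw=True
            )
        return self._handles[species]

    def fetch(self, species, chrom, start, end):
        fa = self._fa(species)
        size = len(fa[chrom])
        return to_rna(str(fa[chrom][max(0, start) : max(0, min(size, end))]))

    def chrom_size(self, species, chrom):
        return len(self._fa(species)[chrom])

    def has(self, species):
        return (self.directory / f"{species}.fa").exists()
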