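"""End-to-end screen orchestration: windows -> hits -> loci -> raw ->
high-confidence, with a per-stage nucleotide funnel and a reproducible
run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .alignment_io import AlignmentBlock, GenomeSet
from .confidence_fdr import (
    ConfidenceRule,
    high_confidence_set,
    make_decoy,
)
from .intervals import GenomicInterval, merge_intervals, total_length
from .locus_pipeline import (
    Hit,
    Locus,
    add_flanks,
    get_realigner,
    group_hits_into_loci,
    merge_locus_blocks,
    merge_reliable_regions,
    predict_boundaries,
    rescore_locus,
)
from .screening import (
    filter_gappy_rows,
    slice_windows,
    subsample_species,
    window_accept,
)
from .structure_scoring import BasePairScorer, ScoreParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters and seeds of one screen run."""

    window_size: int = 120
    window_stride: int = 20
    max_gap: float = 0.7
    min_window_cols: int = 50
    mpi_min: float = 40.0
    max_sample_species: int = 10
    n_samples: int = 5
    #: shuffles per z-score; kept modest because z enters the classifier
    #: averaged over up to 10 sequences
    n_shuffles: int = 12
    hit_p: float = 0.5
    strands: tuple[str, ...] = ("+", "-")
    flank: int = 20
    merge_enabled: bool = True
    merge_max_fetch: int = 20
    merge_max_species: int = 5
    merge_max_cols: int = 400
    boundary_theta: float = 0.85
    boundary_smooth: int = 5
    boundary_unpaired_weight: float = 0.8
    min_locus_cols: int = 50
    decoy_chunk: int = 100
    decoy_every: int = 5
    decoy_mode: str = "columns"
    realigner: str = "none"
    scorer: str = "basepair"
    seed: int = 0

    def score_params(self) -> ScoreParams:
        return ScoreParams(n_shuffles=self.n_shuffles, seed=self.seed)

    def manifest(self) -> dict:
        from . import __version__

        return {"version": __version__, "config": dataclasses.asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in d.items() if k in known}
        if "strands" in kw:
            kw["strands"] = tuple(kw["strands"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _derive_seed(base: int, *tokens) -> int:
    h = base & 0xFFFFFFFF
    for t in tokens:
        h = zlib.crc32(str(t).encode(), h)
    return h & 0x7FFFFFFF


@dataclass
class ScreenResult:
    hits: list[Hit]
    input_footprint: list[GenomicInterval]
    initial_loci: list[Locus]
    refined_loci: list[Locus]
    raw_loci: list[Locus]
    high_confidence: list[Locus]
    funnel: pd.DataFrame
    dropped: list[tuple[str, str]]
    config: RunConfig

    def manifest(self) -> dict:
        m = self.config.manifest()
        m["counts"] = {
            "hits": len(self.hits),
            "initial_loci": len(self.initial_loci),
            "raw_loci": len(self.raw_loci),
            "high_confidence": len(self.high_confidence),
        }
        return m


def screen_windows(
    blocks: Sequence[AlignmentBlock],
    config: RunConfig,
    scorer: BasePairScorer | None = None,
) -> tuple[list[Hit], list[GenomicInterval]]:
    """Stage 1: per-window classification on the configured strands.

    Returns the hits (windows with at least one sample P > 0.5 on a
    strand) and the merged footprint of all accepted windows.
    """
    scorer = scorer or BasePairScorer(config.score_params())
    hits: list[Hit] = []
    accepted: list[GenomicInterval] = []
    for block in blocks:
        for win in slice_windows(block, config.window_size, config.window_stride):
            win = filter_gappy_rows(win, config.max_gap)
            if not window_accept(win, config.min_window_cols, config.mpi_min):
                continue
            accepted.append(win.reference_interval)
            sset = subsample_species(
                win,
                max_n=config.max_sample_species,
                n_samples=config.n_samples,
                seed=_derive_seed(config.seed, block.source_id, win.c0),
            )
            for strand in config.strands:
                ps = []
                best = None
                for smp in sset.samples:
                    res = scorer(smp, strand, model="sequence")
                    ps.append(res.p)
                    if best is None or res.p > best.p:
                        best = res
                if max(ps) > config.hit_p:
                    hits.append(
                        Hit(window=win, strand=strand, score=best, sample_ps=ps)
                    )
    return hits, merge_intervals(accepted)


def refine_loci(
    hits: Sequence[Hit],
    blocks: Sequence[AlignmentBlock],
    genomes: GenomeSet | None,
    config: RunConfig,
    scorer: BasePairScorer | None = None,
) -> tuple[list[Locus], list[Locus], list[tuple[str, str]]]:
    """Stage 2: group hits into loci, merge across blocks, flank, refine
    boundaries and re-score.  Returns (initial loci, refined loci,
    dropped log)."""
    scorer = scorer or BasePairScorer(config.score_params())
    params = config.score_params()
    block_map = {b.source_id: b for b in blocks}
    realigner = get_realigner(config.realigner)
    initial = group_hits_into_loci(list(hits), block_map)
    refined: list[Locus] = []
    dropped: list[tuple[str, str]] = []
    for li, locus in enumerate(initial):
        locus.name = f"loc{li}"
        parts = merge_locus_blocks(
            locus,
            block_map,
            genomes,
            max_fetch=config.merge_max_fetch,
            max_species=config.merge_max_species,
            max_cols=config.merge_max_cols,
            greedy=config.merge_enabled,
        )
        for pj, part in enumerate(parts):
            part.name = f"loc{li}.{pj}" if len(parts) > 1 else f"loc{li}"
            flanked = add_flanks(part, genomes, config.flank)
            flanked.rows = realigner(flanked.rows)
            ranges = predict_boundaries(
                flanked,
                theta=config.boundary_theta,
                smooth=config.boundary_smooth,
                params=params,
                unpaired_weight=config.boundary_unpaired_weight,
            )
            original = (
                flanked.flank_cols[0],
                flanked.n_cols - flanked.flank_cols[1],
            )
            span = merge_reliable_regions(ranges, original)
            if span is None:
                dropped.append((part.name, "no reliable region"))
                continue
            result = rescore_locus(
                flanked,
                span,
                scorer,
                min_cols=config.min_locus_cols,
                max_sample=config.max_sample_species,
                n_samples=config.n_samples,
                seed=_derive_seed(config.seed, "rescore", part.name),
                strands=config.strands,
            )
            if result is None:
                dropped.append((part.name, "refined locus too short"))
                continue
            refined.append(result)
    return initial, refined, dropped


def run_screen(
    blocks: Sequence[AlignmentBlock],
    genomes: GenomeSet | None,
    config: RunConfig | None = None,
    rule: ConfidenceRule = ConfidenceRule(),
) -> ScreenResult:
    """Execute screen -> refine -> confidence and assemble the funnel."""
    config = config or RunConfig()
    scorer = BasePairScorer(config.score_params())
    hits, footprint = screen_windows(blocks, config, scorer)
    initial, refined, dropped = refine_loci(hits, blocks, genomes, config, scorer)
    raw = [l for l in refined if l.stage == "raw"]
    for l in refined:
        if l.stage != "raw":
            dropped.append((l.name, "no sample above 0.5 after re-scoring"))
    hc = high_confidence_set(raw, rule)
    input_nt = total_length([b.reference_interval() for b in blocks])
    funnel = pd.DataFrame(
        [
            ("input_blocks", input_nt),
            ("accepted_windows", total_length(footprint)),
            ("hits", total_length([h.interval for h in hits])),
            ("initial_loci", total_length([l.interval for l in initial])),
            ("raw_loci", total_length([l.interval for l in raw])),
            ("high_confidence", total_length([l.interval for l in hc])),
        ],
        columns=["stage", "nucleotides"],
    )
    return ScreenResult(
        hits=hits,
        input_footprint=footprint,
        initial_loci=initial,
        refined_loci=refined,
        raw_loci=raw,
        high_confidence=hc,
        funnel=funnel,
        dropped=dropped,
        config=config,
    )


def run_decoy_screen(
    blocks: Sequence[AlignmentBlock],
    genomes: GenomeSet | None,
    config: RunConfig | None = None,
) -> tuple[ScreenResult, list[GenomicInterval]]:
    """Shuffle every fifth chunk of blocks and re-run the identical
    pipeline (plus unshuffled flank fetching), returning the decoy
    screen result and the shuffled-region mask."""
    config = config or RunConfig()
    decoy_blocks, mask = make_decoy(
        blocks,
        chunk=config.decoy_chunk,
        every=config.decoy_every,
        seed=_derive_seed(config.seed, "decoy"),
        mode=config.decoy_mode,
    )
    return run_screen(decoy_blocks, genomes, config), mask


def write_manifest(result: ScreenResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.manifest(), fh, indent=1, default=str)
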