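"""Structure-conservation scoring of alignment windows and loci.

The scorer estimates, for an aligned set of sequences, (i) how
thermodynamically unusual each sequence's folding score is relative to a
dinucleotide-preserving shuffled background (z-score), (ii) how well a
single consensus structure explains all sequences, with a bonus for
covarying (compensatory) base pairs (structure conservation index,
SCI), and (iii) a class probability P from a transparent logistic model
over (z, SCI).

Folding is maximum-weight nested base pairing (pair weights GC=3, AU=2,
GU=1, minimum hairpin loop 3).  High score means stable — the sign
convention is inverted relative to a free energy.  The logistic model
is a deliberately simple, documented stand-in for a trained structure
classifier; any external tool can be plugged in through the
``ScorerAdapter`` contract (a callable ``(rows, strand) -> ScoreResult``
registered by name).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from ._fold import nussinov_dp, traceback
from .alignment_io import GAP, AlignmentRow, revcomp
from .screening import encode_rows, mean_pairwise_identity

DEFAULT_PAIR_WEIGHTS = {"GC": 3.0, "AU": 2.0, "GU": 1.0}
MIN_LOOP = 3

#: logistic weights (w0, w_z, w_sci); calibrated on the synthetic
#: benchmark so implanted structures score P > 0.9 and neutral decoys
#: score low at the default generator settings.
DEFAULT_WEIGHTS = (-4.0, 1.0, 3.0)


def _weight_table(pair_weights: dict[str, float]) -> np.ndarray:
    """6x6 directional pair-weight lookup over codes A,C,G,U,N,-."""
    enc = {"A": 0, "C": 1, "G": 2, "U": 3}
    tab = np.zeros((6, 6), dtype=np.float64)
    for duplex, w in pair_weights.items():
        a, b = enc[duplex[0]], enc[duplex[1]]
        tab[a, b] = w
        tab[b, a] = w
    return tab


@dataclass
class ScoreParams:
    pair_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    min_loop: int = MIN_LOOP
    consensus_threshold: float = 0.5  # fraction of rows that must pair
    consensus_penalty: float = 2.0    # q: cost per fraction of non-pairing rows
    consensus_bonus: float = 1.0      # b: reward per extra pair type
    n_shuffles: int = 100
    weights_sequence: tuple[float, float, float] = DEFAULT_WEIGHTS
    weights_structural: tuple[float, float, float] = DEFAULT_WEIGHTS
    seed: int = 0

    def table(self) -> np.ndarray:
        return _weight_table(self.pair_weights)


@dataclass
class ScoreResult:
    """Per-window (or per-locus) structure-conservation statistics."""

    strand: str
    mpi: float
    gc: float
    z: float
    sci: float
    p: float
    consensus_structure: str
    consensus_score: float
    n_species: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"class probability {self.p} outside [0,1]")
        if self.sci < 0:
            raise ValueError(f"negative SCI {self.sci}")
        depth = 0
        for c in self.consensus_structure:
            depth += {"(": 1, ")": -1}.get(c, 0)
            if depth < 0:
                raise ValueError("unbalanced consensus structure")
        if depth != 0:
            raise ValueError("unbalanced consensus structure")


class ScorerAdapter(Protocol):
    def __call__(self, rows: Sequence[AlignmentRow], strand: str) -> ScoreResult: ...


_SCORER_REGISTRY: dict[str, Callable[..., "ScorerAdapter"]] = {}


def register_scorer(name: str, factory: Callable[..., "ScorerAdapter"]) -> None:
    _SCORER_REGISTRY[name] = factory


def get_scorer(name: str, **kw) -> "ScorerAdapter":
    return _SCORER_REGISTRY[name](**kw)


# ---------------------------------------------------------------------------
# Folding


def fold_single(
    seq: str, params: ScoreParams | None = None
) -> tuple[float, str]:
    """Maximum-weight nested pairing of a single RNA string.

    Returns (total pair weight, dot-bracket).  N never pairs.
    """
    params = params or ScoreParams()
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n < params.min_loop + 2:
        return 0.0, "." * n
    mat = encode_rows([seq])
    tab = params.table()
    W = tab[mat[0][:, None], mat[0][None, :]]
    dp = nussinov_dp(W, params.min_loop)
    return float(dp[0, n - 1]), traceback(dp, W, params.min_loop)


def consensus_weight_matrix(
    texts: Sequence[str], params: ScoreParams
) -> np.ndarray:
    """Column-pair weights for consensus folding.

    W[i,j] = mean pair weight over rows able to pair
             - q * fraction of rows unable to pair
             + b * (number of distinct directional pair types - 1),
    and 0 (pairing forbidden) where fewer than ``consensus_threshold``
    of the rows can form a complementary pair.
    """
    mat = encode_rows(texts)
    tab = params.table()
    k, n = mat.shape
    P = tab[mat[:, :, None], mat[:, None, :]]  # k x n x n pair weights
    able = P > 0.0
    n_able = able.sum(axis=0)
    frac_able = n_able / k
    with np.errstate(invalid="ignore"):
        mean_w = np.where(n_able > 0, P.sum(axis=0) / np.maximum(n_able, 1), 0.0)
    # distinct directional pair types among rows able to pair
    code = mat[:, :, None] * 6 + mat[:, None, :]
    ntypes = np.zeros((n, n), dtype=np.int32)
    enc = {"A": 0, "C": 1, "G": 2, "U": 3}
    seen = set()
    for duplex in params.pair_weights:
        for a, b in ((enc[duplex[0]], enc[duplex[1]]), (enc[duplex[1]], enc[duplex[0]])):
            if (a, b) in seen:
                continue
            seen.add((a, b))
            ntypes += (able & (code == a * 6 + b)).any(axis=0)
    W = (
        mean_w
        - params.consensus_penalty * (1.0 - frac_able)
        + params.consensus_bonus * np.maximum(ntypes - 1, 0)
    )
    W[frac_able < params.consensus_threshold] = 0.0
    W[W < 0.0] = 0.0
    return W


def _params_key(params: ScoreParams) -> tuple:
    return (
        tuple(sorted(params.pair_weights.items())),
        params.min_loop,
        params.consensus_threshold,
        params.consensus_penalty,
        params.consensus_bonus,
    )


#: process-wide memoization; decoy screens and re-screens of fixtures
#: sharing blocks re-fold mostly identical inputs
_CONS_CACHE: dict = {}
_Z_CACHE: dict = {}
_F1_CACHE: dict = {}
_CACHE_CAP = 400_000


def fold_consensus(
    rows: Sequence, params: ScoreParams | None = None
) -> tuple[float, str]:
    """Consensus structure of >=2 aligned rows (gapped, equal length).

    For identical rows (no covariation bonus in play) the result equals
    :func:`fold_single` of that sequence.
    """
    params = params or ScoreParams()
    texts = [r.text if isinstance(r, AlignmentRow) else r for r in rows]
    if len(texts) < 2:
        raise ValueError("consensus folding requires >=2 rows")
    key = (tuple(texts), _params_key(params))
    hit = _CONS_CACHE.get(key)
    if hit is not None:
        return hit
    n = len(texts[0])
    if n < params.min_loop + 2:
        return 0.0, "." * n
    W = consensus_weight_matrix(texts, params)
    # forbid hairpin loops shorter than min_loop (in alignment columns)
    for d in range(0, params.min_loop + 1):
        np.fill_diagonal(W[:, d:], 0.0)
    dp = nussinov_dp(W, params.min_loop)
    out = (float(dp[0, n - 1]), traceback(dp, W, params.min_loop))
    if len(_CONS_CACHE) > _CACHE_CAP:
        _CONS_CACHE.clear()
    _CONS_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# Dinucleotide shuffling and z-score


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Random shuffle preserving exact dinucleotide counts and endpoints.

    Altschul–Erickson Eulerian-path sampling: a random last-edge
    arborescence toward the terminal character is drawn, remaining edges
    are permuted, and the Eulerian walk is read off.  Sequences shorter
    than 3 are returned unchanged.
    """
    if len(seq) < 3:
        return seq
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars[:-1], chars[1:]):
        edges.setdefault(a, []).append(b)
    last = chars[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(1000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        # every vertex must reach the terminal vertex via last edges
        ok = True
        for v in vertices:
            seen = {v}
            u = v
            while u != last:
                u = last_edge.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable for ACGU strings
        return seq
    shuffled: dict[str, list[str]] = {}
    for v, succ in edges.items():
        succ = list(succ)
        if v in last_edge:
            succ.remove(last_edge[v])
        perm = rng.permutation(len(succ))
        succ = [succ[i] for i in perm]
        if v in last_edge:
            succ.append(last_edge[v])
        shuffled[v] = succ
    out = [chars[0]]
    counters = {v: 0 for v in shuffled}
    u = chars[0]
    for _ in range(len(chars) - 1):
        nxt = shuffled[u][counters[u]]
        counters[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


def z_score(
    seq: str,
    n_shuffles: int = 100,
    seed: int = 0,
    params: ScoreParams | None = None,
) -> float:
    """Folding-score z relative to a dinucleotide-shuffled background.

    z = (score(seq) - mean(shuffle scores)) / sd(shuffle scores); 0 when
    the background is degenerate (sd < 1e-9).  Higher z means more
    structured than background — the sign convention is inverted
    relative to folding free energies.
    """
    params = params or ScoreParams()
    own, _ = fold_single(seq, params)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        scores[i] = fold_single(dinucleotide_shuffle(seq, rng), params)[0]
    sd = float(np.std(scores, ddof=1)) if n_shuffles > 1 else 0.0
    if sd < 1e-9:
        return 0.0
    return (own - float(np.mean(scores))) / sd


def structure_conservation_index(
    rows: Sequence, params: ScoreParams | None = None
) -> float:
    """SCI = consensus folding score / mean single-sequence folding score.

    0 when the denominator is 0; identical rows (without a covariation
    bonus in play) give exactly 1.  Values above 1 are possible for
    alignments with compensatory pairs.
    """
    params = params or ScoreParams()
    texts = [r.text if isinstance(r, AlignmentRow) else r for r in rows]
    if len(texts) < 2:
        raise ValueError("SCI requires >=2 rows")
    cons, _ = fold_consensus(texts, params)
    singles = [fold_single(t.replace(GAP, ""), params)[0] for t in texts]
    denom = float(np.mean(singles))
    if denom <= 0.0:
        return 0.0
    return cons / denom


# ---------------------------------------------------------------------------
# Classification


def _stable_seed(seq: str, seed: int) -> int:
    return (zlib.crc32(seq.encode()) ^ (seed & 0xFFFFFFFF)) & 0x7FFFFFFF


class BasePairScorer:
    """Built-in scorer: (aligned rows, strand) -> ScoreResult.

    z-scores of individual ungapped sequences are cached across calls;
    the per-sequence shuffle seed is derived from the sequence content
    and the global seed, so identical sequences reappearing in other
    windows (or in the decoy screen) score identically.
    """

    def __init__(self, params: ScoreParams | None = None, model: str = "sequence"):
        self.params = params or ScoreParams()
        self.model = model
        self._pkey = _params_key(self.params)

    def _z(self, seq: str) -> float:
        key = (seq, self.params.n_shuffles, self.params.seed, self._pkey)
        hit = _Z_CACHE.get(key)
        if hit is None:
            if len(_Z_CACHE) > _CACHE_CAP:
                _Z_CACHE.clear()
            hit = z_score(
                seq,
                n_shuffles=self.params.n_shuffles,
                seed=_stable_seed(seq, self.params.seed),
                params=self.params,
            )
            _Z_CACHE[key] = hit
        return hit

    def _fold1(self, seq: str) -> float:
        key = (seq, self._pkey)
        hit = _F1_CACHE.get(key)
        if hit is None:
            if len(_F1_CACHE) > _CACHE_CAP:
                _F1_CACHE.clear()
            hit = fold_single(seq, self.params)[0]
            _F1_CACHE[key] = hit
        return hit

    def __call__(
        self, rows: Sequence, strand: str, model: str | None = None
    ) -> ScoreResult:
        params = self.params
        texts = [r.text if isinstance(r, AlignmentRow) else r for r in rows]
        if strand == "-":
            texts = [revcomp(t) for t in texts]
        mpi = mean_pairwise_identity(texts)
        joined = "".join(t.replace(GAP, "").upper() for t in texts)
        gc = (
            (joined.count("G") + joined.count("C")) / len(joined) if joined else 0.0
        )
        zbar = float(np.mean([self._z(t.replace(GAP, "").upper()) for t in texts]))
        cons_score, cons_struct = fold_consensus(texts, params)
        singles = [self._fold1(t.replace(GAP, "").upper()) for t in texts]
        denom = float(np.mean(singles))
        sci = cons_score / denom if denom > 0 else 0.0
        w0, wz, wsci = (
            params.weights_structural
            if (model or self.model) == "structural"
            else params.weights_sequence
        )
        p = 1.0 / (1.0 + np.exp(-(w0 + wz * zbar + wsci * sci)))
        return ScoreResult(
            strand=strand,
            mpi=mpi,
            gc=gc,
            z=zbar,
            sci=sci,
            p=float(p),
            consensus_structure=cons_struct,
            consensus_score=cons_score,
            n_species=len(texts),
        )


register_scorer("basepair", lambda **kw: BasePairScorer(**kw))


def classify(
    window_rows: Sequence,
    strand: str,
    params: ScoreParams | None = None,
    model: str = "sequence",
) -> ScoreResult:
    """Score one aligned sample on one strand with the built-in scorer."""
    return BasePairScorer(params, model=model)(window_rows, strand)


def logistic_p(
    zbar: float, sci: float, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> float:
    w0, wz, wsci = weights
    return float(1.0 / (1.0 + np.exp(-(w0 + wz * zbar + wsci * sci))))
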