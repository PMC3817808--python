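"""Exhaustive predictor-pair search with a blocked/tiled schedule.

For every target gene the search scores *all* unordered pairs of candidate
predictors by mean conditional entropy and keeps the minimal-MCE pair(s).
Exhaustive enumeration is the only way to respect intrinsically multivariate
prediction — a target may be explained by two genes jointly while neither
helps alone, which defeats greedy selection.

The execution model mirrors a data-tiling scheme for massively parallel
hardware, kept here as an abstract partitioning contract:

* the ``n`` targets are split into ``k`` contiguous segments of
  ``targets_per_block`` genes, one segment per execution *block*;
* the ``n`` candidate predictors are split into ``2k`` contiguous segments;
* each block enumerates tile pairs ``(j1, j2)`` with ``j2 >= j1``, scoring
  every pair drawn from predictor segments ``P_j1 x P_j2`` (within the
  diagonal tile only ``p1 < p2``), so each unordered pair is scored exactly
  once per target;
* for multi-worker runs the ``k`` target segments are grouped into ``m``
  *supersegments*, one per worker; every worker sees the full predictor
  matrix and only its own targets, and the per-worker results are merged.

The tiling never changes which pairs are scored or how, so results are
bit-identical for every choice of ``targets_per_block`` and ``m`` — a
property the test suite leans on heavily.  Gene counts that do not divide
evenly are padded with constant "dummy" genes, which are excluded from
scoring and from results.
"""

from __future__ import annotations

import itertools
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .criterion import pairwise_mce
from .errors import AlignmentError, ConfigurationError
from .io import ExpressionMatrix, lag_align, pad_dummy_genes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tiling plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingPlan:
    """Partition of targets/predictors into segments, blocks and workers.

    ``n`` is the (padded) gene count, ``k`` the number of blocks (= target
    segments), ``m`` the worker count.  Predictor segments number ``2k`` and
    are contiguous near-equal ranges; supersegments group ``k/m`` consecutive
    target segments per worker.
    """

    n: int
    n_original: int
    k: int
    m: int
    targets_per_block: int
    target_segments: tuple[tuple[int, int], ...]
    predictor_segments: tuple[tuple[int, int], ...]
    supersegments: tuple[tuple[int, ...], ...]

    @property
    def n_tiles_per_block(self) -> int:
        two_k = 2 * self.k
        return two_k * (two_k + 1) // 2


def _split_ranges(n: int, parts: int) -> list[tuple[int, int]]:
    """Contiguous near-equal half-open ranges (first ``n % parts`` get +1)."""
    base, extra = divmod(n, parts)
    out, start = [], 0
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        out.append((start, start + size))
        start += size
    return out


def make_tiling_plan(n: int, targets_per_block: int, m: int = 1) -> TilingPlan:
    """Build the segment/supersegment layout for ``n`` genes.

    ``n`` is padded up to a multiple of ``targets_per_block * m`` so that the
    ``k = n / targets_per_block`` blocks divide evenly among the ``m``
    workers.
    """
    if targets_per_block < 1:
        raise ConfigurationError("targets_per_block must be >= 1")
    if m < 1:
        raise ConfigurationError("worker count m must be >= 1")
    if targets_per_block > n:
        raise ConfigurationError(
            f"targets_per_block={targets_per_block} exceeds gene count n={n}"
        )
    unit = targets_per_block * m
    n_padded = -(-n // unit) * unit
    k = n_padded // targets_per_block
    target_segments = tuple(_split_ranges(n_padded, k))
    predictor_segments = tuple(_split_ranges(n_padded, 2 * k))
    per_worker = k // m
    supersegments = tuple(
        tuple(range(w * per_worker, (w + 1) * per_worker)) for w in range(m)
    )
    return TilingPlan(
        n=n_padded,
        n_original=n,
        k=k,
        m=m,
        targets_per_block=targets_per_block,
        target_segments=target_segments,
        predictor_segments=predictor_segments,
        supersegments=supersegments,
    )


# ---------------------------------------------------------------------------
# configuration, counters, results
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Knobs of the pair search.

    ``lag=None`` resolves to 1 on temporal matrices (first-order Markov
    pairing) and 0 otherwise.  Self-loops (a target predicting itself) are
    excluded by default; enable them for temporal data where
    autoregulation is plausible.  ``tie_tol`` widens the tie set to pairs
    within the tolerance of the minimum (0 = exact float equality; scores for
    a given pair are bit-identical across schedules, so exact equality is
    well-defined).
    """

    lag: int | None = None
    allow_self_loops: bool = False
    tie_tol: float = 0.0

    def resolve_lag(self, matrix: ExpressionMatrix) -> int:
        if self.lag is not None:
            return self.lag
        return 1 if matrix.is_temporal else 0


@dataclass
class SearchCounters:
    """Instrumentation mirroring the abstract transfer/evaluation model."""

    pair_evaluations: int = 0
    target_segment_loads: dict[int, int] = field(default_factory=dict)
    predictor_segment_loads: dict[int, int] = field(default_factory=dict)

    def merge(self, other: "SearchCounters") -> None:
        self.pair_evaluations += other.pair_evaluations
        for b, c in other.target_segment_loads.items():
            self.target_segment_loads[b] = self.target_segment_loads.get(b, 0) + c
        for b, c in other.predictor_segment_loads.items():
            self.predictor_segment_loads[b] = self.predictor_segment_loads.get(b, 0) + c


@dataclass(frozen=True)
class PairScore:
    """One scored candidate pair for one target (``p1 < p2``, MCE in bits)."""

    target: int
    pair: tuple[int, int]
    mce: float


@dataclass
class InferenceResult:
    """Per-target minimal-MCE predictor pairs — the inferred network.

    ``best_mce[t]`` is the minimal score for real target ``t`` and
    ``ties[t]`` the lexicographically sorted list of all pairs attaining it
    (gene indices refer to ``gene_names``).  Dummy padding genes are retained
    in ``gene_names``/``dummy_mask`` for bookkeeping but never appear as
    targets or predictors.
    """

    gene_names: list[str]
    dummy_mask: np.ndarray
    target_indices: list[int]
    best_mce: np.ndarray
    ties: list[list[tuple[int, int]]]
    provenance: dict
    counters: SearchCounters | None = None

    def to_rows(self) -> list[tuple[str, str, str, float]]:
        """Flatten to (target, predictor1, predictor2, mce) name rows."""
        rows = []
        for t, mce, tie in zip(self.target_indices, self.best_mce, self.ties):
            for p1, p2 in tie:
                rows.append(
                    (self.gene_names[t], self.gene_names[p1], self.gene_names[p2], float(mce))
                )
        return rows

    def file_provenance(self) -> dict:
        """Provenance written to output files.

        Execution-layout keys (k, m, targets_per_block) are deliberately kept
        out: the schedule provably does not affect the result, and output
        files must be identical however the run was partitioned.
        """
        skip = {"k", "m", "targets_per_block"}
        return {k: v for k, v in self.provenance.items() if k not in skip}

    def pairs_by_name(self) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list[tuple[str, str]]] = {}
        for t, tie in zip(self.target_indices, self.ties):
            out[self.gene_names[t]] = [
                (self.gene_names[p1], self.gene_names[p2]) for p1, p2 in tie
            ]
        return out


class _BestTracker:
    """Running (min MCE, tie list) per target — O(1) state per target.

    With ``tie_tol > 0`` candidates within the tolerance of the running
    minimum are retained and pruned once the final minimum is known.
    """

    def __init__(self, targets: list[int], tie_tol: float = 0.0) -> None:
        self.tie_tol = float(tie_tol)
        self.best: dict[int, float] = {t: np.inf for t in targets}
        self.cands: dict[int, list[tuple[float, int, int]]] = {t: [] for t in targets}

    def update(self, t: int, mce: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> None:
        if mce.size == 0:
            return
        mmin = float(mce.min())
        best = self.best[t]
        if mmin < best:
            self.best[t] = best = mmin
        keep = mce <= best + self.tie_tol
        if keep.any():
            self.cands[t].extend(
                zip(mce[keep].tolist(), p1[keep].tolist(), p2[keep].tolist())
            )
            if len(self.cands[t]) > 4096:
                self._prune(t)

    def _prune(self, t: int) -> None:
        cut = self.best[t] + self.tie_tol
        self.cands[t] = [c for c in self.cands[t] if c[0] <= cut]

    def finalize(self, t: int) -> tuple[float, list[tuple[int, int]]]:
        self._prune(t)
        ties = sorted((p1, p2) for _, p1, p2 in self.cands[t])
        return self.best[t], ties


# ---------------------------------------------------------------------------
# search proper
# ---------------------------------------------------------------------------

def _tile_pairs(
    seg1: tuple[int, int],
    seg2: tuple[int, int],
    diagonal: bool,
    real: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Global (p1, p2) index arrays for one tile, dummies removed.

    Off-diagonal tiles take the full cross product (``p1 < p2`` holds because
    segments are contiguous and ascending); the diagonal tile takes the strict
    upper triangle so no unordered pair is scored twice.
    """
    a = np.arange(seg1[0], seg1[1])[real[seg1[0]:seg1[1]]]
    if diagonal:
        if a.size < 2:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        iu, ju = np.triu_indices(a.size, k=1)
        return a[iu], a[ju]
    b = np.arange(seg2[0], seg2[1])[real[seg2[0]:seg2[1]]]
    if a.size == 0 or b.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    p1 = np.repeat(a, b.size)
    p2 = np.tile(b, a.size)
    return p1, p2


def local_exhaustive_search(
    target_idx: list[int],
    target_codes: np.ndarray,
    pred_codes: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    tracker: _BestTracker,
    *,
    n_states: int,
    allow_self_loops: bool,
    counters: SearchCounters | None = None,
) -> None:
    """Score one tile's predictor pairs against one block's targets.

    ``target_codes`` holds the (lagged) encoded target rows for
    ``target_idx``; ``pred_codes`` the full encoded predictor matrix
    (genes x aligned samples).  The tracker's running minima/ties are updated
    in place.
    """
    if p1.size == 0 or len(target_idx) == 0:
        return
    if target_codes.shape[1] != pred_codes.shape[1]:
        raise AlignmentError("target and predictor views have different sample counts")
    mce = pairwise_mce(target_codes, pred_codes[p1], pred_codes[p2], n_states)
    for row, t in enumerate(target_idx):
        if allow_self_loops:
            valid = slice(None)
            n_valid = p1.size
        else:
            valid = (p1 != t) & (p2 != t)
            n_valid = int(valid.sum())
        tracker.update(t, mce[row][valid], p1[valid], p2[valid])
        if counters is not None:
            counters.pair_evaluations += n_valid


def _search_blocks(
    matrix: ExpressionMatrix,
    plan: TilingPlan,
    config: SearchConfig,
    blocks: list[int],
) -> tuple[dict[int, tuple[float, list[tuple[int, int]]]], SearchCounters]:
    """Run the tiled schedule for the given block indices (one worker's share)."""
    lag = config.resolve_lag(matrix)
    pred_rows, targ_rows = lag_align(matrix, lag)
    enc = {state: i for i, state in enumerate(matrix.alphabet)}
    pred_codes = np.empty((matrix.n_genes, pred_rows.shape[0]), dtype=np.int64)
    targ_codes_full = np.empty((matrix.n_genes, targ_rows.shape[0]), dtype=np.int64)
    for state, code in enc.items():
        pred_codes[(pred_rows == state).T] = code
        targ_codes_full[(targ_rows == state).T] = code
    real = ~matrix.dummy_mask
    counters = SearchCounters()
    results: dict[int, tuple[float, list[tuple[int, int]]]] = {}
    two_k = 2 * plan.k
    for b in blocks:
        lo, hi = plan.target_segments[b]
        targets = [t for t in range(lo, hi) if real[t]]
        tracker = _BestTracker(targets, config.tie_tol)
        target_codes = targ_codes_full[targets]
        # one load of the block's target segment, then the tile schedule
        counters.target_segment_loads[b] = counters.target_segment_loads.get(b, 0) + 1
        counters.predictor_segment_loads.setdefault(b, 0)
        for j1 in range(two_k):
            counters.predictor_segment_loads[b] += 1  # P_j1 transfer
            for j2 in range(j1, two_k):
                counters.predictor_segment_loads[b] += 1  # P_j2 transfer
                p1, p2 = _tile_pairs(
                    plan.predictor_segments[j1],
                    plan.predictor_segments[j2],
                    diagonal=(j1 == j2),
                    real=real,
                )
                local_exhaustive_search(
                    targets,
                    target_codes,
                    pred_codes,
                    p1,
                    p2,
                    tracker,
                    n_states=matrix.n_states,
                    allow_self_loops=config.allow_self_loops,
                    counters=counters,
                )
        for t in targets:
            results[t] = tracker.finalize(t)
    return results, counters


def global_exhaustive_search(
    matrix: ExpressionMatrix,
    plan: TilingPlan,
    config: SearchConfig | None = None,
    *,
    blocks: list[int] | None = None,
) -> InferenceResult:
    """Run the full tiled schedule (all blocks, or a caller-chosen subset)."""
    config = config or SearchConfig()
    if matrix.n_genes != plan.n:
        raise ConfigurationError(
            f"plan expects {plan.n} genes (after padding), matrix has {matrix.n_genes}"
        )
    if blocks is None:
        blocks = list(range(plan.k))
    results, counters = _search_blocks(matrix, plan, config, blocks)
    return _assemble(matrix, plan, config, results, counters)


def _assemble(matrix, plan, config, results, counters) -> InferenceResult:
    targets = sorted(results)
    best = np.array([results[t][0] for t in targets], dtype=float)
    ties = [results[t][1] for t in targets]
    prov = {
        "tool": "mcenet",
        "version": _pkg_version,
        "alphabet": ",".join(str(a) for a in matrix.alphabet),
        "lag": config.resolve_lag(matrix),
        "allow_self_loops": config.allow_self_loops,
        "tie_tol": config.tie_tol,
        "n_genes": matrix.n_real_genes,
        "k": plan.k,
        "m": plan.m,
        "targets_per_block": plan.targets_per_block,
    }
    return InferenceResult(
        gene_names=list(matrix.gene_names),
        dummy_mask=matrix.dummy_mask.copy(),
        target_indices=targets,
        best_mce=best,
        ties=ties,
        provenance=prov,
        counters=counters,
    )


def _worker_entry(args):
    matrix, plan, config, blocks = args
    return _search_blocks(matrix, plan, config, blocks)


def run_inference(
    matrix: ExpressionMatrix,
    targets_per_block: int = 128,
    m: int = 1,
    config: SearchConfig | None = None,
    *,
    parallel: bool = False,
) -> InferenceResult:
    """Top-level driver: pad, plan, dispatch supersegments to workers, merge.

    Every worker receives the full predictor matrix and one supersegment of
    targets; results are merged target-wise.  Output is bit-identical for any
    ``m`` and ``targets_per_block``.  With ``parallel=True`` the ``m``
    supersegments run in separate processes; by default they run serially
    (the partitioning is a data contract, not a concurrency requirement).
    """
    config = config or SearchConfig()
    if matrix.n_real_genes < (2 if config.allow_self_loops else 3):
        raise ConfigurationError("pair search needs at least 3 genes (2 with self-loops)")
    plan = make_tiling_plan(matrix.n_genes, targets_per_block, m)
    padded = pad_dummy_genes(matrix, plan.n) if plan.n != matrix.n_genes else matrix
    work = [
        (padded, plan, config, [b for b in superseg])
        for superseg in plan.supersegments
    ]
    if parallel and m > 1:
        with ProcessPoolExecutor(max_workers=m) as pool:
            worker_out = list(pool.map(_worker_entry, work))
    else:
        worker_out = [_search_blocks(*w) for w in work]
    results: dict[int, tuple[float, list[tuple[int, int]]]] = {}
    counters = SearchCounters()
    for part, cnt in worker_out:
        overlap = set(results) & set(part)
        if overlap:
            raise ConfigurationError(f"targets assigned to two workers: {sorted(overlap)[:5]}")
        results.update(part)
        counters.merge(cnt)
    logger.info(
        "scored %d pairs over %d targets (k=%d, m=%d)",
        counters.pair_evaluations, len(results), plan.k, plan.m,
    )
    return _assemble(padded, plan, config, results, counters)


# ---------------------------------------------------------------------------
# reference implementation
# ---------------------------------------------------------------------------

BRUTE_FORCE_GUARD = 512


def brute_force_oracle(
    matrix: ExpressionMatrix,
    config: SearchConfig | None = None,
) -> InferenceResult:
    """Direct triple loop over targets and all unordered predictor pairs.

    No tiling, no blocking — the reference the scheduled search is tested
    against.  Guarded to small ``n``; this is a correctness tool, not the
    production path.
    """
    config = config or SearchConfig()
    if matrix.n_genes > BRUTE_FORCE_GUARD:
        raise ConfigurationError(
            f"brute force is limited to n <= {BRUTE_FORCE_GUARD} genes"
        )
    lag = config.resolve_lag(matrix)
    pred_rows, targ_rows = lag_align(matrix, lag)
    enc = {state: i for i, state in enumerate(matrix.alphabet)}
    pred_codes = np.empty((matrix.n_genes, pred_rows.shape[0]), dtype=np.int64)
    targ_codes = np.empty((matrix.n_genes, targ_rows.shape[0]), dtype=np.int64)
    for state, code in enc.items():
        pred_codes[(pred_rows == state).T] = code
        targ_codes[(targ_rows == state).T] = code
    real_idx = np.flatnonzero(~matrix.dummy_mask)
    counters = SearchCounters()
    results: dict[int, tuple[float, list[tuple[int, int]]]] = {}
    all_p1, all_p2 = [], []
    for i, j in itertools.combinations(range(real_idx.size), 2):
        all_p1.append(real_idx[i])
        all_p2.append(real_idx[j])
    p1 = np.array(all_p1, dtype=np.int64)
    p2 = np.array(all_p2, dtype=np.int64)
    for t in real_idx:
        tracker = _BestTracker([int(t)], config.tie_tol)
        local_exhaustive_search(
            [int(t)],
            targ_codes[[t]],
            pred_codes,
            p1,
            p2,
            tracker,
            n_states=matrix.n_states,
            allow_self_loops=config.allow_self_loops,
            counters=counters,
        )
        results[int(t)] = tracker.finalize(int(t))
    plan = make_tiling_plan(matrix.n_genes, matrix.n_genes, 1)
    return _assemble(matrix, plan, config, results, counters)
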