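"""Analytic transfer-cost model of the blocked schedule.

The tiled search trades redundant loads of small predictor segments for not
re-reading whole gene columns from slow (global) memory.  This module gives
the closed-form segment/gene transfer counts of that schedule, in abstract
units (one segment or gene load = 1); it deliberately models no bandwidth,
occupancy or runtime.

Per block, the tile loop ``j1 = 0..2k-1``, ``j2 = j1..2k-1`` transfers one
``P_j1`` segment per outer iteration and one ``P_j2`` segment per inner
iteration:

    sum_{j1=0}^{2k-1} (2k - j1 + 1) = 2 + 3 + ... + (2k + 1) = 2k^2 + 3k,

plus a single load of the block's target segment.  With ``k`` blocks and
``n/2k`` genes per predictor segment, total gene transfers are

    k * (n/2k) * (2k^2 + 3k + 1) = n * (k^2 + 3k/2 + 1/2),

i.e. O(n k^2) — each gene is moved O(k^2) times instead of O(n^2) times
without segmentation, a reduction by a factor of (n/k)^2.

The warp/coalescing width ``w`` (32 on the hardware the schedule was designed
around) is carried as metadata only; no count here depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .search import make_tiling_plan

#: Coalescing width kept as metadata; segment sizes that are multiples of it
#: make hardware transfers efficient, but no transfer count depends on it.
COALESCING_WIDTH = 32


@dataclass(frozen=True)
class TransferEstimate:
    """Closed-form transfer counts for one (n, k) configuration."""

    n: int
    k: int
    per_block_segment_transfers: int
    total_gene_transfers: int
    unsegmented_gene_transfers: int
    ratio_unsegmented_to_segmented: float
    coalescing_width: int = COALESCING_WIDTH


def transfers_per_block(k: int) -> int:
    """Predictor-segment transfers per block for a run with ``k`` blocks.

    Excludes the single target-segment load (the companion total below adds
    it back as the ``+1`` inside the parenthesis).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    return 2 * k * k + 3 * k


def total_gene_transfers(n: int, k: int) -> int:
    """Total gene loads across all ``k`` blocks: ``n (k^2 + 3k/2 + 1/2)``.

    Requires ``n`` divisible by ``2k`` (equal predictor segments of size
    ``n/2k``); equals ``k * (n/2k) * (2k^2 + 3k + 1)``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n < 1 or n % (2 * k):
        raise ConfigurationError(f"n={n} must be a positive multiple of 2k={2 * k}")
    return k * (n // (2 * k)) * (2 * k * k + 3 * k + 1)


def unsegmented_ratio(n: int, k: int) -> float:
    """How many times more gene loads an unsegmented O(n^3) scheme needs: ``(n/k)^2``."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n < 1 or n % k:
        raise ConfigurationError(f"n={n} must be a positive multiple of k={k}")
    return float((n // k) ** 2)


def estimate_transfers(n: int, targets_per_block: int, m: int = 1) -> TransferEstimate:
    """Full estimate for a run layout, padding ``n`` exactly as the search does."""
    plan = make_tiling_plan(n, targets_per_block, m)
    n_eff, k = plan.n, plan.k
    # pad further if the equal-predictor-segment assumption needs it
    if n_eff % (2 * k):
        n_eff = -(-n_eff // (2 * k)) * (2 * k)
    total = total_gene_transfers(n_eff, k)
    ratio = unsegmented_ratio(n_eff, k)
    return TransferEstimate(
        n=n_eff,
        k=k,
        per_block_segment_transfers=transfers_per_block(k),
        total_gene_transfers=total,
        unsegmented_gene_transfers=int(total * ratio),
        ratio_unsegmented_to_segmented=ratio,
    )
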