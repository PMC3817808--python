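"""Entropy criterion for predictor-pair evaluation.

For a target gene Y and a candidate predictor pair X = (X1, X2), the score is
the mean conditional entropy (MCE)

    H(Y | X) = sum_x P(X = x) H(Y | X = x),
    H(Y | X = x) = - sum_y P(Y = y | X = x) log2 P(Y = y | X = x),

with all probabilities the plug-in (maximum-likelihood) estimates from a joint
count table over the aligned samples.  Lower MCE means the pair explains the
target better; MCE = 0 means the pair determines the target exactly in the
data.  Entropies are in bits (log base 2); the base rescales every score by
the same factor, so pair rankings do not depend on it.

Conventions: ``0 * log 0 == 0`` and unobserved predictor configurations
contribute nothing — both fall out of the weighted sum naturally.  No
pseudo-counts are applied by default; an optional additive smoothing parameter
exists for users who want to penalize sparsely observed configurations.

The count table is a dense ``|alphabet| x |alphabet|^2`` array (8 or 27 cells)
— small enough to live in registers, which is the design point the blocked
search schedule is built around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import AlignmentError, DistributionError, ValidationError

_LN2 = math.log(2.0)


@dataclass
class CountTable:
    """Joint counts of a target's value vs. a predictor-pair configuration.

    ``counts[y, x1, x2]`` is the number of aligned samples in which the target
    took state index ``y`` while the predictors took state indices
    ``(x1, x2)``; indices follow the order of ``alphabet``.
    """

    counts: np.ndarray
    alphabet: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        a = len(self.alphabet)
        if self.counts.shape != (a, a, a):
            raise ValidationError(
                f"count table shape {self.counts.shape} does not match alphabet size {a}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.total <= 0:
            raise ValidationError("count table must cover at least one sample")
        if int(self.counts.sum()) != self.total:
            raise ValidationError("counts do not sum to total")

    def config_index(self, x: tuple[int, int]) -> tuple[int, int]:
        lut = {state: i for i, state in enumerate(self.alphabet)}
        try:
            return lut[x[0]], lut[x[1]]
        except KeyError as exc:
            raise ValidationError(f"configuration {x} outside alphabet {self.alphabet}") from exc


def _encode(vec: np.ndarray, alphabet: tuple[int, ...]) -> np.ndarray:
    vec = np.asarray(vec)
    out = np.full(vec.shape, -1, dtype=np.int64)
    for code, state in enumerate(alphabet):
        out[vec == state] = code
    if (out < 0).any():
        bad = vec[out < 0][0]
        raise ValidationError(f"value {bad} outside alphabet {alphabet}")
    return out


def build_count_table(target, pred1, pred2, alphabet: tuple[int, ...]) -> CountTable:
    """Tally the joint (target, predictor-pair) configuration counts.

    Sample order is irrelevant; the three vectors must be aligned (equal
    length >= 1).
    """
    y = _encode(target, alphabet)
    x1 = _encode(pred1, alphabet)
    x2 = _encode(pred2, alphabet)
    if not (y.shape == x1.shape == x2.shape) or y.ndim != 1:
        raise AlignmentError(
            f"vector lengths differ: {y.shape}, {x1.shape}, {x2.shape}"
        )
    if y.size == 0:
        raise AlignmentError("cannot build a count table from empty vectors")
    a = len(alphabet)
    code = (y * a + x1) * a + x2
    counts = np.bincount(code, minlength=a * a * a).reshape(a, a, a)
    return CountTable(counts=counts, alphabet=tuple(alphabet), total=int(y.size))


def shannon_entropy(dist) -> float:
    """Shannon entropy of a probability vector, in bits (``-sum p log2 p``)."""
    p = np.asarray(dist, dtype=float)
    if (p < 0).any():
        raise DistributionError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DistributionError(f"probabilities sum to {p.sum()!r}, not 1")
    return float(-xlogy(p, p).sum() / _LN2)


def conditional_entropy(table: CountTable, x: tuple[int, int]) -> float:
    """Entropy of the target's empirical distribution given configuration ``x``.

    ``x`` is a pair of alphabet states.  An unobserved configuration returns 0
    (it carries no weight in the mean).
    """
    i1, i2 = table.config_index(x)
    col = table.counts[:, i1, i2].astype(float)
    n_x = col.sum()
    if n_x == 0:
        return 0.0
    return float((xlogy(n_x, n_x) - xlogy(col, col).sum()) / (n_x * _LN2))


def mce_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized MCE over count tables of shape ``(..., A, n_configs)``.

    The trailing two axes index (target state, predictor configuration).  For
    total sample count N, per-configuration count n_x and cell count c_{y,x},

        MCE = [ sum_x n_x log2 n_x  -  sum_{y,x} c_{y,x} log2 c_{y,x} ] / N,

    which is algebraically the weighted average of conditional entropies and
    handles empty cells/configurations through ``xlogy(0, 0) == 0``.  All
    callers (scalar API, tiled search, brute-force reference) share this one
    kernel, so equal count tables always produce bit-identical scores.
    """
    counts = np.asarray(counts, dtype=np.float64)
    cfg_totals = counts.sum(axis=-2)
    totals = cfg_totals.sum(axis=-1)
    # subtract per configuration so a determined configuration cancels to an
    # exact 0.0 (a single global difference would leave rounding residue and
    # perfectly predicted targets would not score exactly zero)
    per_cfg = xlogy(cfg_totals, cfg_totals) - xlogy(counts, counts).sum(axis=-2)
    return per_cfg.sum(axis=-1) / (totals * _LN2)


def mean_conditional_entropy(table: CountTable, pseudocount: float = 0.0) -> float:
    """Mean conditional entropy of the table, in bits.

    ``pseudocount`` adds a constant to every cell before estimating the
    probabilities (off by default: the plug-in estimate is the stated model).
    """
    a = len(table.alphabet)
    counts = table.counts.reshape(a, a * a).astype(np.float64)
    if pseudocount:
        counts = counts + float(pseudocount)
    return float(mce_from_counts(counts[np.newaxis])[0])


def pairwise_mce(
    target_codes: np.ndarray,
    pred1_codes: np.ndarray,
    pred2_codes: np.ndarray,
    n_states: int,
) -> np.ndarray:
    """MCE for many (target, pair) combinations in one shot.

    Parameters
    ----------
    target_codes
        ``(n_targets, s)`` encoded target rows (codes ``0..n_states-1``).
    pred1_codes, pred2_codes
        ``(n_pairs, s)`` encoded, lag-aligned predictor rows.

    Returns
    -------
    ``(n_targets, n_pairs)`` array of MCE values in bits.
    """
    y = np.atleast_2d(target_codes)
    c1 = np.atleast_2d(pred1_codes)
    c2 = np.atleast_2d(pred2_codes)
    if c1.shape != c2.shape or y.shape[1] != c1.shape[1]:
        raise AlignmentError("target and predictor views must share the sample axis")
    n_cfg = n_states * n_states
    n_cell = n_states * n_cfg
    cfg = c1 * n_states + c2                       # (n_pairs, s)
    code = y[:, None, :] * n_cfg + cfg[None, :, :]  # (n_targets, n_pairs, s)
    nt, npairs, _ = code.shape
    offset = np.arange(nt * npairs, dtype=np.int64).reshape(nt, npairs, 1) * n_cell
    counts = np.bincount((code + offset).ravel(), minlength=nt * npairs * n_cell)
    counts = counts.reshape(nt, npairs, n_states, n_cfg)
    return mce_from_counts(counts)
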