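"""Shared fixtures and the independent entropy oracle used across tests."""

import math
from collections import Counter

import numpy as np
import pytest

from mcenet import BINARY, TERNARY, ExpressionMatrix


def naive_mce(target, pred1, pred2) -> float:
    """Direct evaluation of the criterion formulas from raw vectors.

    Independent of the package's count-table kernel: empirical probabilities
    via Counter, H(Y|X=x) = -sum_y P(y|x) log2 P(y|x), then the P(x)-weighted
    average.  Used as the reference the fast path must match to 1e-12.
    """
    target = list(target)
    n = len(target)
    pair_counts = Counter(zip(pred1, pred2))
    mce = 0.0
    for x, n_x in sorted(pair_counts.items()):
        y_counts = Counter(
            y for y, a, b in zip(target, pred1, pred2) if (a, b) == x
        )
        h = 0.0
        for c in y_counts.values():
            p = c / n_x
            h -= p * math.log2(p)
        mce += (n_x / n) * h
    return mce


def naive_best_pairs(values, alphabet, lag=0, rtol=1e-12):
    """Triple-loop reference: per-target minimal naive MCE and its tie set."""
    s, n = values.shape
    pred = values[: s - lag] if lag else values
    targ = values[lag:] if lag else values
    out = {}
    for t in range(n):
        scores = {}
        for p1 in range(n):
            for p2 in range(p1 + 1, n):
                if t in (p1, p2):
                    continue
                scores[(p1, p2)] = naive_mce(targ[:, t], pred[:, p1], pred[:, p2])
        best = min(scores.values())
        ties = sorted(p for p, v in scores.items() if v <= best + rtol * max(1.0, best) + 1e-15)
        out[t] = (best, ties)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_binary_matrix(rng):
    """16 genes x 30 temporal binary samples of random data."""
    return ExpressionMatrix(
        values=rng.integers(0, 2, size=(30, 16)),
        gene_names=[f"g{j}" for j in range(16)],
        alphabet=BINARY,
        is_temporal=True,
    )


@pytest.fixture
def small_ternary_matrix(rng):
    """12 genes x 24 ternary samples of random data."""
    return ExpressionMatrix(
        values=rng.integers(-1, 2, size=(24, 12)),
        gene_names=[f"g{j}" for j in range(12)],
        alphabet=TERNARY,
        is_temporal=True,
    )
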